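"""Light schedules, experimental protocols, and activity traces.

Time conventions
----------------
All within-package time arithmetic is in *minutes from recording start*;
no calendar or DST handling.  Recording days are anchored at lights-on of
the first LD phase (Zeitgeber time 0), so day ``d`` covers minutes
``[d*1440, (d+1)*1440)``.  Clock times ("hh:mm") appear only in schedule
definitions and in the trace's ``start_clock`` annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MIN_PER_DAY = 1440


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def parse_clock(clock: str) -> int:
    """Parse 'hh:mm' into minutes past midnight."""
    try:
        hh, mm = clock.split(":")
        minutes = int(hh) * 60 + int(mm)
    except Exception as exc:  # noqa: BLE001 - re-raise uniformly
        raise ValidationError(f"bad clock time {clock!r}; expected 'hh:mm'") from exc
    if not 0 <= minutes < MIN_PER_DAY:
        raise ValidationError(f"clock time {clock!r} out of range")
    return minutes


def format_clock(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass(frozen=True)
class Phase:
    """One contiguous block of the protocol (e.g. a week of DD)."""

    label: str
    regime: str  # "LD" or "DD"
    n_days: int
    lights_on_clock: str = "07:00"
    lights_off_clock: str = "19:00"

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValidationError(f"regime must be 'LD' or 'DD', got {self.regime!r}")
        if self.n_days <= 0:
            raise ValidationError("n_days must be positive")
        if self.regime == "LD":
            on = parse_clock(self.lights_on_clock)
            off = parse_clock(self.lights_off_clock)
            # light interval + dark interval must tile the 24 h day
            if on == off:
                raise ValidationError("lights-on and lights-off must differ")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, contiguous sequence of LD/DD phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValidationError("schedule needs at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_days(self) -> int:
        return sum(p.n_days for p in self.phases)

    @property
    def total_minutes(self) -> int:
        return self.total_days * MIN_PER_DAY

    def phase_labels(self) -> list[str]:
        return [p.label for p in self.phases]

    def phase_bounds_min(self) -> list[tuple[int, int]]:
        """(start, end) minutes-from-recording-start for each phase."""
        bounds = []
        start = 0
        for p in self.phases:
            end = start + p.n_days * MIN_PER_DAY
            bounds.append((start, end))
            start = end
        return bounds

    def phase_span(self, label: str) -> tuple[int, int]:
        for p, (lo, hi) in zip(self.phases, self.phase_bounds_min()):
            if p.label == label:
                return lo, hi
        raise ValidationError(
            f"unknown phase {label!r}; available: {self.phase_labels()}"
        )

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise ValidationError(
            f"unknown phase {label!r}; available: {self.phase_labels()}"
        )

    def anchor_clock_min(self) -> int:
        """Lights-on clock of the first LD phase (ZT0 anchor), minutes
        past midnight.  Falls back to 07:00 for all-DD schedules."""
        for p in self.phases:
            if p.regime == "LD":
                return parse_clock(p.lights_on_clock)
        return parse_clock("07:00")

    def dark_mask(self, t_min: np.ndarray, start_clock_min: int) -> np.ndarray:
        """Boolean darkness indicator for sample times ``t_min`` (minutes
        from recording start) given the recording's start clock time."""
        t_min = np.asarray(t_min)
        dark = np.ones(t_min.shape, dtype=bool)  # DD default
        clock = (start_clock_min + t_min) % MIN_PER_DAY
        for p, (lo, hi) in zip(self.phases, self.phase_bounds_min()):
            in_phase = (t_min >= lo) & (t_min < hi)
            if p.regime == "LD":
                on = parse_clock(p.lights_on_clock)
                off = parse_clock(p.lights_off_clock)
                if on < off:
                    light = (clock >= on) & (clock < off)
                else:  # lights span midnight
                    light = (clock >= on) | (clock < off)
                dark[in_phase] = ~light[in_phase]
        return dark

    def slice_days(self, day_lo: int, day_hi: int) -> "LightSchedule":
        """Sub-schedule covering protocol days [day_lo, day_hi)."""
        phases = []
        start = 0
        for p in self.phases:
            end = start + p.n_days
            ov_lo, ov_hi = max(start, day_lo), min(end, day_hi)
            if ov_hi > ov_lo:
                phases.append(replace(p, n_days=ov_hi - ov_lo))
            start = end
        if not phases:
            raise ValidationError("requested day range is empty")
        return LightSchedule(tuple(phases))


@dataclass(frozen=True)
class Intervention:
    """A dosing window: daily (cadence_days=1) or every other day (2)."""

    label: str
    start_day: int
    end_day: int
    cadence_days: int = 1

    def __post_init__(self) -> None:
        if self.cadence_days <= 0:
            raise ValidationError("cadence_days must be positive")
        if self.end_day < self.start_day:
            raise ValidationError("end_day must be >= start_day")


@dataclass(frozen=True)
class Protocol:
    schedule: LightSchedule
    interventions: tuple[Intervention, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "interventions", tuple(self.interventions))
        for iv in self.interventions:
            if iv.start_day < 0 or iv.end_day > self.schedule.total_days:
                raise ValidationError(
                    f"intervention {iv.label!r} lies outside the schedule span"
                )

    @property
    def total_days(self) -> int:
        return self.schedule.total_days


@dataclass
class ActivityTrace:
    """Equally-spaced locomotor activity counts for one animal.

    ``counts`` is a float array; missing samples are NaN, never zero
    (zero is a valid no-movement observation).
    """

    animal_id: str
    group: str
    start_clock: str
    sampling_interval_min: float
    counts: np.ndarray
    schedule: LightSchedule

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValidationError("counts must be one-dimensional")
        if np.nanmin(self.counts, initial=0.0) < 0:
            raise ValidationError("counts must be non-negative")
        if self.sampling_interval_min <= 0:
            raise ValidationError("sampling_interval_min must be positive")

    @property
    def n_samples(self) -> int:
        return self.counts.size

    @property
    def total_minutes(self) -> float:
        return self.n_samples * self.sampling_interval_min

    @property
    def n_days(self) -> float:
        return self.total_minutes / MIN_PER_DAY

    def times_min(self) -> np.ndarray:
        """Sample start times in minutes from recording start."""
        return np.arange(self.n_samples) * self.sampling_interval_min

    def n_missing(self) -> int:
        return int(np.isnan(self.counts).sum())

    def imputed(self) -> "ActivityTrace":
        """Missing samples replaced by the trace mean (NaN-aware)."""
        if self.n_missing() == 0:
            return self
        counts = self.counts.copy()
        fill = np.nanmean(counts) if np.isfinite(np.nanmean(counts)) else 0.0
        counts[np.isnan(counts)] = fill
        return replace_trace(self, counts=counts)


def replace_trace(trace: ActivityTrace, **kwargs) -> ActivityTrace:
    fields = dict(
        animal_id=trace.animal_id,
        group=trace.group,
        start_clock=trace.start_clock,
        sampling_interval_min=trace.sampling_interval_min,
        counts=trace.counts,
        schedule=trace.schedule,
    )
    fields.update(kwargs)
    return ActivityTrace(**fields)


@dataclass
class DoublePlotMatrix:
    """Double-plotted actogram raster: row d = day d followed by day d+1.

    ``light_mask`` matches ``values`` in shape with 1 marking darkness,
    enabling the conventional gray shading of actogram figures.
    """

    bin_min: float
    values: np.ndarray  # days x (2 * bins_per_day), NaN-padded
    light_mask: np.ndarray
    day_labels: list[int]

    @property
    def bins_per_day(self) -> int:
        return self.values.shape[1] // 2


def seven_week_protocol() -> Protocol:
    """The 7-week LD/DD study design used throughout the package.

    Week 1 habituation (LD), Week 2 daily chemotherapy dosing (LD),
    Week 3 daily dosing (DD), Weeks 4-5 treatment every other day (DD),
    Week 6 intensive observation (DD), Week 7 observation (LD).
    Lights on 07:00, off 19:00 in LD weeks.
    """
    phases = (
        Phase("Habituation", "LD", 7),
        Phase("CTX-LD", "LD", 7),
        Phase("CTX-DD", "DD", 7),
        Phase("Treatment-1", "DD", 7),
        Phase("Treatment-2", "DD", 7),
        Phase("Observ.", "DD", 7),
        Phase("Observ.-LD", "LD", 7),
    )
    interventions = (
        Intervention("CTX", start_day=7, end_day=21, cadence_days=1),
        Intervention("treatment", start_day=21, end_day=35, cadence_days=2),
    )
    return Protocol(LightSchedule(phases), interventions)
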