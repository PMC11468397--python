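"""Synthetic locomotor-activity cohorts.

The generator is phenomenological: per-minute counts follow an
inhomogeneous Poisson (optionally gamma-overdispersed) process whose
rate is a mean-one circadian waveform,

    lambda(t) = baseline_rate * [1 - A_eff(t) + 2 * A_eff(t) * w(phi(t))]

with ``w`` a raised-cosine activity bout occupying ``active_fraction``
of the cycle and normalised to cycle-mean 1/2, so the time-averaged
rate equals ``baseline_rate`` for every modulation depth.  The phase
``phi`` is locked to lights-off (+ ``psi_h``) during LD and free-runs
at the animal's intrinsic period tau_i during DD; tau_i is drawn once
per animal.  Disruption (chemotherapy-like) multiplies the amplitude
and adds per-animal period jitter from its onset day; treatment
reverses a stated fraction of both effects from its own onset day.
Light masking is not modelled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .protocol import (
    MIN_PER_DAY,
    ActivityTrace,
    LightSchedule,
    Phase,
    Protocol,
    ValidationError,
    parse_clock,
    seven_week_protocol,
)

TAU_SAFE_RANGE_H = (20.5, 27.5)  # keeps drawn periods inside the analysis band


@dataclass(frozen=True)
class SimParams:
    """Per-group generative parameters (times in hours, rates per minute)."""

    tau_mean_h: float = 23.7
    tau_sd_h: float = 0.15
    amplitude: float = 0.8
    baseline_rate: float = 2.0
    active_fraction: float = 0.4
    psi_h: float = 0.0
    noise_cv: float = 0.2
    disruption_onset_day: Optional[int] = None
    disruption_amp_factor: float = 1.0
    disruption_tau_jitter_h: float = 0.0
    restore_onset_day: Optional[int] = None
    restore_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amplitude", "disruption_amp_factor", "restore_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if not 20.0 < self.tau_mean_h < 28.0:
            raise ValidationError("tau_mean_h must lie in (20, 28) h")
        if not 0.0 < self.active_fraction < 1.0:
            raise ValidationError("active_fraction must lie in (0, 1)")
        if self.tau_sd_h < 0 or self.noise_cv < 0 or self.disruption_tau_jitter_h < 0:
            raise ValidationError("dispersion parameters must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    params: SimParams

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("group size must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    protocol: Protocol
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValidationError("group names must be unique")


def _bout_waveform(phase: np.ndarray, active_fraction: float) -> np.ndarray:
    """Raised-cosine bout over cycle fraction [0, f), cycle-mean 1/2."""
    u = np.mod(phase, 1.0)
    f = active_fraction
    w = np.zeros_like(u)
    inside = u < f
    w[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (u[inside] - f / 2.0) / f))
    return w / f


def _per_minute_profiles(
    params: SimParams, protocol: Protocol, tau_base: float, tau_jitter: float
) -> tuple[np.ndarray, np.ndarray]:
    """Effective amplitude and free-running period for every minute."""
    n = protocol.schedule.total_minutes
    day = np.arange(n) / MIN_PER_DAY
    amp = np.full(n, params.amplitude)
    tau = np.full(n, tau_base)
    if params.disruption_onset_day is not None:
        hit = day >= params.disruption_onset_day
        amp[hit] = params.amplitude * params.disruption_amp_factor
        tau[hit] = tau_base + tau_jitter
        if params.restore_onset_day is not None:
            rf = params.restore_fraction
            rest = day >= params.restore_onset_day
            amp[rest] = params.amplitude * (
                params.disruption_amp_factor + rf * (1.0 - params.disruption_amp_factor)
            )
            tau[rest] = tau_base + (1.0 - rf) * tau_jitter
    np.clip(tau, *TAU_SAFE_RANGE_H, out=tau)
    return amp, tau


def _circadian_phase(
    schedule: LightSchedule, start_clock_min: int, tau_h: np.ndarray, psi_h: float
) -> np.ndarray:
    """Cycle phase (activity onset = 0) for every minute of the recording.

    LD minutes are phase-locked to lights-off + psi; DD minutes advance
    the phase continuously at 1/tau cycles per hour from wherever the
    preceding segment left it (0 for a DD-initial schedule).
    """
    n = schedule.total_minutes
    t = np.arange(n)
    phi = np.empty(n)
    prev_end_phase = 0.0
    for p, (lo, hi) in zip(schedule.phases, schedule.phase_bounds_min()):
        sl = slice(lo, hi)
        if p.regime == "LD":
            off_h = parse_clock(p.lights_off_clock) / 60.0
            clock_h = ((start_clock_min + t[sl]) % MIN_PER_DAY) / 60.0
            phi[sl] = ((clock_h - off_h - psi_h) / 24.0) % 1.0
        else:
            dphi = (1.0 / 60.0) / tau_h[sl]
            phi[sl] = prev_end_phase + np.cumsum(dphi)
        prev_end_phase = phi[hi - 1]
    return phi


def simulate_animal(
    params: SimParams, protocol: Protocol, animal_id: str, group: str = ""
) -> ActivityTrace:
    """Generate one animal's per-minute activity trace.

    Fully deterministic in (params, protocol, animal_id): the random
    stream is keyed on ``params.seed`` and a CRC of ``animal_id``.
    """
    ss = np.random.SeedSequence(
        entropy=params.seed, spawn_key=(zlib.crc32(animal_id.encode()),)
    )
    rng = np.random.default_rng(ss)

    tau_base = float(
        np.clip(rng.normal(params.tau_mean_h, params.tau_sd_h), *TAU_SAFE_RANGE_H)
    )
    tau_jitter = (
        float(rng.normal(0.0, params.disruption_tau_jitter_h))
        if params.disruption_tau_jitter_h > 0
        else 0.0
    )

    sched = protocol.schedule
    start_clock_min = sched.anchor_clock_min()
    amp, tau = _per_minute_profiles(params, protocol, tau_base, tau_jitter)
    phi = _circadian_phase(sched, start_clock_min, tau, params.psi_h)
    w = _bout_waveform(phi, params.active_fraction)
    lam = params.baseline_rate * (1.0 - amp + 2.0 * amp * w)

    if params.noise_cv > 0:
        shape = 1.0 / params.noise_cv**2
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.size)
    counts = rng.poisson(lam).astype(float)

    from .protocol import format_clock

    return ActivityTrace(
        animal_id=animal_id,
        group=group,
        start_clock=format_clock(start_clock_min),
        sampling_interval_min=1.0,
        counts=counts,
        schedule=sched,
    )


def simulate_cohort(spec: CohortSpec) -> list[ActivityTrace]:
    """Generate every animal in a cohort.

    Each animal's sub-seed derives from the cohort seed, its group name
    and its within-group index only, so reordering groups in the spec
    never changes an individual trace.
    """
    traces = []
    for g in spec.groups:
        for i in range(g.n):
            sub = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(zlib.crc32(g.name.encode()), i)
            )
            seed_i = int(sub.generate_state(1)[0] & 0x7FFFFFFF)
            params_i = replace(g.params, seed=seed_i)
            animal_id = f"{g.name}-{i + 1:02d}"
            traces.append(
                simulate_animal(params_i, spec.protocol, animal_id, group=g.name)
            )
    return traces


def default_cohort_spec(seed: int = 0, protocol: Optional[Protocol] = None) -> CohortSpec:
    """Four-group design: control n=6, POI n=8, CM n=5, E2-CM n=5.

    Control animals keep a tight period distribution (SD 0.15 h) and a
    deep rhythm (amplitude 0.8).  Chemotherapy-disrupted animals drop
    to 0.3 amplitude and pick up enough extra period jitter to raise
    the between-animal period SD to 0.8 h during the observation week.
    Treatments reverse 80% (CM) or 95% (E2-CM) of both effects.
    """
    if protocol is None:
        protocol = seven_week_protocol()
    base = SimParams(
        tau_mean_h=23.7,
        tau_sd_h=0.15,
        amplitude=0.8,
        baseline_rate=2.0,
        active_fraction=0.4,
        noise_cv=0.2,
    )
    # jitter chosen so total disrupted period SD = sqrt(0.15^2 + j^2) = 0.8 h
    jitter = float(np.sqrt(0.8**2 - 0.15**2))
    disrupted = replace(
        base,
        disruption_onset_day=7,
        disruption_amp_factor=0.3 / 0.8,
        disruption_tau_jitter_h=jitter,
    )
    groups = (
        GroupSpec("control", 6, base),
        GroupSpec("POI", 8, disrupted),
        GroupSpec("CM", 5, replace(disrupted, restore_onset_day=21, restore_fraction=0.8)),
        GroupSpec("E2-CM", 5, replace(disrupted, restore_onset_day=21, restore_fraction=0.95)),
    )
    return CohortSpec(groups=groups, protocol=protocol, seed=seed)


def dd_observation_protocol(n_days: int = 7) -> Protocol:
    """A minimal constant-darkness protocol for single-phase experiments."""
    return Protocol(LightSchedule((Phase("Observ.", "DD", n_days),)))
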