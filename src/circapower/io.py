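"""Delimited-text readers and writers for traces, schedules and Cq tables.

Traces travel in long format (``animal_id, group, t_min, count``); light
schedules and protocols as nested YAML mirroring the domain types.  Gaps
in a trace's time grid become NaN samples and are reported, never
silently zero-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .protocol import (
    ActivityTrace,
    Intervention,
    LightSchedule,
    Phase,
    Protocol,
    ValidationError,
)

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("animal_id", "group", "t_min", "count")


@dataclass
class GapReport:
    animal_id: str
    n_missing: int
    gap_spans_min: list


def read_activity_table(
    source: Union[str, IO],
    schedule: LightSchedule,
    start_clock: str = "07:00",
    sep: str = ",",
    columns: dict | None = None,
) -> tuple[list[ActivityTrace], list[GapReport]]:
    """Read long-format activity data into per-animal traces.

    ``columns`` may remap the expected column names
    (animal_id/group/t_min/count).  Samples must be in time order per
    animal; negative counts and non-monotone timestamps raise
    :class:`ValidationError` naming the offending row.  Missing minutes
    inside an animal's span become NaN and are listed in the returned
    gap reports.
    """
    colmap = dict(zip(TRACE_COLUMNS, TRACE_COLUMNS))
    if columns:
        colmap.update(columns)
    df = pd.read_csv(source, sep=sep)
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValidationError(f"negative count at row {int(neg[0]) + 2}")

    traces: list[ActivityTrace] = []
    reports: list[GapReport] = []
    for animal_id, sub in df.groupby("animal_id", sort=False):
        t = sub["t_min"].to_numpy(dtype=float)
        diffs = np.diff(t)
        bad = np.where(diffs <= 0)[0]
        if bad.size:
            row = int(sub.index[bad[0] + 1]) + 2
            raise ValidationError(
                f"non-monotone timestamps for animal {animal_id!r} at row {row}"
            )
        dt = float(np.min(diffs)) if diffs.size else 1.0
        n = int(round((t[-1] - t[0]) / dt)) + 1
        counts = np.full(n, np.nan)
        idx = np.round((t - t[0]) / dt).astype(int)
        counts[idx] = sub["count"].to_numpy(dtype=float)
        gaps = np.where(np.isnan(counts))[0]
        if gaps.size:
            spans = _runs(gaps)
            report = GapReport(
                str(animal_id),
                int(gaps.size),
                [(float(t[0] + a * dt), float(t[0] + b * dt)) for a, b in spans],
            )
            reports.append(report)
            logger.warning(
                "animal %s: %d missing samples in %d gap(s)",
                animal_id,
                report.n_missing,
                len(report.gap_spans_min),
            )
        traces.append(
            ActivityTrace(
                animal_id=str(animal_id),
                group=str(sub["group"].iloc[0]),
                start_clock=start_clock,
                sampling_interval_min=dt,
                counts=counts,
                schedule=schedule,
            )
        )
    return traces, reports


def _runs(indices: np.ndarray) -> list:
    """Consecutive-run spans [(first, last), ...] of sorted indices."""
    splits = np.where(np.diff(indices) > 1)[0] + 1
    return [(int(r[0]), int(r[-1])) for r in np.split(indices, splits)]


def write_activity_table(traces: Iterable[ActivityTrace], dest: Union[str, IO]) -> None:
    """Write traces in the long format read back by read_activity_table."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "t_min": tr.times_min(),
                    "count": tr.counts,
                }
            ).dropna(subset=["count"])
        )
    pd.concat(frames, ignore_index=True).to_csv(dest, index=False)


# --- schedule / protocol YAML ------------------------------------------------

def schedule_to_dict(schedule: LightSchedule) -> dict:
    return {
        "phases": [
            {
                "label": p.label,
                "regime": p.regime,
                "n_days": p.n_days,
                "lights_on_clock": p.lights_on_clock,
                "lights_off_clock": p.lights_off_clock,
            }
            for p in schedule.phases
        ]
    }


def schedule_from_dict(d: dict) -> LightSchedule:
    return LightSchedule(tuple(Phase(**p) for p in d["phases"]))


def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "schedule": schedule_to_dict(protocol.schedule),
        "interventions": [
            {
                "label": iv.label,
                "start_day": iv.start_day,
                "end_day": iv.end_day,
                "cadence_days": iv.cadence_days,
            }
            for iv in protocol.interventions
        ],
    }


def protocol_from_dict(d: dict) -> Protocol:
    return Protocol(
        schedule=schedule_from_dict(d["schedule"]),
        interventions=tuple(Intervention(**iv) for iv in d.get("interventions", [])),
    )


def write_protocol(protocol: Protocol, dest: Union[str, IO]) -> None:
    text = yaml.safe_dump(protocol_to_dict(protocol), sort_keys=False)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)


def read_protocol(source: Union[str, IO]) -> Protocol:
    if hasattr(source, "read"):
        d = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            d = yaml.safe_load(fh)
    return protocol_from_dict(d)


# --- matrices ----------------------------------------------------------------

def write_matrix(values: np.ndarray, dest: str, metadata: dict | None = None) -> None:
    """Matrix as CSV plus an optional YAML sidecar (<dest>.meta.yaml)."""
    np.savetxt(dest, values, delimiter=",", fmt="%.10g")
    if metadata is not None:
        with open(str(dest) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=False)


# --- qPCR --------------------------------------------------------------------

CQ_COLUMNS = ("sample_id", "group", "zt", "gene", "replicate", "cq")


def read_cq_table(source: Union[str, IO], sep: str = ",") -> pd.DataFrame:
    """Read a long-format Cq table; validates required columns and cq > 0."""
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Cq table missing columns: {missing}")
    if (df["cq"] <= 0).any():
        row = int(df.index[df["cq"] <= 0][0]) + 2
        raise ValidationError(f"non-positive Cq at row {row}")
    return df
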