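"""Trace conditioning: re-binning, phase slicing, double-plot construction."""

from __future__ import annotations

import numpy as np

from .protocol import (
    MIN_PER_DAY,
    ActivityTrace,
    DoublePlotMatrix,
    ValidationError,
    parse_clock,
    replace_trace,
)


def bin_counts(trace: ActivityTrace, bin_min: float) -> ActivityTrace:
    """Sum counts into consecutive bins of width ``bin_min`` minutes.

    ``bin_min`` must be an integer multiple of the current sampling
    interval.  Total activity is conserved; a bin is NaN only when all
    of its samples are missing.
    """
    ratio = bin_min / trace.sampling_interval_min
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValidationError(
            f"bin width {bin_min} min is not an integer multiple of the "
            f"sampling interval {trace.sampling_interval_min} min"
        )
    if k == 1:
        return trace
    n_bins = trace.n_samples // k
    if n_bins * k != trace.n_samples:
        raise ValidationError(
            f"trace length {trace.n_samples} not divisible into {bin_min}-min bins"
        )
    blocks = trace.counts.reshape(n_bins, k)
    binned = np.nansum(blocks, axis=1)
    binned[np.all(np.isnan(blocks), axis=1)] = np.nan
    return replace_trace(trace, counts=binned, sampling_interval_min=float(bin_min))


def slice_phase(trace: ActivityTrace, phase_label: str) -> ActivityTrace:
    """Restrict a trace to the samples inside one named protocol phase."""
    lo, hi = trace.schedule.phase_span(phase_label)
    dt = trace.sampling_interval_min
    i_lo = int(np.ceil(lo / dt - 1e-9))
    i_hi = min(int(np.ceil(hi / dt - 1e-9)), trace.n_samples)
    if i_hi <= i_lo:
        raise ValidationError(f"trace does not cover phase {phase_label!r}")
    day_lo = lo // MIN_PER_DAY
    day_hi = hi // MIN_PER_DAY
    sub_sched = trace.schedule.slice_days(day_lo, day_hi)
    start_min = (parse_clock(trace.start_clock) + lo) % MIN_PER_DAY
    from .protocol import format_clock

    return replace_trace(
        trace,
        counts=trace.counts[i_lo:i_hi].copy(),
        schedule=sub_sched,
        start_clock=format_clock(int(start_min)),
    )


def double_plot(trace: ActivityTrace, bin_min: float = 6.0) -> DoublePlotMatrix:
    """Build a double-plotted actogram raster.

    Each row shows two consecutive days side by side, so free-running
    drift appears as slanted activity onsets.  Requires at least two
    whole recording days; a trailing day without a successor is padded
    with NaN on its right half.
    """
    binned = bin_counts(trace, bin_min)
    per_day = int(round(MIN_PER_DAY / bin_min))
    if per_day * bin_min != MIN_PER_DAY:
        raise ValidationError("bin width must divide the 24 h day")
    n_days = binned.n_samples // per_day
    if n_days < 2:
        raise ValidationError("double plot needs at least 2 whole recording days")
    days = binned.counts[: n_days * per_day].reshape(n_days, per_day)

    t = binned.times_min()[: n_days * per_day] + bin_min / 2.0
    dark = trace.schedule.dark_mask(t, parse_clock(trace.start_clock))
    dark_days = dark.reshape(n_days, per_day).astype(float)

    values = np.full((n_days, 2 * per_day), np.nan)
    mask = np.zeros((n_days, 2 * per_day))
    values[:, :per_day] = days
    mask[:, :per_day] = dark_days
    values[:-1, per_day:] = days[1:]
    mask[:-1, per_day:] = dark_days[1:]
    mask[-1, per_day:] = dark_days[-1]  # shading continues on the padded half
    return DoublePlotMatrix(
        bin_min=float(bin_min),
        values=values,
        light_mask=mask,
        day_labels=list(range(1, n_days + 1)),
    )
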