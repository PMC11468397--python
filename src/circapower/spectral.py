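"""FFT rhythmometry: spectra, spectrograms, free-running period, CPR.

The circadian power ratio (CPR) is the trapezoidal area of spectral
power over frequencies whose periods lie in the circadian band
(default 20-28 h) divided by the area over the total analysed band
(default: periods from twice the bin width up to the record length,
DC excluded).  The free-running period is the period of the
maximum-power frequency bin in the circadian band, optionally refined
by three-point quadratic interpolation of log power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import get_window

from .protocol import MIN_PER_DAY, ActivityTrace, ValidationError


class NoRhythmError(ValueError):
    """Spectrum carries no variance: rhythm statistics are undefined."""


@dataclass
class Spectrum:
    """One-sided power spectrum of a detrended, tapered activity record.

    Power is |X_k|^2 / n_fft so that, with rectangular taper and no
    padding, DC power + 2*sum(power) (Nyquist counted once) equals the
    sum of squared detrended samples (Parseval).
    """

    frequencies: np.ndarray  # cycles/hour, ascending, DC excluded
    power: np.ndarray
    window_h: float
    taper: str
    pad_factor: int
    bin_min: float
    dc_power: float = 0.0
    nyquist_included: bool = False
    no_variance: bool = False

    def periods_h(self) -> np.ndarray:
        return 1.0 / self.frequencies

    def total_energy(self) -> float:
        """One-sided Parseval sum: DC + 2*interior + Nyquist once."""
        p = self.power
        if self.nyquist_included:
            return self.dc_power + 2.0 * float(np.sum(p[:-1])) + float(p[-1])
        return self.dc_power + 2.0 * float(np.sum(p))


@dataclass
class Spectrogram:
    window_centers_h: np.ndarray
    period_grid_h: np.ndarray  # descending display periods
    power: np.ndarray  # windows x periods; NaN rows = unusable windows
    window_h: float
    step_h: float
    grid_frequencies: Optional[np.ndarray] = None  # mapped bin per display period

    def argmax_periods(self) -> np.ndarray:
        """Per-window peak display period, NaN for unusable windows.

        Adjacent display periods can map to the same underlying
        frequency bin and therefore tie in power; ties resolve to the
        display period closest to that bin's own period.
        """
        out = np.full(self.power.shape[0], np.nan)
        for i, row in enumerate(self.power):
            if np.isnan(row).all():
                continue
            pmax = np.nanmax(row)
            cand = np.where(row == pmax)[0]
            if self.grid_frequencies is not None:
                bin_periods = 1.0 / self.grid_frequencies[cand]
                cand = cand[[np.abs(self.period_grid_h[cand] - bin_periods).argmin()]]
            out[i] = self.period_grid_h[cand[0]]
        return out


@dataclass
class PeriodEstimate:
    animal_id: str
    period_h: float
    band_h: tuple
    peak_power: float
    refined: bool

    def __post_init__(self) -> None:
        lo, hi = self.band_h
        if not lo <= self.period_h <= hi:
            raise ValidationError("estimated period fell outside its band")


@dataclass
class CPRValue:
    animal_id: str
    cpr: float
    circadian_band_h: tuple
    total_band_h: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpr <= 1.0:
            raise ValidationError("CPR must lie in [0, 1]")


def _detrend(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return x - x.mean()
    if mode == "linear":
        t = np.arange(x.size)
        coef = np.polyfit(t, x, 1)
        return x - np.polyval(coef, t)
    raise ValidationError(f"unknown detrend mode {mode!r}")


def _taper(n: int, name: str) -> np.ndarray:
    if name in ("rect", "rectangular", "boxcar", "none"):
        return np.ones(n)
    return get_window(name, n, fftbins=True)


def power_spectrum(
    trace: ActivityTrace,
    taper: str = "hann",
    pad_factor: int = 8,
    detrend: str = "mean",
) -> Spectrum:
    """One-sided power spectrum of a trace (DC excluded from the grid).

    The trace must be gap-free (use ``trace.imputed()`` first) and at
    least two days long.  An all-constant input yields a valid
    spectrum of (near-)zero power flagged ``no_variance``.
    """
    x = np.asarray(trace.counts, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("trace has missing samples; impute before the FFT")
    if trace.total_minutes < 2 * MIN_PER_DAY:
        raise ValidationError("spectrum needs at least 2 days of data")
    if pad_factor < 1 or int(pad_factor) != pad_factor:
        raise ValidationError("pad_factor must be a positive integer")

    no_var = bool(np.ptp(x) == 0)
    xd = _detrend(x, detrend) * _taper(x.size, taper)
    n_fft = x.size * int(pad_factor)
    spec = np.fft.rfft(xd, n=n_fft)
    power = (spec.real**2 + spec.imag**2) / n_fft
    freqs = np.fft.rfftfreq(n_fft, d=trace.sampling_interval_min / 60.0)

    nyq_included = n_fft % 2 == 0
    return Spectrum(
        frequencies=freqs[1:],
        power=power[1:],
        window_h=trace.total_minutes / 60.0,
        taper=taper,
        pad_factor=int(pad_factor),
        bin_min=trace.sampling_interval_min,
        dc_power=float(power[0]),
        nyquist_included=nyq_included,
        no_variance=no_var,
    )


def sliding_spectrogram(
    trace: ActivityTrace,
    window_h: float = 96.0,
    step_h: float = 12.0,
    taper: str = "hann",
    pad_factor: int = 8,
    period_grid_h: Optional[np.ndarray] = None,
    max_missing_fraction: float = 0.1,
) -> Spectrogram:
    """Sliding-window FFT over a trace, resampled to a display period grid.

    Each window's spectrum is mapped to the grid by nearest frequency,
    with no smoothing across windows.  Windows with more than
    ``max_missing_fraction`` missing samples become NaN rows; lighter
    gaps are imputed by the window mean.
    """
    if step_h <= 0:
        raise ValidationError("step_h must be positive")
    record_h = trace.total_minutes / 60.0
    if window_h > record_h:
        raise ValidationError(
            f"window ({window_h} h) exceeds record length ({record_h} h)"
        )
    if period_grid_h is None:
        period_grid_h = np.arange(32.0, 15.99, -0.25)
    period_grid_h = np.asarray(period_grid_h, dtype=float)

    dt_h = trace.sampling_interval_min / 60.0
    w_samp = int(round(window_h / dt_h))
    s_samp = max(1, int(round(step_h / dt_h)))
    n_windows = (trace.n_samples - w_samp) // s_samp + 1

    centers = np.empty(n_windows)
    out = np.full((n_windows, period_grid_h.size), np.nan)
    grid_freqs = None
    from .protocol import replace_trace

    for i in range(n_windows):
        lo = i * s_samp
        seg = trace.counts[lo : lo + w_samp]
        centers[i] = (lo + w_samp / 2.0) * dt_h
        nan_frac = np.isnan(seg).mean()
        if nan_frac > max_missing_fraction:
            continue  # unusable window stays NaN
        if nan_frac > 0:
            seg = seg.copy()
            seg[np.isnan(seg)] = np.nanmean(seg)
        sub = replace_trace(trace, counts=seg)
        spec = power_spectrum(sub, taper=taper, pad_factor=pad_factor)
        idx = np.abs(
            spec.frequencies[None, :] - (1.0 / period_grid_h)[:, None]
        ).argmin(axis=1)
        out[i] = spec.power[idx]
        grid_freqs = spec.frequencies[idx]
    return Spectrogram(
        window_centers_h=centers,
        period_grid_h=period_grid_h,
        power=out,
        window_h=window_h,
        step_h=step_h,
        grid_frequencies=grid_freqs,
    )


def _band_indices(spec: Spectrum, band_h: tuple) -> np.ndarray:
    lo_h, hi_h = band_h
    f = spec.frequencies
    return np.where((f >= 1.0 / hi_h - 1e-15) & (f <= 1.0 / lo_h + 1e-15))[0]


def estimate_free_running_period(
    trace: ActivityTrace,
    band_h: tuple = (20.0, 28.0),
    taper: str = "hann",
    pad_factor: int = 8,
    refine: bool = True,
    detrend: str = "mean",
) -> PeriodEstimate:
    """Free-running period from the peak FFT power inside a period band.

    Caller slices the trace to the analysis phase (e.g. the DD
    observation week) first.  Ties are broken toward the bin nearer
    24 h, then toward the lower period.  With ``refine``, a quadratic
    through the log power of the peak and its two neighbours
    interpolates the peak frequency before conversion to period.
    """
    lo_h, hi_h = band_h
    record_h = trace.total_minutes / 60.0
    if record_h < 2.0 * hi_h:
        raise ValidationError(
            f"record ({record_h:.1f} h) too short to resolve periods up to {hi_h} h"
        )
    spec = power_spectrum(trace, taper=taper, pad_factor=pad_factor, detrend=detrend)
    idx = _band_indices(spec, band_h)
    if idx.size == 0:
        raise ValidationError("no frequency bins inside the requested band")

    band_power = spec.power[idx]
    pmax = band_power.max()
    cand = idx[band_power >= pmax * (1.0 - 1e-12)]
    periods = 1.0 / spec.frequencies[cand]
    order = np.lexsort((periods, np.abs(periods - 24.0)))
    k = int(cand[order[0]])

    period = 1.0 / spec.frequencies[k]
    refined = False
    if refine and 0 < k < spec.power.size - 1:
        p0, p1, p2 = spec.power[k - 1 : k + 2]
        # neighbours at numerical-noise level mean an exact on-grid line:
        # interpolation would fit round-off, not the peak shape
        if p0 > 1e-9 * p1 and p2 > 1e-9 * p1:
            l0, l1, l2 = np.log(p0), np.log(p1), np.log(p2)
            denom = l0 - 2.0 * l1 + l2
            if denom < 0:  # concave: genuine interior peak
                delta = float(np.clip(0.5 * (l0 - l2) / denom, -0.5, 0.5))
                df = spec.frequencies[k + 1] - spec.frequencies[k]
                period = 1.0 / (spec.frequencies[k] + delta * df)
                refined = True
    period = float(np.clip(period, lo_h, hi_h))
    return PeriodEstimate(
        animal_id=trace.animal_id,
        period_h=period,
        band_h=band_h,
        peak_power=float(pmax),
        refined=refined,
    )


def circadian_power_ratio(
    spectrum: Spectrum,
    circadian_band_h: tuple = (20.0, 28.0),
    total_band_h: Optional[tuple] = None,
    animal_id: str = "",
) -> CPRValue:
    """Circadian band power as a fraction of total rhythmic power.

    Both areas are trapezoidal integrals over the same frequency grid,
    so the ratio is exact for flat spectra and bounded in [0, 1].
    Raises :class:`NoRhythmError` for a no-variance spectrum rather
    than returning 0/0.
    """
    if total_band_h is None:
        total_band_h = (2.0 * spectrum.bin_min / 60.0, spectrum.window_h)
    if not (total_band_h[0] <= circadian_band_h[0] and circadian_band_h[1] <= total_band_h[1]):
        raise ValidationError("total band must contain the circadian band")

    tot_idx = _band_indices(spectrum, total_band_h)
    circ_idx = _band_indices(spectrum, circadian_band_h)
    if tot_idx.size < 2 or circ_idx.size < 2:
        raise ValidationError("frequency grid too coarse for the requested bands")

    f = spectrum.frequencies
    p = spectrum.power
    total = float(np.trapezoid(p[tot_idx], f[tot_idx]))
    if spectrum.no_variance or total <= 1e-12 * tot_idx.size:
        raise NoRhythmError("no rhythmic power in spectrum")
    circ = float(np.trapezoid(p[circ_idx], f[circ_idx]))
    cpr = min(max(circ / total, 0.0), 1.0)
    return CPRValue(
        animal_id=animal_id or spectrum_id(spectrum),
        cpr=cpr,
        circadian_band_h=tuple(circadian_band_h),
        total_band_h=tuple(total_band_h),
    )


def flat_spectrum_cpr(
    spectrum: Spectrum,
    circadian_band_h: tuple = (20.0, 28.0),
    total_band_h: Optional[tuple] = None,
) -> float:
    """CPR a perfectly flat spectrum would score on this grid.

    The band-fraction expectation for white noise: the ratio of the
    circadian band's frequency span to the total band's span, computed
    with the same trapezoidal rule used for real spectra.
    """
    flat = Spectrum(
        frequencies=spectrum.frequencies,
        power=np.ones_like(spectrum.power),
        window_h=spectrum.window_h,
        taper=spectrum.taper,
        pad_factor=spectrum.pad_factor,
        bin_min=spectrum.bin_min,
    )
    return circadian_power_ratio(flat, circadian_band_h, total_band_h, "flat").cpr


def spectrum_id(spectrum: Spectrum) -> str:
    return f"spectrum-{spectrum.window_h:g}h"
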