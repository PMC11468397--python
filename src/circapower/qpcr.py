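"""qPCR relative quantification and Zeitgeber-time course assembly.

Implements standard-curve efficiency estimation (Cq vs log10 template
from a fivefold dilution series), efficiency-corrected relative
expression against the geometric mean of two reference genes, the
classic 2^-ddCq fold change against a single reference, and LOWESS
smoothing of 4-hourly ZT time courses with the conventional ZT24 = ZT0
wrap.

Efficiency conventions: a *percent* efficiency of 100 means perfect
doubling; the corresponding per-cycle *amplification factor* is 2.0.
Use :func:`amplification_factor` / :func:`efficiency_percent` to
convert explicitly rather than guessing from magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .protocol import ValidationError

ZT_GRID = (0, 4, 8, 12, 16, 20)
FIVEFOLD_LOG10 = np.log10(5.0)


@dataclass
class EfficiencyEstimate:
    gene: str
    slope: float  # Cq per log10(template)
    efficiency_pct: float
    r2: float
    acceptable: bool


@dataclass
class RelExpression:
    sample_id: str
    gene: str
    value: float
    method: str  # "efficiency-corrected-dual-ref" or "ddcq"
    reference_genes: tuple
    calibrator: str
    group: Optional[str] = None
    zt: Optional[float] = None


@dataclass
class ZTSeries:
    gene: str
    group: str
    points: dict  # zt -> list of replicate values
    smoothed: Optional[pd.DataFrame] = None  # columns zt, value


def amplification_factor(efficiency_pct: float) -> float:
    """Per-cycle amplification factor from percent efficiency (100 -> 2.0)."""
    return 1.0 + efficiency_pct / 100.0


def efficiency_percent(factor: float) -> float:
    """Percent efficiency from a per-cycle amplification factor (2.0 -> 100)."""
    return (factor - 1.0) * 100.0


def fit_efficiency(
    standards: Union[pd.DataFrame, Sequence[Mapping]],
    gene: str = "",
    dilution_fold: float = 5.0,
) -> EfficiencyEstimate:
    """Amplification efficiency from a serial-dilution standard curve.

    ``standards`` holds ``dilution_step`` (0 = most concentrated, each
    step dividing template by ``dilution_fold``) and ``cq``.  The
    least-squares slope of Cq on log10(relative template) gives
    efficiency_pct = (10^(-1/slope) - 1) * 100; 90-110% is acceptable.
    """
    df = pd.DataFrame(standards)
    for c in ("dilution_step", "cq"):
        if c not in df.columns:
            raise ValidationError(f"standards need a {c!r} column")
    if df["dilution_step"].nunique() < 3:
        raise ValidationError("need at least 3 distinct dilution steps")
    log_template = -df["dilution_step"].to_numpy(dtype=float) * np.log10(dilution_fold)
    cq = df["cq"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(log_template, cq, 1)
    if slope >= 0:
        raise ValidationError(
            "standard-curve slope must be negative (more template, lower Cq)"
        )
    fitted = slope * log_template + intercept
    ss_res = float(((cq - fitted) ** 2).sum())
    ss_tot = float(((cq - cq.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyEstimate(
        gene=gene,
        slope=float(slope),
        efficiency_pct=float(eff),
        r2=r2,
        acceptable=bool(90.0 <= eff <= 110.0),
    )


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq per (sample, gene), carrying group/zt labels along."""
    keep = [c for c in ("group", "zt") if c in table.columns]
    return (
        table.groupby(["sample_id", "gene"] + keep, as_index=False)["cq"]
        .mean()
    )


def _select_calibrator(df: pd.DataFrame, calibrator) -> tuple[pd.DataFrame, str]:
    """Rows matching a calibrator descriptor (sample list or column filters)."""
    if isinstance(calibrator, (list, tuple, set)):
        mask = df["sample_id"].isin(list(calibrator))
        desc = f"samples={sorted(map(str, calibrator))}"
    elif isinstance(calibrator, Mapping):
        mask = pd.Series(True, index=df.index)
        for col, val in calibrator.items():
            if col not in df.columns:
                raise ValidationError(f"calibrator refers to unknown column {col!r}")
            mask &= df[col] == val
        desc = ",".join(f"{k}={v}" for k, v in calibrator.items())
    else:
        raise ValidationError("calibrator must be a sample list or column-filter map")
    sel = df[mask]
    if sel.empty:
        raise ValidationError("calibrator selects no samples")
    return sel, desc


def _mean_cq(df: pd.DataFrame, gene: str, context: str) -> pd.Series:
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise ValidationError(f"no Cq values for gene {gene!r} in {context}")
    return sub.set_index("sample_id")["cq"]


def relative_expression_dual_ref(
    table: pd.DataFrame,
    target: str,
    refs: Sequence[str],
    efficiencies: Mapping[str, float],
    calibrator,
) -> list[RelExpression]:
    """Efficiency-corrected relative expression with dual reference genes.

    Per sample s with per-gene amplification factors E:

        ratio = E_t^(Cq_t,cal - Cq_t,s) / geomean_r E_r^(Cq_r,cal - Cq_r,s)

    Technical replicates are averaged to one Cq per (sample, gene)
    first; the calibrator Cq is the mean over the calibrator samples.
    """
    refs = tuple(refs)
    genes = (target,) + refs
    for g in genes:
        if g not in efficiencies:
            raise ValidationError(f"no amplification factor for gene {g!r}")
    flat = collapse_replicates(table)
    cal_rows, cal_desc = _select_calibrator(flat, calibrator)
    cal_cq = {g: float(_mean_cq(cal_rows, g, "calibrator").mean()) for g in genes}

    labels = flat.drop_duplicates("sample_id").set_index("sample_id")
    target_cq = _mean_cq(flat, target, "table")
    ref_cq = {r: _mean_cq(flat, r, "table") for r in refs}

    out = []
    for sample_id, cq_t in target_cq.items():
        num = efficiencies[target] ** (cal_cq[target] - cq_t)
        log_den = 0.0
        for r in refs:
            if sample_id not in ref_cq[r].index:
                raise ValidationError(
                    f"sample {sample_id!r} lacks a {r!r} reference measurement"
                )
            log_den += (cal_cq[r] - float(ref_cq[r][sample_id])) * np.log(
                efficiencies[r]
            )
        den = np.exp(log_den / len(refs))  # geometric mean of reference factors
        out.append(
            RelExpression(
                sample_id=str(sample_id),
                gene=target,
                value=float(num / den),
                method="efficiency-corrected-dual-ref",
                reference_genes=refs,
                calibrator=cal_desc,
                group=labels.at[sample_id, "group"] if "group" in labels else None,
                zt=float(labels.at[sample_id, "zt"]) if "zt" in labels else None,
            )
        )
    return out


def ddcq_fold_change(
    table: pd.DataFrame, target: str, ref: str, calibrator
) -> list[RelExpression]:
    """2^-ddCq fold change against a single reference gene.

    fold = 2^-[(Cq_t,s - Cq_ref,s) - (Cq_t,cal - Cq_ref,cal)]; the
    calibrator's own fold change is exactly 1.
    """
    flat = collapse_replicates(table)
    cal_rows, cal_desc = _select_calibrator(flat, calibrator)
    dcq_cal = float(_mean_cq(cal_rows, target, "calibrator").mean()) - float(
        _mean_cq(cal_rows, ref, "calibrator").mean()
    )
    labels = flat.drop_duplicates("sample_id").set_index("sample_id")
    t_cq = _mean_cq(flat, target, "table")
    r_cq = _mean_cq(flat, ref, "table")
    out = []
    for sample_id, cq_t in t_cq.items():
        if sample_id not in r_cq.index:
            raise ValidationError(
                f"sample {sample_id!r} lacks a {ref!r} reference measurement"
            )
        ddcq = (cq_t - float(r_cq[sample_id])) - dcq_cal
        out.append(
            RelExpression(
                sample_id=str(sample_id),
                gene=target,
                value=float(2.0 ** (-ddcq)),
                method="ddcq",
                reference_genes=(ref,),
                calibrator=cal_desc,
                group=labels.at[sample_id, "group"] if "group" in labels else None,
                zt=float(labels.at[sample_id, "zt"]) if "zt" in labels else None,
            )
        )
    return out


def assemble_zt_series(
    expr: Sequence[RelExpression], wrap: bool = True, gene: str = "", group: str = ""
) -> ZTSeries:
    """Collect relative-expression values into a per-ZT time course.

    ZT labels must lie on the 4-hourly sampling grid; with ``wrap`` the
    ZT24 point is created as an exact copy of ZT0 (the convention for
    closing diurnal curves).  Wrapping is idempotent.
    """
    points: dict = {}
    zt24: list = []
    for e in expr:
        if e.zt is None:
            raise ValidationError(f"sample {e.sample_id!r} has no ZT label")
        zt = float(e.zt)
        if zt == 24.0:
            zt24.append(float(e.value))  # wrap duplicates of ZT0 by convention
            continue
        if zt not in ZT_GRID:
            raise ValidationError(f"ZT {e.zt} is off the sampling grid {ZT_GRID}")
        points.setdefault(zt, []).append(float(e.value))
    if zt24 and 0.0 not in points:
        points[0.0] = zt24
    if wrap and 0.0 in points:
        points[24.0] = list(points[0.0])
    return ZTSeries(
        gene=gene or (expr[0].gene if expr else ""),
        group=group or (expr[0].group or "" if expr else ""),
        points=dict(sorted(points.items())),
    )


def _local_linear_smooth(
    x: np.ndarray, y: np.ndarray, xgrid: np.ndarray, span: float
) -> np.ndarray:
    """Locally weighted (tricube) linear regression evaluated at xgrid.

    The classic LOWESS local-linear step with no robustness
    iterations: for each evaluation point, the k = ceil(span*n)
    nearest data points are tricube-weighted by distance and fit with
    weighted least squares.  Reproduces constants exactly, and linear
    data exactly for any span.
    """
    n = x.size
    k = min(n, max(3, int(np.ceil(span * n))))
    out = np.empty(xgrid.size)
    for j, x0 in enumerate(xgrid):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        if h == 0:
            h = np.sort(d)[-1] or 1.0
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        w[d < h * 1e-12] = 1.0
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 0 else 0.0
        out[j] = ym + slope * (x0 - xm)
    return out


def lowess_curve(
    series: ZTSeries, span: float = 0.5, grid_step_h: float = 0.5
) -> ZTSeries:
    """LOWESS (local-linear) smoothing of the per-ZT replicate means.

    Evaluated on a ``grid_step_h`` grid across [0, 24]; span 0.5 is the
    "medium" default.  Returns a new series with ``smoothed`` filled.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must lie in (0, 1]")
    zts = np.array(sorted(series.points))
    if zts.size < 4:
        raise ValidationError("need at least 4 distinct ZT points to smooth")
    means = np.array([np.mean(series.points[z]) for z in zts])
    grid = np.arange(0.0, 24.0 + 1e-9, grid_step_h)
    fitted = _local_linear_smooth(zts, means, grid, span)
    return ZTSeries(
        gene=series.gene,
        group=series.group,
        points=series.points,
        smoothed=pd.DataFrame({"zt": grid, "value": fitted}),
    )
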