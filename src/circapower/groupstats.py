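"""Group summaries and ANOVA/Tukey comparison machinery.

Per-group period and CPR panels are summarised as mean and sample SD
(n-1 denominator); multi-group comparisons use one-way or two-way
ANOVA followed by Tukey's HSD, with the conventional star codes
(* p<0.05, ** p<0.01, *** p<0.001).  Two-way per-timepoint contrasts
are reported as letter codes restricted to a named set of group pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import ValidationError

#: Default letter -> contrast mapping for per-timepoint two-way comparisons.
DEFAULT_CONTRAST_LETTERS = {
    "a": ("control", "POI"),
    "b": ("CM", "POI"),
    "c": ("E2-CM", "POI"),
    "d": ("CM", "E2-CM"),
}


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupSummary:
    groups: dict  # name -> {"n": int, "mean": float, "sd": float, "values": list}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": g, "n": d["n"], "mean": d["mean"], "sd": d["sd"]}
                for g, d in self.groups.items()
            ]
        )


@dataclass
class TukeyPair:
    contrast: tuple
    diff: float
    p_adj: float
    stars: str
    stratum: Optional[float] = None


@dataclass
class AnovaResult:
    design: str  # "one-way" or "two-way"
    factors: dict  # factor -> {"F": float, "df": (d1, d2), "p": float}
    tukey_pairs: list
    per_timepoint_letters: Optional[dict] = None
    error_term: str = "pooled"

    def tukey_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contrast": f"{c.contrast[0]} vs {c.contrast[1]}",
                    "stratum": c.stratum,
                    "diff": c.diff,
                    "p_adj": c.p_adj,
                    "stars": c.stars,
                }
                for c in self.tukey_pairs
            ]
        )


def _as_frame(values, required: Sequence[str]) -> pd.DataFrame:
    df = pd.DataFrame(values)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing fields: {missing}")
    return df


def summarize_by_group(values: Union[pd.DataFrame, Sequence[Mapping]]) -> GroupSummary:
    """Mean, sample SD (n-1) and n for each group."""
    df = _as_frame(values, ("group", "value"))
    out = {}
    for g, sub in df.groupby("group", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        out[g] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "values": v.tolist(),
        }
    return GroupSummary(out)


def _tukey_pairs(
    means: Mapping[str, float],
    ns: Mapping[str, int],
    mse: float,
    df_err: int,
    stratum: Optional[float] = None,
) -> list:
    """Tukey-Kramer adjusted p for every group pair via the studentized range."""
    k = len(means)
    pairs = []
    for g1, g2 in combinations(means, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        if se == 0:
            p = 0.0 if diff != 0 else 1.0
        else:
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
        p = min(max(p, 0.0), 1.0)
        pairs.append(TukeyPair((g1, g2), float(diff), p, significance_stars(p), stratum))
    return pairs


def one_way_anova_tukey(
    values: Union[pd.DataFrame, Sequence[Mapping]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA with Tukey's HSD across all group pairs."""
    df = _as_frame(values, ("group", "value"))
    groups = {g: sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group", sort=False)}
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")

    f_stat, p = stats.f_oneway(*groups.values())
    n_total = sum(v.size for v in groups.values())
    k = len(groups)
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_err
    if not np.isfinite(f_stat):  # zero within-group variance everywhere
        f_stat, p = np.inf, 0.0
    means = {g: float(v.mean()) for g, v in groups.items()}
    ns = {g: int(v.size) for g, v in groups.items()}
    return AnovaResult(
        design="one-way",
        factors={"group": {"F": float(f_stat), "df": (k - 1, df_err), "p": float(p)}},
        tukey_pairs=_tukey_pairs(means, ns, mse, df_err),
    )


def two_way_anova_tukey(
    values: Union[pd.DataFrame, Sequence[Mapping]],
    alpha: float = 0.05,
    error_term: str = "pooled",
    contrast_letters: Optional[Mapping[str, tuple]] = None,
) -> AnovaResult:
    """Two-way (group x time) ANOVA with per-timepoint Tukey contrasts.

    Requires a complete group x zt factorial with >= 2 replicates per
    cell.  ``error_term`` chooses the mean-square error for the
    per-timepoint Tukey tests: "pooled" uses the full-model residual
    (more power at small n), "stratum" refits within each timepoint.
    Significant contrasts among the named pairs are encoded as letters
    per timepoint (default a/b/c/d for the four standard pairs).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if error_term not in ("pooled", "stratum"):
        raise ValidationError("error_term must be 'pooled' or 'stratum'")
    df = _as_frame(values, ("group", "zt", "value"))
    cell_n = df.groupby(["group", "zt"]).size()
    groups = sorted(df["group"].unique())
    zts = sorted(df["zt"].unique())
    missing = [
        (g, z) for g in groups for z in zts if (g, z) not in cell_n.index
    ]
    if missing:
        raise ValidationError(f"missing factorial cells: {missing}")
    thin = cell_n[cell_n < 2]
    if len(thin):
        raise ValidationError(f"cells with fewer than 2 replicates: {list(thin.index)}")

    model = smf.ols("value ~ C(group) * C(zt)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def row(name):
        r = table.loc[name]
        return {
            "F": float(r["F"]),
            "df": (int(r["df"]), int(table.loc["Residual", "df"])),
            "p": float(r["PR(>F)"]),
        }

    factors = {
        "group": row("C(group)"),
        "zt": row("C(zt)"),
        "interaction": row("C(group):C(zt)"),
    }
    pooled_mse = float(model.mse_resid)
    pooled_df = int(model.df_resid)

    letters_map = dict(contrast_letters or DEFAULT_CONTRAST_LETTERS)
    tukey_pairs: list = []
    per_tp: dict = {}
    for z in zts:
        sub = df[df["zt"] == z]
        means = {g: float(sub.loc[sub["group"] == g, "value"].mean()) for g in groups}
        ns = {g: int((sub["group"] == g).sum()) for g in groups}
        if error_term == "pooled":
            mse, dferr = pooled_mse, pooled_df
        else:
            vals = [sub.loc[sub["group"] == g, "value"].to_numpy() for g in groups]
            dferr = sum(v.size for v in vals) - len(groups)
            mse = sum(((v - v.mean()) ** 2).sum() for v in vals) / dferr
        pairs = _tukey_pairs(means, ns, mse, dferr, stratum=float(z))
        tukey_pairs.extend(pairs)
        codes = ""
        padj = {frozenset(p.contrast): p.p_adj for p in pairs}
        for letter, (g1, g2) in sorted(letters_map.items()):
            key = frozenset((g1, g2))
            if key in padj and padj[key] < alpha:
                codes += letter
        per_tp[float(z)] = codes
    return AnovaResult(
        design="two-way",
        factors=factors,
        tukey_pairs=tukey_pairs,
        per_timepoint_letters=per_tp,
        error_term=error_term,
    )
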