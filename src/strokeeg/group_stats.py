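"""Four-group comparisons: one-way ANOVA, eta-squared, significance stars.

Each metric x band cell is compared across experimental groups with a
classical fixed-effects one-way ANOVA.  Effect size is eta-squared,

    eta^2 = SS_between / SS_total,

group summaries are mean +/- SEM, and stars follow the usual thresholds
(* p<0.05, ** p<0.01, *** p<0.001) on the unadjusted p-value.  Normality
(Shapiro-Wilk per group) and variance homogeneity (Levene) checks are
advisory: they are reported but never change the analysis path.  An
optional Holm adjustment across bands and a Welch ANOVA variant are
available behind flags, both off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .bands import band_order_index
from .records import MetricTable

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class ZeroVarianceError(ValueError):
    """All values identical: ANOVA undefined."""


class InsufficientDataError(ValueError):
    pass


def stars_for_p(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


@dataclass
class AssumptionReport:
    """Advisory normality / homogeneity diagnostics for one comparison."""

    shapiro_p: dict[str, float]  # per-group; nan for degenerate (constant) groups
    levene_p: float
    flags: list[str] = field(default_factory=list)


def assumption_checks(groups: list[np.ndarray], labels: list[str] | None = None) -> AssumptionReport:
    """Shapiro-Wilk normality per group and Levene homogeneity across groups.

    Advisory only; degenerate (constant) groups get a nan normality p and a
    flag rather than an error.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    flags = []
    shapiro_p = {}
    for lab, g in zip(labels, groups):
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            raise InsufficientDataError(f"group {lab!r} has n={g.size} < 3")
        if np.ptp(g) == 0:
            shapiro_p[lab] = float("nan")
            flags.append(f"normality undefined for constant group {lab!r}")
        else:
            shapiro_p[lab] = float(sst.shapiro(g).pvalue)
    try:
        levene_p = float(sst.levene(*groups, center="median").pvalue)
    except ValueError:
        levene_p = float("nan")
        flags.append("variance homogeneity undefined")
    return AssumptionReport(shapiro_p=shapiro_p, levene_p=levene_p, flags=flags)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Classical one-way fixed-effects ANOVA: returns (F, p, eta_squared).

    eta^2 = SS_between / SS_total from the direct sum-of-squares
    decomposition; F = (SS_between/df_b) / (SS_within/df_w).
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(groups):
        if g.size < 2:
            raise InsufficientDataError(f"group {i} has n={g.size} < 2")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise ZeroVarianceError("all values identical; ANOVA undefined")
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    eta_sq = ss_between / ss_total
    if ss_within == 0:
        return float("inf"), 0.0, eta_sq
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(sst.f.sf(f_stat, df_b, df_w))
    return f_stat, p, eta_sq


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA: returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    vars_ = np.array([g.var(ddof=1) for g in groups])
    if np.any(vars_ == 0):
        raise ZeroVarianceError("constant group; Welch ANOVA undefined")
    w = ns / vars_
    mw = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1))
    den = 1 + 2 * (k - 2) * lam / (k**2 - 1)
    f_stat = float(num / den)
    df2 = float((k**2 - 1) / (3 * lam))
    p = float(sst.f.sf(f_stat, k - 1, df2))
    return f_stat, p


@dataclass
class GroupComparison:
    """One band's four-group comparison for one metric."""

    metric_name: str
    band: str
    group_summaries: dict[str, dict[str, float]]  # group -> {n, mean, sem}
    F: float
    p: float
    eta_squared: float
    stars: str
    assumptions: AssumptionReport | None = None


def compare_groups(
    table: MetricTable,
    group_order: list[str],
    holm: bool = False,
    welch: bool = False,
    check_assumptions: bool = True,
) -> list[GroupComparison]:
    """Per-band ANOVA over a metric table, in canonical band order.

    ``holm`` applies a Holm step-down adjustment to the p-values across
    bands (stars then follow the adjusted p); ``welch`` swaps in Welch's
    ANOVA for the F and p (eta-squared stays the classical SS ratio).
    """
    bands = sorted(table.data["band"].unique(), key=band_order_index)
    comparisons = []
    for band in bands:
        groups = table.group_values(band, group_order)
        f_stat, p, eta_sq = one_way_anova(groups)
        if welch:
            f_stat, p = welch_anova(groups)
        summaries = {
            g: {
                "n": int(v.size),
                "mean": float(v.mean()),
                "sem": float(sst.sem(v)) if v.size > 1 else float("nan"),
            }
            for g, v in zip(group_order, groups)
        }
        assumptions = None
        if check_assumptions:
            try:
                assumptions = assumption_checks(groups, group_order)
            except InsufficientDataError:
                pass  # advisory only; too-small groups never block the ANOVA
        comparisons.append(
            GroupComparison(
                metric_name=table.metric_name,
                band=band,
                group_summaries=summaries,
                F=f_stat,
                p=p,
                eta_squared=eta_sq,
                stars="",
                assumptions=assumptions,
            )
        )
    ps = np.array([c.p for c in comparisons])
    if holm:
        from statsmodels.stats.multitest import multipletests

        ps = multipletests(ps, method="holm")[1]
    for c, p in zip(comparisons, ps):
        c.p = float(p)
        c.stars = stars_for_p(float(p))
    return comparisons


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into a tidy table (one row per band)."""
    rows = []
    for c in comparisons:
        row: dict = {"metric": c.metric_name, "band": c.band}
        for g, s in c.group_summaries.items():
            row[f"{g}_n"] = s["n"]
            row[f"{g}_mean"] = s["mean"]
            row[f"{g}_sem"] = s["sem"]
        row.update(F=c.F, p=c.p, eta_squared=c.eta_squared, stars=c.stars)
        if c.assumptions is not None:
            row["levene_p"] = c.assumptions.levene_p
            row["min_shapiro_p"] = float(np.nanmin(list(c.assumptions.shapiro_p.values())))
        rows.append(row)
    return pd.DataFrame(rows)
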