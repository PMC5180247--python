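"""Differentially changed elements (DCEs).

Group comparisons are cross-sectional: animals at each time point are
distinct, so the two-sample Wilcoxon rank-sum (Mann-Whitney) test applies.
An element is a DCE between two groups at a time point when the two-sided
rank-sum p-value is below alpha (default 0.05, uncorrected — a
Benjamini-Hochberg option is available but off by default); its direction
is the sign of the median difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import IonomeDataset


@dataclass
class AnovaResult:
    f_group: float
    p_group: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value.

    Exact by enumeration of the null permutation distribution when both
    samples have n <= 8 and the pooled data are tie-free; otherwise midranks
    with the tie-corrected normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact = len(a) <= 8 and len(b) <= 8 and not _has_ties(pooled)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def dce_scan(dataset: IonomeDataset, reference_group: str, comparison_group: str,
             alpha: float = 0.05, bh_correct: bool = False) -> pd.DataFrame:
    """Scan all (element, shared time point) pairs for DCEs.

    Direction is relative to the reference: "increased" means the comparison
    group's median exceeds the reference median. Records are sorted by time
    then by canonical element order. With ``bh_correct`` the significance
    call uses Benjamini-Hochberg adjusted p-values (column ``q_value``).
    """
    times = dataset.shared_timepoints(reference_group, comparison_group)
    if not times:
        raise ValueError(f"groups {reference_group!r} and {comparison_group!r} "
                         "share no time points")
    rows = []
    for t in times:
        for e in dataset.element_order:
            ref = dataset.cell_values(reference_group, t, e)
            comp = dataset.cell_values(comparison_group, t, e)
            if len(ref) < 3 or len(comp) < 3:
                raise ValueError(f"cell ({t}, {e}) has fewer than 3 replicates")
            p = wilcoxon_rank_sum(ref, comp)
            diff = float(np.median(comp) - np.median(ref))
            direction = "increased" if diff > 0 else (
                "decreased" if diff < 0 else "unchanged")
            rows.append((e, t, reference_group, comparison_group, p, diff,
                         direction))
    out = pd.DataFrame(rows, columns=[
        "element", "time_months", "reference_group", "comparison_group",
        "p_value", "median_difference", "direction"])
    if bh_correct:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["is_dce"] = out["q_value"] < alpha
    else:
        out["is_dce"] = out["p_value"] < alpha
    return out


def dce_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Condense a DCE scan into one row per time point with the lists of
    increased and decreased elements (the usual publication table shape)."""
    rows = []
    for t, sub in records.groupby("time_months"):
        sig = sub[sub["is_dce"]]
        rows.append((
            t,
            ", ".join(sig.loc[sig["direction"] == "increased", "element"]) or "-",
            ", ".join(sig.loc[sig["direction"] == "decreased", "element"]) or "-",
        ))
    return pd.DataFrame(rows, columns=["time_months", "increased", "decreased"])


def anova_group_time(dataset: IonomeDataset, element: str,
                     groups: tuple[str, str]) -> AnovaResult:
    """Two-way fixed-effects ANOVA of concentration on group x time.

    Animals are sacrificed at their time point, so time is a between-subject
    factor here, not a repeated measure. Restricted to the time points the
    two groups share; an empty cell raises with the cell named.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    g1, g2 = groups
    times = dataset.shared_timepoints(g1, g2)
    if len(times) < 2:
        raise ValueError("need at least 2 shared time points for the ANOVA")
    df = dataset.records
    sub = df[(df["element"] == element) & df["group"].isin(groups)
             & df["time_months"].isin(times)].copy()
    for g in groups:
        for t in times:
            cell = sub[(sub["group"] == g) & (sub["time_months"] == t)]
            if len(cell) < 2:
                raise ValueError(f"cell (group={g}, time={t}) has < 2 replicates")
    model = ols("concentration ~ C(group) * C(time_months)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return AnovaResult(
        f_group=float(table.loc["C(group)", "F"]),
        p_group=float(table.loc["C(group)", "PR(>F)"]),
        f_time=float(table.loc["C(time_months)", "F"]),
        p_time=float(table.loc["C(time_months)", "PR(>F)"]),
        f_interaction=float(table.loc["C(group):C(time_months)", "F"]),
        p_interaction=float(table.loc["C(group):C(time_months)", "PR(>F)"]),
    )
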