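"""QC stage: Dixon's Q outlier screen with mean replacement, and a
normality screen justifying nonparametric group tests.

Dixon's Q (the r10 ratio) tests a single suspect value in a small sample:
Q = (gap between the extreme and its nearest neighbour) / (sample range).
It is only tabulated for 3 <= n <= 10, which fits the six-replicate design.
A flagged value is replaced by the mean of the remaining replicates in the
same cell — conservative imputation that keeps the cell size intact for
downstream rank statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .dataset import IonomeDataset

# Two-tailed critical values for Dixon's r10 ratio at alpha = 0.05
# (classical table, e.g. Rorabacher, Anal. Chem. 1991, Table 1).
DIXON_Q_CRITICAL_05: dict[int, float] = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
    8: 0.526, 9: 0.493, 10: 0.466,
}


@dataclass
class QcReport:
    """Outcome of the QC pass on one (group, time, element) cell."""

    group: str
    time: float
    element: str
    n: int
    q_statistic: float
    q_critical: float
    outlier_index: int | None
    outlier_value: float | None
    replaced_value: float | None
    ks_p: float


def dixon_q(values) -> tuple[float, int | None]:
    """Dixon's r10 statistic and the suspect's index in the original order.

    Both extremes are tested; the larger Q wins. An all-equal sample has
    zero range and returns (0.0, None).
    """
    x = np.asarray(values, float)
    n = len(x)
    if not 3 <= n <= 10:
        raise ValueError(f"Dixon's Q is tabulated for 3 <= n <= 10, got n={n}")
    order = np.argsort(x, kind="stable")
    s = x[order]
    rng = s[-1] - s[0]
    if rng == 0:
        return 0.0, None
    q_low = (s[1] - s[0]) / rng
    q_high = (s[-1] - s[-2]) / rng
    if q_high >= q_low:
        return float(q_high), int(order[-1])
    return float(q_low), int(order[0])


def detect_and_replace(values, alpha: float = 0.05):
    """Single-pass Dixon screen on one cell.

    If Q exceeds the tabulated critical value the suspect is replaced by the
    arithmetic mean of the remaining values. At most one replacement is made:
    the test is defined for one suspect value and n = 6 leaves no room for
    iterative cascades.

    Returns ``(cleaned_values, q_statistic, q_critical, outlier_index,
    replaced_value)`` where the last two are None when nothing was flagged.
    """
    if alpha != 0.05:
        raise ValueError("only the alpha = 0.05 critical table is shipped")
    x = np.asarray(values, float)
    q, suspect = dixon_q(x)
    q_crit = DIXON_Q_CRITICAL_05[len(x)]
    if suspect is None or q <= q_crit:
        return x.copy(), q, q_crit, None, None
    rest = np.delete(x, suspect)
    cleaned = x.copy()
    replacement = float(rest.mean())
    cleaned[suspect] = replacement
    return cleaned, q, q_crit, int(suspect), replacement


def ks_normality(values, estimated_params: bool = True) -> float:
    """P-value of a Kolmogorov-Smirnov-type composite normality test.

    With ``estimated_params`` (default) the mean and sd are estimated from
    the sample and the Lilliefors small-sample calibration is used; otherwise
    a plain KS test against N(mean, sd) with the sample moments plugged in
    (anti-conservative, provided for comparison only).
    """
    x = np.asarray(values, float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations for the normality screen")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality is undefined")
    if estimated_params:
        return float(lilliefors(x, dist="norm", pvalmethod="table")[1])
    return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


def qc_dataset(dataset: IonomeDataset, alpha: float = 0.05
               ) -> tuple[IonomeDataset, pd.DataFrame]:
    """Run the Dixon + normality screen over every (group, time, element) cell.

    Returns the cleaned dataset (flagged outliers mean-replaced) and a report
    table with one row per cell.
    """
    df = dataset.records.copy()
    reports: list[QcReport] = []
    for (g, t, e), sub in df.groupby(["group", "time_months", "element"],
                                     sort=True):
        idx = sub.index[np.argsort(sub["sample_id"].to_numpy())]
        x = df.loc[idx, "concentration"].to_numpy(float)
        cleaned, q, q_crit, suspect, replacement = detect_and_replace(x, alpha)
        df.loc[idx, "concentration"] = cleaned
        try:
            ks_p = ks_normality(cleaned)
        except ValueError:
            ks_p = float("nan")
        reports.append(QcReport(
            group=g, time=t, element=e, n=len(x), q_statistic=q,
            q_critical=q_crit, outlier_index=suspect,
            outlier_value=None if suspect is None else float(x[suspect]),
            replaced_value=replacement, ks_p=ks_p))
    report = pd.DataFrame([r.__dict__ for r in reports])
    return IonomeDataset(df, dataset.element_order), report
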