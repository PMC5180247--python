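"""Synthetic ionome generator with planted effects.

Concentrations are drawn per (group, time) cell from a log-normal Gaussian
copula: a latent multivariate normal vector z with unit variances and a
correlation matrix built from the planted Spearman targets is mapped to

    concentration[e] = cell_mean[e] * exp(sigma[e] * z[e])

so marginals are log-normal (positive, right-skewed, like ICP-MS tissue
data) and each planted pair attains its target rank correlation exactly in
population via the copula identity r = 2 sin(pi * rho_s / 6), where r is
the latent Pearson correlation. Rank correlations are preserved by the
monotone exp transform. After exponentiation each observation independently
becomes a gross outlier (multiplied by ``outlier_multiplier``) with
probability ``outlier_rate``.

The default configuration mirrors a three-group longitudinal mouse study:
wild-type (WT), a transgenic Alzheimer's model (AD) and a selenium-treated
transgenic group (Se); time points 2-12 months (the Se group starts at 4);
six animals per group x time cell; 15 elements — 102 animals in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import ELEMENTS, IonomeDataset

GROUPS = ("WT", "AD", "Se")

#: Baseline cell means, arbitrary concentration units, ordered roughly like
#: mammalian brain tissue (major minerals >> trace metals >> ultratrace).
BASELINE_MEANS: dict[str, float] = {
    "Ca": 400.0, "Mg": 300.0, "Fe": 60.0, "Zn": 50.0, "Cu": 12.0,
    "Mn": 1.5, "Se": 0.4, "Cr": 0.3, "Pb": 0.2, "V": 0.05,
    "Co": 0.05, "As": 0.05, "Cd": 0.02, "Hg": 0.02, "Bi": 0.01,
}

#: Default log-scale sd per element (~20% coefficient of variation).
DEFAULT_CV = 0.2

#: Planted mean shifts, in log-scale sd units. Positive = elevated.
SHIFT_SD = 3.0


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study.

    ``cell_means[(group, time, element)]`` is the log-scale location
    (i.e. the median concentration); ``cell_cv[element]`` the log-scale sd;
    ``planted_correlations`` a list of (group, time, elementA, elementB,
    target Spearman rho) tuples. Pairs not listed are independent in the
    latent copula.
    """

    groups: tuple[str, ...]
    timepoints_by_group: dict[str, tuple[float, ...]]
    n_replicates: int
    elements: tuple[str, ...]
    cell_means: dict[tuple[str, float, str], float]
    cell_cv: dict[str, float]
    planted_correlations: list[tuple[str, float, str, str, float]] = field(
        default_factory=list)
    outlier_rate: float = 0.0
    outlier_multiplier: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        self.elements = tuple(self.elements)
        self.validate()

    def validate(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3 (small-sample outlier "
                             "testing needs at least 3 replicates)")
        unknown_groups = set(self.timepoints_by_group) - set(self.groups)
        if unknown_groups:
            raise ValueError(f"timepoints_by_group keys not in groups: {unknown_groups}")
        for g, t, a, b, rho in self.planted_correlations:
            if a == b:
                raise ValueError(f"planted correlation references {a} twice")
            if a not in self.elements or b not in self.elements:
                raise ValueError(f"planted pair ({a}, {b}) not in element panel")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"planted rho {rho} for ({a}, {b}) not in (-1, 1)")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")

    @property
    def n_animals(self) -> int:
        return self.n_replicates * sum(
            len(self.timepoints_by_group[g]) for g in self.groups)

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["elements"] = list(self.elements)
        d["timepoints_by_group"] = {g: list(t) for g, t in
                                    self.timepoints_by_group.items()}
        d["cell_means"] = [
            {"group": g, "time": t, "element": e, "mean": m}
            for (g, t, e), m in self.cell_means.items()]
        d["planted_correlations"] = [list(p) for p in self.planted_correlations]
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cell_means"] = {(r["group"], r["time"], r["element"]): r["mean"]
                           for r in d["cell_means"]}
        d["timepoints_by_group"] = {g: tuple(t) for g, t in
                                    d["timepoints_by_group"].items()}
        d["planted_correlations"] = [tuple(p) for p in d["planted_correlations"]]
        return cls(**d)


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho_s`` under a
    Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-design mirror of the three-group brain ionome experiment.

    Planted structure:

    * AD vs WT — Fe and Zn elevated from 8 months (disease signature).
    * Se vs AD — Se elevated at every Se-group time point (supplementation),
      Fe and Zn back at WT level from 8 months (treatment reversal).
    * Conserved correlated blocks {Zn, Cu}, {Fe, V}, {Pb, Cd, Bi} in every
      cell, plus an Se-Ca correlation only in the Se-treated group.
    * Fe-Mn correlation reversal at 4 months: strongly positive in AD,
      negative in WT and in the Se-treated group.

    Mean shifts are 3 log-scale sd, large enough for rank tests at n = 6.
    """
    timepoints = {"WT": (2., 4., 6., 8., 10., 12.),
                  "AD": (2., 4., 6., 8., 10., 12.),
                  "Se": (4., 6., 8., 10., 12.)}
    cv = {e: DEFAULT_CV for e in ELEMENTS}
    shift = math.exp(SHIFT_SD * DEFAULT_CV)

    means: dict[tuple[str, float, str], float] = {}
    for g in GROUPS:
        for t in timepoints[g]:
            for e in ELEMENTS:
                m = BASELINE_MEANS[e]
                if g == "AD" and t >= 8 and e in ("Fe", "Zn"):
                    m *= shift
                if g == "Se" and e == "Se":
                    m *= shift
                means[(g, t, e)] = m

    planted: list[tuple[str, float, str, str, float]] = []
    for g in GROUPS:
        for t in timepoints[g]:
            planted += [(g, t, "Zn", "Cu", 0.85),
                        (g, t, "Pb", "Cd", 0.80),
                        (g, t, "Pb", "Bi", 0.80),
                        (g, t, "Cd", "Bi", 0.80)]
            if t != 4:
                planted.append((g, t, "Fe", "V", 0.85))
            if g == "Se":
                planted.append((g, t, "Se", "Ca", 0.90))
    # Fe-Mn reversal at 4 months (treatment pushes the AD correlation back
    # toward the WT state).
    planted += [("AD", 4., "Fe", "Mn", 0.90),
                ("WT", 4., "Fe", "Mn", -0.60),
                ("Se", 4., "Fe", "Mn", -0.32)]

    return SyntheticConfig(
        groups=GROUPS,
        timepoints_by_group=timepoints,
        n_replicates=6,
        elements=ELEMENTS,
        cell_means=means,
        cell_cv=cv,
        planted_correlations=planted,
        outlier_rate=0.01,
        outlier_multiplier=5.0,
        seed=seed,
    )


def _cell_latent_correlation(config: SyntheticConfig, group: str,
                             time: float) -> np.ndarray:
    E = len(config.elements)
    idx = {e: i for i, e in enumerate(config.elements)}
    R = np.eye(E)
    for g, t, a, b, rho in config.planted_correlations:
        if g == group and t == time:
            r = spearman_to_latent_pearson(rho)
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    # fail loudly rather than repairing: a silently "nearest-PD" matrix
    # would not honour the planted targets
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin <= 1e-10:
        raise ValueError(
            f"planted correlations for cell ({group}, {time}) imply a "
            f"non-positive-definite latent matrix (min eigenvalue {eigmin:.3g})")
    return R


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> IonomeDataset:
    """Draw one dataset from the configured copula model.

    Identical (config, seed) pairs yield identical tables. ``seed=None``
    falls back to ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for g in config.groups:
        for t in config.timepoints_by_group[g]:
            R = _cell_latent_correlation(config, g, t)
            L = np.linalg.cholesky(R)
            z = rng.standard_normal((config.n_replicates, len(config.elements))) @ L.T
            sigma = np.array([config.cell_cv[e] for e in config.elements])
            mu = np.array([config.cell_means[(g, t, e)] for e in config.elements])
            conc = mu * np.exp(sigma * z)
            if config.outlier_rate > 0:
                mask = rng.random(conc.shape) < config.outlier_rate
                conc = np.where(mask, conc * config.outlier_multiplier, conc)
            for i in range(config.n_replicates):
                sid = f"{g}_{int(t):02d}m_{i + 1}"
                for j, e in enumerate(config.elements):
                    rows.append((sid, g, t, e, conc[i, j]))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "time_months",
                                     "element", "concentration"])
    return IonomeDataset(df, config.elements)


def inject_known_outlier(dataset: IonomeDataset, cell: tuple[str, float, str],
                         index: int, multiplier: float) -> IonomeDataset:
    """Multiply one replicate of one cell by ``multiplier`` (QC fixture).

    ``index`` counts replicates of the cell in stable sample_id order.
    Returns a modified copy; the input is untouched.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    group, time, element = cell
    df = dataset.records
    m = ((df["group"] == group) & (df["time_months"] == time)
         & (df["element"] == element))
    cell_idx = df.index[m][np.argsort(df.loc[m, "sample_id"].to_numpy())]
    if len(cell_idx) == 0:
        raise KeyError(f"unknown cell {cell}")
    if not 0 <= index < len(cell_idx):
        raise IndexError(f"replicate index {index} out of range for cell with "
                         f"{len(cell_idx)} replicates")
    out = df.copy()
    out.loc[cell_idx[index], "concentration"] *= multiplier
    return IonomeDataset(out, dataset.element_order)
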