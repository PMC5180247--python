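"""Tidy container for an ionome panel and its delimited-table round trip.

A dataset is one row per (animal, element) measurement. Every animal
(``sample_id``) belongs to exactly one (group, time) cell because animals
are sacrificed at their time point; there are no repeated measures across
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical element panel, in the order used throughout the package.
ELEMENTS: tuple[str, ...] = (
    "Se", "Fe", "Zn", "Cu", "Mg", "Hg", "Ca", "Cr",
    "V", "Mn", "Cd", "Co", "Pb", "As", "Bi",
)

REQUIRED_COLUMNS = ("sample_id", "group", "time_months", "element", "concentration")


@dataclass
class IonomeDataset:
    """Long-format elemental concentrations with design metadata.

    Parameters
    ----------
    records
        DataFrame with columns ``sample_id, group, time_months, element,
        concentration``. Concentrations are strictly positive, in arbitrary
        concentration units.
    element_order
        Canonical ordering of the element symbols (defaults to the
        15-element panel).
    """

    records: pd.DataFrame
    element_order: tuple[str, ...] = field(default=ELEMENTS)

    def __post_init__(self) -> None:
        self.element_order = tuple(self.element_order)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=["sample_id", "element"])
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise ValueError(f"duplicate (sample_id, element) rows at index {rows}")
        bad = df["concentration"] <= 0
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ValueError(f"non-positive concentrations at rows {rows}")
        design = df.groupby("sample_id")[["group", "time_months"]].nunique()
        conflicted = design[(design > 1).any(axis=1)]
        if not conflicted.empty:
            raise ValueError(
                f"sample_ids mapped to more than one (group, time): "
                f"{conflicted.index.tolist()[:5]}"
            )

    # -- views ---------------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return sorted(self.records["group"].unique())

    def timepoints(self, group: str) -> list[float]:
        sub = self.records.loc[self.records["group"] == group, "time_months"]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return sorted(sub.unique())

    def shared_timepoints(self, group_a: str, group_b: str) -> list[float]:
        return sorted(set(self.timepoints(group_a)) & set(self.timepoints(group_b)))

    def cell_values(self, group: str, time: float, element: str) -> np.ndarray:
        """Replicate concentrations for one (group, time, element) cell,
        in stable sample_id order."""
        df = self.records
        m = (
            (df["group"] == group)
            & (df["time_months"] == time)
            & (df["element"] == element)
        )
        sub = df.loc[m].sort_values("sample_id")
        if sub.empty:
            raise KeyError(f"no data for cell ({group}, {time}, {element})")
        return sub["concentration"].to_numpy(float)

    def wide(self, group: str, time: float) -> pd.DataFrame:
        """Samples x elements concentration matrix for one (group, time) cell."""
        df = self.records
        sub = df[(df["group"] == group) & (df["time_months"] == time)]
        if sub.empty:
            raise KeyError(f"no data for cell ({group}, {time})")
        w = sub.pivot(index="sample_id", columns="element", values="concentration")
        cols = [e for e in self.element_order if e in w.columns]
        extra = [e for e in w.columns if e not in self.element_order]
        return w[cols + sorted(extra)]

    def copy(self) -> "IonomeDataset":
        return IonomeDataset(self.records.copy(), self.element_order)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_ionome_table(dataset: IonomeDataset, path: str | Path) -> Path:
    """Write the canonical long-format table (TSV for .tsv/.tab, else CSV)."""
    path = Path(path)
    dataset.records.to_csv(path, sep=_sep_for(path), index=False,
                           columns=list(REQUIRED_COLUMNS))
    return path


def read_ionome_table(path: str | Path,
                      element_order: tuple[str, ...] = ELEMENTS) -> IonomeDataset:
    """Read and validate a long-format concentration table.

    Unknown element symbols are accepted with a warning; duplicate
    (sample, element) rows and non-positive concentrations are rejected
    with the offending row numbers.
    """
    import warnings

    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = sorted(set(df["element"]) - set(element_order))
    if unknown:
        warnings.warn(f"{path}: element symbols outside the canonical panel: {unknown}")
        element_order = tuple(element_order) + tuple(unknown)
    return IonomeDataset(df, element_order)
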