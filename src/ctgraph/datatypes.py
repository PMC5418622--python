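"""Core in-memory containers for single-cell qPCR data.

The raw instrument readout is a matrix of cycle-threshold (Ct) values, one
row per captured cell and one column per TaqMan assay.  Undetected wells are
held internally as ``NaN``; on disk they may be blank, ``NA`` or an
instrument sentinel such as ``999``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Allowed per-cell quality-control flags.  ``empty`` and ``doublet`` mirror
#: the capture-site image QC of microfluidic single-cell chips.
QC_FLAGS = ("ok", "empty", "doublet")

#: Marker-panel categories recognised throughout the package.
PANEL_CATEGORIES = (
    "pluripotency",
    "definitive_endoderm",
    "hepatoblast",
    "hepatocyte",
    "epithelial",
    "mesenchymal",
    "control",
    "other",
)


def _as_str_list(x: Iterable) -> list[str]:
    return [str(v) for v in x]


@dataclass
class CtMatrix:
    """Raw Ct values per cell x assay with day labels and QC flags.

    ``values[i, j]`` is the Ct of assay ``assay_ids[j]`` in cell
    ``cell_ids[i]``; ``NaN`` marks an undetected well.  Every cell carries an
    integer day-of-differentiation label and a QC flag.
    """

    values: np.ndarray
    cell_ids: list[str]
    day: np.ndarray
    assay_ids: list[str]
    control_assays: list[str] = field(default_factory=list)
    qc_flags: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _as_str_list(self.cell_ids)
        self.assay_ids = _as_str_list(self.assay_ids)
        self.control_assays = _as_str_list(self.control_assays)
        self.day = np.asarray(self.day, dtype=int)
        if self.qc_flags is None:
            self.qc_flags = ["ok"] * len(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cell x assay matrix")
        n, m = self.values.shape
        if len(self.cell_ids) != n or len(self.day) != n or len(self.qc_flags) != n:
            raise ValueError("cell_ids, day and qc_flags must match the row count")
        if len(self.assay_ids) != m:
            raise ValueError("assay_ids must match the column count")
        detected = ~np.isnan(self.values)
        if np.any(~np.isfinite(self.values[detected])):
            raise ValueError("detected Ct values must be finite")
        if np.any(self.values[detected] <= 0):
            raise ValueError("detected Ct values must be > 0")
        unknown = set(self.control_assays) - set(self.assay_ids)
        if unknown:
            raise ValueError(f"control assays not in assay_ids: {sorted(unknown)}")
        bad_flags = set(self.qc_flags) - set(QC_FLAGS)
        if bad_flags:
            raise ValueError(f"unknown QC flags: {sorted(bad_flags)}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def undetected(self) -> np.ndarray:
        """Boolean mask of undetected wells."""
        return np.isnan(self.values)

    def subset_cells(self, index: np.ndarray) -> "CtMatrix":
        """Row subset by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CtMatrix(
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            day=self.day[index],
            assay_ids=list(self.assay_ids),
            control_assays=list(self.control_assays),
            qc_flags=[self.qc_flags[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.cell_ids, columns=self.assay_ids)
        df.insert(0, "day", self.day)
        df.insert(1, "qc", self.qc_flags)
        df.index.name = "cell_id"
        return df

    def __eq__(self, other: object) -> bool:  # value equality incl. NaN wells
        if not isinstance(other, CtMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.assay_ids == other.assay_ids
            and self.control_assays == other.control_assays
            and self.qc_flags == other.qc_flags
            and np.array_equal(self.day, other.day)
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class ExpressionMatrix:
    """Nonnegative relative expression (log2 units above LOD) per cell x gene.

    A value of exactly zero means the gene was undetected (Ct at or above the
    limit of detection) in that cell.
    """

    values: np.ndarray
    cell_ids: list[str]
    day: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _as_str_list(self.cell_ids)
        self.gene_ids = _as_str_list(self.gene_ids)
        self.day = np.asarray(self.day, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cell x gene matrix")
        n, m = self.values.shape
        if len(self.cell_ids) != n or len(self.day) != n:
            raise ValueError("cell_ids and day must match the row count")
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids must match the column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(
                f"gene {gene!r} not present; available genes: {self.gene_ids}"
            ) from None

    def gene(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across cells."""
        return self.values[:, self.gene_index(gene)]

    def cells_on_day(self, day: int) -> np.ndarray:
        return self.day == int(day)

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            day=self.day[index],
            gene_ids=list(self.gene_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)
        df.insert(0, "day", self.day)
        df.index.name = "cell_id"
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.day, other.day)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class MarkerPanel:
    """Maps each gene of the assay panel to exactly one marker category."""

    categories: dict[str, str]

    def __post_init__(self) -> None:
        self.categories = {str(g): str(c) for g, c in self.categories.items()}
        bad = set(self.categories.values()) - set(PANEL_CATEGORIES)
        if bad:
            raise ValueError(
                f"unknown panel categories {sorted(bad)}; "
                f"allowed: {PANEL_CATEGORIES}"
            )

    def category(self, gene: str) -> str:
        return self.categories[gene]

    def genes_in(self, category: str) -> list[str]:
        return [g for g, c in self.categories.items() if c == category]

    def __contains__(self, gene: str) -> bool:
        return gene in self.categories

    def __len__(self) -> int:
        return len(self.categories)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.categories), "category": list(self.categories.values())}
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "MarkerPanel":
        return cls(dict(mapping))
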