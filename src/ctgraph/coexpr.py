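"""Gene-gene correlation clustering and marker co-detection statistics.

Two complementary views of marker relationships at single-cell resolution:

* correlation clustering over a day range — Pearson correlation of gene
  expression across cells, average-linkage hierarchical clustering on
  ``1 - r``, with a flat cut (default 2 clusters) that, in a staged EMT,
  separates the epithelial/pluripotency module (CDH1, POU5F1, SOX2) from
  the mesenchymal/DE module (CDH2, SOX17, GATA4/6, FOXA2);

* coincidence/exclusivity — per gene pair and day, the 2x2 detection table
  (both / A-only / B-only / neither), co-detection fraction, Jaccard index,
  a Haldane-Anscombe-corrected odds ratio, and the expression correlation
  among cells detecting at least one of the pair.  A small odds ratio
  flags mutually exclusive markers (e.g. SOX17 vs CDH1 in DE cells), a
  large one coincident markers (SOX17 vs CDH2).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from .datatypes import ExpressionMatrix, MarkerPanel

log = logging.getLogger(__name__)

#: Default odds-ratio cutoffs for the exclusivity labels.
EXCLUSIVE_BELOW = 0.2
COINCIDENT_ABOVE = 5.0


@dataclass
class CorrelationResult:
    """Gene correlation matrix with its hierarchical clustering."""

    correlation: pd.DataFrame  # gene x gene
    linkage_matrix: np.ndarray  # scipy merge tree
    cluster_labels: dict[str, int]  # flat labels at the requested cut
    dropped_genes: list[str]  # zero-variance genes excluded

    @property
    def genes(self) -> list[str]:
        return list(self.correlation.index)


@dataclass
class CoincidenceResult:
    """Co-detection statistics for one gene pair on one day."""

    gene_a: str
    gene_b: str
    day: int
    n_cells: int
    both: int
    a_only: int
    b_only: int
    neither: int
    co_detection_fraction: float
    jaccard: float
    odds_ratio: float
    expression_correlation: float

    def label(
        self,
        exclusive_below: float = EXCLUSIVE_BELOW,
        coincident_above: float = COINCIDENT_ABOVE,
    ) -> str:
        if self.odds_ratio < exclusive_below:
            return "exclusive"
        if self.odds_ratio > coincident_above:
            return "coincident"
        return "neither"


def gene_correlation(
    expr: ExpressionMatrix,
    day_range: tuple[int, int] = (0, 3),
    genes: list[str] | None = None,
    method: str = "pearson",
    linkage_method: str = "average",
    n_clusters: int = 2,
) -> CorrelationResult:
    """Correlate gene expression across cells of ``day_range`` (inclusive)
    and cluster the genes hierarchically on distance ``1 - r``.

    Zero-variance genes are excluded with a warning in the log.  Requires
    at least 3 cells in the range.
    """
    lo, hi = day_range
    mask = (expr.day >= lo) & (expr.day <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 cells in days {lo}..{hi}, found {int(mask.sum())}"
        )
    gene_list = genes if genes is not None else list(expr.gene_ids)
    idx = [expr.gene_index(g) for g in gene_list]
    X = expr.values[mask][:, idx]
    var = X.var(axis=0)
    dropped = [g for g, v in zip(gene_list, var) if v == 0]
    if dropped:
        log.warning("gene_correlation: dropping zero-variance genes %s", dropped)
    kept = [g for g, v in zip(gene_list, var) if v > 0]
    X = X[:, var > 0]
    if len(kept) < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    if method == "pearson":
        R = np.corrcoef(X.T)
    elif method == "spearman":
        R, _ = spearmanr(X)
        R = np.atleast_2d(R)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    corr = pd.DataFrame(R, index=kept, columns=kept)
    dist = squareform(np.clip(1.0 - R, 0.0, None), checks=False)
    Z = linkage(dist, method=linkage_method)
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = dict(zip(kept, (int(c) for c in flat)))
    return CorrelationResult(corr, Z, labels, dropped)


def detection_table(
    a: np.ndarray, b: np.ndarray, detection_floor: float = 0.0
) -> tuple[int, int, int, int]:
    """2x2 detection counts (both, A-only, B-only, neither)."""
    da = np.asarray(a) > detection_floor
    db = np.asarray(b) > detection_floor
    both = int(np.sum(da & db))
    a_only = int(np.sum(da & ~db))
    b_only = int(np.sum(~da & db))
    neither = int(np.sum(~da & ~db))
    return both, a_only, b_only, neither


def odds_ratio_from_table(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Odds ratio of co-detection; Haldane-Anscombe +0.5 on all four cells
    whenever any count is zero."""
    cells = [both, a_only, b_only, neither]
    if min(cells) == 0:
        both, a_only, b_only, neither = (c + 0.5 for c in cells)
    return (both * neither) / (a_only * b_only)


def coincidence(
    expr: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    day: int,
    detection_floor: float = 0.0,
) -> CoincidenceResult:
    """Co-detection statistics for a gene pair among the cells of one day.

    A cell "detects" a gene when its expression exceeds ``detection_floor``.
    The expression correlation is Pearson's r over cells detecting at least
    one of the pair (NaN if fewer than 2 such cells or degenerate).
    """
    mask = expr.cells_on_day(day)
    if mask.sum() < 1:
        raise ValueError(f"no cells on day {day}")
    a = expr.gene(gene_a)[mask]
    b = expr.gene(gene_b)[mask]
    both, a_only, b_only, neither = detection_table(a, b, detection_floor)
    n = both + a_only + b_only + neither
    union = both + a_only + b_only
    jaccard = both / union if union > 0 else 1.0  # two empty detection sets
    orat = odds_ratio_from_table(both, a_only, b_only, neither)
    any_det = (a > detection_floor) | (b > detection_floor)
    if any_det.sum() >= 2 and a[any_det].var() > 0 and b[any_det].var() > 0:
        r = float(pearsonr(a[any_det], b[any_det]).statistic)
    else:
        r = float("nan")
    return CoincidenceResult(
        gene_a=gene_a,
        gene_b=gene_b,
        day=int(day),
        n_cells=n,
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        co_detection_fraction=both / n,
        jaccard=jaccard,
        odds_ratio=float(orat),
        expression_correlation=r,
    )


def exclusivity_report(
    expr: ExpressionMatrix,
    panel: MarkerPanel,
    day: int,
    detection_floor: float = 0.0,
    exclusive_below: float = EXCLUSIVE_BELOW,
    coincident_above: float = COINCIDENT_ABOVE,
) -> pd.DataFrame:
    """Coincidence statistics for every (DE gene, epithelial or mesenchymal
    gene) pair on one day, ranked by odds ratio ascending.

    Each row is labelled ``exclusive`` (odds ratio below the lower cutoff),
    ``coincident`` (above the upper cutoff) or ``neither``.
    """
    de_genes = [g for g in panel.genes_in("definitive_endoderm") if g in expr.gene_ids]
    partners = [
        g
        for g in panel.genes_in("epithelial") + panel.genes_in("mesenchymal")
        if g in expr.gene_ids
    ]
    rows = []
    for a in de_genes:
        for b in partners:
            res = coincidence(expr, a, b, day, detection_floor)
            rows.append(
                {
                    "de_gene": a,
                    "partner_gene": b,
                    "partner_category": panel.category(b),
                    "day": res.day,
                    "both": res.both,
                    "a_only": res.a_only,
                    "b_only": res.b_only,
                    "neither": res.neither,
                    "co_detection_fraction": res.co_detection_fraction,
                    "jaccard": res.jaccard,
                    "odds_ratio": res.odds_ratio,
                    "expression_correlation": res.expression_correlation,
                    "label": res.label(exclusive_below, coincident_above),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "de_gene", "partner_gene", "partner_category", "day",
            "both", "a_only", "b_only", "neither",
            "co_detection_fraction", "jaccard", "odds_ratio",
            "expression_correlation", "label",
        ],
    )
    if len(df):
        df = df.sort_values("odds_ratio", kind="mergesort").reset_index(drop=True)
    return df
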