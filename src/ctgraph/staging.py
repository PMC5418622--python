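"""Bulk time-course staging and bulk-vs-pseudobulk concordance.

The bulk matrix is a gene x timepoint table of log-scale expression over a
differentiation time course.  PCA over the timepoints stages the samples
(pluripotent -> definitive endoderm -> hepatocyte-like); marker-panel
trajectories summarize each category as the mean per-gene z-score per
timepoint, with an EMT score defined as the mesenchymal minus the
epithelial trajectory; and pseudobulk concordance measures how well the
per-day average of single-cell expression recapitulates the matched bulk
column (squared Pearson correlation over shared genes).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import ExpressionMatrix, MarkerPanel
from .network import _pca

log = logging.getLogger(__name__)


@dataclass
class StageResult:
    """PCA staging of a bulk time course."""

    coordinates: pd.DataFrame  # timepoint x PC scores
    explained_variance_share: np.ndarray
    gene_loadings: pd.DataFrame  # gene x PC

    def ranked_loadings(self, pc: int = 1) -> pd.Series:
        """Gene loadings of one component ranked by magnitude (descending)."""
        col = f"PC{pc}"
        s = self.gene_loadings[col]
        return s.reindex(s.abs().sort_values(ascending=False).index)


@dataclass
class ConcordanceResult:
    """Squared Pearson correlation between pseudobulk and bulk at one day."""

    r2: float
    day: int
    n_genes: int
    table: pd.DataFrame  # per-gene (pseudobulk, bulk) pairs


def pca_timecourse(bulk: pd.DataFrame, n_pcs: int = 3) -> StageResult:
    """Gene-centered PCA over the timepoint samples of a bulk matrix.

    Requires at least 3 timepoints.  Returns sample coordinates, variance
    shares and the per-PC gene loadings (rank them with
    :meth:`StageResult.ranked_loadings`).
    """
    if bulk.shape[1] < 3:
        raise ValueError(f"PCA needs >= 3 samples, got {bulk.shape[1]}")
    X = bulk.to_numpy(float).T  # samples x genes
    if not np.all(np.isfinite(X)):
        raise ValueError("bulk matrix contains non-finite values")
    scores, shares, loadings, _rank = _pca(X, n_pcs)
    k = scores.shape[1]
    pc_names = [f"PC{i + 1}" for i in range(k)]
    return StageResult(
        coordinates=pd.DataFrame(scores, index=bulk.columns, columns=pc_names),
        explained_variance_share=shares,
        gene_loadings=pd.DataFrame(loadings, index=bulk.index, columns=pc_names),
    )


def panel_trajectory(bulk: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Per-category mean z-score per timepoint, plus an EMT score.

    Each gene is z-scored across timepoints (constant genes contribute
    zeros); a category's trajectory is the mean z-score of its genes
    present in the bulk matrix.  Categories with no present genes are
    omitted with a warning.  The ``emt_score`` row is the mesenchymal minus
    the epithelial trajectory when both are available.
    """
    z = bulk.sub(bulk.mean(axis=1), axis=0)
    sd = bulk.std(axis=1, ddof=0)
    # genes constant up to float rounding contribute zeros, not noise
    const = sd <= bulk.abs().max(axis=1).clip(lower=1.0) * 1e-12
    z = z.div(sd.where(~const, 1.0), axis=0)
    z[const] = 0.0
    missing = [g for g in panel.categories if g not in bulk.index]
    if missing:
        log.warning("panel_trajectory: genes absent from bulk matrix: %s", missing)
    rows = {}
    for cat in dict.fromkeys(panel.categories.values()):
        genes = [g for g in panel.genes_in(cat) if g in bulk.index]
        if not genes:
            log.warning("panel_trajectory: category %r has no present genes", cat)
            continue
        rows[cat] = z.loc[genes].mean(axis=0)
    traj = pd.DataFrame(rows).T
    if "mesenchymal" in traj.index and "epithelial" in traj.index:
        traj.loc["emt_score"] = traj.loc["mesenchymal"] - traj.loc["epithelial"]
    traj.index.name = "category"
    return traj


def pseudobulk_concordance(
    expr: ExpressionMatrix,
    bulk: pd.DataFrame,
    day: int,
    log2_bulk: bool = False,
) -> ConcordanceResult:
    """Squared Pearson correlation of pseudobulk vs the bulk column of ``day``.

    The pseudobulk is the mean relative expression per gene over that day's
    cells.  ``log2_bulk=True`` applies ``log2(x + 1)`` to the bulk side
    first, for bulk matrices given on a linear scale.  Requires at least 3
    shared genes.
    """
    if day not in bulk.columns:
        raise ValueError(f"day {day} not among bulk timepoints {list(bulk.columns)}")
    mask = expr.cells_on_day(day)
    if mask.sum() < 1:
        raise ValueError(f"no single cells on day {day}")
    pseudo = pd.Series(expr.values[mask].mean(axis=0), index=expr.gene_ids)
    shared = [g for g in expr.gene_ids if g in bulk.index]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 genes shared between single-cell and bulk, got {len(shared)}"
        )
    x = pseudo[shared].to_numpy(float)
    y = bulk.loc[shared, day].to_numpy(float)
    if log2_bulk:
        y = np.log2(y + 1.0)
    r = pearsonr(x, y).statistic
    table = pd.DataFrame({"gene": shared, "pseudobulk": x, "bulk": y})
    return ConcordanceResult(
        r2=float(r * r), day=int(day), n_genes=len(shared), table=table
    )
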