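"""Well QC and conversion of Ct values to relative expression.

Cells flagged as empty or doublet capture sites are removed, as are cells
whose control assays (GAPDH/ACTB) read undetected — a proxy for failed
wells when image-based flags are unavailable.  Relative expression is
defined on the log2 scale as the limit-of-detection Ct minus the observed
Ct, floored at zero: a well at or above the LOD counts as undetected (0),
and each cycle below the LOD doubles expression.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import CtMatrix, ExpressionMatrix

log = logging.getLogger(__name__)


def filter_cells(
    ct: CtMatrix, config: PipelineConfig | None = None
) -> tuple[CtMatrix, pd.DataFrame]:
    """Remove QC-failing cells.

    A cell is dropped when its capture site was flagged ``empty`` or
    ``doublet``, or when any control assay is undetected.  Returns the
    retained subset together with a log of removals (one row per removed
    cell with the reason).

    Raises
    ------
    ValueError
        If no control assays are designated, or every cell is removed.
    """
    if not ct.control_assays:
        raise ValueError("CtMatrix has no control assays designated")
    removed: list[tuple[str, str]] = []
    keep = np.ones(ct.n_cells, dtype=bool)
    ctrl_idx = [ct.assay_ids.index(a) for a in ct.control_assays]
    ctrl_undetected = np.isnan(ct.values[:, ctrl_idx]).any(axis=1)
    for i in range(ct.n_cells):
        if ct.qc_flags[i] in ("empty", "doublet"):
            keep[i] = False
            removed.append((ct.cell_ids[i], ct.qc_flags[i]))
        elif ctrl_undetected[i]:
            keep[i] = False
            removed.append((ct.cell_ids[i], "control_undetected"))
    if not keep.any():
        raise ValueError(
            "all cells removed by QC; review control assays and QC flags"
        )
    removals = pd.DataFrame(removed, columns=["cell_id", "reason"])
    if len(removals):
        log.info("filter_cells removed %d of %d cells", len(removals), ct.n_cells)
    return ct.subset_cells(keep), removals


def ct_to_relative_expression(
    ct: CtMatrix, config: PipelineConfig | None = None, delta_ct: bool = False
) -> ExpressionMatrix:
    """Convert Ct to relative expression ``r = max(0, lod_ct - Ct)``.

    Undetected wells map to 0.  With ``delta_ct=True`` the per-cell mean
    control Ct is subtracted from every detected well first (classic
    control-gene normalization), then the same LOD floor applies; this mode
    is off by default.

    Raises
    ------
    ValueError
        If any detected Ct is negative.
    """
    if config is None:
        config = PipelineConfig()
    values = ct.values
    detected = ~np.isnan(values)
    if np.any(values[detected] < 0):
        raise ValueError("negative Ct values are not valid cycle counts")
    work = values
    if delta_ct:
        ctrl_idx = [ct.assay_ids.index(a) for a in ct.control_assays]
        if not ctrl_idx:
            raise ValueError("delta_ct mode requires control assays")
        ctrl_mean = np.nanmean(values[:, ctrl_idx], axis=1)
        work = values - ctrl_mean[:, None] + np.nanmean(ctrl_mean)
    r = np.where(detected, np.clip(config.lod_ct - work, 0.0, None), 0.0)
    return ExpressionMatrix(
        values=r,
        cell_ids=list(ct.cell_ids),
        day=ct.day.copy(),
        gene_ids=list(ct.assay_ids),
    )
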