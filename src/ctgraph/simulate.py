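"""Synthetic single-cell qPCR time courses with planted EMT/DE structure.

The generator emulates a microfluidic qPCR experiment following human ES
cells through Activin A-induced definitive endoderm (DE) formation: staged
cell populations are drawn over days 0-3 (plus a small residual day-5/7
hESC-like population), each with a population-specific mean log2 expression
profile, cell-to-cell spread, and per-gene dropout.  Expression is converted
to Ct through the limit-of-detection relation ``Ct = lod_ct - expression``,
so downstream normalization recovers the drawn values exactly for detected
wells.

The planted structure mirrors what a real differentiation exhibits:

* day-0 cells are epithelial and pluripotent (CDH1, POU5F1, NANOG, SOX2);
* days 1-2 are transitional, with mesenchymal genes (CDH2, VIM, SNAI1)
  rising while CDH1 and the pluripotency module decline;
* day-3 DE cells co-express CDH2 with SOX17/GATA6/GATA4/FOXA2 and have
  lost CDH1 (the planted epithelial-to-mesenchymal transition);
* a small double-positive day-3 population co-expresses pluripotency and
  DE markers, and a few day-3 laggards remain hESC-like;
* residual hESC-like cells persist at days 5 and 7.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import PipelineConfig
from .datatypes import CtMatrix, ExpressionMatrix, MarkerPanel

# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

#: Named marker genes of the assay panel, by category.
PANEL_GENES: dict[str, str] = {
    "POU5F1": "pluripotency",
    "NANOG": "pluripotency",
    "SOX2": "pluripotency",
    "SOX17": "definitive_endoderm",
    "GATA4": "definitive_endoderm",
    "GATA6": "definitive_endoderm",
    "FOXA2": "definitive_endoderm",
    "EOMES": "definitive_endoderm",
    "GSC": "definitive_endoderm",
    "LGR5": "definitive_endoderm",
    "HNF4A": "hepatoblast",
    "AFP": "hepatoblast",
    "ALB": "hepatocyte",
    "TTR": "hepatocyte",
    "CDH1": "epithelial",
    "CDH2": "mesenchymal",
    "VIM": "mesenchymal",
    "SNAI1": "mesenchymal",
    "SNAI2": "mesenchymal",
    "ZEB1": "mesenchymal",
    "KLF8": "mesenchymal",
    "TGFB1": "mesenchymal",
}

N_MARKER_GENES = 46
CONTROL_GENES = ("GAPDH", "ACTB")

#: Synthetic filler assays padding the named markers to the 46-gene panel;
#: they carry a flat, population-independent baseline.
FILLER_GENES = tuple(
    f"FILLER{i:02d}" for i in range(1, N_MARKER_GENES - len(PANEL_GENES) + 1)
)


def default_panel() -> MarkerPanel:
    """Marker panel of the default scenario: 46 markers plus 2 controls."""
    cats = dict(PANEL_GENES)
    for g in FILLER_GENES:
        cats[g] = "other"
    for g in CONTROL_GENES:
        cats[g] = "control"
    return MarkerPanel(cats)


def panel_gene_order() -> list[str]:
    """Column order used by the default scenario (markers then controls)."""
    return list(PANEL_GENES) + list(FILLER_GENES) + list(CONTROL_GENES)


# ---------------------------------------------------------------------------
# Population specifications
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One homogeneous cell population of the simulated time course.

    ``mean_expression`` gives the noiseless mean relative expression (log2
    units above the detection limit) per gene; genes omitted from the
    mapping are silent (mean 0, never detected).  ``within_population_sd``
    and ``dropout_prob`` may be a single number applied to every expressed
    gene or a per-gene mapping.
    """

    name: str
    day: int
    n_cells: int
    mean_expression: dict[str, float]
    within_population_sd: float | dict[str, float] = 0.8
    dropout_prob: float | dict[str, float] = 0.05

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if any(m < 0 for m in self.mean_expression.values()):
            raise ValueError(f"population {self.name}: means must be >= 0")
        drops = (
            self.dropout_prob.values()
            if isinstance(self.dropout_prob, dict)
            else [self.dropout_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in drops):
            raise ValueError(f"population {self.name}: dropout_prob must be in [0,1]")

    def _vector(self, attr: str, genes: list[str], default: float) -> np.ndarray:
        spec = getattr(self, attr)
        if isinstance(spec, dict):
            return np.array([spec.get(g, default) for g in genes], float)
        return np.full(len(genes), float(spec))

    def means(self, genes: list[str]) -> np.ndarray:
        return np.array([self.mean_expression.get(g, 0.0) for g in genes], float)

    def sds(self, genes: list[str]) -> np.ndarray:
        sd = self._vector("within_population_sd", genes, default=0.0)
        sd[self.means(genes) == 0] = 0.0
        return sd

    def dropouts(self, genes: list[str]) -> np.ndarray:
        return self._vector("dropout_prob", genes, default=0.0)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "day": self.day,
            "n_cells": self.n_cells,
            "mean_expression": dict(self.mean_expression),
            "within_population_sd": self.within_population_sd,
            "dropout_prob": self.dropout_prob,
        }


def _profile(
    means: dict[str, float],
    filler_mean: float = 3.0,
    control_means: tuple[float, float] = (14.0, 13.5),
) -> dict[str, float]:
    """Complete a marker profile: silent named markers at 0, flat filler
    baseline, and control genes."""
    prof = {g: 0.0 for g in PANEL_GENES}
    prof.update(means)
    for g in FILLER_GENES:
        prof[g] = filler_mean
    prof["GAPDH"], prof["ACTB"] = control_means
    return prof


def _dropouts(
    means: dict[str, float], overrides: dict[str, float] | None = None
) -> dict[str, float]:
    """Expression-dependent dropout: detection failure is frequent for
    low-expressed genes and rare for abundant transcripts, as in real
    single-cell qPCR."""
    d = {}
    for g, mu in means.items():
        if mu >= 8.0:
            d[g] = 0.002
        elif mu >= 4.0:
            d[g] = 0.05
        else:
            d[g] = 0.3
    d["GAPDH"] = d["ACTB"] = 0.002  # controls detected in >=99% of cells
    if overrides:
        d.update(overrides)
    return d


def default_emt_scenario() -> list[PopulationSpec]:
    """The default staged differentiation: 501 cells, days 0-3 plus 5/7.

    Eight populations plant the expected structure: an epithelial
    pluripotent day-0 pool, two transitional days, a large day-3 DE
    population with CDH1 silenced, a small day-3 double-positive
    population, day-3 hESC-like laggards, and residual hESC-like cells at
    days 5 and 7.
    """
    profiles: list[tuple[str, int, int, dict[str, float], float]] = [
        # (name, day, n_cells, marker means, within-population sd)
        ("hesc_d0", 0, 120,
         {"CDH1": 12.0, "POU5F1": 12.0, "SOX2": 11.0, "NANOG": 11.0}, 0.8),
        ("transitional_d1", 1, 90,
         {"CDH1": 10.5, "POU5F1": 10.0, "SOX2": 9.5, "NANOG": 9.0,
          "CDH2": 3.0, "VIM": 3.0, "SNAI1": 3.5, "TGFB1": 3.0,
          "EOMES": 3.5, "GSC": 3.0}, 1.0),
        ("transitional_d2", 2, 90,
         {"CDH1": 8.0, "POU5F1": 8.0, "SOX2": 7.5, "NANOG": 7.0,
          "CDH2": 7.0, "VIM": 6.5, "SNAI1": 7.0, "SNAI2": 4.0,
          "ZEB1": 4.0, "KLF8": 3.5, "TGFB1": 5.0, "EOMES": 7.0,
          "GSC": 6.0, "SOX17": 5.0, "GATA6": 5.0, "LGR5": 3.5}, 1.0),
        ("de_d3", 3, 150,
         {"CDH2": 11.0, "VIM": 10.0, "SNAI1": 9.0, "SNAI2": 6.0,
          "ZEB1": 6.0, "KLF8": 5.0, "TGFB1": 7.0, "SOX17": 11.0,
          "GATA6": 11.0, "GATA4": 9.0, "FOXA2": 10.0, "EOMES": 8.0,
          "GSC": 8.0, "LGR5": 7.0, "HNF4A": 3.0, "POU5F1": 4.0,
          "NANOG": 3.5, "SOX2": 3.0}, 0.9),
        # double-positive intermediates: pluripotency and DE markers
        # expressed simultaneously; 5% of the day-3 pool
        ("double_positive_d3", 3, 8,
         {"POU5F1": 10.0, "SOX2": 9.5, "NANOG": 9.5, "SOX17": 9.0,
          "GATA4": 8.0, "GATA6": 9.0, "FOXA2": 6.0, "CDH2": 8.0,
          "VIM": 6.0, "SNAI1": 6.0}, 1.0),
        # day-3 laggards that never responded to Activin A
        ("laggard_d3", 3, 12,
         {"CDH1": 10.0, "POU5F1": 8.5, "SOX2": 8.0, "NANOG": 7.5}, 0.8),
        # residual undifferentiated cells; NANOG decays with time in the
        # differentiation medium and autocrine TGFB1 exposure leaves a mild
        # mesenchymal trace, keeping them near but not inside day 0
        ("hesc_like_d5", 5, 18,
         {"CDH1": 11.0, "POU5F1": 10.5, "SOX2": 10.0, "NANOG": 8.5,
          "VIM": 2.5, "TGFB1": 2.5}, 0.8),
        ("hesc_like_d7", 7, 13,
         {"CDH1": 10.5, "POU5F1": 10.0, "SOX2": 9.5, "NANOG": 8.0,
          "VIM": 3.0, "TGFB1": 3.0}, 0.8),
    ]
    specs = []
    for name, day, n, means, sd in profiles:
        prof = _profile(means)
        specs.append(
            PopulationSpec(
                name=name,
                day=day,
                n_cells=n,
                mean_expression=prof,
                within_population_sd=sd,
                dropout_prob=_dropouts(prof),
            )
        )
    assert sum(s.n_cells for s in specs) == 501
    return specs


#: Population names of the residual undifferentiated cells at days 5/7.
RESIDUAL_POPULATIONS = ("hesc_like_d5", "hesc_like_d7")


def scenario_to_json(scenario: list[PopulationSpec], path: str | Path) -> None:
    Path(path).write_text(json.dumps([s.to_dict() for s in scenario], indent=1))


def scenario_from_json(path: str | Path) -> list[PopulationSpec]:
    data = json.loads(Path(path).read_text())
    return [PopulationSpec(**d) for d in data]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted ground truth: one record per generated cell."""

    cell_ids: list[str]
    population: list[str]
    day: np.ndarray
    mean_profiles: np.ndarray  # cell x gene noiseless means
    gene_ids: list[str]
    panel: MarkerPanel = field(default_factory=default_panel)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_profiles, index=self.cell_ids,
                          columns=self.gene_ids)
        df.insert(0, "population", self.population)
        df.insert(1, "day", self.day)
        df.index.name = "cell_id"
        return df


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_ct_matrix(
    scenario: list[PopulationSpec],
    config: PipelineConfig | None = None,
    seed: int | None = None,
    noiseless: bool = False,
    empty_rate: float = 0.0,
    doublet_rate: float = 0.0,
) -> tuple[CtMatrix, SyntheticTruth]:
    """Draw a Ct matrix from a staged scenario.

    Per cell and gene, relative expression is drawn from a normal with the
    population's mean and spread truncated at zero (silent genes stay at
    exactly zero), an independent dropout event may zero the well, and the
    result maps to ``Ct = lod_ct - expression``; wells at zero expression
    become the undetected sentinel.  ``noiseless=True`` emits each
    population's exact mean profile with no dropout.  Output is
    deterministic given ``seed``.
    """
    if config is None:
        config = PipelineConfig()
    if not scenario or sum(s.n_cells for s in scenario) == 0:
        raise ValueError("scenario contains no cells")
    rng = np.random.default_rng(config.random_seed if seed is None else seed)

    genes = sorted({g for s in scenario for g in s.mean_expression})
    # keep panel order when the scenario uses the default panel
    default_order = [g for g in panel_gene_order() if g in set(genes)]
    if len(default_order) == len(genes):
        genes = default_order

    blocks, cell_ids, days, pops, mean_rows = [], [], [], [], []
    for spec in scenario:
        n = spec.n_cells
        if n == 0:
            continue
        mu = spec.means(genes)
        sd = spec.sds(genes)
        drop = spec.dropouts(genes)
        if noiseless:
            expr = np.tile(mu, (n, 1))
        else:
            expr = np.tile(mu, (n, 1))
            on = (mu > 0) & (sd > 0)
            for j in np.flatnonzero(on):
                a = -mu[j] / sd[j]
                expr[:, j] = truncnorm.rvs(
                    a, np.inf, loc=mu[j], scale=sd[j], size=n, random_state=rng
                )
            dropped = rng.random((n, len(genes))) < drop[None, :]
            expr[dropped] = 0.0
        expr = np.minimum(expr, config.lod_ct - 0.5)  # keep Ct > 0
        blocks.append(expr)
        ids = [f"{spec.name}_c{k:03d}" for k in range(n)]
        cell_ids.extend(ids)
        days.extend([spec.day] * n)
        pops.extend([spec.name] * n)
        mean_rows.append(np.tile(mu, (n, 1)))

    expr_all = np.vstack(blocks)
    ct_values = np.where(expr_all > 0, config.lod_ct - expr_all, np.nan)

    n_total = len(cell_ids)
    qc = np.array(["ok"] * n_total, dtype=object)
    if not noiseless and (empty_rate > 0 or doublet_rate > 0):
        u = rng.random(n_total)
        qc[u < empty_rate] = "empty"
        qc[(u >= empty_rate) & (u < empty_rate + doublet_rate)] = "doublet"

    controls = [g for g in CONTROL_GENES if g in genes]
    ct = CtMatrix(
        values=ct_values,
        cell_ids=cell_ids,
        day=np.array(days),
        assay_ids=genes,
        control_assays=controls,
        qc_flags=list(qc),
    )
    panel = default_panel()
    if set(genes) - set(panel.categories):
        panel = MarkerPanel(
            {g: panel.categories.get(g, "other") for g in genes}
        )
    truth = SyntheticTruth(
        cell_ids=cell_ids,
        population=pops,
        day=np.array(days),
        mean_profiles=np.vstack(mean_rows),
        gene_ids=genes,
        panel=panel,
    )
    return ct, truth


def generate_bulk_from_truth(
    truth: SyntheticTruth,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matched bulk profile: per day, the mean noiseless expression over that
    day's cells, plus optional i.i.d. Gaussian measurement noise.

    With ``noise_sd=0`` the bulk is exactly the population-weighted mean
    profile, so a noiseless pseudobulk comparison yields perfect
    concordance.
    """
    if len(truth.cell_ids) == 0:
        raise ValueError("truth contains no cells")
    rng = np.random.default_rng(seed)
    days = sorted(set(int(d) for d in truth.day))
    cols = {}
    for d in days:
        mask = truth.day == d
        col = truth.mean_profiles[mask].mean(axis=0)
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=col.shape)
        cols[d] = col
    bulk = pd.DataFrame(cols, index=truth.gene_ids)
    bulk.index.name = "gene"
    return bulk
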