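"""Pipeline configuration shared by all analysis stages."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Default seed used whenever the caller does not supply one.
DEFAULT_SEED = 101


@dataclass
class PipelineConfig:
    """Tunable parameters for the full Ct-to-network pipeline.

    Parameters
    ----------
    lod_ct:
        Limit-of-detection cycle threshold. Wells at or above this Ct are
        treated as undetected; relative expression is ``lod_ct - Ct`` floored
        at zero, so the value also sets the maximum dynamic range (in log2
        units) of the expression scale.
    n_pcs:
        Number of singular components retained for the cell-cell embedding.
    weak_threshold, strong_threshold:
        Similarity cutoffs (on the 0-1 normalized scale) above which a
        candidate edge is kept as a weak or strong link, respectively.
    max_edges_per_node:
        Per-node cap on the number of best-scoring edges selected.
    detection_floor:
        Expression strictly above this value counts as "detected" in the
        co-detection statistics.
    random_seed:
        Seed for every randomized operation (simulation, layout).
    """

    lod_ct: float = 25.0
    n_pcs: int = 3
    weak_threshold: float = 0.92
    strong_threshold: float = 0.99
    max_edges_per_node: int = 50
    detection_floor: float = 0.0
    random_seed: int = field(default=DEFAULT_SEED)

    def __post_init__(self) -> None:
        if not (0.0 <= self.weak_threshold <= self.strong_threshold <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 <= weak <= strong <= 1, got "
                f"weak={self.weak_threshold}, strong={self.strong_threshold}"
            )
        if self.n_pcs < 1:
            raise ValueError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if self.max_edges_per_node < 1:
            raise ValueError(
                f"max_edges_per_node must be >= 1, got {self.max_edges_per_node}"
            )
        if self.lod_ct <= 0:
            raise ValueError(f"lod_ct must be positive, got {self.lod_ct}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)
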