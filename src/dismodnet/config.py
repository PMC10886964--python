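"""Pipeline configuration.

All thresholds of the analysis are collected in one dataclass whose defaults
are the published study settings: microarray significance at FDR <= 0.05 and
|log2 fold change| >= 0.5, proteomics at |fold change| >= 1.2 and p <= 0.05,
a nine-point cluster-density grid 0.1..0.9, module calling at BH-adjusted
p < 0.05, disease-miRNA calling at TRS > 0, and biomarker screening at
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_DENSITY_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every stage of the pipeline.

    Parameters
    ----------
    de_fdr_max : float
        Microarray significance cutoff on the adjusted p-value (inclusive).
    de_abs_logfc_min : float
        Minimum |log2 fold change| for microarray rows (inclusive).
    prot_abs_fc_min : float
        Minimum symmetrised linear fold change ``max(FC, 1/FC)`` for
        proteomics rows (inclusive).
    prot_p_max : float
        Proteomics p-value cutoff (inclusive).
    density_grid : tuple of float
        Cluster-density thresholds swept by the overlapping clustering stage.
    cp_min : float
        Cluster-property admission threshold of the greedy cluster growth.
    min_cluster_size : int
        Smallest cluster emitted by the clustering stage.
    module_fdr_max : float
        BH-adjusted p cutoff (strict ``<``) for calling disease modules.
    trs_min : float
        Disease-miRNA calling threshold (strict ``>``; default 0).
    biomarker_alpha : float
        Empirical-p cutoff (inclusive) for NSR/TFP biomarker screening.
    sim_min : float
        Jaccard similarity threshold used when folding a bipartite
        miRNA-target graph onto its miRNA side.
    attach_ratio : float
        Fraction of a bicluster's miRNAs a gene must target to be attached.
    trs_normalize_by : str
        ``"mrm"`` divides each per-dataset relevance score by that dataset's
        total module count; ``"sub_mrm"`` by its disease-module count only.
    sscore_aggregate : str
        ``"max"`` (best containing cluster) or ``"sum"`` over clusters.
    roc_universe : str
        ``"all"`` scores every network gene (unclustered genes at 0);
        ``"clustered"`` restricts the ROC to clustered genes.
    rng_seed : int
        Seed for every stochastic component.
    """

    de_fdr_max: float = 0.05
    de_abs_logfc_min: float = 0.5
    prot_abs_fc_min: float = 1.2
    prot_p_max: float = 0.05
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID
    cp_min: float = 0.5
    min_cluster_size: int = 2
    module_fdr_max: float = 0.05
    trs_min: float = 0.0
    biomarker_alpha: float = 0.05
    sim_min: float = 0.33
    attach_ratio: float = 0.5
    trs_normalize_by: str = "mrm"
    sscore_aggregate: str = "max"
    roc_universe: str = "all"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr_max", "prot_p_max", "module_fdr_max", "biomarker_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        grid = tuple(float(d) for d in self.density_grid)
        if not grid:
            raise ValueError("density_grid must be non-empty")
        if any(not 0.0 < d < 1.0 for d in grid):
            raise ValueError(f"density_grid entries must lie in (0,1), got {grid}")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError(f"density_grid must be strictly increasing, got {grid}")
        object.__setattr__(self, "density_grid", grid)
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.trs_normalize_by not in ("mrm", "sub_mrm"):
            raise ValueError("trs_normalize_by must be 'mrm' or 'sub_mrm'")
        if self.sscore_aggregate not in ("max", "sum"):
            raise ValueError("sscore_aggregate must be 'max' or 'sum'")
        if self.roc_universe not in ("all", "clustered"):
            raise ValueError("roc_universe must be 'all' or 'clustered'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML key-value file; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "density_grid" in data:
            data["density_grid"] = tuple(data["density_grid"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["density_grid"] = list(d["density_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
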