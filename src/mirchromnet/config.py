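"""Pipeline configuration: the single home of every numeric threshold."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Numeric thresholds of the analysis.

    Defaults follow the published conventions: a 50 kb upstream TSS search
    window, +/-2 kb promoter-sharing and anchor-mapping windows, +/-5 kb mark
    profiling, >= 2 replicates per retained edge (1 for genomic neighbours,
    within 10 kb), >= 2 databases per target pair, >= 10 mapped pairs per
    tested community link at FDR 0.001, 10^3 permutations, term enrichment at
    BH FDR 0.05, and chi-square disease enrichment at alpha 0.001 on classes
    with >= 2 member MIRs.
    """

    tss_search_window: int = 50_000
    promoter_share_window: int = 2_000
    anchor_tss_window: int = 2_000
    mark_profile_window: int = 5_000
    min_edge_replicates: int = 2
    neighbor_min_replicates: int = 1
    neighbor_max_gap: int = 10_000
    min_target_databases: int = 2
    min_community_pairs: int = 10
    community_link_fdr: float = 0.001
    n_permutations: int = 1_000
    term_enrichment_fdr: float = 0.05
    chi2_min_mirs: int = 2
    chi2_alpha: float = 0.001
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        windows = (
            self.tss_search_window,
            self.promoter_share_window,
            self.anchor_tss_window,
            self.mark_profile_window,
            self.neighbor_max_gap,
        )
        if any(w <= 0 for w in windows):
            raise ValueError("all windows must be > 0")
        counts = (
            self.min_edge_replicates,
            self.neighbor_min_replicates,
            self.min_target_databases,
            self.min_community_pairs,
            self.n_permutations,
            self.chi2_min_mirs,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all count thresholds must be >= 1")
        rates = (self.community_link_fdr, self.term_enrichment_fdr, self.chi2_alpha)
        if any(not (0.0 < r < 1.0) for r in rates):
            raise ValueError("FDR/alpha thresholds must lie in (0, 1)")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
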