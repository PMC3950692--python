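"""End-to-end orchestration of the analysis stages on an in-memory bundle."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment, mir_models, network, promoters
from .config import PipelineConfig
from .simulate import SimulatedBundle
from .types import GenomicInterval, PromoterCall


@dataclass
class PipelineResult:
    config: PipelineConfig
    promoter_calls: list[PromoterCall]
    tss_index: network.TssIndex
    network: network.GeneNetwork
    communities: list[network.Community]
    mir_edges: list[mir_models.MirEdge]
    model_assignments: list[mir_models.ModelAssignment]
    filtered_targets: list
    mapping: enrichment.PairMapping
    links: list[enrichment.CommunityLink]
    extras: dict = field(default_factory=dict)


def annotate_promoters(bundle: SimulatedBundle, config: PipelineConfig):
    calls = promoters.assign_tss(
        bundle.mirs,
        bundle.curated_tss,
        bundle.cage_tags,
        bundle.rnapii_peaks,
        config,
    )
    calls = promoters.classify_promoter_sharing(calls, bundle.genes, config)
    h3k4me3 = [p for p in bundle.mark_peaks if p.mark == "H3K4me3"]
    return promoters.annotate_h3k4me3_support(calls, h3k4me3, config)


def analyze_bundle(
    bundle: SimulatedBundle,
    config: PipelineConfig | None = None,
    blacklist: list[GenomicInterval] | None = None,
) -> PipelineResult:
    """Annotate promoters, build the network, assign models and map targets."""
    if config is None:
        config = PipelineConfig(random_seed=bundle.config.seed)
    calls = annotate_promoters(bundle, config)
    tss_index = network.build_tss_index(bundle.genes, calls)
    interactions = network.filter_sv_blacklist(
        bundle.interactions, blacklist or []
    )
    net = network.build_network(interactions, tss_index, config)
    communities = network.find_communities(net)
    edges = mir_models.build_mir_network(
        interactions, bundle.mirs, tss_index, config, net, communities
    )
    assignments = mir_models.assign_interaction_model(
        bundle.mirs, calls, bundle.rnapii_peaks, net, edges, config
    )
    filtered = enrichment.filter_target_pairs(bundle.targets, config)
    mapping = enrichment.map_pairs_to_communities(filtered, communities)
    links = (
        enrichment.community_link_network(mapping, communities, config)
        if communities
        else []
    )
    return PipelineResult(
        config=config,
        promoter_calls=calls,
        tss_index=tss_index,
        network=net,
        communities=communities,
        mir_edges=edges,
        model_assignments=assignments,
        filtered_targets=filtered,
        mapping=mapping,
        links=links,
    )


def recovered_partition(result: PipelineResult) -> set[frozenset[str]]:
    return {frozenset(c.members) for c in result.communities}


def restrict_partition(
    partition: set[frozenset[str]], keep: set[str]
) -> set[frozenset[str]]:
    """Drop entities outside ``keep`` and discard emptied blocks."""
    out = set()
    for block in partition:
        restricted = frozenset(m for m in block if m in keep)
        if restricted:
            out.add(restricted)
    return out
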