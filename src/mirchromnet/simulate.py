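"""Seeded synthetic input bundles with planted, recoverable structure.

The generator emulates the study conditions end to end: two cell lines with
three (K562) and four (MCF7) replicates, roughly half of the MIRs intragenic,
TSS evidence split across the curated/CAGE/RNAPII tiers in the proportions of
the real annotation (about 55/18/12 percent of MIRs, the rest without a
promoter), chromatin communities planted as connected blocks of promoter-
bearing entities whose anchor pairs are re-emitted independently per
replicate, single-replicate noise contacts, miRNA-target pairs enriched
between designated community pairs and depleted within communities, and
expression/mark signal driven by a per-entity activity level.

Planted anchors are centred on TSSs, and entities whose TSSs lie within
6 kb of each other are treated as one placement unit (an anchor can never
reach an entity more than 4 kb away, so cross-community captures are
impossible by construction). Noise contacts are drawn from unit pairs never
used before, which makes every noise-derived gene pair single-replicate by
construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .types import (
    DuplexInteraction,
    ExpressionRecord,
    GeneRecord,
    GenomicInterval,
    MirRecord,
    Peak,
    TargetPair,
    make_duplex,
)

ACTIVE_MARKS = (
    "H3K4me3", "H3K4me2", "H3K4me1", "H3K9ac", "H3K27ac", "H3K79me2",
    "H2A.Z", "DNase", "CTCF", "BRG1", "CHD1",
)
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3", "DNAme", "CBX2", "CBX8")

#: the 10 disease classes used for MIR labels
DISEASE_CLASSES = (
    "Cancer", "Cardiovascular", "Connectivetissue", "Dermatological",
    "Gastrointestinal", "Hematological", "Immunological", "Muscular",
    "Neurological", "Psychiatric",
)

_COLLISION_BP = 6_000  # entities closer than this share a placement unit


@dataclass
class SimulationConfig:
    n_chromosomes: int = 4
    chrom_length: int = 12_000_000
    n_genes: int = 500
    n_mirs: int = 150
    fraction_intragenic: float = 0.5
    n_clusters: int = 10
    n_families: int = 15
    n_disease_categories: int = 10
    n_planted_communities: int = 40
    community_size_min: int = 4
    community_size_mean: float = 10.0
    extra_edge_rate: float = 0.4
    edge_reproducibility: float = 0.8
    noise_edge_rate: float = 30.0
    cell_lines: dict[str, int] = field(
        default_factory=lambda: {"K562": 3, "MCF7": 4}
    )
    fraction_cell_specific_communities: float = 0.2
    base_target_rate: float = 0.06
    target_between_enrichment: float = 5.0
    target_self_depletion: float = 0.2
    n_enriched_pairs: int = 2
    expression_activity_effect: float = 1.0
    expression_noise_sd: float = 0.5
    generate_mark_peaks: bool = True
    tier_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "curated": 0.546, "cage": 0.180, "rnapii": 0.118, "none": 0.156
        }
    )
    n_database_probs: tuple[float, ...] = (0.35, 0.30, 0.15, 0.10, 0.06, 0.04)
    anchor_width_range: tuple[int, int] = (500, 4_000)
    pet_count_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.fraction_intragenic,
            self.edge_reproducibility,
            self.fraction_cell_specific_communities,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.target_between_enrichment < 0 or self.target_self_depletion < 0:
            raise ValueError("target multipliers must be >= 0")
        if min(self.n_chromosomes, self.n_genes) < 1 or self.n_mirs < 0:
            raise ValueError("counts must be non-negative (>=1 chromosome/gene)")
        if abs(sum(self.tier_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("tier fractions must sum to 1")
        if abs(sum(self.n_database_probs) - 1.0) > 1e-9:
            raise ValueError("n_database probabilities must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """The planted structure every downstream stage should recover."""

    communities: list[list[str]]  # disjoint member blocks
    community_cells: list[list[str]]  # cell lines each block is planted in
    enriched_pairs: list[tuple[int, int]]  # block-index pairs with extra targets
    planted_edges: list[dict]  # u, v, block, cells, single_replicate
    neighbor_pairs: list[tuple[str, str]]  # clustered pairs planted at 1 replicate
    activity: dict[str, float]
    tss: dict[str, tuple[str, int]]  # effective TSS of promoter-bearing entities
    mir_tier: dict[str, str]  # effective evidence tier per MIR
    evidence_tss: dict[str, tuple[str, int]] = field(default_factory=dict)
    intended_tier: dict[str, str] = field(default_factory=dict)

    @property
    def community_of(self) -> dict[str, int]:
        return {m: i for i, block in enumerate(self.communities) for m in block}

    @property
    def planted_entities(self) -> set[str]:
        return {e[k] for e in self.planted_edges for k in ("u", "v")}

    def partition(self) -> set[frozenset[str]]:
        return {frozenset(block) for block in self.communities}

    def to_json(self, path: str | Path) -> None:
        io.write_json(
            {
                "communities": self.communities,
                "community_cells": self.community_cells,
                "enriched_pairs": [list(p) for p in self.enriched_pairs],
                "planted_edges": self.planted_edges,
                "neighbor_pairs": [list(p) for p in self.neighbor_pairs],
                "activity": self.activity,
                "tss": {k: list(v) for k, v in self.tss.items()},
                "mir_tier": self.mir_tier,
                "evidence_tss": {k: list(v) for k, v in self.evidence_tss.items()},
                "intended_tier": self.intended_tier,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            communities=[list(b) for b in d["communities"]],
            community_cells=[list(c) for c in d["community_cells"]],
            enriched_pairs=[tuple(p) for p in d["enriched_pairs"]],
            planted_edges=d["planted_edges"],
            neighbor_pairs=[tuple(p) for p in d["neighbor_pairs"]],
            activity=d["activity"],
            tss={k: (v[0], int(v[1])) for k, v in d["tss"].items()},
            mir_tier=d["mir_tier"],
            evidence_tss={
                k: (v[0], int(v[1])) for k, v in d.get("evidence_tss", {}).items()
            },
            intended_tier=d.get("intended_tier", {}),
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


# ---------------------------------------------------------------------------
# genome + planted structure

def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[MirRecord], GroundTruth]:
    """Place genes and MIRs, assign evidence tiers and the planted partition."""
    rng = _rng(config, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    n_intra = (
        int(rng.binomial(config.n_mirs, config.fraction_intragenic))
        if config.n_mirs
        else 0
    )
    n_inter = config.n_mirs - n_intra

    # cluster plan over intergenic MIRs
    cluster_sizes: list[int] = []
    remaining = n_inter
    for _ in range(config.n_clusters):
        size = int(2 + rng.integers(0, 3))  # 2..4 members
        if remaining - size < 0:
            break
        cluster_sizes.append(size)
        remaining -= size
    n_singles = remaining
    # promoterless MIRs are intergenic singles placed in peak deserts, so no
    # RNAPII evidence from a neighbouring gene can reach their search window
    n_none = min(n_singles, int(round(config.tier_fractions["none"] * config.n_mirs)))

    # interleave placement items across chromosomes
    items: list[tuple[str, int]] = (
        [("gene", 0)] * config.n_genes
        + [("cluster", s) for s in cluster_sizes]
        + [("single", 0)] * (n_singles - n_none)
        + [("single_none", 0)] * n_none
    )
    rng.shuffle(items)

    cursors = {c: 100_000 for c in chroms}
    genes_raw: list[dict] = []
    mirs_raw: list[dict] = []
    cluster_counter = 0
    for idx, (kind, size) in enumerate(items):
        chrom = chroms[idx % len(chroms)]
        gap = int(rng.integers(25_000, 60_001))
        pos = cursors[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            length = int(rng.integers(3_000, 10_001))
            genes_raw.append(
                {"chrom": chrom, "start": pos, "end": pos + length, "strand": strand}
            )
            cursors[chrom] = pos + length
        elif kind in ("single", "single_none"):
            desert = kind == "single_none"
            if desert:
                pos = cursors[chrom] + int(rng.integers(60_000, 80_001))
            length = int(rng.integers(60, 121))
            mirs_raw.append(
                {
                    "chrom": chrom, "start": pos, "end": pos + length,
                    "strand": strand, "context": "intergenic",
                    "cluster": None, "host": None, "desert": desert,
                }
            )
            cursors[chrom] = pos + length + (60_000 if desert else 0)
        else:  # cluster
            cluster_id = f"cl-{cluster_counter:03d}"
            cluster_counter += 1
            cur = pos
            for k in range(size):
                length = int(rng.integers(60, 121))
                mirs_raw.append(
                    {
                        "chrom": chrom, "start": cur, "end": cur + length,
                        "strand": strand, "context": "intergenic",
                        "cluster": cluster_id, "host": None,
                    }
                )
                cur += length
                if k < size - 1:
                    cur += int(rng.integers(4_000, 8_001))
            cursors[chrom] = cur
        if cursors[chrom] > config.chrom_length:
            raise ValueError(
                "genome too small to place requested features; increase "
                "chrom_length or n_chromosomes"
            )

    # name genes and pick hosts for intragenic MIRs
    genes_raw.sort(key=lambda g: (g["chrom"], g["start"]))
    for i, g in enumerate(genes_raw):
        g["gene_id"] = f"GENE{i + 1:04d}"
        g["symbol"] = f"G{i + 1}"
    hostable = [g for g in genes_raw if g["end"] - g["start"] >= 3_000]
    if n_intra > len(hostable):
        raise ValueError("not enough genes long enough to host intragenic MIRs")
    hosts = rng.choice(len(hostable), size=n_intra, replace=False)
    for h in hosts:
        g = hostable[int(h)]
        length = int(rng.integers(60, 121))
        offset = int(rng.integers(800, g["end"] - g["start"] - length - 400))
        mirs_raw.append(
            {
                "chrom": g["chrom"], "start": g["start"] + offset,
                "end": g["start"] + offset + length, "strand": g["strand"],
                "context": "intragenic", "cluster": None, "host": g["gene_id"],
            }
        )

    mirs_raw.sort(key=lambda m: (m["chrom"], m["start"]))
    for i, m in enumerate(mirs_raw):
        m["mir_id"] = f"mir-{i + 1:04d}"

    gene_tss = {
        g["gene_id"]: (g["chrom"], g["start"] if g["strand"] == "+" else g["end"] - 1)
        for g in genes_raw
    }

    # intended evidence tiers and own-promoter positions; desert singles are
    # the 'none' tier, every other MIR draws from the renormalized tiers
    active_tiers = [t for t in ("curated", "cage", "rnapii")
                    if config.tier_fractions.get(t, 0.0) > 0]
    weights = np.array([config.tier_fractions[t] for t in active_tiers])
    tier_p = weights / weights.sum() if weights.size else weights
    intended_tier: dict[str, str] = {}
    evidence_tss: dict[str, tuple[str, int]] = {}
    for m in mirs_raw:
        if m.get("desert") or not active_tiers:
            intended_tier[m["mir_id"]] = "none"
            continue
        tier = active_tiers[int(rng.choice(len(active_tiers), p=tier_p))]
        intended_tier[m["mir_id"]] = tier
        if m["context"] == "intragenic":
            evidence_tss[m["mir_id"]] = gene_tss[m["host"]]
            continue
        five_prime = m["start"] if m["strand"] == "+" else m["end"] - 1
        max_off = 1_500 if m["cluster"] is not None else 5_000
        offset = int(rng.integers(200, max_off + 1))
        pos = five_prime - offset if m["strand"] == "+" else five_prime + offset
        evidence_tss[m["mir_id"]] = (m["chrom"], max(0, pos))

    # the effective TSS/tier is what the promoter cascade yields from this
    # evidence; planted anchors and the partition are built on it, so the
    # pipeline's annotation agrees with the ground truth by construction
    mir_tier, tss = _effective_tss(
        genes_raw, mirs_raw, gene_tss, intended_tier, evidence_tss
    )

    truth = _plant_structure(config, rng, genes_raw, mirs_raw, tss, mir_tier)
    truth.evidence_tss = evidence_tss
    truth.intended_tier = intended_tier

    # per-entity activity; planted entities transcribe hardest
    comm_of = truth.community_of
    activity: dict[str, float] = {}
    host_act: dict[str, float] = {}
    for g in genes_raw:
        a = float(rng.lognormal(0.0, 1.0))
        if g["gene_id"] in comm_of:
            a *= 3.0
        activity[g["gene_id"]] = a
        host_act[g["gene_id"]] = a
    for m in mirs_raw:
        if m["context"] == "intragenic":
            base = host_act[m["host"]] ** 0.8 * float(rng.lognormal(0.0, 0.3))
        else:
            base = float(rng.lognormal(0.0, 1.0))
        tier = mir_tier[m["mir_id"]]
        if m["mir_id"] in comm_of:
            base *= 3.0
        elif tier == "none":
            base *= 0.3
        activity[m["mir_id"]] = base
    truth.activity = activity

    # family / disease labels, themed per planted block
    families = [f"fam-{i:03d}" for i in range(max(1, config.n_families))]
    classes = list(DISEASE_CLASSES[: config.n_disease_categories])
    block_family = {
        b: families[int(rng.integers(len(families)))]
        for b in range(len(truth.communities))
    }
    block_disease = {
        b: classes[int(rng.integers(len(classes)))] if classes else None
        for b in range(len(truth.communities))
    }
    cluster_family: dict[str, str] = {}
    for m in mirs_raw:
        fam = None
        if m["cluster"] is not None:
            fam = cluster_family.setdefault(
                m["cluster"], families[int(rng.integers(len(families)))]
            )
        block = comm_of.get(m["mir_id"])
        if fam is None and block is not None and rng.random() < 0.5:
            fam = block_family[block]
        if fam is None and rng.random() < 0.4:
            fam = families[int(rng.integers(len(families)))]
        diseases: set[str] = set()
        if classes:
            if block is not None and block_disease[block] and rng.random() < 0.6:
                diseases.add(block_disease[block])
            if rng.random() < (0.25 if diseases else 0.4):
                diseases.add(classes[int(rng.integers(len(classes)))])
        m["family"] = fam
        m["diseases"] = frozenset(diseases)

    genes = [
        GeneRecord(
            g["gene_id"],
            g["symbol"],
            GenomicInterval(g["chrom"], g["start"], g["end"], g["strand"]),
        )
        for g in genes_raw
    ]
    mirs = [
        MirRecord(
            mir_id=m["mir_id"],
            pre_mirna=GenomicInterval(m["chrom"], m["start"], m["end"], m["strand"]),
            context=m["context"],
            host_gene_id=m["host"],
            cluster_id=m["cluster"],
            family_id=m["family"],
            disease_categories=m["diseases"],
        )
        for m in mirs_raw
    ]
    return genes, mirs, truth


def _effective_tss(
    genes_raw: list[dict],
    mirs_raw: list[dict],
    gene_tss: dict[str, tuple[str, int]],
    intended_tier: dict[str, str],
    evidence_tss: dict[str, tuple[str, int]],
) -> tuple[dict[str, str], dict[str, tuple[str, int]]]:
    """Run the promoter evidence cascade on the planted evidence."""
    from .config import PipelineConfig
    from .promoters import assign_tss

    temp_mirs = [
        MirRecord(
            mir_id=m["mir_id"],
            pre_mirna=GenomicInterval(m["chrom"], m["start"], m["end"], m["strand"]),
            context=m["context"],
            host_gene_id=m["host"],
        )
        for m in mirs_raw
    ]
    curated = {
        mid: evidence_tss[mid]
        for mid, tier in intended_tier.items()
        if tier == "curated"
    }

    def point_peak(chrom: str, pos: int, mark: str) -> Peak:
        return Peak(
            GenomicInterval(chrom, max(0, pos - 10), pos + 10),
            pos, 1.0, mark, "sim", "sim",
        )

    cage = [
        point_peak(*evidence_tss[mid], "CAGE")
        for mid, tier in intended_tier.items()
        if tier == "cage"
    ]
    rnapii = [point_peak(c, p, "RNAPII") for c, p in gene_tss.values()] + [
        point_peak(*evidence_tss[mid], "RNAPII")
        for mid, tier in intended_tier.items()
        if tier != "none"
    ]
    calls = assign_tss(temp_mirs, curated, cage, rnapii, PipelineConfig())
    mir_tier = {c.mir_id: c.evidence_tier for c in calls}
    tss: dict[str, tuple[str, int]] = dict(gene_tss)
    for c in calls:
        if c.tss is not None:
            tss[c.mir_id] = (c.chrom, c.tss)
    return mir_tier, tss


def _placement_units(
    tss: dict[str, tuple[str, int]], eligible: list[str]
) -> list[list[str]]:
    """Group eligible entities whose TSSs lie within the collision distance."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for eid in eligible:
        chrom, pos = tss[eid]
        by_chrom.setdefault(chrom, []).append((pos, eid))
    units: list[list[str]] = []
    for chrom, items in sorted(by_chrom.items()):
        items.sort()
        current = [items[0][1]]
        last = items[0][0]
        for pos, eid in items[1:]:
            if pos - last <= _COLLISION_BP:
                current.append(eid)
            else:
                units.append(current)
                current = [eid]
            last = pos
        units.append(current)
    return units


def _plant_structure(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes_raw: list[dict],
    mirs_raw: list[dict],
    tss: dict[str, tuple[str, int]],
    mir_tier: dict[str, str],
) -> GroundTruth:
    eligible = [g["gene_id"] for g in genes_raw] + [
        m["mir_id"] for m in mirs_raw if mir_tier[m["mir_id"]] != "none"
    ]
    units = _placement_units(tss, eligible)
    mir_id_set = {m["mir_id"] for m in mirs_raw}
    mir_units = [u for u in units if any(e in mir_id_set for e in u)]
    gene_units = [u for u in units if not any(e in mir_id_set for e in u)]
    rng.shuffle(mir_units)
    rng.shuffle(gene_units)

    mean, lo = config.community_size_mean, config.community_size_min
    p_geom = 1.0 / max(1.0, mean - lo + 1.0)
    blocks: list[list[str]] = []

    # MIR hotspot blocks and gene-rich partner blocks for the planted
    # enriched target pairs (MIR-dense communities mirror the hotspot
    # regions of the real interactome)
    n_hub_pairs = config.n_enriched_pairs
    hub_size = max(lo, int(round(2 * mean)))
    hub_ids: list[int] = []
    target_ids: list[int] = []
    for _ in range(n_hub_pairs):
        block: list[str] = []
        while len(block) < hub_size and mir_units:
            block.extend(mir_units.pop())
        if len(block) >= 2:
            hub_ids.append(len(blocks))
            blocks.append(sorted(block))
    for _ in range(len(hub_ids)):
        block = []
        while len(block) < hub_size and gene_units:
            block.extend(gene_units.pop())
        if len(block) >= 2:
            target_ids.append(len(blocks))
            blocks.append(sorted(block))

    rest = mir_units + gene_units
    rng.shuffle(rest)
    i = 0
    while len(blocks) < config.n_planted_communities and i < len(rest):
        target = lo + int(rng.geometric(p_geom)) - 1
        block = []
        while len(block) < target and i < len(rest):
            block.extend(rest[i])
            i += 1
        if len(block) >= 2:
            blocks.append(sorted(block))

    cells = sorted(config.cell_lines)
    community_cells = []
    for _ in blocks:
        if len(cells) > 1 and rng.random() < config.fraction_cell_specific_communities:
            community_cells.append([cells[int(rng.integers(len(cells)))]])
        else:
            community_cells.append(list(cells))

    # spanning tree + extra edges per block
    planted_edges: list[dict] = []
    edge_set: set[frozenset[str]] = set()
    for b, block in enumerate(blocks):
        members = list(rng.permutation(block))
        for k in range(1, len(members)):
            j = int(rng.integers(0, k))
            u, v = sorted((members[k], members[j]))
            planted_edges.append(
                {
                    "u": u, "v": v, "block": b,
                    "cells": community_cells[b], "single_replicate": False,
                }
            )
            edge_set.add(frozenset((u, v)))
        n_extra = int(round(config.extra_edge_rate * len(block)))
        attempts = 0
        while n_extra > 0 and attempts < 50 * len(block):
            attempts += 1
            u, v = (
                block[int(rng.integers(len(block)))],
                block[int(rng.integers(len(block)))],
            )
            if u == v or frozenset((u, v)) in edge_set:
                continue
            u, v = sorted((u, v))
            planted_edges.append(
                {
                    "u": u, "v": v, "block": b,
                    "cells": community_cells[b], "single_replicate": False,
                }
            )
            edge_set.add(frozenset((u, v)))
            n_extra -= 1

    # clustered MIR pairs planted at a single replicate (neighbour rule)
    comm_of = {m: b for b, block in enumerate(blocks) for m in block}
    neighbor_pairs: list[tuple[str, str]] = []
    by_cluster: dict[str, list[str]] = {}
    for m in mirs_raw:
        if m["cluster"] is not None and m["mir_id"] in comm_of:
            by_cluster.setdefault(m["cluster"], []).append(m["mir_id"])
    coords = {m["mir_id"]: (m["start"], m["end"]) for m in mirs_raw}
    for members in by_cluster.values():
        members.sort()
        for u, v in zip(members, members[1:]):
            if comm_of[u] != comm_of[v] or frozenset((u, v)) in edge_set:
                continue
            gap = max(coords[u][0], coords[v][0]) - min(coords[u][1], coords[v][1])
            if gap > 10_000:  # must satisfy the neighbour rule's default gap
                continue
            b = comm_of[u]
            planted_edges.append(
                {
                    "u": u, "v": v, "block": b,
                    "cells": community_cells[b], "single_replicate": True,
                }
            )
            edge_set.add(frozenset((u, v)))
            neighbor_pairs.append((u, v))

    # enriched target pairs join each MIR hotspot block to one gene-rich
    # partner block, so the planted excess of MIR(A)->gene(B) pairs is not
    # swallowed by the blocks' own background incidence
    enriched_pairs = list(zip(hub_ids, target_ids))

    return GroundTruth(
        communities=blocks,
        community_cells=community_cells,
        enriched_pairs=enriched_pairs,
        planted_edges=planted_edges,
        neighbor_pairs=neighbor_pairs,
        activity={},
        tss=tss,
        mir_tier=mir_tier,
    )


# ---------------------------------------------------------------------------
# ChIA-PET interactions + RNAPII peaks

def generate_chia_pet(
    genome: tuple[list[GeneRecord], list[MirRecord]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[list[DuplexInteraction], list[Peak]]:
    """Emit duplex interactions per cell line/replicate plus RNAPII peaks."""
    rng = _rng(config, 1)
    replicates = {
        cell: [f"rep{i + 1}" for i in range(n)]
        for cell, n in sorted(config.cell_lines.items())
    }
    wlo, whi = config.anchor_width_range

    def anchor_at(eid: str) -> GenomicInterval:
        chrom, pos = truth.tss[eid]
        width = int(rng.integers(wlo, whi + 1))
        start = max(0, pos - width // 2)
        return GenomicInterval(chrom, start, start + width)

    def pet() -> int:
        return 1 + int(rng.poisson(max(0.0, config.pet_count_mean - 1.0)))

    interactions: list[DuplexInteraction] = []
    for edge in truth.planted_edges:
        for cell in edge["cells"]:
            reps = replicates[cell]
            if edge["single_replicate"]:
                chosen = [reps[int(rng.integers(len(reps)))]]
            else:
                chosen = [r for r in reps if rng.random() < config.edge_reproducibility]
            for rep in chosen:
                interactions.append(
                    make_duplex(
                        anchor_at(edge["u"]), anchor_at(edge["v"]), pet(), cell, rep
                    )
                )

    # noise: unit-level pairs, each used in exactly one replicate overall
    genes, mirs = genome
    eligible = sorted(truth.tss)
    units = _placement_units(truth.tss, eligible)
    unit_of = {eid: i for i, unit in enumerate(units) for eid in unit}
    used_unit_pairs = {
        frozenset((unit_of[e["u"]], unit_of[e["v"]]))
        for e in truth.planted_edges
    }
    for cell, reps in replicates.items():
        for rep in reps:
            n_noise = int(rng.poisson(config.noise_edge_rate))
            emitted = 0
            attempts = 0
            while emitted < n_noise and attempts < 100 * max(1, n_noise):
                attempts += 1
                u = eligible[int(rng.integers(len(eligible)))]
                v = eligible[int(rng.integers(len(eligible)))]
                key = frozenset((unit_of[u], unit_of[v]))
                if u == v or len(key) < 2 or key in used_unit_pairs:
                    continue
                used_unit_pairs.add(key)
                interactions.append(
                    make_duplex(anchor_at(u), anchor_at(v), pet(), cell, rep)
                )
                emitted += 1

    # RNAPII peaks sit at each entity's own promoter evidence position
    peak_sites = {
        eid: truth.tss[eid] for eid in eligible if eid not in truth.mir_tier
    }
    peak_sites.update(
        {
            mid: pos
            for mid, pos in truth.evidence_tss.items()
            if truth.intended_tier.get(mid) != "none"
        }
    )
    peaks: list[Peak] = []
    for eid in sorted(peak_sites):
        chrom, pos = peak_sites[eid]
        act = truth.activity.get(eid, 1.0)
        for cell, reps in replicates.items():
            for rep in reps:
                width = int(rng.integers(400, 1_201))
                start = max(0, pos - width // 2)
                end = max(start + width, pos + 1)
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, end),
                        pos,
                        float(act * rng.lognormal(0.0, 0.3)),
                        "RNAPII",
                        cell,
                        rep,
                    )
                )
    return interactions, peaks


# ---------------------------------------------------------------------------
# miRNA-target pairs

def generate_targets(
    genome: tuple[list[GeneRecord], list[MirRecord]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[TargetPair]:
    """Bernoulli target pairs with planted between-community enrichment."""
    rng = _rng(config, 2)
    genes, mirs = genome
    comm_of = truth.community_of
    enriched = {frozenset(p) for p in truth.enriched_pairs}
    db_probs = np.array(config.n_database_probs)

    pairs: list[TargetPair] = []
    for mir in mirs:
        bm = comm_of.get(mir.mir_id)
        for gene in genes:
            bg = comm_of.get(gene.gene_id)
            rate = config.base_target_rate
            if bm is not None and bg is not None:
                if bm == bg:
                    rate *= config.target_self_depletion
                elif frozenset((bm, bg)) in enriched:
                    rate *= config.target_between_enrichment
            if rng.random() < min(1.0, rate):
                n_db = 1 + int(rng.choice(len(db_probs), p=db_probs))
                pairs.append(TargetPair(mir.mir_id, gene.gene_id, n_db))
    return pairs


# ---------------------------------------------------------------------------
# expression + chromatin marks

@dataclass
class SimulatedExpression:
    expression: list[ExpressionRecord]
    mark_peaks: list[Peak]
    mark_counts: pd.DataFrame  # entities x marks, as emitted


def generate_expression_marks(
    genome: tuple[list[GeneRecord], list[MirRecord]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> SimulatedExpression:
    """Expression monotone in activity plus noise; mark counts tied to activity."""
    rng = _rng(config, 3)
    genes, mirs = genome
    cells = sorted(config.cell_lines)
    comm_of = truth.community_of

    cell_boost: dict[tuple[str, str], float] = {}
    for b, block_cells in enumerate(truth.community_cells):
        if len(block_cells) == 1:
            for m in truth.communities[b]:
                for cell in cells:
                    cell_boost[(m, cell)] = 3.0 if cell in block_cells else 1 / 3.0

    entity_ids = [g.gene_id for g in genes] + [m.mir_id for m in mirs]
    expression: list[ExpressionRecord] = []
    for eid in entity_ids:
        act = truth.activity.get(eid, 0.1)
        for cell in cells:
            noise = float(rng.lognormal(0.0, config.expression_noise_sd))
            value = (act ** config.expression_activity_effect) * noise
            value *= cell_boost.get((eid, cell), 1.0)
            expression.append(ExpressionRecord(eid, cell, float(value)))

    # mark peaks around promoters (single pooled track per mark)
    promoter_ids = sorted(truth.tss)
    acts = np.array([truth.activity.get(e, 0.1) for e in promoter_ids])
    a_norm = (
        np.argsort(np.argsort(acts)) / max(1, len(acts) - 1)
        if len(acts) > 1
        else np.ones(len(acts))
    )
    if not config.generate_mark_peaks:
        empty = pd.DataFrame(index=pd.Index(promoter_ids, name="entity_id"))
        return SimulatedExpression(expression, [], empty)

    # idiosyncratic per-mark baselines/slopes keep the marks distinguishable
    # (a label permutation cannot reproduce the observed correlation pattern)
    mark_params = {}
    for j, mark in enumerate(ACTIVE_MARKS):
        mark_params[mark] = (0.3 + 0.15 * j, 3.0 + 0.6 * j)  # lam = b + s*a
    for j, mark in enumerate(REPRESSIVE_MARKS):
        base = 2.0 + 1.1 * j
        mark_params[mark] = (base, -0.85 * base)
    mark_peaks: list[Peak] = []
    counts = {}
    for i, eid in enumerate(promoter_ids):
        chrom, pos = truth.tss[eid]
        row = {}
        for mark in ACTIVE_MARKS + REPRESSIVE_MARKS:
            b_m, s_m = mark_params[mark]
            lam = max(0.05, b_m + s_m * a_norm[i])
            row[mark] = int(rng.poisson(lam))
        for mark, n in row.items():
            for _ in range(n):
                center = int(pos + rng.integers(-4_500, 4_501))
                center = max(0, center)
                mark_peaks.append(
                    Peak(
                        GenomicInterval(chrom, max(0, center - 200), center + 200),
                        center,
                        1.0,
                        mark,
                        cells[0],
                        "pooled",
                    )
                )
        counts[eid] = row
    mark_counts = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    mark_counts.index.name = "entity_id"
    return SimulatedExpression(expression, mark_peaks, mark_counts)


# ---------------------------------------------------------------------------
# terms + whole-bundle orchestration

def generate_terms(
    genome: tuple[list[GeneRecord], list[MirRecord]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Flat GO-style term labels: block signature terms + shared terms on
    enriched block pairs + random background terms."""
    rng = _rng(config, 4)
    genes, _ = genome
    gene_ids = [g.gene_id for g in genes]
    mir_ids = set()
    comm_of = truth.community_of
    background_terms = [f"term-bg-{i:03d}" for i in range(30)]
    rows: list[tuple[str, str]] = []
    for gid in gene_ids:
        for _ in range(2):
            rows.append((gid, background_terms[int(rng.integers(30))]))
    for b, block in enumerate(truth.communities):
        block_genes = [m for m in block if m not in mir_ids and m in set(gene_ids)]
        for t in range(2):
            term = f"term-block{b:03d}-{t}"
            for gid in block_genes:
                if rng.random() < 0.7:
                    rows.append((gid, term))
    for k, (ba, bb) in enumerate(truth.enriched_pairs):
        term = f"term-shared-{k:02d}"
        for b in (ba, bb):
            for gid in truth.communities[b]:
                if gid in set(gene_ids) and rng.random() < 0.7:
                    rows.append((gid, term))
    df = pd.DataFrame(sorted(set(rows)), columns=["gene_id", "term_id"])
    return df


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genes: list[GeneRecord]
    mirs: list[MirRecord]
    truth: GroundTruth
    interactions: list[DuplexInteraction]
    rnapii_peaks: list[Peak]
    expression: list[ExpressionRecord]
    mark_peaks: list[Peak]
    targets: list[TargetPair]
    terms: pd.DataFrame

    @property
    def curated_tss(self) -> pd.DataFrame:
        rows = [
            {
                "mir_id": m,
                "chrom": self.truth.evidence_tss[m][0],
                "tss": self.truth.evidence_tss[m][1],
            }
            for m, tier in sorted(self.truth.intended_tier.items())
            if tier == "curated"
        ]
        return pd.DataFrame(rows, columns=["mir_id", "chrom", "tss"])

    @property
    def cage_tags(self) -> list[Peak]:
        tags = []
        for m, tier in sorted(self.truth.intended_tier.items()):
            if tier != "cage":
                continue
            chrom, pos = self.truth.evidence_tss[m]
            tags.append(
                Peak(
                    GenomicInterval(chrom, max(0, pos - 10), pos + 10),
                    pos, 1.0, "CAGE", "pooled", "pooled",
                )
            )
        return tags


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run all generators for one seeded configuration."""
    genes, mirs, truth = generate_genome(config)
    interactions, rnapii = generate_chia_pet((genes, mirs), truth, config)
    sim_expr = generate_expression_marks((genes, mirs), truth, config)
    targets = generate_targets((genes, mirs), truth, config)
    terms = generate_terms((genes, mirs), truth, config)
    return SimulatedBundle(
        config=config,
        genes=genes,
        mirs=mirs,
        truth=truth,
        interactions=interactions,
        rnapii_peaks=rnapii,
        expression=sim_expr.expression,
        mark_peaks=sim_expr.mark_peaks,
        targets=targets,
        terms=terms,
    )


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write the full input bundle in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_annotations(bundle.genes, outdir / "genes.gff3")
    io.write_annotations(bundle.mirs, outdir / "mirs.gff3")
    io.write_interactions(bundle.interactions, outdir / "interactions.bedpe")
    io.write_peak_table(
        bundle.rnapii_peaks + bundle.mark_peaks, outdir / "peaks.tsv"
    )
    io.write_peaks(bundle.cage_tags, outdir / "cage.bed")
    io.write_table(bundle.curated_tss, outdir / "curated_tss.tsv")
    io.write_expression(bundle.expression, outdir / "expression.tsv")
    io.write_targets(bundle.targets, outdir / "targets.tsv")
    io.write_table(bundle.terms, outdir / "terms.tsv")
    # empty SV blacklist by default; TADs tile each chromosome
    (outdir / "blacklist.bed").write_text("")
    tads = [
        GenomicInterval(f"chr{c + 1}", s, s + 500_000)
        for c in range(bundle.config.n_chromosomes)
        for s in range(0, bundle.config.chrom_length, 500_000)
    ]
    io.write_bed(tads, outdir / "tads.bed")
    bundle.truth.to_json(outdir / "ground_truth.json")
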