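"""MIR chromatin interaction models and the MIR-MIR interactome.

Direct MIR-MIR contacts come from shared duplex interactions and must be
recovered by >= ``min_edge_replicates`` replicates in one cell line, unless
the two pre-miRNAs are genomic neighbours (same chromosome, gap <=
``neighbor_max_gap``), in which case >= ``neighbor_min_replicates`` suffices.
Indirect contacts join MIR pairs that co-occupy a chromatin community and
are connected only through intermediate nodes; their supporting path edges
must come from >= 2 independent (cell line, replicate) datasets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .network import (
    Community,
    GeneNetwork,
    TssIndex,
    pair_support,
)
from .promoters import _PointIndex
from .stats import percent
from .types import DuplexInteraction, MirRecord, Peak, PromoterCall


@dataclass(frozen=True)
class MirEdge:
    mir_a: str
    mir_b: str
    linkage: str  # direct | indirect
    support: tuple[tuple[str, tuple[str, ...]], ...]  # (cell, replicates)
    via_neighbor_rule: bool
    cell_status: str  # '<cell>-specific' | 'common' | 'mixed'
    intrachromosomal: bool

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.mir_a, self.mir_b))

    def n_datasets(self) -> int:
        return sum(len(reps) for _, reps in self.support)


def _status(cells: Sequence[str]) -> str:
    cells = sorted(set(cells))
    if not cells:
        return "mixed"
    if len(cells) == 1:
        return f"{cells[0]}-specific"
    return "common"


def _gap(a, b) -> int | None:
    """Genomic gap between two pre-miRNA intervals; None if different chroms."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def build_mir_network(
    interactions: Sequence[DuplexInteraction],
    mirs: Sequence[MirRecord],
    tss_index: TssIndex,
    config: PipelineConfig,
    network: GeneNetwork | None = None,
    communities: Sequence[Community] | None = None,
) -> list[MirEdge]:
    """Construct direct and (when communities are given) indirect MIR edges.

    ``interactions`` must already be blacklist-filtered.
    """
    by_id = {m.mir_id: m for m in mirs}
    mir_ids = tss_index.mir_ids

    edges: list[MirEdge] = []
    direct_pairs: set[frozenset[str]] = set()
    for pair, cells in pair_support(interactions, tss_index, config).items():
        u, v = sorted(pair)
        if u not in mir_ids or v not in mir_ids:
            continue
        qualifying = [
            c for c, reps in cells.items() if len(reps) >= config.min_edge_replicates
        ]
        via_neighbor = False
        if not qualifying:
            rec_u, rec_v = by_id.get(u), by_id.get(v)
            if rec_u is None or rec_v is None:
                continue
            gap = _gap(rec_u.pre_mirna, rec_v.pre_mirna)
            if gap is None or gap > config.neighbor_max_gap:
                continue
            qualifying = [
                c
                for c, reps in cells.items()
                if len(reps) >= config.neighbor_min_replicates
            ]
            if not qualifying:
                continue
            via_neighbor = True
        rec_u, rec_v = by_id.get(u), by_id.get(v)
        intra = (
            rec_u is not None
            and rec_v is not None
            and rec_u.pre_mirna.chrom == rec_v.pre_mirna.chrom
        )
        edges.append(
            MirEdge(
                u,
                v,
                "direct",
                tuple(
                    (c, tuple(sorted(reps))) for c, reps in sorted(cells.items())
                ),
                via_neighbor,
                _status(qualifying),
                intra,
            )
        )
        direct_pairs.add(pair)

    if network is not None and communities is not None:
        edges.extend(
            _indirect_edges(network, communities, by_id, direct_pairs)
        )
    return edges


def _indirect_edges(
    network: GeneNetwork,
    communities: Sequence[Community],
    by_id: Mapping[str, MirRecord],
    direct_pairs: set[frozenset[str]],
) -> list[MirEdge]:
    graph = network.graph
    out: list[MirEdge] = []
    for comm in communities:
        comm_mirs = sorted(m for m in comm.members if m in network.mir_ids)
        if len(comm_mirs) < 2:
            continue
        sub = graph.subgraph(comm.members)
        for i, u in enumerate(comm_mirs):
            paths = nx.single_source_shortest_path(sub, u)
            for v in comm_mirs[i + 1:]:
                if frozenset((u, v)) in direct_pairs or v not in paths:
                    continue
                path = paths[v]
                per_cell: dict[str, set[str]] = defaultdict(set)
                common_cells: set[str] | None = None
                for a, b in zip(path, path[1:]):
                    support = sub.edges[a, b]["support"]
                    for cell, reps in support.items():
                        per_cell[cell].update(reps)
                    edge_cells = set(sub.edges[a, b]["cell_status"])
                    common_cells = (
                        edge_cells
                        if common_cells is None
                        else common_cells & edge_cells
                    )
                n_datasets = sum(len(r) for r in per_cell.values())
                if n_datasets < 2:
                    continue
                rec_u, rec_v = by_id.get(u), by_id.get(v)
                intra = (
                    rec_u is not None
                    and rec_v is not None
                    and rec_u.pre_mirna.chrom == rec_v.pre_mirna.chrom
                )
                out.append(
                    MirEdge(
                        u,
                        v,
                        "indirect",
                        tuple(
                            (c, tuple(sorted(r))) for c, r in sorted(per_cell.items())
                        ),
                        False,
                        _status(sorted(common_cells or [])),
                        intra,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# model assignment

@dataclass(frozen=True)
class ModelAssignment:
    mir_id: str
    model: str  # basal | interaction | not_assigned
    submodel: str | None = None  # mir_mir | mir_gene_only (interaction only)

    def __post_init__(self) -> None:
        if self.model not in ("basal", "interaction", "not_assigned"):
            raise ValueError(f"bad model {self.model!r}")
        if (self.model == "interaction") != (self.submodel is not None):
            raise ValueError("submodel present exactly for the interaction model")


def assign_interaction_model(
    mirs: Sequence[MirRecord],
    promoter_calls: Sequence[PromoterCall],
    rnapii_peaks: Iterable[Peak],
    network: GeneNetwork,
    mir_edges: Sequence[MirEdge],
    config: PipelineConfig,
) -> list[ModelAssignment]:
    """Partition all annotated MIRs into the three chromatin models.

    interaction: the MIR is a node of the chromatin network (submodel
    ``mir_mir`` when it carries >= 1 MIR-MIR edge, else ``mir_gene_only``);
    basal: not in the network but >= 1 RNAPII peak center within
    +/- ``anchor_tss_window`` of its TSS; not_assigned otherwise (including
    MIRs with no promoter call).
    """
    calls = {c.mir_id: c for c in promoter_calls}
    pol = _PointIndex(rnapii_peaks)
    edged = {m for e in mir_edges for m in (e.mir_a, e.mir_b)}
    nodes = network.nodes
    out = []
    for mir in mirs:
        call = calls.get(mir.mir_id)
        if mir.mir_id in nodes or mir.mir_id in edged:
            sub = "mir_mir" if mir.mir_id in edged else "mir_gene_only"
            out.append(ModelAssignment(mir.mir_id, "interaction", sub))
            continue
        if call is not None and call.tss is not None:
            import numpy as np

            pos = pol._pos.get(call.chrom)
            w = config.anchor_tss_window
            if pos is not None and pos.size:
                i0 = np.searchsorted(pos, call.tss - w, side="left")
                i1 = np.searchsorted(pos, call.tss + w, side="right")
                if i1 > i0:
                    out.append(ModelAssignment(mir.mir_id, "basal"))
                    continue
        out.append(ModelAssignment(mir.mir_id, "not_assigned"))
    return out


def model_counts(assignments: Sequence[ModelAssignment]) -> dict[str, int]:
    counts = {"basal": 0, "interaction": 0, "not_assigned": 0}
    for a in assignments:
        counts[a.model] += 1
    return counts


# ---------------------------------------------------------------------------
# summaries

def cell_specificity_summary(edges: Sequence[MirEdge]) -> pd.DataFrame:
    """Counts and integer percentages of edges by cell status."""
    total = len(edges)
    tally: dict[str, int] = defaultdict(int)
    for e in edges:
        tally[e.cell_status] += 1
    rows = [
        {
            "cell_status": status,
            "n_edges": n,
            "percent": percent(n, total) if total else 0.0,
        }
        for status, n in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["cell_status", "n_edges", "percent"])


def cluster_membership_fraction(
    edges: Sequence[MirEdge], mirs: Sequence[MirRecord]
) -> tuple[int, int, float]:
    """Edges whose two MIRs share a non-null cluster id.

    Returns (n_within_cluster, n_edges, percent at one decimal).
    """
    cluster = {m.mir_id: m.cluster_id for m in mirs}
    n_in = sum(
        1
        for e in edges
        if cluster.get(e.mir_a) is not None
        and cluster.get(e.mir_a) == cluster.get(e.mir_b)
    )
    total = len(edges)
    return n_in, total, percent(n_in, total, 1) if total else 0.0


def mir_edges_frame(edges: Sequence[MirEdge]) -> pd.DataFrame:
    rows = []
    for e in edges:
        support = ";".join(f"{c}:{','.join(reps)}" for c, reps in e.support)
        rows.append(
            {
                "mir1": e.mir_a,
                "mir2": e.mir_b,
                "linkage": e.linkage,
                "support": support,
                "cell_status": e.cell_status,
                "via_neighbor_rule": int(e.via_neighbor_rule),
                "intrachromosomal": int(e.intrachromosomal),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mir1", "mir2", "linkage", "support",
            "cell_status", "via_neighbor_rule", "intrachromosomal",
        ],
    )
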