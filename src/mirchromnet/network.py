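"""Gene-level chromatin interaction network and its community partition.

Each duplex interaction links the set of promoter-bearing entities mapped to
one anchor with the set mapped to the other anchor (an entity maps to an
anchor when the +/-2 kb window around its TSS overlaps the anchor interval).
Entity pairs are aggregated over all interactions; a pair becomes a network
edge when some single cell line recovers it in at least
``min_edge_replicates`` distinct replicates. Chromatin communities are the
connected components of the retained-edge graph.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .config import PipelineConfig
from .types import DuplexInteraction, GeneRecord, GenomicInterval, PromoterCall


# ---------------------------------------------------------------------------
# TSS index

@dataclass
class TssIndex:
    """Maps promoter-bearing entity ids to TSS points, with fast anchor lookup."""

    tss: dict[str, tuple[str, int]]
    mir_ids: frozenset[str]
    _pos: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ids: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        bychrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
        for eid, (chrom, pos) in self.tss.items():
            bychrom[chrom].append((pos, eid))
        for chrom, items in bychrom.items():
            items.sort()
            self._pos[chrom] = np.array([i[0] for i in items], dtype=np.int64)
            self._ids[chrom] = [i[1] for i in items]

    def entities_on_anchor(self, anchor: GenomicInterval, window: int) -> set[str]:
        """Entities whose TSS window overlaps the anchor interval."""
        pos = self._pos.get(anchor.chrom)
        if pos is None or pos.size == 0:
            return set()
        # window [tss-w, tss+w+1) overlaps [s, e) iff s-w <= tss <= e+w-1
        i0 = int(np.searchsorted(pos, anchor.start - window, side="left"))
        i1 = int(np.searchsorted(pos, anchor.end + window - 1, side="right"))
        return set(self._ids[anchor.chrom][i0:i1])


def build_tss_index(
    genes: Sequence[GeneRecord], promoter_calls: Sequence[PromoterCall]
) -> TssIndex:
    tss = {g.gene_id: (g.interval.chrom, g.tss) for g in genes}
    mir_ids = set()
    for c in promoter_calls:
        if c.tss is not None:
            tss[c.mir_id] = (c.chrom, c.tss)
            mir_ids.add(c.mir_id)
    return TssIndex(tss, frozenset(mir_ids))


# ---------------------------------------------------------------------------
# blacklist filter

def filter_sv_blacklist(
    interactions: Sequence[DuplexInteraction],
    blacklist: Sequence[GenomicInterval],
) -> list[DuplexInteraction]:
    """Drop interactions with either anchor overlapping a blacklist region."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in blacklist:
        trees[iv.chrom][iv.start:iv.end] = True
    if not trees:
        return list(interactions)

    def hit(anchor: GenomicInterval) -> bool:
        tree = trees.get(anchor.chrom)
        return bool(tree is not None and tree.overlap(anchor.start, anchor.end))

    return [d for d in interactions if not (hit(d.anchor_a) or hit(d.anchor_b))]


# ---------------------------------------------------------------------------
# linking and network construction

def link_genes_to_interaction(
    interaction: DuplexInteraction, tss_index: TssIndex, config: PipelineConfig
) -> set[frozenset[str]]:
    """Unordered entity pairs chromatin-linked by one duplex interaction.

    Pairs are the cross product of the two anchors' entity sets minus self
    pairs; entities co-located on a single anchor produce no pair.
    """
    w = config.anchor_tss_window
    set_a = tss_index.entities_on_anchor(interaction.anchor_a, w)
    set_b = tss_index.entities_on_anchor(interaction.anchor_b, w)
    return {
        frozenset((a, b)) for a in set_a for b in set_b if a != b
    }


@dataclass
class GeneNetwork:
    """The replicate-filtered chromatin interaction graph.

    ``graph`` nodes are entity ids; each edge carries ``support`` (a dict
    cell_line -> frozenset of replicate ids) and ``cell_status`` (the tuple
    of cell lines individually meeting the replicate threshold).
    """

    graph: nx.Graph
    mir_ids: frozenset[str]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            support = ";".join(
                f"{cell}:{','.join(sorted(reps))}"
                for cell, reps in sorted(data["support"].items())
            )
            rows.append(
                {
                    "id1": a,
                    "id2": b,
                    "support": support,
                    "cell_status": cell_status_label(data["cell_status"]),
                }
            )
        return pd.DataFrame(rows, columns=["id1", "id2", "support", "cell_status"])


def cell_status_label(cells: Sequence[str]) -> str:
    cells = sorted(cells)
    if len(cells) == 1:
        return f"{cells[0]}-only"
    return "common"


def pair_support(
    interactions: Iterable[DuplexInteraction],
    tss_index: TssIndex,
    config: PipelineConfig,
) -> dict[frozenset[str], dict[str, set[str]]]:
    """Aggregate per-pair replicate support over all duplex interactions."""
    support: dict[frozenset[str], dict[str, set[str]]] = defaultdict(
        lambda: defaultdict(set)
    )
    for d in interactions:
        for pair in link_genes_to_interaction(d, tss_index, config):
            support[pair][d.cell_line].add(d.replicate_id)
    return support


def build_network(
    interactions: Sequence[DuplexInteraction],
    tss_index: TssIndex,
    config: PipelineConfig,
) -> GeneNetwork:
    """Build the gene-level network with the per-cell-line replicate filter."""
    graph = nx.Graph()
    for pair, cells in pair_support(interactions, tss_index, config).items():
        qualifying = tuple(
            sorted(
                cell
                for cell, reps in cells.items()
                if len(reps) >= config.min_edge_replicates
            )
        )
        if not qualifying:
            continue
        u, v = sorted(pair)
        graph.add_edge(
            u,
            v,
            support={cell: frozenset(reps) for cell, reps in cells.items()},
            cell_status=qualifying,
        )
    return GeneNetwork(graph, tss_index.mir_ids & set(graph.nodes))


# ---------------------------------------------------------------------------
# communities

@dataclass(frozen=True)
class Community:
    community_id: str
    members: tuple[str, ...]
    n_mirs: int
    is_giant: bool

    @property
    def size(self) -> int:
        return len(self.members)


def find_communities(network: GeneNetwork) -> list[Community]:
    """Connected components of the retained-edge graph, largest first.

    Isolated entities are not graph nodes, so every community has >= 1 edge.
    The single giant community is the largest component; size ties break to
    the component with the smallest lexicographic member id.
    """
    comps = [tuple(sorted(c)) for c in nx.connected_components(network.graph)]
    comps.sort(key=lambda members: (-len(members), members[0]))
    width = max(4, len(str(len(comps))))
    return [
        Community(
            community_id=f"C{i:0{width}d}",
            members=members,
            n_mirs=sum(1 for m in members if m in network.mir_ids),
            is_giant=(i == 1),
        )
        for i, members in enumerate(comps, start=1)
    ]


def communities_frame(communities: Sequence[Community]) -> pd.DataFrame:
    rows = [
        {"entity_id": m, "community_id": c.community_id, "is_giant": int(c.is_giant)}
        for c in communities
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["entity_id", "community_id", "is_giant"])


def communities_from_frame(df: pd.DataFrame, mir_ids: Iterable[str]) -> list[Community]:
    mir_ids = set(mir_ids)
    out = []
    for cid, group in df.groupby("community_id"):
        members = tuple(sorted(group["entity_id"].astype(str)))
        out.append(
            Community(
                str(cid),
                members,
                sum(1 for m in members if m in mir_ids),
                bool(group["is_giant"].iloc[0]),
            )
        )
    out.sort(key=lambda c: (-c.size, c.members[0]))
    return out


# ---------------------------------------------------------------------------
# summaries

def topology_summary(network: GeneNetwork, communities: Sequence[Community]) -> dict:
    """Community-size and degree summaries plus the standard group contrasts.

    Contrasts: MIR vs coding-gene node degree (one-sided Mann-Whitney, MIRs
    greater) and MIR-containing vs MIR-free community size (two-sided
    Wilcoxon rank-sum). A contrast with an empty group is reported as
    not-applicable (p = None). The log-log slope of binned degree frequencies
    is descriptive only.
    """
    sizes = np.array([c.size for c in communities], dtype=int)
    size_values, size_counts = (
        np.unique(sizes, return_counts=True) if sizes.size else (np.array([]), np.array([]))
    )
    degrees = dict(network.graph.degree())
    mir_deg = [d for n, d in degrees.items() if n in network.mir_ids]
    gene_deg = [d for n, d in degrees.items() if n not in network.mir_ids]
    if mir_deg and gene_deg:
        u, p_deg = sps.mannwhitneyu(mir_deg, gene_deg, alternative="greater")
        degree_test = {"U": float(u), "p": float(p_deg)}
    else:
        degree_test = {"U": None, "p": None}

    with_mir = [c.size for c in communities if c.n_mirs > 0]
    without_mir = [c.size for c in communities if c.n_mirs == 0]
    if with_mir and without_mir:
        stat, p_size = sps.ranksums(with_mir, without_mir)
        size_test = {"statistic": float(stat), "p": float(p_size)}
    else:
        size_test = {"statistic": None, "p": None}

    deg_arr = np.array(list(degrees.values()), dtype=int)
    slope = None
    if deg_arr.size:
        vals, counts = np.unique(deg_arr, return_counts=True)
        mask = vals > 0
        if mask.sum() >= 2:
            x = np.log10(vals[mask])
            y = np.log10(counts[mask])
            slope = float(np.polyfit(x, y, 1)[0])

    return {
        "n_nodes": network.graph.number_of_nodes(),
        "n_edges": network.graph.number_of_edges(),
        "n_communities": len(communities),
        "community_size_histogram": {
            int(v): int(c) for v, c in zip(size_values, size_counts)
        },
        "node_degrees": {n: int(d) for n, d in degrees.items()},
        "mir_vs_gene_degree": degree_test,
        "mir_vs_mirfree_community_size": size_test,
        "degree_loglog_slope": slope,
    }


def tad_overlap_report(
    communities: Sequence[Community],
    tads: Sequence[GenomicInterval],
    tss_index: TssIndex,
) -> pd.DataFrame:
    """Per community: distinct TADs hit by member TSSs and the in-TAD fraction."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, tad in enumerate(tads):
        trees[tad.chrom][tad.start:tad.end] = i
    rows = []
    for c in communities:
        tad_ids: set[int] = set()
        inside = 0
        for m in c.members:
            loc = tss_index.tss.get(m)
            if loc is None:
                continue
            chrom, pos = loc
            tree = trees.get(chrom)
            hits = tree[pos] if tree is not None else set()
            if hits:
                inside += 1
                tad_ids.update(h.data for h in hits)
        rows.append(
            {
                "community_id": c.community_id,
                "size": c.size,
                "n_tads": len(tad_ids),
                "fraction_in_tads": inside / c.size if c.size else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["community_id", "size", "n_tads", "fraction_in_tads"]
    )
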