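"""Mapping miRNA-target pairs onto chromatin communities and testing them.

The community-community link network is tested with an upper-tail
hypergeometric test whose universe is the set of all mapped
between-community target pairs: for a community pair {A, B}, the population
size N is the total number of mapped between-community pairs, the success
count K the pairs incident to A, the draw count n the pairs incident to B
and the observation k the pooled pair count between A and B. Benjamini-
Hochberg correction runs over all tested pairs and links are significant at
q <= ``community_link_fdr``. Permutation controls resample same-size random
gene sets and report the add-one empirical FDR.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .network import Community
from .stats import bh_adjust, empirical_p, hypergeom_upper_tail, percent
from .types import ExpressionRecord, TargetPair


def filter_target_pairs(
    pairs: Sequence[TargetPair], config: PipelineConfig
) -> list[TargetPair]:
    """Keep pairs supported by >= ``min_target_databases`` databases."""
    return [p for p in pairs if p.n_databases >= config.min_target_databases]


# ---------------------------------------------------------------------------
# mapping

@dataclass
class PairMapping:
    frame: pd.DataFrame  # mir_id, target_gene_id, status, mir_community, target_community
    n_total_input: int
    n_mapped: int
    n_within: int
    n_between: int

    @property
    def n_unmapped(self) -> int:
        return self.n_total_input - self.n_mapped

    @property
    def within_percent(self) -> float:
        """Share of mapped pairs arising within one community (one decimal)."""
        return percent(self.n_within, self.n_mapped, 1) if self.n_mapped else 0.0

    @property
    def mapped_percent(self) -> float:
        return percent(self.n_mapped, self.n_total_input, 1) if self.n_total_input else 0.0


def community_index(communities: Sequence[Community]) -> dict[str, str]:
    return {m: c.community_id for c in communities for m in c.members}


def map_pairs_to_communities(
    pairs: Sequence[TargetPair], communities: Sequence[Community]
) -> PairMapping:
    """Locate each target pair on the community partition.

    A pair is mapped when both endpoints are network nodes; it is "within"
    when both fall in the same community.
    """
    comm_of = community_index(communities)
    rows = []
    for p in pairs:
        cm = comm_of.get(p.mir_id)
        cg = comm_of.get(p.target_gene_id)
        if cm is None or cg is None:
            status = "unmapped"
        elif cm == cg:
            status = "within"
        else:
            status = "between"
        rows.append(
            {
                "mir_id": p.mir_id,
                "target_gene_id": p.target_gene_id,
                "status": status,
                "mir_community": cm or ".",
                "target_community": cg or ".",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["mir_id", "target_gene_id", "status", "mir_community", "target_community"],
    )
    status = frame["status"] if len(frame) else pd.Series(dtype=object)
    n_within = int((status == "within").sum())
    n_between = int((status == "between").sum())
    return PairMapping(
        frame=frame,
        n_total_input=len(pairs),
        n_mapped=n_within + n_between,
        n_within=n_within,
        n_between=n_between,
    )


def within_community_depletion_test(
    mapping: PairMapping, communities: Sequence[Community]
) -> dict:
    """Fisher test of within/between pair status against giant-community incidence.

    Table convention: rows split mapped pairs by whether either endpoint lies
    in the giant community; columns split them within vs between. A zero
    margin yields p = 1 with a warning.
    """
    giant = next(c.community_id for c in communities if c.is_giant)
    mapped = mapping.frame[mapping.frame["status"] != "unmapped"]
    in_giant = (mapped["mir_community"] == giant) | (
        mapped["target_community"] == giant
    )
    within = mapped["status"] == "within"
    table = np.array(
        [
            [int((within & in_giant).sum()), int((within & ~in_giant).sum())],
            [int((~within & in_giant).sum()), int((~within & ~in_giant).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        odds, p = float("nan"), 1.0
    else:
        odds, p = sps.fisher_exact(table, alternative="two-sided")
    return {
        "table": table.tolist(),
        "odds_ratio": float(odds),
        "p": float(p),
        "giant_community": giant,
    }


# ---------------------------------------------------------------------------
# community-community link network

@dataclass(frozen=True)
class CommunityLink:
    community_a: str
    community_b: str
    n_pairs: int
    p: float
    q: float
    significant: bool


def community_link_network(
    mapping: PairMapping,
    communities: Sequence[Community],
    config: PipelineConfig,
    min_pairs: int | None = None,
) -> list[CommunityLink]:
    """Hypergeometric community-pair enrichment of mapped between-community pairs.

    ``min_pairs`` overrides ``config.min_community_pairs`` (the sensitivity
    re-run uses 5).
    """
    if min_pairs is None:
        min_pairs = config.min_community_pairs
    between = mapping.frame[mapping.frame["status"] == "between"]
    N = len(between)
    if N == 0:
        warnings.warn("no mapped between-community pairs; empty link network")
        return []
    incident: dict[str, int] = defaultdict(int)
    pooled: dict[tuple[str, str], int] = defaultdict(int)
    for cm, cg in zip(between["mir_community"], between["target_community"]):
        incident[cm] += 1
        incident[cg] += 1
        key = (cm, cg) if cm <= cg else (cg, cm)
        pooled[key] += 1
    tested = sorted(key for key, n in pooled.items() if n >= min_pairs)
    if not tested:
        warnings.warn("no community pair reaches the minimum pair count")
        return []
    pvals = [
        hypergeom_upper_tail(pooled[key], N, incident[key[0]], incident[key[1]])
        for key in tested
    ]
    qvals = bh_adjust(pvals)
    return [
        CommunityLink(
            a,
            b,
            pooled[(a, b)],
            float(p),
            float(q),
            bool(q <= config.community_link_fdr),
        )
        for (a, b), p, q in zip(tested, pvals, qvals)
    ]


def links_frame(links: Sequence[CommunityLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "community_a": l.community_a,
                "community_b": l.community_b,
                "n_pairs": l.n_pairs,
                "p": l.p,
                "q": l.q,
                "significant": int(l.significant),
            }
            for l in links
        ],
        columns=["community_a", "community_b", "n_pairs", "p", "q", "significant"],
    )


# ---------------------------------------------------------------------------
# permutation controls

@dataclass
class PermutationSummary:
    variant: str  # between | within
    observed: np.ndarray
    null_statistics: np.ndarray
    mw_p: float | None
    empirical_fdr: float
    n_permutations: int
    seed: int | None = None

    @property
    def observed_statistic(self) -> float:
        return float(np.mean(self.observed)) if self.observed.size else 0.0


def permutation_percent_targeted(
    communities: Sequence[Community],
    mapping: PairMapping,
    mir_ids: Iterable[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    n_permutations: int | None = None,
    gene_pool: Sequence[str] | None = None,
) -> dict[str, PermutationSummary]:
    """Observed vs resampled percent of community genes targeted by MIRs.

    For each community the observed statistic is the percentage of its
    protein-coding genes targeted by networked MIRs from another community
    ("between") or from the community itself ("within"). The null resamples
    a same-size random gene set per community from ``gene_pool`` — all
    annotated protein-coding genes, independent of MIRs and of network
    membership (10^3 draws by default); genes absent from the network carry
    no mapped targeting. Each null replicate draws the community sets
    jointly without replacement, so the resampled sets are disjoint like
    the observed partition. The per-replicate summary statistic is the mean
    percentage over communities; the Mann-Whitney p compares the observed
    per-community values against the pooled null values.
    """
    if n_permutations is None:
        n_permutations = config.n_permutations
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    mir_ids = set(mir_ids)

    comm_list = [c for c in communities if any(m not in mir_ids for m in c.members)]
    comm_ids = [c.community_id for c in comm_list]
    cid_to_idx = {cid: i for i, cid in enumerate(comm_ids)}
    networked = {m for c in comm_list for m in c.members if m not in mir_ids}
    if gene_pool is None:
        gene_pool = networked
    gene_pool = sorted(set(gene_pool) | networked)
    gid_to_idx = {g: i for i, g in enumerate(gene_pool)}
    G, C = len(gene_pool), len(comm_ids)

    # gene x community indicator: gene g is targeted by >=1 MIR of community c
    targeted_by = np.zeros((G, C), dtype=bool)
    mapped = mapping.frame[mapping.frame["status"] != "unmapped"]
    for gid, cm in zip(mapped["target_gene_id"], mapped["mir_community"]):
        gi = gid_to_idx.get(gid)
        ci = cid_to_idx.get(cm)
        if gi is not None and ci is not None:
            targeted_by[gi, ci] = True
    n_targeting = targeted_by.sum(axis=1)
    any_targeted = n_targeting >= 1
    # community index when a gene's single targeting community is that one
    sole = np.where(n_targeting == 1, targeted_by.argmax(axis=1), -1)

    member_idx = [
        np.array(
            [gid_to_idx[m] for m in c.members if m not in mir_ids], dtype=int
        )
        for c in comm_list
    ]
    sizes = np.array([idx.size for idx in member_idx], dtype=int)

    def percents(sets: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        between = np.empty(C)
        within = np.empty(C)
        for ci, idx in enumerate(sets):
            n = idx.size
            if n == 0:
                between[ci] = within[ci] = 0.0
                continue
            n_any = int(any_targeted[idx].sum())
            n_only_self = int((sole[idx] == ci).sum())
            between[ci] = 100.0 * (n_any - n_only_self) / n
            within[ci] = 100.0 * targeted_by[idx, ci].sum() / n
        return between, within

    obs_between, obs_within = percents(member_idx)
    null_between = np.empty(n_permutations)
    null_within = np.empty(n_permutations)
    null_between_values = []
    null_within_values = []
    total = int(sizes.sum())
    if total > G:
        raise ValueError("gene pool smaller than the community gene total")
    bounds = np.cumsum(sizes)[:-1]
    for r in range(n_permutations):
        joint = rng.choice(G, size=total, replace=False)
        draws = np.split(joint, bounds)
        nb, nw = percents(draws)
        null_between[r] = nb.mean() if C else 0.0
        null_within[r] = nw.mean() if C else 0.0
        null_between_values.append(nb)
        null_within_values.append(nw)

    def summarize(observed, null_stats, null_values, variant) -> PermutationSummary:
        pooled = np.concatenate(null_values) if null_values else np.array([])
        if observed.size and pooled.size and (
            np.ptp(observed) > 0 or np.ptp(pooled) > 0
        ):
            _, mw_p = sps.mannwhitneyu(observed, pooled, alternative="two-sided")
            mw_p = float(mw_p)
        else:
            mw_p = None
        return PermutationSummary(
            variant=variant,
            observed=observed,
            null_statistics=null_stats,
            mw_p=mw_p,
            empirical_fdr=empirical_p(null_stats, float(np.mean(observed))),
            n_permutations=n_permutations,
        )

    return {
        "between": summarize(obs_between, null_between, null_between_values, "between"),
        "within": summarize(obs_within, null_within, null_within_values, "within"),
    }


# ---------------------------------------------------------------------------
# shared enriched terms

def enriched_terms_for_gene_sets(
    gene_sets: Sequence[np.ndarray],
    term_matrix: np.ndarray,
    fdr: float,
) -> list[set[int]]:
    """BH-corrected upper-tail hypergeometric term enrichment per gene set.

    ``term_matrix`` is a genes x terms indicator over the annotated
    background; ``gene_sets`` hold row indices into it.
    """
    N = term_matrix.shape[0]
    K = term_matrix.sum(axis=0)
    out = []
    for idx in gene_sets:
        n = idx.size
        if n == 0:
            out.append(set())
            continue
        k = term_matrix[idx].sum(axis=0)
        present = np.flatnonzero(k > 0)
        if present.size == 0:
            out.append(set())
            continue
        pvals = sps.hypergeom.sf(k[present] - 1, N, K[present], n)
        qvals = bh_adjust(pvals)
        out.append(set(present[qvals <= fdr].tolist()))
    return out


def shared_enriched_terms(
    links: Sequence[CommunityLink],
    communities: Sequence[Community],
    term_annotations: pd.DataFrame,
    mir_ids: Iterable[str],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    n_permutations: int | None = None,
) -> dict:
    """Shared over-represented terms between linked communities vs random sets."""
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    if n_permutations is None:
        n_permutations = config.n_permutations
    mir_ids = set(mir_ids)

    genes = sorted(set(term_annotations["gene_id"].astype(str)))
    terms = sorted(set(term_annotations["term_id"].astype(str)))
    gidx = {g: i for i, g in enumerate(genes)}
    tidx = {t: i for i, t in enumerate(terms)}
    matrix = np.zeros((len(genes), len(terms)), dtype=bool)
    for g, t in zip(term_annotations["gene_id"], term_annotations["term_id"]):
        matrix[gidx[str(g)], tidx[str(t)]] = True

    linked_comms = sorted({l.community_a for l in links} | {l.community_b for l in links})
    by_id = {c.community_id: c for c in communities}
    comm_gene_idx = {
        cid: np.array(
            [gidx[m] for m in by_id[cid].members if m not in mir_ids and m in gidx],
            dtype=int,
        )
        for cid in linked_comms
    }
    enriched = dict(
        zip(
            linked_comms,
            enriched_terms_for_gene_sets(
                [comm_gene_idx[c] for c in linked_comms],
                matrix,
                config.term_enrichment_fdr,
            ),
        )
    )
    observed = np.array(
        [len(enriched[l.community_a] & enriched[l.community_b]) for l in links],
        dtype=int,
    )

    G = len(genes)
    null_shared = []
    for _ in range(n_permutations):
        random_sets = [
            rng.choice(G, size=comm_gene_idx[c].size, replace=False)
            if comm_gene_idx[c].size
            else np.array([], dtype=int)
            for c in linked_comms
        ]
        rand_enriched = dict(
            zip(
                linked_comms,
                enriched_terms_for_gene_sets(
                    random_sets, matrix, config.term_enrichment_fdr
                ),
            )
        )
        null_shared.append(
            [
                len(rand_enriched[l.community_a] & rand_enriched[l.community_b])
                for l in links
            ]
        )
    null_arr = np.array(null_shared, dtype=int) if null_shared else np.zeros((0, 0))
    if observed.size and null_arr.size and (
        np.ptp(observed) > 0 or np.ptp(null_arr) > 0
    ):
        _, mw_p = sps.mannwhitneyu(
            observed, null_arr.ravel(), alternative="two-sided"
        )
        mw_p = float(mw_p)
    else:
        mw_p = None
    per_link = pd.DataFrame(
        {
            "community_a": [l.community_a for l in links],
            "community_b": [l.community_b for l in links],
            "shared_terms": observed,
        }
    )
    return {
        "per_link": per_link,
        "observed_mean": float(observed.mean()) if observed.size else 0.0,
        "null_mean": float(null_arr.mean()) if null_arr.size else 0.0,
        "mw_p": mw_p,
        "n_permutations": n_permutations,
    }


# ---------------------------------------------------------------------------
# target expression contrast

def target_expression_contrast(
    communities: Sequence[Community],
    mapping: PairMapping,
    expression: Sequence[ExpressionRecord],
    mir_ids: Iterable[str],
) -> pd.DataFrame:
    """Per cell line: MIR-vs-mean-target Spearman and target/non-target t-test."""
    mir_ids = set(mir_ids)
    comm_of = community_index(communities)
    mapped = mapping.frame[mapping.frame["status"] != "unmapped"]
    targets_of: dict[str, set[str]] = defaultdict(set)
    for mid, gid in zip(mapped["mir_id"], mapped["target_gene_id"]):
        targets_of[mid].add(gid)
    targeted_genes = set().union(*targets_of.values()) if targets_of else set()
    community_genes = {m for c in communities for m in c.members if m not in mir_ids}

    expr = pd.DataFrame(
        [(r.entity_id, r.cell_line, r.value) for r in expression],
        columns=["entity_id", "cell_line", "value"],
    )
    rows = []
    for cell, sub in expr.groupby("cell_line"):
        values = dict(zip(sub["entity_id"], sub["value"]))
        mir_x, target_y = [], []
        for mid, tg in targets_of.items():
            if mid not in values:
                continue
            tvals = [values[g] for g in tg if g in values]
            if tvals:
                mir_x.append(values[mid])
                target_y.append(float(np.mean(tvals)))
        if len(mir_x) >= 3 and np.ptp(mir_x) > 0 and np.ptp(target_y) > 0:
            rho, rho_p = sps.spearmanr(mir_x, target_y)
            rho, rho_p = float(rho), float(rho_p)
        else:
            rho = rho_p = None
        tvals = [
            values[g] for g in community_genes & targeted_genes if g in values
        ]
        nvals = [
            values[g] for g in community_genes - targeted_genes if g in values
        ]
        if len(tvals) >= 2 and len(nvals) >= 2:
            t, t_p = sps.ttest_ind(tvals, nvals, equal_var=False)
            t, t_p = float(t), float(t_p)
        else:
            t = t_p = None
        rows.append(
            {
                "cell_line": cell,
                "spearman_rho": rho,
                "spearman_p": rho_p,
                "mean_target_expr": float(np.mean(tvals)) if tvals else None,
                "mean_nontarget_expr": float(np.mean(nvals)) if nvals else None,
                "t_statistic": t,
                "t_p": t_p,
            }
        )
    return pd.DataFrame(rows)
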