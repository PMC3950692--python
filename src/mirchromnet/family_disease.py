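"""Family/disease co-localization statistics on the MIR interactome.

The permutation null redraws the observed number of MIR-MIR contacts
uniformly (without replacement) from all unordered pairs of networked MIRs,
so every replicate preserves the edge count exactly; empirical FDRs use the
add-one estimator.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .mir_models import MirEdge
from .network import Community
from .stats import empirical_p, percent


@dataclass(frozen=True)
class EnrichmentResult:
    group_id: str
    n_members: int  # networked members
    observed: int
    null_mean: float
    null_sd: float
    empirical_fdr: float
    n_permutations: int


def group_contact_enrichment(
    edges: Sequence[MirEdge],
    group_map: Mapping[str, set[str] | frozenset[str]],
    config: PipelineConfig,
    rng: np.random.Generator | None = None,
    n_permutations: int | None = None,
) -> list[EnrichmentResult]:
    """Within-group contact counts vs a uniform random-rewiring null.

    ``group_map`` maps a group id (family or disease category) to its member
    MIR ids; a MIR may belong to several disease categories. Groups with
    fewer than two networked members are excluded.
    """
    if not edges:
        raise ValueError("empty edge list")
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    if n_permutations is None:
        n_permutations = config.n_permutations

    nodes = sorted({m for e in edges for m in (e.mir_a, e.mir_b)})
    node_idx = {m: i for i, m in enumerate(nodes)}
    n = len(nodes)
    if n < 2:
        raise ValueError("need >= 2 networked MIRs")
    iu, ju = np.triu_indices(n, k=1)
    n_pairs_total = iu.size
    n_edges = len({e.pair for e in edges})
    edge_pairs = {tuple(sorted((node_idx[e.mir_a], node_idx[e.mir_b]))) for e in edges}

    groups = {
        gid: frozenset(members) & set(nodes)
        for gid, members in group_map.items()
    }
    groups = {g: m for g, m in sorted(groups.items()) if len(m) >= 2}
    member_mask = {
        gid: np.isin(np.arange(n), [node_idx[m] for m in members])
        for gid, members in groups.items()
    }
    observed = {
        gid: sum(1 for i, j in edge_pairs if mask[i] and mask[j])
        for gid, mask in member_mask.items()
    }

    gids = list(groups)
    mask_matrix = np.column_stack([member_mask[g] for g in gids])  # n x G
    null_matrix = np.empty((n_permutations, len(gids)), dtype=int)
    for r in range(n_permutations):
        draw = rng.choice(n_pairs_total, size=n_edges, replace=False)
        null_matrix[r] = (
            mask_matrix[iu[draw]] & mask_matrix[ju[draw]]
        ).sum(axis=0)
    null_counts = {gid: null_matrix[:, j] for j, gid in enumerate(gids)}

    return [
        EnrichmentResult(
            group_id=gid,
            n_members=len(groups[gid]),
            observed=observed[gid],
            null_mean=float(null_counts[gid].mean()),
            null_sd=float(null_counts[gid].std(ddof=0)),
            empirical_fdr=empirical_p(null_counts[gid], observed[gid]),
            n_permutations=n_permutations,
        )
        for gid in groups
    ]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "n_members": r.n_members,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "empirical_fdr": r.empirical_fdr,
            }
            for r in results
        ],
        columns=["group_id", "n_members", "observed", "null_mean", "null_sd", "empirical_fdr"],
    )


def disease_concordance(
    edges: Sequence[MirEdge], disease_map: Mapping[str, set[str] | frozenset[str]]
) -> dict:
    """Among edges whose both MIRs are disease-annotated, the share with a
    disease category in common (nearest-integer percent), plus the
    per-category edge tally (an edge may count in several categories)."""
    both_annotated = 0
    sharing = 0
    per_category: dict[str, int] = defaultdict(int)
    for e in edges:
        da = set(disease_map.get(e.mir_a, ()))
        db = set(disease_map.get(e.mir_b, ()))
        if not da or not db:
            continue
        both_annotated += 1
        common = da & db
        if common:
            sharing += 1
            for cat in common:
                per_category[cat] += 1
    return {
        "n_both_annotated": both_annotated,
        "n_sharing": sharing,
        "percent_sharing": percent(sharing, both_annotated) if both_annotated else 0.0,
        "per_category": dict(sorted(per_category.items())),
    }


def community_disease_chi2(
    communities: Sequence[Community],
    disease_map: Mapping[str, set[str] | frozenset[str]],
    mir_ids: set[str] | frozenset[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Chi-square disease-class enrichment per community.

    Background is all networked MIRs carrying >= 1 disease label. For each
    (community, class) with at least ``chi2_min_mirs`` member MIRs in the
    class, a 2-cell observed-vs-expected chi-square (1 df) compares the
    class count among the community's annotated MIRs against the background
    class frequency; significant at p < ``chi2_alpha``.
    """
    networked_mirs = {
        m for c in communities for m in c.members if m in mir_ids
    }
    background = [m for m in sorted(networked_mirs) if disease_map.get(m)]
    n_bg = len(background)
    class_bg: dict[str, int] = defaultdict(int)
    for m in background:
        for cat in disease_map[m]:
            class_bg[cat] += 1

    rows = []
    for comm in communities:
        annotated = [
            m for m in comm.members if m in mir_ids and disease_map.get(m)
        ]
        m_count = len(annotated)
        if m_count == 0:
            continue
        class_obs: dict[str, int] = defaultdict(int)
        for m in annotated:
            for cat in disease_map[m]:
                class_obs[cat] += 1
        for cat, o in sorted(class_obs.items()):
            if o < config.chi2_min_mirs:
                continue
            freq = class_bg[cat] / n_bg if n_bg else 0.0
            e = m_count * freq
            testable = 0.0 < e < m_count
            if testable:
                stat = (o - e) ** 2 / e + ((m_count - o) - (m_count - e)) ** 2 / (
                    m_count - e
                )
                p = float(sps.chi2.sf(stat, df=1))
            else:
                stat, p = float("nan"), float("nan")
            rows.append(
                {
                    "community_id": comm.community_id,
                    "disease_class": cat,
                    "n_mirs_in_class": o,
                    "n_annotated_mirs": m_count,
                    "background_frequency": freq,
                    "chi2": stat,
                    "p": p,
                    "testable": int(testable),
                    "significant": int(testable and p < config.chi2_alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "community_id", "disease_class", "n_mirs_in_class",
            "n_annotated_mirs", "background_frequency", "chi2", "p",
            "testable", "significant",
        ],
    )
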