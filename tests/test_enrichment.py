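"""Community-level miRNA-target mapping, tests and permutation controls."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from mirchromnet.config import PipelineConfig
from mirchromnet.enrichment import (
    PairMapping,
    community_link_network,
    filter_target_pairs,
    map_pairs_to_communities,
    permutation_percent_targeted,
    shared_enriched_terms,
    target_expression_contrast,
    within_community_depletion_test,
)
from mirchromnet.network import Community
from mirchromnet.stats import bh_adjust, empirical_p, hypergeom_upper_tail, percent
from mirchromnet.types import ExpressionRecord, TargetPair


@pytest.fixture(scope="module")
def config():
    return PipelineConfig()


def make_mapping(rows):
    frame = pd.DataFrame(
        rows,
        columns=["mir_id", "target_gene_id", "status", "mir_community", "target_community"],
    )
    n_within = int((frame.status == "within").sum())
    n_between = int((frame.status == "between").sum())
    return PairMapping(frame, len(frame), n_within + n_between, n_within, n_between)


class TestFilterAndMapping:
    def test_database_threshold(self, config):
        pairs = [TargetPair("m", "g1", 1), TargetPair("m", "g2", 2)]
        assert filter_target_pairs(pairs, config) == [pairs[1]]
        at = [TargetPair("m", "g", 2)]
        assert filter_target_pairs(at, config) == at

    def test_mapping_statuses(self):
        comms = [
            Community("C1", ("m1", "g1"), 1, True),
            Community("C2", ("g2",), 0, False),
        ]
        pairs = [
            TargetPair("m1", "g2", 2),
            TargetPair("m1", "g1", 2),
            TargetPair("m1", "gX", 2),
        ]
        mapping = map_pairs_to_communities(pairs, comms)
        assert list(mapping.frame.status) == ["between", "within", "unmapped"]
        assert mapping.n_mapped == 2 and mapping.n_within == 1

    def test_conservation_on_synthetic_bundle(self, result):
        m = result.mapping
        assert m.n_within + m.n_between + m.n_unmapped == len(result.filtered_targets)


class TestDepletionTest:
    def test_zero_margin_gives_p_one(self):
        comms = [Community("C1", ("m", "g"), 1, True)]
        mapping = make_mapping([])  # no mapped pairs at all
        with pytest.warns(UserWarning, match="degenerate"):
            out = within_community_depletion_test(mapping, comms)
        assert out["p"] == 1.0

    def test_fisher_matches_fixed_margin_enumeration(self):
        # giant/other x within/between table [[1, 9], [11, 3]]
        comms = [
            Community("G", ("x",), 0, True),
            Community("O", ("y",), 0, False),
        ]
        rows = (
            [("m", "g", "within", "G", "G")] * 1
            + [("m", "g", "within", "O", "O")] * 9
            + [("m", "g", "between", "G", "O")] * 11
            + [("m", "g", "between", "O", "O2")] * 3
        )
        out = within_community_depletion_test(make_mapping(rows), comms)
        assert out["table"] == [[1, 9], [11, 3]]
        assert out["p"] == pytest.approx(_fisher_two_sided(1, 9, 11, 3), rel=1e-9)
        assert out["p"] == pytest.approx(0.0028, abs=3e-4)

    def test_depletion_detected_on_synthetic_bundle(self, result):
        out = within_community_depletion_test(result.mapping, result.communities)
        assert 0.0 <= out["p"] <= 1.0
        assert np.array(out["table"]).sum() == result.mapping.n_mapped


def _fisher_two_sided(a, b, c, d):
    """Fixed-margin enumeration of the two-sided Fisher exact p."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestLinkNetwork:
    def test_below_min_pairs_not_tested(self, config):
        rows = [("m", "g", "between", "A", "B")] * 9
        links = community_link_network(
            make_mapping(rows),
            [Community("A", ("a",), 0, True), Community("B", ("b",), 0, False)],
            config,
        )
        assert links == []

    def test_upper_tail_matches_combinatorial_closed_form(self):
        # N=20, K=6, n=5, k=5 -> C(6,5)*C(14,0)/C(20,5) = 6/15504
        assert hypergeom_upper_tail(5, 20, 6, 5) == pytest.approx(6 / 15504, rel=1e-12)

    def test_tail_monotone_in_k(self):
        ps = [hypergeom_upper_tail(k, 100, 30, 40) for k in range(0, 31)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_sensitivity_mode_tests_more_pairs(self, config, result):
        default = result.links
        relaxed = community_link_network(
            result.mapping, result.communities, config, min_pairs=5
        )
        assert len(relaxed) >= len(default)
        assert {(l.community_a, l.community_b) for l in default} <= {
            (l.community_a, l.community_b) for l in relaxed
        }

    def test_bh_qvalues_monotone_in_p(self, result):
        if not result.links:
            pytest.skip("no tested links in fixture")
        by_p = sorted(result.links, key=lambda l: l.p)
        qs = [l.q for l in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))


class TestBhAndEmpirical:
    def test_bh_rejects_like_manual_stepup(self):
        rng = np.random.default_rng(1)
        ps = rng.uniform(size=25)
        qs = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps)
        manual = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, ps[idx] * m / rank)
            manual[idx] = prev
        assert np.allclose(qs, manual)

    def test_empirical_p_add_one(self):
        assert empirical_p([1, 2, 3], 4) == pytest.approx(1 / 4)
        assert empirical_p([5, 5, 5], 5) == pytest.approx(1.0)

    def test_percent_half_up(self):
        assert percent(132, 154) == 86.0
        assert percent(111, 1260, 1) == 8.8
        assert percent(1, 800, 1) == 0.1


class TestPermutationControls:
    def test_seeded_determinism(self, result, config):
        mir_ids = {m for m in result.network.mir_ids}
        kwargs = dict(n_permutations=50)
        a = permutation_percent_targeted(
            result.communities, result.mapping, mir_ids, config,
            np.random.default_rng(9), **kwargs,
        )
        b = permutation_percent_targeted(
            result.communities, result.mapping, mir_ids, config,
            np.random.default_rng(9), **kwargs,
        )
        assert np.array_equal(a["between"].null_statistics, b["between"].null_statistics)
        assert a["between"].empirical_fdr == b["between"].empirical_fdr

    def test_planted_enrichment_detected(self, result, bundle, config):
        mir_ids = set(result.network.mir_ids)
        out = permutation_percent_targeted(
            result.communities, result.mapping, mir_ids, config,
            np.random.default_rng(3), n_permutations=999,
            gene_pool=[g.gene_id for g in bundle.genes],
        )
        # genes are targeted from other communities above the resampled rate
        assert out["between"].empirical_fdr <= 0.001 + 1e-9

    def test_zero_permutations_rejected(self, result, config):
        with pytest.raises(ValueError):
            permutation_percent_targeted(
                result.communities, result.mapping, set(), config,
                np.random.default_rng(0), n_permutations=0,
            )


class TestSharedTerms:
    def test_counts_match_set_intersection_oracle(self, result, bundle, config):
        links = [l for l in result.links if l.significant] or result.links[:2]
        if not links:
            pytest.skip("no links in fixture")
        mir_ids = {m.mir_id for m in bundle.mirs}
        out = shared_enriched_terms(
            links, result.communities, bundle.terms, mir_ids, config,
            np.random.default_rng(0), n_permutations=5,
        )
        assert len(out["per_link"]) == len(links)
        assert (out["per_link"].shared_terms >= 0).all()

    def test_extreme_enrichment_is_detected(self, config):
        genes = [f"g{i}" for i in range(200)]
        rows = [(g, "bg") for g in genes] + [(g, "T") for g in genes[:10]]
        terms = pd.DataFrame(rows, columns=["gene_id", "term_id"])
        comms = [
            Community("A", tuple(genes[:10]), 0, True),
            Community("B", tuple(genes[:10]), 0, False),
        ]
        from mirchromnet.enrichment import CommunityLink

        links = [CommunityLink("A", "B", 10, 1e-9, 1e-9, True)]
        out = shared_enriched_terms(
            links, comms, terms, set(), config,
            np.random.default_rng(0), n_permutations=20,
        )
        # both communities carry term T exclusively -> it is shared
        assert out["per_link"].shared_terms.iloc[0] >= 1

    def test_planted_shared_terms_exceed_random(self, result, bundle, config):
        links = [l for l in result.links if l.significant]
        if not links:
            pytest.skip("no significant links in fixture")
        mir_ids = {m.mir_id for m in bundle.mirs}
        out = shared_enriched_terms(
            links, result.communities, bundle.terms, mir_ids, config,
            np.random.default_rng(1), n_permutations=99,
        )
        assert out["observed_mean"] > out["null_mean"]


class TestTargetExpression:
    def test_constant_expression_not_applicable(self, result):
        expr = [
            ExpressionRecord(e, "K562", 1.0)
            for c in result.communities
            for e in c.members
        ] + [
            ExpressionRecord(m, "K562", 1.0)
            for m in result.network.mir_ids
        ]
        out = target_expression_contrast(
            result.communities, result.mapping, expr, result.network.mir_ids
        )
        assert out.spearman_rho.isna().all()

    def test_planted_repression_detected(self):
        # 100 targeted vs 300 non-targeted community genes, targets halved
        rng = np.random.default_rng(0)
        mirs = [f"m{i}" for i in range(10)]
        genes_a = [f"ga{i}" for i in range(200)]
        genes_b = [f"gb{i}" for i in range(200)]
        comms = [
            Community("A", tuple(sorted(mirs + genes_a)), len(mirs), True),
            Community("B", tuple(genes_b), 0, False),
        ]
        rows = [
            (m, g, "between", "A", "B") for m in mirs for g in genes_b[:100]
        ]
        mapping = make_mapping(rows)
        targeted = set(genes_b[:100])
        expr = [ExpressionRecord(m, "K562", float(rng.lognormal(0, 0.3))) for m in mirs]
        for g in genes_a + genes_b:
            base = float(rng.lognormal(3, 0.3))
            if g in targeted:
                base *= 0.5
            expr.append(ExpressionRecord(g, "K562", base))
        out = target_expression_contrast(comms, mapping, expr, set(mirs))
        row = out.iloc[0]
        assert row.mean_target_expr < row.mean_nontarget_expr
        assert row.t_p < 0.01
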