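"""Properties of the synthetic-data generator."""

import numpy as np
import pytest
from scipy import stats as sps

from mirchromnet.config import PipelineConfig
from mirchromnet.enrichment import filter_target_pairs
from mirchromnet.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_chia_pet,
    generate_expression_marks,
    generate_genome,
    generate_targets,
    simulate_bundle,
    write_bundle,
)


def test_same_seed_identical_output():
    a = simulate_bundle(SimulationConfig(seed=3))
    b = simulate_bundle(SimulationConfig(seed=3))
    assert a.genes == b.genes and a.mirs == b.mirs
    assert a.interactions == b.interactions
    assert a.expression == b.expression and a.targets == b.targets
    assert a.truth.communities == b.truth.communities


def test_no_mirs_still_valid():
    genes, mirs, truth = generate_genome(
        SimulationConfig(seed=0, n_mirs=0, n_clusters=0)
    )
    assert mirs == [] and len(genes) == 500
    assert all(t != "none" or m not in truth.tss for m, t in truth.mir_tier.items())


def test_genome_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        generate_genome(SimulationConfig(seed=0, chrom_length=200_000))


def test_intragenic_fraction_binomial():
    cfg = SimulationConfig(
        seed=42, n_mirs=1000, n_genes=1100, n_chromosomes=12,
        chrom_length=13_000_000, n_clusters=0, n_planted_communities=5,
        n_enriched_pairs=0,
    )
    _, mirs, _ = generate_genome(cfg)
    n_intra = sum(1 for m in mirs if m.context == "intragenic")
    sd = np.sqrt(1000 * 0.25)
    assert abs(n_intra - 500) <= 3 * sd


def test_intragenic_mirs_inside_host_same_strand():
    genes, mirs, _ = generate_genome(SimulationConfig(seed=9))
    by_id = {g.gene_id: g for g in genes}
    for m in mirs:
        if m.context != "intragenic":
            continue
        host = by_id[m.host_gene_id]
        assert host.interval.start <= m.pre_mirna.start
        assert m.pre_mirna.end <= host.interval.end
        assert host.interval.strand == m.pre_mirna.strand


def test_clustered_mirs_within_neighbor_gap():
    _, mirs, _ = generate_genome(SimulationConfig(seed=9))
    by_cluster = {}
    for m in mirs:
        if m.cluster_id:
            by_cluster.setdefault(m.cluster_id, []).append(m)
    assert by_cluster, "expected clusters in the default configuration"
    for members in by_cluster.values():
        members.sort(key=lambda m: m.pre_mirna.start)
        for a, b in zip(members, members[1:]):
            assert b.pre_mirna.start - a.pre_mirna.end <= 10_000


def test_full_reproducibility_emits_all_replicates():
    cfg = SimulationConfig(
        seed=2, edge_reproducibility=1.0, noise_edge_rate=0.0, n_clusters=0,
        fraction_cell_specific_communities=0.0,
    )
    genes, mirs, truth = generate_genome(cfg)
    interactions, _ = generate_chia_pet((genes, mirs), truth, cfg)
    n_expected = sum(
        sum(cfg.cell_lines[c] for c in e["cells"]) for e in truth.planted_edges
    )
    assert len(interactions) == n_expected


def test_zero_reproducibility_emits_nothing():
    cfg = SimulationConfig(
        seed=2, edge_reproducibility=0.0, noise_edge_rate=0.0, n_clusters=0
    )
    genes, mirs, truth = generate_genome(cfg)
    interactions, _ = generate_chia_pet((genes, mirs), truth, cfg)
    assert interactions == []


def test_replicate_recovery_matches_binomial_closed_form():
    # P(>=2 of 3 at 0.8) = 1 - (0.2^3 + 3*0.8*0.2^2) = 0.896
    cfg = SimulationConfig(
        seed=8, cell_lines={"K562": 3}, edge_reproducibility=0.8,
        noise_edge_rate=0.0, n_clusters=0,
        fraction_cell_specific_communities=0.0,
    )
    genes, mirs, truth = generate_genome(cfg)
    interactions, _ = generate_chia_pet((genes, mirs), truth, cfg)
    # recover per-edge replicate support by mapping anchors back to TSS windows
    from mirchromnet.network import TssIndex

    tss_index = TssIndex(truth.tss, frozenset(truth.mir_tier))
    pcfg = PipelineConfig()
    support: dict[frozenset, set[str]] = {}
    for d in interactions:
        a = tss_index.entities_on_anchor(d.anchor_a, pcfg.anchor_tss_window)
        b = tss_index.entities_on_anchor(d.anchor_b, pcfg.anchor_tss_window)
        for u in a:
            for v in b:
                if u != v:
                    support.setdefault(frozenset((u, v)), set()).add(d.replicate_id)
    n_rec = sum(
        1
        for e in truth.planted_edges
        if len(support.get(frozenset((e["u"], e["v"])), set())) >= 2
    )
    n_tot = len(truth.planted_edges)
    frac = n_rec / n_tot
    sd = np.sqrt(0.896 * 0.104 / n_tot)
    assert abs(frac - 0.896) <= 3 * sd


def test_self_depletion_zero_removes_within_pairs():
    cfg = SimulationConfig(seed=4, target_self_depletion=0.0)
    genes, mirs, truth = generate_genome(cfg)
    pairs = generate_targets((genes, mirs), truth, cfg)
    comm = truth.community_of
    assert not any(
        comm.get(p.mir_id) is not None
        and comm.get(p.mir_id) == comm.get(p.target_gene_id)
        for p in pairs
    )


def test_uniform_target_null_goodness_of_fit():
    """With multipliers at 1 the community-pair target counts follow the flat
    Bernoulli rate: chi-square GOF not rejected at alpha=0.01 in >=18/20 seeds."""
    rejections = 0
    for seed in range(20):
        cfg = SimulationConfig(
            seed=100 + seed, target_between_enrichment=1.0,
            target_self_depletion=1.0, n_enriched_pairs=0,
        )
        genes, mirs, truth = generate_genome(cfg)
        pairs = generate_targets((genes, mirs), truth, cfg)
        comm = truth.community_of
        blocks = truth.communities
        mir_ids = {m.mir_id for m in mirs}
        n_mirs_b = [sum(1 for x in b if x in mir_ids) for b in blocks]
        n_genes_b = [len(b) - nm for b, nm in zip(blocks, n_mirs_b)]
        obs: dict[tuple[int, int], int] = {}
        for p in pairs:
            bm, bg = comm.get(p.mir_id), comm.get(p.target_gene_id)
            if bm is None or bg is None or bm == bg:
                continue
            obs[(bm, bg)] = obs.get((bm, bg), 0) + 1
        stat = 0.0
        dof = 0
        for bm in range(len(blocks)):
            for bg in range(len(blocks)):
                if bm == bg:
                    continue
                exp = n_mirs_b[bm] * n_genes_b[bg] * cfg.base_target_rate
                if exp < 5:
                    continue
                o = obs.get((bm, bg), 0)
                stat += (o - exp) ** 2 / exp
                dof += 1
        if dof and sps.chi2.sf(stat, dof) < 0.01:
            rejections += 1
    assert rejections <= 2


def test_single_database_support_filters_to_empty():
    cfg = SimulationConfig(seed=4, n_database_probs=(1.0, 0, 0, 0, 0, 0))
    genes, mirs, truth = generate_genome(cfg)
    pairs = generate_targets((genes, mirs), truth, cfg)
    assert pairs and filter_target_pairs(pairs, PipelineConfig()) == []


def test_noise_free_expression_perfectly_ranks_activity():
    cfg = SimulationConfig(
        seed=6, expression_noise_sd=0.0, fraction_cell_specific_communities=0.0
    )
    genes, mirs, truth = generate_genome(cfg)
    sim = generate_expression_marks((genes, mirs), truth, cfg)
    values = {
        (r.entity_id, r.cell_line): r.value for r in sim.expression
    }
    ids = [m.mir_id for m in mirs]
    act = [truth.activity[i] for i in ids]
    rpm = [values[(i, "K562")] for i in ids]
    rho, _ = sps.spearmanr(act, rpm)
    assert rho == pytest.approx(1.0)


def test_activity_expression_correlation_with_default_noise():
    """Spearman(activity, RPM) > 0.5 for nearly every seed at n=500 MIRs."""
    cfg0 = SimulationConfig(
        n_mirs=500, n_genes=600, n_chromosomes=8, chrom_length=12_000_000,
        fraction_cell_specific_communities=0.0,
    )
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = cfg0.replace(seed=1000 + seed)
        genes, mirs, truth = generate_genome(cfg)
        sim = generate_expression_marks((genes, mirs), truth, cfg)
        values = {
            (r.entity_id, r.cell_line): r.value for r in sim.expression
        }
        ids = [m.mir_id for m in mirs]
        act = [truth.activity[i] for i in ids]
        rpm = [values[(i, "K562")] for i in ids]
        rho, _ = sps.spearmanr(act, rpm)
        hits += rho > 0.5
    assert hits >= 0.95 * n_seeds


def test_noise_derived_pairs_are_single_replicate(bundle, result):
    """Every gene pair derived from a noise contact has one-replicate support."""
    from mirchromnet.network import pair_support

    planted = {
        frozenset((e["u"], e["v"])) for e in bundle.truth.planted_edges
    }
    support = pair_support(
        bundle.interactions, result.tss_index, result.config
    )
    planted_entities = bundle.truth.community_of
    for pair, cells in support.items():
        u, v = sorted(pair)
        if planted_entities.get(u) == planted_entities.get(v) and (
            planted_entities.get(u) is not None
        ):
            continue  # pair within one planted block (planted or derived)
        n_datasets = sum(len(reps) for reps in cells.values())
        assert n_datasets == 1, (u, v, cells)


def test_bundle_roundtrip_ground_truth(tmp_path, bundle):
    write_bundle(bundle, tmp_path)
    truth = GroundTruth.from_json(tmp_path / "ground_truth.json")
    assert truth.communities == bundle.truth.communities
    assert truth.tss == bundle.truth.tss
    assert truth.enriched_pairs == bundle.truth.enriched_pairs
    assert (tmp_path / "interactions.bedpe").exists()
    assert (tmp_path / "peaks.tsv").exists()
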