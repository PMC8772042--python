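import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from recurbin.cluster_engine import (
    BinningConfig,
    ThresholdSchedule,
    _contig_center,
    accept_bins,
    filter_contigs,
    filter_low_probability,
    kmeans_probability,
    kmedoids_probability,
    metacomplexity,
    run_recursive,
    run_single_pass,
)
from recurbin.features import build_features
from recurbin.io_formats import ContigRecord, ContigSet, MarkerHitRecord
from recurbin.marker_quality import MarkerSetCatalog, build_hit_table
from recurbin.synthetic_data import (
    SyntheticCommunitySpec,
    generate_community,
    two_scale_abundance,
)


@pytest.fixture(scope="module")
def feats(community):
    return build_features(community.contigs, community.depth)


def _truth_labels(community, ids):
    return [community.truth.genome_of[c] for c in ids]


# --------------------------------------------------------------- length filter

def test_length_filter_boundary():
    cs = ContigSet([ContigRecord(f"c{n}", "A" * n) for n in (1499, 1500, 1501)])
    kept = filter_contigs(cs, 1500)
    assert kept.ids == ["c1500", "c1501"]


def test_length_filter_zero_is_identity(community):
    assert filter_contigs(community.contigs, 0).ids == community.contigs.ids


def test_length_filter_all_short_errors():
    cs = ContigSet([ContigRecord("c1", "ACGT")])
    with pytest.raises(ValueError):
        filter_contigs(cs, 1500)


# -------------------------------------------------------------------- k-means

def test_kmeans_recovers_two_separated_genomes(model):
    com = generate_community(SyntheticCommunitySpec(n_genomes=2, rng_seed=4))
    f = build_features(com.contigs, com.depth)
    labels, centers, _ = kmeans_probability(f, model, 2, rng=0)
    ari = adjusted_rand_score(_truth_labels(com, f.contig_ids), labels)
    assert ari == 1.0


def test_kmeans_converges_immediately_from_true_partition(model, community, feats):
    # seed one center inside each planted genome
    seeds = []
    seen = set()
    for cid in feats.contig_ids:
        g = community.truth.genome_of[cid]
        if g not in seen:
            seen.add(g)
            seeds.append(cid)
    labels, _, objective = kmeans_probability(feats, model, len(seeds), init_seed_ids=seeds)
    assert adjusted_rand_score(_truth_labels(community, feats.contig_ids), labels) == 1.0
    # objective recorded per assignment step and never pathological
    assert len(objective) >= 1


def test_kmeans_objective_nondecreasing_until_convergence(model, community, feats):
    _, _, objective = kmeans_probability(feats, model, 10, rng=3)
    # final assignment against final centers is the argmax everywhere, so the
    # last step cannot lose probability
    assert objective[-1] >= objective[0] - 1e-6


def test_kmeans_k_exceeding_n_rejected(model, feats):
    with pytest.raises(ValueError):
        kmeans_probability(feats, model, len(feats) + 1)


def test_kmeans_empty_cluster_reseeded(model, feats):
    # k close to n forces empty clusters during iteration; all labels remain valid
    labels, centers, _ = kmeans_probability(feats, model, 25, rng=5)
    assert set(labels) <= set(range(25))
    assert all(np.any(labels == lab) for lab in range(25))


# ---------------------------------------------------------- probability filter

def test_prob_filter_zero_threshold_keeps_all(model, community, feats):
    labels, centers, _ = kmeans_probability(feats, model, 10, rng=1)
    out, s1, prob = filter_low_probability(feats, labels, centers, model, 1e-12)
    assert s1 == []
    assert np.all(out == labels)


def test_prob_filter_threshold_one_removes_uncertain(model, community, feats):
    labels, centers, _ = kmeans_probability(feats, model, 10, rng=1)
    out, s1, prob = filter_low_probability(feats, labels, centers, model, 0.999999999)
    removed = prob < 0.999999999
    assert len(s1) == removed.sum()
    assert np.all((out == -1) == removed)


def test_prob_filter_flags_planted_chimeras(model):
    """Contigs spliced from two genomes are enriched among the filtered-out."""
    com = generate_community(
        SyntheticCommunitySpec(n_genomes=4, chimera_rate=0.15, rng_seed=9, signature_divergence=0.9)
    )
    f = build_features(com.contigs, com.depth)
    labels, centers, _ = kmeans_probability(f, model, 4, rng=9)
    _, s1, prob = filter_low_probability(f, labels, centers, model, 0.80)
    chimera = np.array([com.truth.is_chimera(c) for c in f.contig_ids])
    if s1:
        removed_rate = chimera[s1].mean()
        overall_rate = chimera.mean()
        assert removed_rate >= overall_rate


def test_raw_filter_kind_uses_combined_probability(model, community, feats):
    labels, centers, _ = kmeans_probability(feats, model, 10, rng=1)
    out, s1, prob = filter_low_probability(feats, labels, centers, model, 0.5, kind="raw")
    # raw per-contig probabilities are tiny products; everything is filtered
    assert len(s1) == len(feats)


# ------------------------------------------------------------------ accept_bins

def _ladder_catalog():
    return MarkerSetCatalog("ladder", [[f"m{i}" for i in range(10)]])


def _table_with_recall(catalog, frac, contig="c0"):
    n = int(round(frac * 10))
    recs = [MarkerHitRecord(contig, f"m{i}") for i in range(n)]
    return build_hit_table(recs, catalog)


def test_accept_at_top_rung():
    cat = _ladder_catalog()
    t = _table_with_recall(cat, 1.0)
    sched = ThresholdSchedule()
    accepted, s2, term = accept_bins({0: ["c0"]}, t, cat, sched)
    assert len(accepted) == 1 and not term and sched.current_rung == 0


def test_ladder_descends_to_lowest_matching_rung():
    cat = _ladder_catalog()
    t = _table_with_recall(cat, 0.5)
    sched = ThresholdSchedule()
    accepted, s2, term = accept_bins({0: ["c0"]}, t, cat, sched)
    assert len(accepted) == 1 and not term
    assert sched.current_rung == 2  # 0.5 >= 0.30 only


def test_ladder_exhaustion_signals_termination():
    cat = _ladder_catalog()
    t = _table_with_recall(cat, 0.1)
    sched = ThresholdSchedule()
    accepted, s2, term = accept_bins({0: ["c0"]}, t, cat, sched)
    assert accepted == [] and term
    assert s2 == ["c0"]


def test_low_precision_blocks_acceptance():
    cat = _ladder_catalog()
    # every marker duplicated -> contamination 1.0 -> precision 0.5 < 0.9
    recs = [MarkerHitRecord(c, f"m{i}") for i in range(10) for c in ("c0", "c1")]
    t = build_hit_table(recs, cat)
    sched = ThresholdSchedule()
    accepted, s2, term = accept_bins({0: ["c0", "c1"]}, t, cat, sched)
    assert accepted == [] and term


# ------------------------------------------------------------------- k-medoids

def test_kmedoids_single_genome_single_medoid(model):
    com = generate_community(SyntheticCommunitySpec(n_genomes=1, rng_seed=6))
    f = build_features(com.contigs, com.depth)
    labels, medoids, _ = kmedoids_probability(f, model, [f.contig_ids[0]])
    assert np.all(labels == 0)
    assert 0 <= medoids[0] < len(f)


def test_kmedoids_recovers_two_genomes_from_marker_seeds(model):
    com = generate_community(SyntheticCommunitySpec(n_genomes=2, rng_seed=8))
    f = build_features(com.contigs, com.depth)
    table = build_hit_table(com.hits, com.catalog)
    from recurbin.marker_quality import estimate_k_and_seeds

    sel = estimate_k_and_seeds(table)
    labels, _, criterion = kmedoids_probability(f, model, sel.seed_contig_ids)
    assert adjusted_rand_score(_truth_labels(com, f.contig_ids), labels) == 1.0
    assert all(b <= a + 1e-9 for a, b in zip(criterion, criterion[1:]))


def test_kmedoids_criterion_matches_exhaustive_enumeration(model):
    """On a small pool the fixed point attains the global optimum over all medoid sets."""
    com = generate_community(
        SyntheticCommunitySpec(n_genomes=3, genome_length=18_000, rng_seed=10)
    )
    f = build_features(com.contigs, com.depth)
    assert len(f) <= 12
    k = 3
    seeds, seen = [], set()
    for cid in f.contig_ids:  # one seed per planted genome
        g = com.truth.genome_of[cid]
        if g not in seen:
            seen.add(g)
            seeds.append(cid)
    _, medoids, criterion = kmedoids_probability(f, model, seeds)

    diss = np.column_stack(
        [-model.log_scores(f.tnf, f.cov, f.lengths, _contig_center(f, m)) for m in range(len(f))]
    )  # diss[i, m]
    best = min(
        diss[:, list(combo)].min(axis=1).sum()
        for combo in itertools.combinations(range(len(f)), k)
    )
    assert criterion[-1] == pytest.approx(best, rel=1e-9)


def test_kmedoids_clamps_oversized_k(model):
    com = generate_community(SyntheticCommunitySpec(n_genomes=1, genome_length=12_000, rng_seed=2))
    f = build_features(com.contigs, com.depth)
    labels, medoids, _ = kmedoids_probability(f, model, list(f.contig_ids) + [f.contig_ids[0]])
    assert len(medoids) <= len(f)


# -------------------------------------------------------------- metacomplexity

@pytest.mark.parametrize(
    "gn,cn,score,band",
    [
        (40, 20, 60, "low"),
        (596, 478, 1074, "high"),
        (0, 0, 0, "low"),
        (200, 0, 200, "low"),
        (201, 0, 201, "medium"),
        (800, 0, 800, "medium"),
        (0, 801, 801, "high"),
        (1400, 0, 1400, "high"),
        (1400, 1, 1401, "ultra-high"),
    ],
)
def test_metacomplexity_bands(gn, cn, score, band):
    assert metacomplexity(gn, cn) == (score, band)


def test_metacomplexity_rejects_negative():
    with pytest.raises(ValueError):
        metacomplexity(-1, 0)


# --------------------------------------------------------------- full pipeline

def test_recursive_pipeline_recovers_planted_genomes(model, community):
    res = run_recursive(
        community.contigs, community.depth, model, community.hits, community.catalog,
        BinningConfig(rng_seed=1),
    )
    hq = [b for b in res.accepted_bins if b.quality.precision >= 0.9 and b.quality.recall >= 0.9]
    assert len(hq) >= 9
    pred = {c: b.bin_id for b in res.accepted_bins for c in b.contig_ids}
    ids = [c for c in community.contigs.ids if c in pred]
    ari = adjusted_rand_score([community.truth.genome_of[c] for c in ids], [pred[c] for c in ids])
    assert ari >= 0.95


def test_partition_conservation(model, community):
    res = run_recursive(
        community.contigs, community.depth, model, community.hits, community.catalog,
        BinningConfig(rng_seed=2),
    )
    binned = set(res.binned_ids)
    residual = set(res.residual_ids)
    assert binned.isdisjoint(residual)
    assert binned | residual == set(community.contigs.ids)
    assert len(res.binned_ids) + len(res.residual_ids) == len(community.contigs)


def test_determinism_under_fixed_seed(model, community):
    kwargs = (community.contigs, community.depth, model, community.hits, community.catalog)
    r1 = run_recursive(*kwargs, BinningConfig(rng_seed=5))
    r2 = run_recursive(*kwargs, BinningConfig(rng_seed=5))
    assert [b.contig_ids for b in r1.accepted_bins] == [b.contig_ids for b in r2.accepted_bins]
    assert r1.residual_ids == r2.residual_ids
    assert r1.trace == r2.trace


def test_empty_residual_means_single_round(model, community):
    res = run_recursive(
        community.contigs, community.depth, model, community.hits, community.catalog,
        BinningConfig(rng_seed=1),
    )
    if not res.residual_ids:
        assert len(res.trace) == 1


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_termination_and_monotone_shrinkage_on_hard_input(model, seed):
    """Indistinct genomes (divergence 0): pipeline must still terminate cleanly."""
    com = generate_community(
        SyntheticCommunitySpec(n_genomes=5, genome_length=40_000, signature_divergence=0.0, rng_seed=seed)
    )
    cfg = BinningConfig(rng_seed=seed, max_rounds=20)
    res = run_recursive(com.contigs, com.depth, model, com.hits, com.catalog, cfg)
    assert len(res.trace) <= cfg.max_rounds
    # the residual pool never grows from round to round
    prev = None
    for t in res.trace:
        if prev is not None:
            assert t["pool_size"] <= prev
        prev = t["pool_size"]
    assert set(res.binned_ids) | set(res.residual_ids) == set(com.contigs.ids)


def test_recursion_never_worse_than_single_pass(model):
    for seed in (1, 4, 5):
        spec = SyntheticCommunitySpec(n_genomes=8, rng_seed=seed, signature_divergence=0.7)
        ab = two_scale_abundance(4, 4, 3, np.random.default_rng(seed + 1000))
        com = generate_community(spec, abundance=ab)
        cfg = BinningConfig(rng_seed=seed)
        rec = run_recursive(com.contigs, com.depth, model, com.hits, com.catalog, cfg)
        sp = run_single_pass(com.contigs, com.depth, model, com.hits, com.catalog, cfg)
        assert len(rec.accepted_bins) >= len(sp.accepted_bins)
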