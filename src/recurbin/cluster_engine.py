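"""Two-stage recursive clustering of contigs.

Stage 1 runs a probability-model K-means over all contigs passing the
length filter: each contig is assigned to the center with the highest
combined composition+coverage probability, and centers are updated to
cluster centroids.  Stage 2 then repeats: contigs whose assignment is
below the minimum probability threshold are pooled (S1); each remaining
cluster is scored with the marker-based quality estimators and bins
meeting the precision/recall thresholds are extracted into the accepted
set Q, the rest pooled (S2); the pool S = S1 U S2 is re-clustered with a
probability K-medoids seeded by marker-carrying contigs.  Each pass
shrinks the problem, so rare community members that were drowned out in
the first pass can be resolved in later rounds.  When nothing qualifies
even at the lowest recall rung the recursion stops.

The recall acceptance threshold descends a fixed ladder (default
0.90 -> 0.60 -> 0.30) while the precision threshold stays constant
(default 0.90); the rung only moves when a full evaluation accepts
nothing at the current rung.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureTable, build_features
from .io_formats import ContigSet, DepthTable, MarkerHitRecord
from .marker_quality import (
    BinQuality,
    MarkerHitTable,
    MarkerSetCatalog,
    build_hit_table,
    estimate_k_and_seeds,
    eval_bin_quality,
)
from .prob_model import ProbabilityModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ClusterCenter:
    """A cluster center: either a member-contig medoid or a running centroid.

    ``length_proxy`` feeds the length-bin lookup of the composition
    posterior; for centroids it is the median member length.
    """

    tnf: np.ndarray
    cov: np.ndarray
    length_proxy: int
    kind: str = "centroid"  # or "medoid_contig"
    source_contig_id: Optional[str] = None


@dataclass
class ThresholdSchedule:
    """Quality thresholds with a descending recall ladder at fixed precision."""

    precision_min: float = 0.90
    recall_ladder: tuple[float, ...] = (0.90, 0.60, 0.30)
    prob_min: float = 0.80
    current_rung: int = 0

    def __post_init__(self) -> None:
        if not all(x > y for x, y in zip(self.recall_ladder, self.recall_ladder[1:])):
            raise ValueError("recall ladder must be strictly decreasing")
        if not all(0 < r <= 1 for r in self.recall_ladder):
            raise ValueError("recall rungs must lie in (0, 1]")
        if not (0 < self.prob_min < 1):
            raise ValueError("prob_min must lie in (0, 1)")


@dataclass
class AcceptedBin:
    bin_id: str
    contig_ids: list[str]
    quality: BinQuality
    recursion_round: int


@dataclass
class BinningResult:
    """Accepted bins (Q), the residual pool, and the per-round trace."""

    accepted_bins: list[AcceptedBin]
    residual_ids: list[str]
    trace: list[dict]
    seed: int
    assignment_probabilities: dict[str, float] = field(default_factory=dict)
    thresholds: Optional[dict] = None

    @property
    def binned_ids(self) -> list[str]:
        return [cid for b in self.accepted_bins for cid in b.contig_ids]


@dataclass
class BinningConfig:
    min_contig_length: int = 1500
    prob_min: float = 0.80
    precision_min: float = 0.90
    recall_ladder: tuple[float, ...] = (0.90, 0.60, 0.30)
    k_strategy: str = "median"
    k_override: Optional[int] = None
    k_fallback: int = 5
    max_rounds: int = 20
    max_iter_kmeans: int = 100
    max_iter_kmedoids: int = 50
    rng_seed: int = 0
    prob_filter_kind: str = "posterior"  # or "raw"

    def schedule(self) -> ThresholdSchedule:
        return ThresholdSchedule(self.precision_min, tuple(self.recall_ladder), self.prob_min)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def filter_contigs(contigs: ContigSet, min_length: int = 1500) -> ContigSet:
    """Drop contigs shorter than ``min_length`` (kept iff length >= min_length)."""
    if min_length < 0:
        raise ValueError("min_length must be nonnegative")
    kept = [c.id for c in contigs if c.length >= min_length]
    if not kept:
        raise ValueError(f"no contigs of length >= {min_length} remain")
    return contigs.subset(kept)


def _contig_center(features: FeatureTable, idx: int) -> ClusterCenter:
    return ClusterCenter(
        tnf=features.tnf[idx],
        cov=features.cov[idx],
        length_proxy=int(features.lengths[idx]),
        kind="medoid_contig",
        source_contig_id=features.contig_ids[idx],
    )


def _centroid_center(features: FeatureTable, member_idx: np.ndarray) -> ClusterCenter:
    tnf = features.tnf[member_idx].mean(axis=0)
    s = tnf.sum()
    if s > 0:
        tnf = tnf / s
    return ClusterCenter(
        tnf=tnf,
        cov=features.cov[member_idx].mean(axis=0),
        length_proxy=int(np.median(features.lengths[member_idx])),
        kind="centroid",
    )


def _score_matrix(features: FeatureTable, centers: Sequence[ClusterCenter], model: ProbabilityModel) -> np.ndarray:
    """Log combined probability of every contig (rows) against every center (cols)."""
    return np.column_stack(
        [model.log_scores(features.tnf, features.cov, features.lengths, c) for c in centers]
    )


def kmeans_probability(
    features: FeatureTable,
    model: ProbabilityModel,
    k: int,
    init_seed_ids: Optional[Sequence[str]] = None,
    rng: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> tuple[np.ndarray, list[ClusterCenter], list[float]]:
    """Probability-model K-means.

    Assignment associates each contig with the center of highest combined
    probability (ties to the lowest center index); the update step replaces
    each center with its cluster centroid.  An emptied cluster is reseeded
    with the currently worst-assigned contig.  Returns the final labels,
    centers, and the total log-probability after each assignment step.
    """
    n = len(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of contigs ({n})")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if init_seed_ids is not None:
        if len(init_seed_ids) != k:
            raise ValueError("init_seeds length must equal k")
        centers = [_contig_center(features, features.index_of(cid)) for cid in init_seed_ids]
    else:
        idx = rng.choice(n, size=k, replace=False)
        centers = [_contig_center(features, int(i)) for i in np.sort(idx)]
    labels = np.full(n, -1, dtype=int)
    objective: list[float] = []
    for _ in range(max_iter):
        scores = _score_matrix(features, centers, model)
        new_labels = np.argmax(scores, axis=1)
        best = scores[np.arange(n), new_labels]
        # reseed empty clusters with the worst-assigned contigs
        for lab in range(k):
            if not np.any(new_labels == lab):
                worst = int(np.argmin(best))
                new_labels[worst] = lab
                best[worst] = np.inf  # not reused for another empty cluster
                centers[lab] = _contig_center(features, worst)
        objective.append(float(scores[np.arange(n), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centers = [_centroid_center(features, np.flatnonzero(labels == lab)) for lab in range(k)]
    return labels, centers, objective


def responsibilities(scores: np.ndarray) -> np.ndarray:
    """Per-contig posterior over centers (softmax of log combined scores)."""
    m = scores.max(axis=1, keepdims=True)
    w = np.exp(scores - m)
    return w / w.sum(axis=1, keepdims=True)


def filter_low_probability(
    features: FeatureTable,
    labels: np.ndarray,
    centers: Sequence[ClusterCenter],
    model: ProbabilityModel,
    prob_min: float,
    kind: str = "posterior",
) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Move weakly assigned contigs out of their clusters into the pool S1.

    ``kind='posterior'`` (default) thresholds the normalized assignment
    probability of the contig's center among all current centers, which is
    the scale on which an 80 % minimum is meaningful; ``kind='raw'``
    thresholds the raw combined probability itself.  Returns labels with
    -1 for removed contigs, the removed indices (S1), and the per-contig
    probability of the assigned center.
    """
    if kind not in ("posterior", "raw"):
        raise ValueError(f"unknown probability filter kind {kind!r}")
    scores = _score_matrix(features, centers, model)
    n = len(features)
    assigned = scores[np.arange(n), labels]
    if kind == "posterior":
        prob = responsibilities(scores)[np.arange(n), labels]
    else:
        prob = np.exp(assigned)
    keep = prob >= prob_min
    out_labels = np.where(keep, labels, -1)
    s1 = [int(i) for i in np.flatnonzero(~keep)]
    return out_labels, s1, prob


def accept_bins(
    clusters: dict[int, list[str]],
    hit_table: MarkerHitTable,
    catalog: MarkerSetCatalog,
    schedule: ThresholdSchedule,
) -> tuple[list[tuple[list[str], BinQuality]], list[str], bool]:
    """Extract clusters meeting the quality thresholds into Q.

    A bin is accepted iff precision >= precision_min and recall >= the
    current recall rung.  If nothing qualifies and a lower rung exists the
    rung advances and the clusters are re-evaluated; if nothing qualifies
    at the lowest rung the recursion is signalled to terminate.  Returns
    (accepted, S2 contig ids, terminated); ``schedule.current_rung`` is
    updated in place.
    """
    qualities = {
        lab: eval_bin_quality(ids, hit_table, catalog)
        for lab, ids in clusters.items()
        if ids
    }
    terminated = False
    while True:
        rung = schedule.recall_ladder[schedule.current_rung]
        accepted_labels = [
            lab
            for lab, q in qualities.items()
            if q.precision >= schedule.precision_min and q.recall >= rung
        ]
        if accepted_labels:
            break
        if schedule.current_rung + 1 < len(schedule.recall_ladder):
            schedule.current_rung += 1
            continue
        terminated = True
        break
    accepted = [(clusters[lab], qualities[lab]) for lab in sorted(accepted_labels)] if not terminated else []
    taken = {lab for lab in accepted_labels} if not terminated else set()
    s2 = [cid for lab, ids in sorted(clusters.items()) if lab not in taken for cid in ids]
    return accepted, s2, terminated


def kmedoids_probability(
    features: FeatureTable,
    model: ProbabilityModel,
    seed_ids: Sequence[str],
    max_iter: int = 50,
) -> tuple[np.ndarray, list[int], list[float]]:
    """Probability K-medoids over a contig pool.

    Assignment associates each contig with the medoid contig of highest
    combined probability; the update step swaps each medoid for the member
    minimizing the average dissimilarity -log P(member in medoid) within
    its cluster.  Returns labels, medoid indices, and the total
    dissimilarity after each step.
    """
    n = len(features)
    k = len(seed_ids)
    if k > n:
        logger.warning("k=%d clamped to pool size %d", k, n)
        seed_ids = seed_ids[:n]
        k = n
    if k < 1:
        raise ValueError("at least one medoid seed required")
    medoids = [features.index_of(cid) for cid in seed_ids]
    diss_cache: dict[int, np.ndarray] = {}

    def diss(m: int) -> np.ndarray:
        if m not in diss_cache:
            diss_cache[m] = -model.log_scores(features.tnf, features.cov, features.lengths, _contig_center(features, m))
        return diss_cache[m]

    labels = np.full(n, -1, dtype=int)
    criterion: list[float] = []
    for _ in range(max_iter):
        D = np.column_stack([diss(m) for m in medoids])
        labels = np.argmin(D, axis=1)
        for ci, m in enumerate(medoids):
            labels[m] = ci  # a medoid always belongs to its own cluster
        criterion.append(float(D[np.arange(n), labels].sum()))
        new_medoids = list(medoids)
        for ci in range(k):
            members = np.flatnonzero(labels == ci)
            if members.size == 0:
                continue
            costs = [float(diss(int(m))[members].mean()) for m in members]
            new_medoids[ci] = int(members[int(np.argmin(costs))])
        if new_medoids == medoids:
            break
        medoids = new_medoids
    D = np.column_stack([diss(m) for m in medoids])
    labels = np.argmin(D, axis=1)
    for ci, m in enumerate(medoids):
        labels[m] = ci
    criterion.append(float(D[np.arange(n), labels].sum()))
    return labels, medoids, criterion


def metacomplexity(gn: int, cn: int) -> tuple[int, str]:
    """Dataset complexity score: genome count + distinct circular elements.

    Bands: [0, 200] low, (200, 800] medium, (800, 1400] high, above 1400
    ultra-high.
    """
    if gn < 0 or cn < 0:
        raise ValueError("genome and circular-element counts must be nonnegative")
    score = int(gn) + int(cn)
    if score <= 200:
        band = "low"
    elif score <= 800:
        band = "medium"
    elif score <= 1400:
        band = "high"
    else:
        band = "ultra-high"
    return score, band


# ---------------------------------------------------------------------------
# The recursive pipeline
# ---------------------------------------------------------------------------

def _stage1(
    features: FeatureTable,
    model: ProbabilityModel,
    hit_table: MarkerHitTable,
    config: BinningConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[ClusterCenter], dict]:
    n = len(features)
    if config.k_override is not None:
        k = min(config.k_override, n)
        seeds = None
    else:
        sel = estimate_k_and_seeds(hit_table, config.k_strategy)
        k = min(sel.k, n)
        seeds = [cid for cid in sel.seed_contig_ids if cid in set(features.contig_ids)][:k]
        if len(seeds) != k:
            seeds = None  # fall back to random initialization
    labels, centers, _ = kmeans_probability(
        features, model, k, init_seed_ids=seeds, rng=rng, max_iter=config.max_iter_kmeans
    )
    info = {"k": k, "seeded": seeds is not None}
    return labels, centers, info


def run_recursive(
    contigs: ContigSet,
    depth_table: DepthTable,
    model: ProbabilityModel,
    hit_records: Sequence[MarkerHitRecord],
    catalog: MarkerSetCatalog,
    config: Optional[BinningConfig] = None,
) -> BinningResult:
    """Run the full two-stage recursive binning pipeline."""
    config = config or BinningConfig()
    rng = np.random.default_rng(config.rng_seed)
    filtered = filter_contigs(contigs, config.min_contig_length)
    features = build_features(filtered, depth_table.restrict_to(filtered.ids))
    full_table = build_hit_table(hit_records, catalog).restrict(filtered.ids)
    schedule = config.schedule()

    labels, centers, stage1_info = _stage1(features, model, full_table, config, rng)
    work = features
    trace: list[dict] = []
    accepted: list[AcceptedBin] = []
    probs: dict[str, float] = {}
    residual: list[str] = []

    for round_no in range(1, config.max_rounds + 1):
        out_labels, s1_idx, prob = filter_low_probability(
            work, labels, centers, model, config.prob_min, config.prob_filter_kind
        )
        for i, cid in enumerate(work.contig_ids):
            probs[cid] = float(prob[i])
        clusters = {
            int(lab): [work.contig_ids[i] for i in np.flatnonzero(out_labels == lab)]
            for lab in np.unique(out_labels)
            if lab >= 0
        }
        s1_ids = [work.contig_ids[i] for i in s1_idx]
        new_bins, s2_ids, terminated = accept_bins(clusters, full_table, catalog, schedule)
        for ids, quality in new_bins:
            accepted.append(
                AcceptedBin(f"bin.{len(accepted) + 1}", list(ids), quality, round_no)
            )
        pool = sorted(set(s1_ids) | set(s2_ids))
        trace.append(
            {
                "round": round_no,
                "k": len(centers),
                "n_clusters": len(clusters),
                "accepted": len(new_bins),
                "rung": schedule.current_rung,
                "recall_threshold": schedule.recall_ladder[schedule.current_rung],
                "pool_size": len(pool),
            }
        )
        logger.info(
            "round %d: k=%d accepted=%d rung=%.2f pool=%d",
            round_no, len(centers), len(new_bins),
            schedule.recall_ladder[schedule.current_rung], len(pool),
        )
        if terminated or not pool or round_no == config.max_rounds:
            residual = pool
            break
        # re-cluster the pool S with marker-seeded K-medoids
        work = features.subset(pool)
        sub_table = full_table.restrict(pool)
        try:
            sel = estimate_k_and_seeds(sub_table, config.k_strategy)
            seed_ids = sel.seed_contig_ids[: min(sel.k, len(pool))]
        except ValueError:
            k2 = min(config.k_fallback, len(pool))
            idx = np.sort(rng.choice(len(pool), size=k2, replace=False))
            seed_ids = [pool[int(i)] for i in idx]
        labels, medoids, _ = kmedoids_probability(
            work, model, seed_ids, max_iter=config.max_iter_kmedoids
        )
        centers = [_contig_center(work, m) for m in medoids]

    return BinningResult(
        accepted_bins=accepted,
        residual_ids=residual,
        trace=trace,
        seed=config.rng_seed,
        assignment_probabilities=probs,
        thresholds={
            "min_contig_length": config.min_contig_length,
            "prob_min": config.prob_min,
            "precision_min": config.precision_min,
            "recall_ladder": list(config.recall_ladder),
            "stage1": stage1_info,
        },
    )


def run_single_pass(
    contigs: ContigSet,
    depth_table: DepthTable,
    model: ProbabilityModel,
    hit_records: Sequence[MarkerHitRecord],
    catalog: MarkerSetCatalog,
    config: Optional[BinningConfig] = None,
) -> BinningResult:
    """Stage-1 K-means followed by a single filter/accept pass (no recursion).

    Baseline for measuring the benefit of the recursive strategy under
    identical thresholds.
    """
    config = config or BinningConfig()
    single = BinningConfig(**{**config.__dict__, "max_rounds": 1})
    return run_recursive(contigs, depth_table, model, hit_records, catalog, single)
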