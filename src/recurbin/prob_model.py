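"""The same-genome probability model.

Two contigs from one genome tend to have (a) similar tetranucleotide
frequencies and (b) correlated read depths across samples.  The model
combines both signals into a single probability that a contig S belongs
to a cluster centered at G:

* composition: the posterior P(same genome | D) for the Euclidean TNF
  distance D, derived empirically by sampling intra- and inter-genome
  fragment pairs, with the prior odds of "different genome" fixed at 10:1.
  For speed the posterior is approximated per contig-length-bin pair by a
  logistic curve 1 / (1 + exp(-(b + c * D))) with c < 0 (probability
  decreases with distance).
* coverage: under shotgun sequencing (Lander-Waterman), read depth is
  Poisson; the likelihood of the contig's depth in each sample given the
  center's depth as the Poisson mean, multiplied over samples (independent
  libraries).  Depths are fractional, so the continuous extension
  exp(x*ln(lam) - lam - lnGamma(x+1)) is used.

The product of the two factors is the sole score used by both clustering
stages.  All arithmetic is in log space with a global probability floor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.linear_model import LogisticRegression

from .features import tnf

logger = logging.getLogger(__name__)

#: Lower edges of the contig-length bins used for the logistic parameters;
#: the last bin is unbounded above.  Geometric spacing covers the typical
#: contig-length distribution of short-read assemblies.
DEFAULT_LENGTH_BIN_EDGES: tuple[int, ...] = (1500, 3000, 6000, 12000, 24000, 48000, 96000)

DEFAULT_PRIOR_RATIO = 10.0   # P(different) / P(same), as stated by the model
DEFAULT_LAMBDA_FLOOR = 0.01  # Poisson mean floor for zero-coverage centers
DEFAULT_EPS_LOG = 1e-300     # global probability floor
_PARAM_CLIP = 50.0           # |b + c*d| bound for separable logistic fits

MODEL_SCHEMA_VERSION = 1


def length_bin_of(lengths, edges: Sequence[int]) -> np.ndarray:
    """Index of the length bin for each length; below the first edge clamps to bin 0."""
    idx = np.searchsorted(np.asarray(edges), np.asarray(lengths), side="right") - 1
    return np.clip(idx, 0, len(edges) - 1)


# ---------------------------------------------------------------------------
# Empirical distance priors and the Bayesian posterior
# ---------------------------------------------------------------------------

@dataclass
class DistancePrior:
    """Histogram densities of TNF distance for same- and different-genome pairs."""

    grid: np.ndarray          # bin edges, length nbins+1
    density_same: np.ndarray  # length nbins, integrates to 1
    density_diff: np.ndarray
    n_pairs: int
    length_bin_pair: tuple[int, int]

    def _interp(self, density: np.ndarray, d: float) -> float:
        centers = 0.5 * (self.grid[:-1] + self.grid[1:])
        return float(np.interp(d, centers, density, left=0.0, right=0.0))

    def density_at(self, d: float) -> tuple[float, float]:
        return self._interp(self.density_same, d), self._interp(self.density_diff, d)


def _draw_fragment(genome: str, length: int, rng: np.random.Generator) -> str:
    start = int(rng.integers(0, len(genome) - length + 1))
    return genome[start : start + length]


def _fragment_length(lo: int, hi: int, cap: int, rng: np.random.Generator) -> int:
    hi = min(hi, cap)
    lo = min(lo, hi)
    return int(rng.integers(lo, hi + 1))


def _bin_bounds(bin_idx: int, edges: Sequence[int]) -> tuple[int, int]:
    lo = edges[bin_idx]
    hi = edges[bin_idx + 1] - 1 if bin_idx + 1 < len(edges) else 2 * edges[-1]
    return lo, hi


def sample_distance_priors(
    genomes: Sequence[str],
    n_pairs: int,
    length_bin_pair: tuple[int, int] = (0, 0),
    rng_seed: int | np.random.Generator = 0,
    edges: Sequence[int] = DEFAULT_LENGTH_BIN_EDGES,
    n_grid: int = 60,
) -> DistancePrior:
    """Empirical TNF-distance densities from intra- vs inter-genome fragment pairs.

    Fragment lengths are drawn uniformly within each bin of the requested
    length-bin pair.  Genomes shorter than twice the maximum fragment
    length are excluded (they cannot yield two disjoint-ish fragments).
    """
    if n_pairs < 1000:
        raise ValueError("n_pairs must be >= 1000 for stable densities")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    lo_i, hi_i = _bin_bounds(length_bin_pair[0], edges)
    lo_j, hi_j = _bin_bounds(length_bin_pair[1], edges)
    usable = [g for g in genomes if len(g) // 2 >= max(lo_i, lo_j)]
    if len(usable) < len(genomes):
        logger.warning("%d genomes too short for length-bin pair %s; excluded", len(genomes) - len(usable), length_bin_pair)
    if len(usable) < 2:
        raise ValueError("fewer than two genomes long enough for the requested length bins")
    cap = min(len(g) for g in usable) // 2
    d_same = np.empty(n_pairs)
    d_diff = np.empty(n_pairs)
    for t in range(n_pairs):
        li = _fragment_length(lo_i, hi_i, cap, rng)
        lj = _fragment_length(lo_j, hi_j, cap, rng)
        g = usable[int(rng.integers(len(usable)))]
        v1, _ = tnf(_draw_fragment(g, li, rng))
        v2, _ = tnf(_draw_fragment(g, lj, rng))
        d_same[t] = np.linalg.norm(v1 - v2)
        ga, gb = rng.choice(len(usable), size=2, replace=False)
        v1, _ = tnf(_draw_fragment(usable[ga], li, rng))
        v2, _ = tnf(_draw_fragment(usable[gb], lj, rng))
        d_diff[t] = np.linalg.norm(v1 - v2)
    hi_edge = max(d_same.max(), d_diff.max()) * 1.05 + 1e-12
    grid = np.linspace(0.0, hi_edge, n_grid + 1)
    dens_same, _ = np.histogram(d_same, bins=grid, density=True)
    dens_diff, _ = np.histogram(d_diff, bins=grid, density=True)
    return DistancePrior(grid, dens_same, dens_diff, n_pairs, tuple(length_bin_pair))


def posterior_same_genome(d: float, prior: DistancePrior, prior_ratio: float = DEFAULT_PRIOR_RATIO) -> float:
    """Bayesian posterior that two contigs at TNF distance ``d`` share a genome.

    P(R|D) = P(R)P(D|R) / (P(R)P(D|R) + P(T)P(D|T)) with
    P(T)/P(R) = ``prior_ratio``.  Returns 0 (conservative) where both
    empirical densities vanish.
    """
    if d < 0:
        raise ValueError("distance must be nonnegative")
    p_same, p_diff = prior.density_at(d)
    denom = p_same + prior_ratio * p_diff
    if denom <= 0.0:
        logger.warning("both prior densities vanish at d=%.4g; returning 0", d)
        return 0.0
    return p_same / denom


# ---------------------------------------------------------------------------
# Logistic approximation per length-bin pair
# ---------------------------------------------------------------------------

@dataclass
class LogisticParams:
    """Per length-bin-pair parameters of the logistic distance posterior."""

    length_bins: tuple[int, ...]
    b: np.ndarray  # (B, B) intercepts, symmetric
    c: np.ndarray  # (B, B) slopes, symmetric, negative where fitted
    fitted: np.ndarray = field(default=None)  # bool (B, B): True if fit from own data

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.fitted is None:
            self.fitted = np.ones_like(self.b, dtype=bool)
        if not (np.isfinite(self.b).all() and np.isfinite(self.c).all()):
            raise ValueError("logistic parameters must be finite")
        if np.any(self.c >= 0):
            raise ValueError("logistic slope c must be negative in every cell")
        if not (np.allclose(self.b, self.b.T) and np.allclose(self.c, self.c.T)):
            raise ValueError("logistic parameter matrices must be symmetric")


def fit_logistic(
    training_pairs: Sequence[tuple[float, bool, int, int]],
    length_bins: Sequence[int] = DEFAULT_LENGTH_BIN_EDGES,
) -> LogisticParams:
    """Maximum-likelihood logistic fit of same-genome label on TNF distance,
    one (b, c) pair per contig-length-bin pair.

    ``training_pairs`` are (distance, same_genome, len_i, len_j) tuples.
    A cell with fewer than 50 positives or 50 negatives borrows the
    parameters of the nearest covered cell (flagged in ``fitted``).
    Perfectly separable cells are clipped so |b + c*d| <= 50 over the
    observed distance range.
    """
    B = len(length_bins)
    arr = np.array([(d, 1.0 if s else 0.0, li, lj) for d, s, li, lj in training_pairs], dtype=float)
    if arr.size == 0:
        raise ValueError("no training pairs supplied")
    bins_i = length_bin_of(arr[:, 2], length_bins)
    bins_j = length_bin_of(arr[:, 3], length_bins)
    lo = np.minimum(bins_i, bins_j)
    hi = np.maximum(bins_i, bins_j)
    b = np.full((B, B), np.nan)
    c = np.full((B, B), np.nan)
    fitted = np.zeros((B, B), dtype=bool)
    for i in range(B):
        for j in range(i, B):
            mask = (lo == i) & (hi == j)
            y = arr[mask, 1]
            if mask.sum() < 100 or y.sum() < 50 or (len(y) - y.sum()) < 50:
                continue
            d = arr[mask, 0]
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
            clf.fit(d.reshape(-1, 1), y)
            bij = float(clf.intercept_[0])
            cij = float(clf.coef_[0, 0])
            if cij >= 0:
                logger.warning("non-decreasing logistic in cell (%d,%d); forcing small negative slope", i, j)
                cij = -1e-6
            # clip separable fits so |b + c*d| stays bounded on the data range
            d_lo, d_hi = float(d.min()), float(d.max())
            worst = max(abs(bij + cij * d_lo), abs(bij + cij * d_hi))
            if worst > _PARAM_CLIP:
                scale = _PARAM_CLIP / worst
                bij *= scale
                cij *= scale
                logger.warning("separable logistic cell (%d,%d) clipped", i, j)
            b[i, j] = b[j, i] = bij
            c[i, j] = c[j, i] = cij
            fitted[i, j] = fitted[j, i] = True
    if not fitted.any():
        raise ValueError("no length-bin cell had enough labeled pairs (need >=50 of each class)")
    # borrow nearest covered cell for under-covered cells
    covered = np.argwhere(fitted)
    for i in range(B):
        for j in range(B):
            if fitted[i, j]:
                continue
            dists = np.abs(covered[:, 0] - i) + np.abs(covered[:, 1] - j)
            ci, cj = covered[int(np.argmin(dists))]
            b[i, j] = b[ci, cj]
            c[i, j] = c[ci, cj]
    b = 0.5 * (b + b.T)
    c = 0.5 * (c + c.T)
    return LogisticParams(tuple(int(e) for e in length_bins), b, c, fitted)


# ---------------------------------------------------------------------------
# The combined scorer
# ---------------------------------------------------------------------------

@dataclass
class ProbabilityModel:
    """Combined composition + coverage same-genome scorer."""

    logistic: LogisticParams
    prior_ratio: float = DEFAULT_PRIOR_RATIO
    eps_log: float = DEFAULT_EPS_LOG
    lambda_floor: float = DEFAULT_LAMBDA_FLOOR
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior_ratio <= 0:
            raise ValueError("prior_ratio must be positive")
        if not (0 < self.eps_log <= 1e-10):
            raise ValueError("eps_log must be in (0, 1e-10]")

    # -- composition factor -------------------------------------------------
    def logistic_params_for(self, len_i, len_j) -> tuple[np.ndarray, np.ndarray]:
        bi = length_bin_of(len_i, self.logistic.length_bins)
        bj = length_bin_of(len_j, self.logistic.length_bins)
        return self.logistic.b[bi, bj], self.logistic.c[bi, bj]

    def log_p_dist(self, d, len_i, len_j) -> np.ndarray:
        b, c = self.logistic_params_for(len_i, len_j)
        z = b + c * np.asarray(d, dtype=float)
        return -np.logaddexp(0.0, -z)

    def p_dist(self, d, len_i, len_j):
        """Logistic approximation of the same-genome posterior at TNF distance d."""
        return np.exp(self.log_p_dist(d, len_i, len_j))

    # -- coverage factor ----------------------------------------------------
    def log_p_cov_single(self, cov_s, cov_g) -> np.ndarray:
        """Log continuous-Poisson density of the contig depth given the center depth."""
        x = np.asarray(cov_s, dtype=float)
        lam = np.maximum(np.asarray(cov_g, dtype=float), self.lambda_floor)
        if np.any(x < 0):
            raise ValueError("coverage must be nonnegative")
        return x * np.log(lam) - lam - gammaln(x + 1.0)

    def p_cov_single(self, cov_s: float, cov_g: float) -> float:
        return float(np.exp(self.log_p_cov_single(cov_s, cov_g)))

    def log_p_cov(self, cov_s_vector, cov_g_vector) -> float:
        x = np.atleast_1d(np.asarray(cov_s_vector, dtype=float))
        g = np.atleast_1d(np.asarray(cov_g_vector, dtype=float))
        if x.shape != g.shape:
            raise ValueError("coverage vectors must have the same number of samples")
        lp = float(self.log_p_cov_single(x, g).sum())
        return max(lp, np.log(self.eps_log))

    def p_cov(self, cov_s_vector, cov_g_vector) -> float:
        """Product over samples of the per-sample Poisson factor (log-space, floored)."""
        return float(np.exp(self.log_p_cov(cov_s_vector, cov_g_vector)))

    # -- combined -----------------------------------------------------------
    def log_p_combined(self, tnf_s, cov_s, len_s, center) -> float:
        d = float(np.linalg.norm(np.asarray(tnf_s) - np.asarray(center.tnf)))
        lp = float(self.log_p_dist(d, len_s, center.length_proxy)) + self.log_p_cov(cov_s, center.cov)
        return float(np.clip(lp, np.log(self.eps_log), 0.0))

    def p_combined(self, tnf_s, cov_s, len_s, center) -> float:
        """P(S in G) = composition posterior x coverage likelihood product."""
        return float(np.exp(self.log_p_combined(tnf_s, cov_s, len_s, center)))

    def log_scores(self, tnf_matrix: np.ndarray, cov_matrix: np.ndarray, lengths: np.ndarray, center) -> np.ndarray:
        """Vectorized log p_combined of every contig row against one center."""
        d = np.linalg.norm(tnf_matrix - center.tnf[None, :], axis=1)
        lp_dist = self.log_p_dist(d, lengths, np.full(len(lengths), center.length_proxy))
        lam = np.maximum(np.asarray(center.cov, dtype=float), self.lambda_floor)
        lp_cov = (cov_matrix * np.log(lam)[None, :] - lam[None, :] - gammaln(cov_matrix + 1.0)).sum(axis=1)
        return np.clip(lp_dist + lp_cov, np.log(self.eps_log), 0.0)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: ProbabilityModel, path: str | Path) -> None:
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "length_bins": list(model.logistic.length_bins),
        "b": model.logistic.b.tolist(),
        "c": model.logistic.c.tolist(),
        "fitted": model.logistic.fitted.astype(int).tolist(),
        "prior_ratio": model.prior_ratio,
        "eps_log": model.eps_log,
        "lambda_floor": model.lambda_floor,
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path: str | Path) -> ProbabilityModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {payload.get('version')!r}")
    logistic = LogisticParams(
        tuple(payload["length_bins"]),
        np.array(payload["b"], dtype=float),
        np.array(payload["c"], dtype=float),
        np.array(payload["fitted"], dtype=bool),
    )
    return ProbabilityModel(
        logistic,
        prior_ratio=float(payload["prior_ratio"]),
        eps_log=float(payload["eps_log"]),
        lambda_floor=float(payload.get("lambda_floor", DEFAULT_LAMBDA_FLOOR)),
        training_meta=payload.get("training_meta", {}),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def sample_training_pairs(
    genomes: Sequence[str],
    n_pairs_per_cell: int,
    length_bins: Sequence[int] = DEFAULT_LENGTH_BIN_EDGES,
    prior_ratio: float = DEFAULT_PRIOR_RATIO,
    rng_seed: int | np.random.Generator = 0,
) -> list[tuple[float, bool, int, int]]:
    """Labeled (distance, same_genome, len_i, len_j) tuples for the logistic fit.

    Class balance encodes the prior: same-genome pairs are drawn with
    probability 1/(1+prior_ratio), so the fitted logistic approximates the
    Bayesian posterior under the stated prior odds rather than a
    balanced-class posterior.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if len(genomes) < 2:
        raise ValueError("need at least two training genomes")
    cap = min(len(g) for g in genomes) // 2
    p_same = 1.0 / (1.0 + prior_ratio)
    pairs: list[tuple[float, bool, int, int]] = []
    B = len(length_bins)
    for i in range(B):
        if length_bins[i] > cap:
            break
        for j in range(i, B):
            if length_bins[j] > cap:
                break
            lo_i, hi_i = _bin_bounds(i, length_bins)
            lo_j, hi_j = _bin_bounds(j, length_bins)
            for _ in range(n_pairs_per_cell):
                li = _fragment_length(lo_i, hi_i, cap, rng)
                lj = _fragment_length(lo_j, hi_j, cap, rng)
                same = bool(rng.random() < p_same)
                if same:
                    g = genomes[int(rng.integers(len(genomes)))]
                    s1 = _draw_fragment(g, li, rng)
                    s2 = _draw_fragment(g, lj, rng)
                else:
                    ga, gb = rng.choice(len(genomes), size=2, replace=False)
                    s1 = _draw_fragment(genomes[ga], li, rng)
                    s2 = _draw_fragment(genomes[gb], lj, rng)
                v1, _ = tnf(s1)
                v2, _ = tnf(s2)
                pairs.append((float(np.linalg.norm(v1 - v2)), same, li, lj))
    return pairs


def train_model(
    genomes: Sequence[str],
    n_pairs_per_cell: int = 1200,
    length_bins: Sequence[int] = DEFAULT_LENGTH_BIN_EDGES,
    prior_ratio: float = DEFAULT_PRIOR_RATIO,
    rng_seed: int = 0,
    training_meta: Optional[dict] = None,
) -> ProbabilityModel:
    """Train the combined model on a set of reference genome sequences."""
    rng = np.random.default_rng(rng_seed)
    pairs = sample_training_pairs(genomes, n_pairs_per_cell, length_bins, prior_ratio, rng)
    logistic = fit_logistic(pairs, length_bins)
    meta = {"n_genomes": len(genomes), "n_pairs_per_cell": n_pairs_per_cell, "rng_seed": rng_seed}
    meta.update(training_meta or {})
    return ProbabilityModel(logistic, prior_ratio=prior_ratio, training_meta=meta)
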