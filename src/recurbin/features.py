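"""Sequence-composition and coverage features.

Every contig is represented by (a) its tetranucleotide frequency (TNF)
vector — normalized counts of overlapping 4-mers, folded by reverse
complement so the representation is strand-independent (136 canonical
4-mers = 120 complement pairs + 16 palindromes) — and (b) its vector of
per-sample mean read depths.  These two matrices feed the probability
model and the clustering stages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import ContigSet, DepthTable

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# char -> 2-bit code; N (and anything else) -> 4 marks an invalid position
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

N_CANONICAL = 136


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer_index() -> list[str]:
    """The 136 canonical 4-mers, lexicographically ordered.

    The canonical representative of a 4-mer is the lexicographic minimum of
    the 4-mer and its reverse complement.
    """
    reps = {min(k, reverse_complement(k)) for k in ("".join(p) for p in itertools.product(_BASES, repeat=4))}
    return sorted(reps)


def _build_fold_map() -> np.ndarray:
    """Map each of the 256 4-mer codes to its canonical slot in 0..135."""
    index = {k: i for i, k in enumerate(canonical_kmer_index())}
    fold = np.empty(256, dtype=np.int64)
    for code in range(256):
        kmer = "".join(_BASES[(code >> (2 * (3 - j))) & 3] for j in range(4))
        fold[code] = index[min(kmer, reverse_complement(kmer))]
    return fold


_FOLD = _build_fold_map()
_UNIFORM_ROW = np.full(N_CANONICAL, 1.0 / N_CANONICAL)


def tnf(sequence: str) -> tuple[np.ndarray, bool]:
    """Canonical tetranucleotide frequency vector of a sequence.

    Overlapping 4-mers (stride 1); windows containing N are skipped.
    Returns ``(vector, valid)``; a sequence with no valid 4-mer gets the
    uniform fallback row and ``valid=False``.
    """
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return _UNIFORM_ROW.copy(), False
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    if not valid.any():
        return _UNIFORM_ROW.copy(), False
    kcodes = ((c0 * 4 + c1) * 4 + c2) * 4 + c3
    counts256 = np.bincount(kcodes[valid], minlength=256).astype(float)
    counts = np.zeros(N_CANONICAL)
    np.add.at(counts, _FOLD, counts256)
    return counts / counts.sum(), True


@dataclass
class CompositionMatrix:
    """Per-contig canonical TNF rows (n x 136); invalid rows are uniform and flagged."""

    contig_ids: list[str]
    tnf: np.ndarray
    valid: np.ndarray  # bool per row
    kmer_index: list[str]


@dataclass
class CoverageMatrix:
    contig_ids: list[str]
    cov: np.ndarray  # (n, M) nonnegative
    sample_names: list[str]
    normalized: bool = False


def composition_matrix(contigs: ContigSet) -> CompositionMatrix:
    rows = np.empty((len(contigs), N_CANONICAL))
    valid = np.empty(len(contigs), dtype=bool)
    for i, rec in enumerate(contigs):
        rows[i], valid[i] = tnf(rec.sequence)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d contigs had no valid 4-mer; uniform TNF fallback used", n_bad)
    return CompositionMatrix(contigs.ids, rows, valid, canonical_kmer_index())


def normalize_coverage(depth_table: DepthTable, mode: str = "none") -> CoverageMatrix:
    """Optionally rescale depth columns to a common library size.

    ``none`` passes depths through unchanged (the default: per-base mean
    depth is already length-normalized).  ``per_sample_scale`` divides each
    sample column by its mean over contigs so column means become 1,
    restoring comparability across libraries of different size.  The
    Poisson coverage model always consumes raw depths; the normalized
    matrix only affects distance/centroid geometry when requested.
    """
    if mode not in ("none", "per_sample_scale"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    cov = depth_table.depth.copy()
    if mode == "per_sample_scale":
        means = cov.mean(axis=0)
        for j, m in enumerate(means):
            if m > 0:
                cov[:, j] /= m
            else:
                logger.warning("sample %s has zero mean depth; column left unscaled", depth_table.sample_names[j])
    return CoverageMatrix(list(depth_table.contig_ids), cov, list(depth_table.sample_names), mode != "none")


def euclidean_distance(tnf_i: np.ndarray, tnf_j: np.ndarray) -> float:
    """Euclidean distance between two TNF vectors."""
    a = np.asarray(tnf_i, dtype=float)
    b = np.asarray(tnf_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("TNF vectors must have equal length")
    return float(np.linalg.norm(a - b))


@dataclass
class FeatureTable:
    """Bundled per-contig features consumed by the clustering engine.

    ``cov`` holds raw mean depths (the Poisson model's scale); ``lengths``
    drive the length-bin lookup of the composition posterior.
    """

    contig_ids: list[str]
    tnf: np.ndarray       # (n, 136)
    cov: np.ndarray       # (n, M) raw depths
    lengths: np.ndarray   # (n,)
    sample_names: list[str]

    def __post_init__(self) -> None:
        self._index = {cid: i for i, cid in enumerate(self.contig_ids)}

    def __len__(self) -> int:
        return len(self.contig_ids)

    def index_of(self, contig_id: str) -> int:
        return self._index[contig_id]

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        rows = [self._index[i] for i in ids]
        return FeatureTable(list(ids), self.tnf[rows], self.cov[rows], self.lengths[rows], list(self.sample_names))


def build_features(contigs: ContigSet, depth_table: DepthTable) -> FeatureTable:
    """Compute the TNF matrix and align raw depths to the contig order."""
    comp = composition_matrix(contigs)
    depth = depth_table.restrict_to(contigs.ids)
    return FeatureTable(contigs.ids, comp.tnf, depth.depth, contigs.lengths, list(depth.sample_names))
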