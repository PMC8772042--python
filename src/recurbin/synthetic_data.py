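"""Synthetic metagenomic communities with planted ground truth.

The generator produces data with exactly the statistical structure the
binning model assumes: each genome is an order-0 Markov nucleotide
sequence with its own base composition (so genomes differ in 4-mer
signature by a tunable amount), genomes are fragmented into contigs with
truncated-exponential lengths, per-contig per-sample depths are Poisson
draws around a per-genome per-sample mean abundance (read depth under
shotgun sequencing is Poisson), and every genome carries exactly one copy
of each catalog marker gene, placed on a uniformly chosen contig.
Optionally a fraction of contigs are chimeras spliced from two genomes.

Everything is deterministic under the spec's ``rng_seed``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    ContigRecord,
    ContigSet,
    DepthTable,
    MarkerHitRecord,
    write_depth_table,
    write_fasta,
    write_marker_hits,
)
from .marker_quality import MarkerSetCatalog

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Dirichlet concentration scale for genome base compositions at maximal
#: divergence; larger values make genomes compositionally more alike.
_CONCENTRATION_SCALE = 20.0


@dataclass
class SyntheticCommunitySpec:
    """Parameters of a planted community.

    Defaults describe a well-separated multi-sample community: 10 genomes
    of 100 kb, 3 independently sequenced samples with log-normal mean
    depths (median ~20x), contigs with truncated-exponential lengths of
    minimum 2.5 kb, and strongly distinct genome signatures.
    """

    n_genomes: int = 10
    genome_length: int = 100_000
    n_samples: int = 3
    depth_lognorm_mu: float = math.log(20.0)
    depth_lognorm_sigma: float = 0.7
    contig_min_length: int = 2500
    contig_length_scale: float = 5000.0  # exponential scale above the minimum
    contig_overlap: int = 0
    signature_divergence: float = 0.9
    chimera_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.n_samples < 1 or self.genome_length < 1:
            raise ValueError("counts and lengths must be >= 1")
        if not (0.0 <= self.chimera_rate < 1.0):
            raise ValueError("chimera_rate must lie in [0, 1)")
        if not (0.0 <= self.signature_divergence <= 1.0):
            raise ValueError("signature_divergence must lie in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground-truth labels for every emitted contig."""

    genome_of: dict[str, str]                      # contig_id -> genome_id
    chimera_parents: dict[str, tuple[str, str]] = field(default_factory=dict)
    marker_placements: list[tuple[str, str, str]] = field(default_factory=list)  # (genome, marker, contig)

    def is_chimera(self, contig_id: str) -> bool:
        return contig_id in self.chimera_parents

    def labels_for(self, contig_ids: Sequence[str]) -> list[str]:
        return [self.genome_of[cid] for cid in contig_ids]


def generate_genomes(spec: SyntheticCommunitySpec, rng: Optional[np.random.Generator] = None) -> list[str]:
    """Order-0 Markov genomes with compositions drawn around uniform.

    The Dirichlet concentration is inversely related to
    ``signature_divergence``: at 0 every genome shares the uniform
    composition; near 1 compositions scatter widely, so pairwise TNF
    distances grow with divergence.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    genomes = []
    for _ in range(spec.n_genomes):
        d = spec.signature_divergence
        if d <= 0.0:
            comp = np.full(4, 0.25)
        else:
            conc = _CONCENTRATION_SCALE * (1.0 - d) / d
            alpha = np.full(4, max(conc * 0.25, 0.05))
            comp = rng.dirichlet(alpha)
        idx = rng.choice(4, size=spec.genome_length, p=comp)
        genomes.append("".join(_BASES[idx]))
    return genomes


def _cut_points(total: int, spec: SyntheticCommunitySpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    """(start, length) pairs of truncated-exponential cuts covering one genome.

    Consecutive cuts overlap by ``contig_overlap`` bases; the tail is
    absorbed into the last cut so no emitted contig is shorter than the
    minimum.
    """
    cuts: list[tuple[int, int]] = []
    pos = 0
    while total - pos >= spec.contig_min_length:
        ell = spec.contig_min_length + int(rng.exponential(spec.contig_length_scale))
        ell = min(ell, total - pos)
        if total - pos - ell < spec.contig_min_length:
            ell = total - pos
        cuts.append((pos, ell))
        if pos + ell >= total:
            break
        pos += ell - spec.contig_overlap
    return cuts


def fragment_and_cover(
    genomes: Sequence[str],
    spec: SyntheticCommunitySpec,
    rng: Optional[np.random.Generator] = None,
    abundance: Optional[np.ndarray] = None,
) -> tuple[ContigSet, DepthTable, PlantedTruth]:
    """Fragment genomes into contigs and draw per-sample observed depths.

    ``abundance`` (n_genomes x n_samples mean depths) overrides the
    log-normal draws, e.g. for two-scale abundant/rare mixtures.  The
    observed depth of a contig of length L with planted mean lam is
    Poisson(lam * L) / L, i.e. the mean per-base depth implied by a
    Poisson read count.  A chimeric contig takes its second half from a
    different genome and mixes the parents' abundances half-and-half.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    n_g = len(genomes)
    if abundance is None:
        abundance = rng.lognormal(spec.depth_lognorm_mu, spec.depth_lognorm_sigma, size=(n_g, spec.n_samples))
    abundance = np.asarray(abundance, dtype=float)
    if abundance.shape != (n_g, spec.n_samples):
        raise ValueError("abundance must have shape (n_genomes, n_samples)")
    records: list[ContigRecord] = []
    depths: list[np.ndarray] = []
    truth = PlantedTruth(genome_of={})
    for g, genome in enumerate(genomes):
        gid = f"g{g}"
        for j, (pos, ell) in enumerate(_cut_points(len(genome), spec, rng)):
            cid = f"{gid}_c{j}"
            seq = genome[pos : pos + ell]
            lam = abundance[g]
            if spec.chimera_rate > 0 and n_g > 1 and rng.random() < spec.chimera_rate:
                other = int(rng.integers(n_g - 1))
                other = other + 1 if other >= g else other
                half = ell // 2
                start = int(rng.integers(0, len(genomes[other]) - (ell - half) + 1))
                seq = seq[:half] + genomes[other][start : start + (ell - half)]
                lam = 0.5 * (abundance[g] + abundance[other])
                truth.chimera_parents[cid] = (gid, f"g{other}")
            obs = rng.poisson(lam * ell) / ell
            records.append(ContigRecord(cid, seq))
            depths.append(obs)
            truth.genome_of[cid] = gid
    contigs = ContigSet(records)
    table = DepthTable(contigs.ids, [f"s{k}" for k in range(spec.n_samples)], np.vstack(depths))
    return contigs, table, truth


def plant_markers(
    contigs: ContigSet,
    truth: PlantedTruth,
    catalog: MarkerSetCatalog,
    rng: Optional[np.random.Generator] = None,
    rng_seed: int = 0,
) -> list[MarkerHitRecord]:
    """Place exactly one copy of every catalog marker on each genome.

    Each marker lands on a uniformly chosen contig of its genome; a
    chimeric contig is eligible for markers of either parent.  Markers are
    bookkeeping hit records only — contig nucleotides are not altered.
    """
    rng = rng or np.random.default_rng(rng_seed)
    pools: dict[str, list[str]] = {}
    for cid in contigs.ids:
        pools.setdefault(truth.genome_of[cid], []).append(cid)
        if truth.is_chimera(cid):
            other = truth.chimera_parents[cid][1]
            pools.setdefault(other, []).append(cid)
    records: list[MarkerHitRecord] = []
    for gid in sorted(set(truth.genome_of.values())):
        pool = pools.get(gid)
        if not pool:
            raise ValueError(f"genome {gid} produced no contigs; cannot plant markers")
        for marker in catalog.all_markers:
            cid = pool[int(rng.integers(len(pool)))]
            records.append(MarkerHitRecord(cid, marker))
            truth.marker_placements.append((gid, marker, cid))
    return records


@dataclass
class Community:
    """A fully generated fixture: contigs, depths, marker hits, and truth."""

    spec: SyntheticCommunitySpec
    contigs: ContigSet
    depth: DepthTable
    truth: PlantedTruth
    hits: list[MarkerHitRecord]
    catalog: MarkerSetCatalog


def default_catalog() -> MarkerSetCatalog:
    """The packaged synthetic single-copy marker catalog."""
    path = Path(__file__).parent / "data" / "synthetic_marker_catalog.json"
    return MarkerSetCatalog.from_json(path)


def generate_community(
    spec: SyntheticCommunitySpec,
    catalog: Optional[MarkerSetCatalog] = None,
    abundance: Optional[np.ndarray] = None,
) -> Community:
    """Generate genomes, contigs, depths and planted markers in one call."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(spec.rng_seed)
    genomes = generate_genomes(spec, rng)
    contigs, depth, truth = fragment_and_cover(genomes, spec, rng, abundance=abundance)
    hits = plant_markers(contigs, truth, catalog, rng)
    return Community(spec, contigs, depth, truth, hits, catalog)


def two_scale_abundance(
    n_abundant: int,
    n_rare: int,
    n_samples: int,
    rng: np.random.Generator,
    mu_high: float = math.log(40.0),
    mu_low: float = math.log(4.0),
    sigma: float = 0.5,
) -> np.ndarray:
    """Mean-depth matrix for a mixture of abundant and rare genomes."""
    high = rng.lognormal(mu_high, sigma, size=(n_abundant, n_samples))
    low = rng.lognormal(mu_low, sigma, size=(n_rare, n_samples))
    return np.vstack([high, low])


def write_fixture(community: Community, outdir: str | Path) -> dict:
    """Emit a complete on-disk fixture directory.

    Writes contigs.fa, depth.tsv (plain layout), markers.tsv, truth.tsv
    and spec.json; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": outdir / "contigs.fa",
        "depth": outdir / "depth.tsv",
        "markers": outdir / "markers.tsv",
        "truth": outdir / "truth.tsv",
        "spec": outdir / "spec.json",
    }
    write_fasta(community.contigs, paths["contigs"])
    write_depth_table(community.depth, paths["depth"])
    write_marker_hits(community.hits, paths["markers"])
    with open(paths["truth"], "w") as fh:
        fh.write("contig_id\tgenome_id\tis_chimera\n")
        for cid in community.contigs.ids:
            fh.write(
                f"{cid}\t{community.truth.genome_of[cid]}\t{int(community.truth.is_chimera(cid))}\n"
            )
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(community.spec), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def read_truth(path: str | Path) -> PlantedTruth:
    genome_of: dict[str, str] = {}
    chimera: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            cid, gid, flag = line.rstrip("\n").split("\t")
            genome_of[cid] = gid
            if flag == "1":
                chimera[cid] = (gid, "?")
    return PlantedTruth(genome_of=genome_of, chimera_parents=chimera)
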