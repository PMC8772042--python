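"""Single-copy marker genes: strain-count estimation and bin quality.

Single-copy marker genes occur exactly once per genome, so (a) the number
of contigs carrying a given marker estimates the number of strains in the
sample, and those contigs make natural initial cluster centers, and (b)
within a candidate bin, missing markers indicate incompleteness while
multi-copy markers indicate contamination.  Quality is averaged over
*collocated marker sets* (groups of markers that co-occur on genomes)
rather than over individual genes:

    recall              = mean over sets s of |s intersect found| / |s|
    contamination_index = mean over sets s of (sum over g in s of max(N_g - 1, 0)) / |s|

where N_g is the copy number of marker g in the bin.  The thresholded
purity is reported as precision = 1 / (1 + contamination_index), which is
1 for a bin with no duplicated marker and decreases as extra copies
accumulate.

Gene prediction and HMM search are consumed as external tools or
precomputed hit tables, never reimplemented.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
import tempfile
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .io_formats import MarkerHitRecord, read_marker_hits

logger = logging.getLogger(__name__)


@dataclass
class MarkerSetCatalog:
    """Collocated single-copy marker sets."""

    name: str
    sets: list[list[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("catalog must contain at least one marker set")
        for s in self.sets:
            if not s:
                raise ValueError("empty marker set in catalog")
            if len(set(s)) != len(s):
                raise ValueError("duplicate marker ids within a set")

    @property
    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sets:
            for m in s:
                seen.setdefault(m)
        return list(seen)

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerSetCatalog":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(name=payload["name"], sets=[list(s) for s in payload["sets"]])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "sets": self.sets}, fh, indent=2)


@dataclass
class MarkerHitTable:
    """Marker -> contigs (with multiplicity) and the inverse mapping."""

    hits: dict[str, list[str]]            # marker_id -> contig ids, one entry per hit
    contig_markers: dict[str, list[str]]  # contig_id -> marker ids, one entry per hit
    records: list[MarkerHitRecord] = field(default_factory=list)

    def restrict(self, contig_ids: Sequence[str]) -> "MarkerHitTable":
        keep = set(contig_ids)
        recs = [r for r in self.records if r.contig_id in keep]
        return _table_from_records(recs)

    @property
    def n_hits(self) -> int:
        return sum(len(v) for v in self.hits.values())


def _table_from_records(records: Sequence[MarkerHitRecord]) -> MarkerHitTable:
    hits: dict[str, list[str]] = defaultdict(list)
    inverse: dict[str, list[str]] = defaultdict(list)
    for rec in records:
        hits[rec.marker_id].append(rec.contig_id)
        inverse[rec.contig_id].append(rec.marker_id)
    return MarkerHitTable(dict(hits), dict(inverse), list(records))


def build_hit_table(records: Sequence[MarkerHitRecord], catalog: MarkerSetCatalog) -> MarkerHitTable:
    """Restrict hits to catalog markers; duplicate (contig, marker) hits are kept."""
    known = set(catalog.all_markers)
    kept = [r for r in records if r.marker_id in known]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("%d marker hits not in catalog %s dropped", n_dropped, catalog.name)
    return _table_from_records(kept)


@dataclass
class SeedSelection:
    """Estimated strain count k and the contigs used as initial centers."""

    k: int
    seed_contig_ids: list[str]
    selected_marker: str
    per_marker_counts: dict[str, int]


def _hit_span(rec: MarkerHitRecord) -> int:
    if rec.coords is None:
        return 0
    lo, hi = rec.coords
    return abs(hi - lo) + 1


def estimate_k_and_seeds(hit_table: MarkerHitTable, strategy: str = "median") -> SeedSelection:
    """Estimate the number of strains from per-marker contig counts.

    Each single-copy marker should appear on as many distinct contigs as
    there are strains.  ``median`` (default) takes the lower median of the
    per-marker distinct-contig counts, robust to spuriously rare or
    promiscuous markers; ``min_literal`` takes the minimum count >= 1.  The
    distinct contigs carrying the selected marker become the seeds.
    """
    if strategy not in ("median", "min_literal"):
        raise ValueError(f"unknown k strategy {strategy!r}")
    counts = {m: len(set(cids)) for m, cids in hit_table.hits.items() if cids}
    if not counts:
        raise ValueError(
            "no marker hits available to estimate the strain count; "
            "supply --k-override or a marker hit table"
        )
    if strategy == "median":
        values = sorted(counts.values())
        k = values[(len(values) - 1) // 2]  # lower median
    else:
        k = min(counts.values())
    candidates = [m for m, c in counts.items() if c == k]
    spans = {
        m: sum(_hit_span(r) for r in hit_table.records if r.marker_id == m)
        for m in candidates
    }
    selected = min(candidates, key=lambda m: (-spans[m], m))
    seeds = sorted(set(hit_table.hits[selected]))
    return SeedSelection(k=k, seed_contig_ids=seeds, selected_marker=selected, per_marker_counts=counts)


@dataclass
class BinQuality:
    """Marker-based completeness (recall) and purity of one bin."""

    recall: float
    contamination_index: float
    n_markers_found: int

    @property
    def precision(self) -> float:
        return 1.0 / (1.0 + self.contamination_index)


def eval_bin_quality(
    bin_contigs: Sequence[str],
    hit_table: MarkerHitTable,
    catalog: MarkerSetCatalog,
) -> BinQuality:
    """Set-averaged recall and multicopy contamination index of a bin."""
    if not bin_contigs:
        raise ValueError("bin_contigs must be non-empty")
    members = set(bin_contigs)
    copy_number: Counter[str] = Counter()
    for cid in members:
        for m in hit_table.contig_markers.get(cid, ()):
            copy_number[m] += 1
    recall_terms = []
    contam_terms = []
    for s in catalog.sets:
        found = sum(1 for g in s if copy_number[g] >= 1)
        extra = sum(max(copy_number[g] - 1, 0) for g in s)
        recall_terms.append(found / len(s))
        contam_terms.append(extra / len(s))
    n_found = sum(1 for g in catalog.all_markers if copy_number[g] >= 1)
    return BinQuality(
        recall=float(sum(recall_terms) / len(recall_terms)),
        contamination_index=float(sum(contam_terms) / len(contam_terms)),
        n_markers_found=n_found,
    )


def run_external_marker_scan(
    contigs_fasta: str | Path,
    tool_config: dict,
) -> list[MarkerHitRecord]:
    """Run an external gene-prediction + HMM-search command and parse its output.

    ``tool_config`` must provide ``command`` (list of argv tokens; the
    placeholders ``{fasta}`` and ``{out}`` are substituted) and ``dialect``
    (one of the marker-hit dialects).  This is optional plumbing for users
    with FragGeneScan/hmmsearch installed; the supported alternative is a
    precomputed hit TSV.
    """
    command = tool_config.get("command")
    dialect = tool_config.get("dialect", "hmmer_domtbl")
    if not command:
        raise ValueError("tool_config must define 'command'")
    exe = command[0]
    if shutil.which(exe) is None and not Path(exe).exists():
        raise FileNotFoundError(
            f"external marker-scan binary {exe!r} not found; "
            "provide a precomputed hit TSV (contig_id<TAB>marker_id) instead"
        )
    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "hits.out"
        argv = [tok.format(fasta=str(contigs_fasta), out=str(out)) for tok in command]
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"marker scan command failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        if not out.exists():
            raise RuntimeError("marker scan command produced no output file")
        return read_marker_hits(out, dialect)
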