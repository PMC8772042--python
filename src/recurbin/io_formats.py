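"""On-disk formats: contig FASTA, depth tables, marker hits, bin output.

The binner consumes assembled contigs (FASTA), a per-contig per-sample
depth table (either the common ``jgi_summarize_bam_contig_depths`` layout
or a plain contig-by-sample TSV), and marker-gene hits (HMMER3 tabular
output or a two-column TSV).  Results are written as one FASTA per
accepted bin plus a membership table and a JSON summary.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class ContigRecord:
    """A single assembled contig: unique id, upper-case ACGTN sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class ContigSet:
    """Ordered collection of contigs with unique identifiers."""

    def __init__(self, records: Sequence[ContigRecord]):
        self._records: dict[str, ContigRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise ValueError(f"duplicate contig id: {rec.id!r}")
            if not rec.id or any(ch.isspace() for ch in rec.id):
                raise ValueError(f"invalid contig id: {rec.id!r}")
            if rec.length < 1:
                raise ValueError(f"empty sequence for contig {rec.id!r}")
            self._records[rec.id] = rec

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self._records.values()], dtype=np.int64)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ContigRecord]:
        return iter(self._records.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._records

    def __getitem__(self, contig_id: str) -> ContigRecord:
        return self._records[contig_id]

    def subset(self, ids: Sequence[str]) -> "ContigSet":
        """New ContigSet restricted to ``ids``, in the given order."""
        return ContigSet([self._records[i] for i in ids])


@dataclass
class DepthTable:
    """Per-contig mean read depth across M samples (rows align to contig_ids)."""

    contig_ids: list[str]
    sample_names: list[str]
    depth: np.ndarray  # shape (n_contigs, M)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2 or self.depth.shape != (
            len(self.contig_ids),
            len(self.sample_names),
        ):
            raise ValueError("depth matrix shape does not match ids/samples")
        if np.any(self.depth < 0):
            raise ValueError("negative depth values are not allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def restrict_to(self, contig_ids: Sequence[str]) -> "DepthTable":
        """Rows restricted and reordered to ``contig_ids``.

        Raises if any requested contig is missing from the table.
        """
        index = {cid: i for i, cid in enumerate(self.contig_ids)}
        missing = [cid for cid in contig_ids if cid not in index]
        if missing:
            raise ValueError(
                "contigs absent from depth table: " + ", ".join(missing[:20])
            )
        rows = [index[cid] for cid in contig_ids]
        return DepthTable(list(contig_ids), list(self.sample_names), self.depth[rows])


@dataclass(frozen=True)
class MarkerHitRecord:
    """One marker-gene hit on a contig.

    ``coords`` are 1-based inclusive alignment coordinates on the contig
    (HMMER convention); they are informational only.
    """

    contig_id: str
    marker_id: str
    score: Optional[float] = None
    coords: Optional[tuple[int, int]] = None


def read_fasta(path: str | Path) -> ContigSet:
    """Read contigs from FASTA.

    Sequences are upper-cased; any character outside {A,C,G,T,N} becomes N
    (counted and logged).  Duplicate ids and empty files are hard errors.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        n_mapped += sum(1 for a, b in zip(seq, cleaned) if a != b)
        records.append(ContigRecord(id=rec.id, sequence=cleaned))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_mapped:
        logger.warning("%d non-ACGTN characters mapped to N while reading %s", n_mapped, path)
    return ContigSet(records)


def write_fasta(contigs: ContigSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(recs, str(Path(path)), "fasta")


def read_depth_table(path: str | Path, contig_set: Optional[ContigSet] = None) -> DepthTable:
    """Read a depth table TSV.

    Two layouts are auto-detected:

    * the ``jgi_summarize_bam_contig_depths`` layout
      (``contigName  contigLen  totalAvgDepth  s1  s1-var  s2  s2-var ...``),
      detected by a ``totalAvgDepth`` column; variance columns are dropped;
    * a plain layout: first column contig id, one column per sample.

    When ``contig_set`` is given, rows are restricted and reordered to it;
    a contig missing from the table is a hard error naming the missing ids.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"depth table {path} needs at least two columns")
    cols = list(df.columns)
    contig_ids = df.iloc[:, 0].astype(str).tolist()
    if "totalAvgDepth" in cols:
        data_cols = cols[3:]
        if len(data_cols) % 2 != 0:
            # tolerate tables without variance columns after totalAvgDepth
            sample_cols = data_cols
        else:
            sample_cols = data_cols[0::2]
        if not sample_cols:
            raise ValueError(f"depth table {path} has no sample columns")
    else:
        sample_cols = cols[1:]
    depth = df[sample_cols].to_numpy(dtype=float)
    if np.any(depth < 0):
        raise ValueError(f"negative depth values in {path}")
    table = DepthTable(contig_ids, [str(c) for c in sample_cols], depth)
    if contig_set is not None:
        table = table.restrict_to(contig_set.ids)
    return table


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    """Write a plain-layout depth table (contigName + one column per sample)."""
    df = pd.DataFrame(table.depth, columns=table.sample_names)
    df.insert(0, "contigName", table.contig_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# Column positions in HMMER3 whitespace-delimited tabular output.
_TBL_TARGET, _TBL_QUERY, _TBL_SCORE = 0, 2, 5
_DOMTBL_TARGET, _DOMTBL_QUERY, _DOMTBL_SCORE = 0, 3, 7
_DOMTBL_ALI_FROM, _DOMTBL_ALI_TO = 17, 18

MARKER_DIALECTS = ("tsv", "hmmer_tbl", "hmmer_domtbl")


def read_marker_hits(path: str | Path, dialect: str = "tsv") -> list[MarkerHitRecord]:
    """Parse marker-gene hits.

    ``tsv``: two tab-separated columns ``contig_id, marker_id`` (an optional
    third numeric column is taken as score).  ``hmmer_tbl`` / ``hmmer_domtbl``:
    HMMER3 ``--tblout`` / ``--domtblout`` files where the *target* is the
    contig (or a gene named ``<contig>_<n>``) and the *query* is the marker.
    """
    if dialect not in MARKER_DIALECTS:
        raise ValueError(f"unknown marker-hit dialect {dialect!r}; expected one of {MARKER_DIALECTS}")
    records: list[MarkerHitRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "tsv":
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed marker TSV line: {line!r}")
                score = float(parts[2]) if len(parts) > 2 and parts[2] else None
                records.append(MarkerHitRecord(parts[0], parts[1], score=score))
            else:
                parts = line.split()
                if dialect == "hmmer_tbl":
                    if len(parts) <= _TBL_SCORE:
                        raise ValueError(f"malformed tblout line: {line!r}")
                    records.append(
                        MarkerHitRecord(
                            parts[_TBL_TARGET],
                            parts[_TBL_QUERY],
                            score=float(parts[_TBL_SCORE]),
                        )
                    )
                else:
                    if len(parts) <= _DOMTBL_ALI_TO:
                        raise ValueError(f"malformed domtblout line: {line!r}")
                    records.append(
                        MarkerHitRecord(
                            parts[_DOMTBL_TARGET],
                            parts[_DOMTBL_QUERY],
                            score=float(parts[_DOMTBL_SCORE]),
                            coords=(
                                int(parts[_DOMTBL_ALI_FROM]),
                                int(parts[_DOMTBL_ALI_TO]),
                            ),
                        )
                    )
    return records


def write_marker_hits(records: Sequence[MarkerHitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.contig_id}\t{rec.marker_id}\n")


def write_bins(result, outdir: str | Path, contig_set: ContigSet) -> dict:
    """Write an accepted-bin directory and return its manifest.

    Produces ``bin.<k>.fa`` per accepted bin, ``membership.tsv``
    (contig_id, bin_id, assignment_probability) covering every input contig
    (residuals as ``unbinned``), and ``summary.json`` with per-bin quality,
    the recursion trace and the thresholds used.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"bins": [], "membership": str(outdir / "membership.tsv")}
    rows: list[tuple[str, str, float]] = []
    probs: Mapping[str, float] = getattr(result, "assignment_probabilities", {}) or {}
    for bin_ in result.accepted_bins:
        fa = outdir / f"{bin_.bin_id}.fa"
        write_fasta(contig_set.subset(bin_.contig_ids), fa)
        manifest["bins"].append(
            {
                "bin_id": bin_.bin_id,
                "fasta": str(fa),
                "n_contigs": len(bin_.contig_ids),
                "recall": bin_.quality.recall,
                "precision": bin_.quality.precision,
                "contamination_index": bin_.quality.contamination_index,
                "recursion_round": bin_.recursion_round,
            }
        )
        for cid in bin_.contig_ids:
            rows.append((cid, bin_.bin_id, float(probs.get(cid, float("nan")))))
    for cid in result.residual_ids:
        rows.append((cid, "unbinned", float(probs.get(cid, float("nan")))))
    with open(outdir / "membership.tsv", "w") as fh:
        fh.write("contig_id\tbin_id\tassignment_probability\n")
        for cid, bid, p in rows:
            fh.write(f"{cid}\t{bid}\t{p:.6g}\n")
    summary = {
        "n_bins": len(result.accepted_bins),
        "n_unbinned": len(result.residual_ids),
        "seed": result.seed,
        "thresholds": getattr(result, "thresholds", None),
        "trace": result.trace,
        "bins": manifest["bins"],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest["summary"] = str(outdir / "summary.json")
    return manifest
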