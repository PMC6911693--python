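"""Sequence records, FASTA I/O, global alignment and ITS region annotation.

The internal transcribed spacer (ITS) cistron ITS1–5.8S–ITS2 is the unit
of analysis throughout the package.  This module holds the basic
containers (records, clone sets, alignments, region intervals), reads and
writes FASTA through Biopython, and provides the affine-gap global
aligner and the progressive multiple aligner every downstream stage uses.
All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import _kernels
from .errors import AlignmentError, AnnotationError, FastaFormatError

ALLOWED = set("ACGTN")
ALLOWED_GAPPED = set("ACGTN-")
#: IUPAC ambiguity codes other than N are rejected on input: the clone
#: consensus sequences this package handles are unambiguous calls.
REJECTED_IUPAC = set("RYSWKMBDHV")


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring; a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence over {A,C,G,T,N,-}; gaps only inside alignments."""

    id: str
    residues: str
    accession: str | None = None
    taxon: str | None = None
    molecule: str | None = None  # "ITS", "trnL-trnF", "trnT-trnL"

    def __post_init__(self):
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED_GAPPED
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_gapped(self) -> bool:
        return "-" in self.residues

    def ungapped(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.replace("-", ""))


@dataclass(frozen=True)
class CloneSet:
    """All sequenced clones for one accession (the paper's unit of typing)."""

    accession_name: str
    clones: tuple[SequenceRecord, ...]
    ploidy: str | None = None
    taxon: str | None = None

    def __post_init__(self):
        if len(self.clones) < 1:
            raise ValueError(f"{self.accession_name}: clone set is empty")
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.accession_name}: duplicate clone ids")

    @property
    def n_clones(self) -> int:
        return len(self.clones)


Interval = tuple[int, int]


@dataclass(frozen=True)
class ItsRegions:
    """ITS1 / 5.8S / ITS2 half-open intervals on an ungapped sequence."""

    its1: Interval
    r58s: Interval
    its2: Interval

    def __post_init__(self):
        for name, (s, e) in self.items():
            if not (0 <= s < e):
                raise ValueError(f"{name}: empty or negative interval ({s},{e})")
        if not (self.its1[1] <= self.r58s[0] and self.r58s[1] <= self.its2[0]):
            raise ValueError("regions out of order or overlapping")

    def items(self):
        return (("ITS1", self.its1), ("5.8S", self.r58s), ("ITS2", self.its2))

    @property
    def full(self) -> Interval:
        return (self.its1[0], self.its2[1])

    def length(self, region: str) -> int:
        s, e = self.as_dict()[region]
        return e - s

    def as_dict(self) -> dict[str, Interval]:
        return {"ITS1": self.its1, "5.8S": self.r58s, "ITS2": self.its2,
                "full": self.full}


@dataclass
class Alignment:
    """Gapped records of equal length; removing gaps recovers the inputs."""

    records: list[SequenceRecord]
    score: float | None = None
    partition_boundary: int | None = None  # set by concat_cpdna

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("alignment with no rows")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def row(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def columns(self) -> np.ndarray:
        """(n_rows, n_cols) encoded residue matrix."""
        return np.stack([_kernels.encode_seq(r.residues) for r in self.records])


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, molecule: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Headers are split at the first whitespace; sequences are upper-cased
    and U is mapped to T.  Empty files and non-{A,C,G,T,N} characters
    (including IUPAC ambiguity codes other than N) are errors.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace("U", "T")
        bad = set(residues) - ALLOWED
        if bad:
            raise FastaFormatError(
                f"{path.name}: record {rec.id!r} contains disallowed "
                f"characters {sorted(bad)}"
            )
        records.append(SequenceRecord(id=rec.id, residues=residues,
                                      molecule=molecule))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FastaFormatError(f"{path}: duplicate record ids")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Pairwise global alignment


def global_align(a: SequenceRecord, b: SequenceRecord,
                 scoring: Scoring = DEFAULT_SCORING) -> Alignment:
    """Optimal global alignment under affine-gap scoring.

    Deterministic tie-breaking: substitution preferred over gaps, then
    gap-in-b (consuming a) over gap-in-a.
    """
    for r in (a, b):
        if r.is_gapped:
            raise AlignmentError(f"record {r.id!r} already contains gaps")
        if not r.residues:
            raise AlignmentError(f"record {r.id!r} is empty")
    score, ops = _kernels.gotoh_align(
        _kernels.encode_seq(a.residues), _kernels.encode_seq(b.residues),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            ra.append(a.residues[i]); rb.append(b.residues[j]); i += 1; j += 1
        elif op == 1:
            ra.append(a.residues[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b.residues[j]); j += 1
    return Alignment(
        records=[replace(a, residues="".join(ra)),
                 replace(b, residues="".join(rb))],
        score=float(score))


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _kmer_set(residues: str, k: int) -> set[str]:
    return {residues[i:i + k] for i in range(len(residues) - k + 1)}


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 6) -> np.ndarray:
    sets = [_kmer_set(s, k) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) if denom else 0
            d[i, j] = d[j, i] = 1.0 - (shared / denom if denom else 0.0)
    return d


def _rows_to_profile(rows: list[np.ndarray]) -> np.ndarray:
    length = len(rows[0])
    prof = np.zeros((length, 6), dtype=np.float64)
    for row in rows:
        for pos in range(length):
            prof[pos, row[pos]] += 1.0
    return prof


def progressive_msa(records: Sequence[SequenceRecord],
                    scoring: Scoring = DEFAULT_SCORING,
                    k: int = 6) -> Alignment:
    """Progressive multiple alignment: k-mer/UPGMA guide tree, profile merges.

    Input order does not affect column content: records are canonically
    ordered before guide-tree construction and restored afterwards.
    This is deliberately a simple aligner; every statistic downstream
    (GC, motifs, MFE, pairwise distances) is alignment-light by design.
    """
    if len(records) < 2:
        raise AlignmentError("progressive_msa needs at least 2 records")
    for r in records:
        if r.is_gapped:
            raise AlignmentError(f"record {r.id!r} already contains gaps")
    order = sorted(range(len(records)),
                   key=lambda i: (records[i].residues, records[i].id))
    canon = [records[i] for i in order]
    # cluster state: list of encoded gapped rows per original canon index
    clusters: dict[int, list[tuple[int, np.ndarray]]] = {
        i: [(i, _kernels.encode_seq(canon[i].residues))] for i in range(len(canon))
    }
    if len(canon) == 2:
        merge_plan = [(0, 1, 2)]
    else:
        dm = _kmer_distance_matrix([r.residues for r in canon], k=k)
        z = linkage(squareform(dm, checks=False), method="average")
        merge_plan = [(int(a), int(b), len(canon) + t)
                      for t, (a, b, _, _) in enumerate(z)]
    for ia, ib, inew in merge_plan:
        rows_a = clusters.pop(ia)
        rows_b = clusters.pop(ib)
        pa = _rows_to_profile([r for _, r in rows_a])
        pb = _rows_to_profile([r for _, r in rows_b])
        _, ops = _kernels.profile_align(
            pa, pb, scoring.match, scoring.mismatch,
            scoring.gap_open, scoring.gap_extend)
        new_rows = []
        for idx, row in rows_a:
            out = np.empty(len(ops), dtype=np.int8)
            p = 0
            for c, op in enumerate(ops):
                if op == 2:
                    out[c] = 5
                else:
                    out[c] = row[p]; p += 1
            new_rows.append((idx, out))
        for idx, row in rows_b:
            out = np.empty(len(ops), dtype=np.int8)
            p = 0
            for c, op in enumerate(ops):
                if op == 1:
                    out[c] = 5
                else:
                    out[c] = row[p]; p += 1
            new_rows.append((idx, out))
        clusters[inew] = new_rows
    (final_rows,) = clusters.values()
    by_canon = {idx: row for idx, row in final_rows}
    gapped = [None] * len(records)
    for canon_pos, orig_pos in enumerate(order):
        gapped[orig_pos] = replace(
            records[orig_pos],
            residues=_kernels.decode_seq(by_canon[canon_pos]))
    return Alignment(records=list(gapped))


# ---------------------------------------------------------------------------
# ITS region annotation


def annotate_regions(seq: SequenceRecord, reference: SequenceRecord,
                     reference_regions: ItsRegions,
                     scoring: Scoring = DEFAULT_SCORING) -> ItsRegions:
    """Transfer ITS1/5.8S/ITS2 boundaries from an annotated reference.

    The query is globally aligned to the reference and each boundary
    coordinate is mapped through the alignment, so insertions inside a
    region lengthen that region only.
    """
    if seq.residues == reference.residues:
        return reference_regions
    aln = global_align(reference, seq, scoring)
    ref_row = aln.records[0].residues
    seq_row = aln.records[1].residues
    # boundary map: reference coordinate -> query coordinate
    ref2seq = np.zeros(len(reference) + 1, dtype=int)
    ri = si = 0
    for cr, cs in zip(ref_row, seq_row):
        if cr != "-":
            ref2seq[ri] = si
            ri += 1
        if cs != "-":
            si += 1
    ref2seq[len(reference)] = si
    try:
        mapped = ItsRegions(
            its1=(int(ref2seq[reference_regions.its1[0]]),
                  int(ref2seq[reference_regions.its1[1]])),
            r58s=(int(ref2seq[reference_regions.r58s[0]]),
                  int(ref2seq[reference_regions.r58s[1]])),
            its2=(int(ref2seq[reference_regions.its2[0]]),
                  int(ref2seq[reference_regions.its2[1]])))
    except ValueError as exc:
        raise AnnotationError(f"annotation failed for {seq.id!r}: {exc}") from exc
    if mapped.its2[1] > len(seq.ungapped()):
        raise AnnotationError(f"annotation failed for {seq.id!r}: out of range")
    return mapped


# ---------------------------------------------------------------------------
# Packaged reference + metadata table


def _data_path(name: str):
    return importlib.resources.files("pseudits").joinpath("data", name)


def load_reference_its() -> tuple[SequenceRecord, ItsRegions]:
    """Packaged annotated reference ITS (synthetic stand-in sequence).

    The sequence is a deterministic synthetic 611-bp short-type ITS with
    annotated region boundaries and the three conserved 5.8S motifs; it
    plays the role of an annotated reference for boundary transfer.
    """
    recs = read_fasta(_data_path("synthetic_reference_its.fasta"), molecule="ITS")
    meta = json.loads(_data_path("synthetic_reference_its.json").read_text())
    regions = ItsRegions(its1=tuple(meta["its1"]), r58s=tuple(meta["r58s"]),
                         its2=tuple(meta["its2"]))
    return recs[0], regions


METADATA_COLUMNS = [
    "accession_name", "taxon", "ploidy", "its_lengths", "heterozygosity_pct",
    "its_accessions", "clone_number", "trnLF_bp", "trnLF_accession",
    "trnTL_bp", "trnTL_accession",
]


def load_metadata(path: str | Path | None = None) -> pd.DataFrame:
    """Load the accession metadata table (packaged copy of the study table).

    Columns: accession_name, taxon, ploidy, its_lengths (slash-separated
    bp, majority variant first), heterozygosity_pct, its_accessions,
    clone_number, trnLF_bp/accession, trnTL_bp/accession.
    """
    if path is None:
        path = _data_path("table1.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    df["clone_number"] = df["clone_number"].astype(int)
    df["heterozygosity_pct"] = df["heterozygosity_pct"].astype(float)
    df["its_length_list"] = df["its_lengths"].map(
        lambda s: [int(x) for x in s.split("/")])
    return df
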