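"""Collapse clone sets into consensus ITS copy variants and type them.

An accession's 7–20 sequenced clones are clustered (absorbing PCR
miscalls), each cluster is collapsed to a majority-rule consensus, and
the consensuses are typed by length class (short ~611 bp vs long
~624–631 bp) and support rank (α1/α2 within short, β1/β2 within long).
Clone-level heterozygosity is the percentage of clones carrying a
variant other than the top-supported one.  The module also catalogues
SNP/InDel differences between copies and classifies the diagnostic
13-bp insertion allele of long-type sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .errors import AlignmentError
from .seqio import (CloneSet, Scoring, DEFAULT_SCORING, SequenceRecord,
                    global_align)

#: The three 13-bp insertion alleles observed at the long-type ITS locus.
KNOWN_THIRTEENMERS = ("CGTATACAATGCG", "TGTGTGCAATGCG", "CGTACACAATGCG")

#: Length threshold separating short-type (~611 bp) from long-type
#: (~624–631 bp) ITS sequences; midpoint of the observed gap.
DEFAULT_LENGTH_THRESHOLD = 618

#: Substitution tolerance for absorbing PCR errors into a cluster.
#: InDel-bearing clones are never absorbed (they always found a new
#: variant), so 1-SNP copy variants survive while sub-consensus noise
#: is corrected.
DEFAULT_MAX_INTRA_DIFF = 2


@dataclass
class CopyVariant:
    """A consensus ITS copy with clone support and type labels."""

    consensus: SequenceRecord
    support: int
    length_class: str | None = None  # "short" | "long"
    rank_label: str | None = None    # α, β, α1, α2, β1, β2
    is_recombinant: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.consensus)


@dataclass
class IndelEvent:
    position: int  # 0-based alignment column where the gap run starts
    length: int
    kind: str      # "insertion" (gap in first sequence) | "deletion"


@dataclass
class VariantCatalogue:
    """Per-accession typing summary."""

    accession_name: str
    variants: list[CopyVariant]
    heterozygosity_pct: float
    thirteenmer_allele: str = "absent"

    @property
    def n_clones(self) -> int:
        return sum(v.support for v in self.variants)


def _hamming_or_inf(a: str, b: str) -> float:
    if len(a) != len(b):
        return float("inf")
    return float(sum(x != y for x, y in zip(a, b)))


def cluster_clones(cs: CloneSet,
                   max_intra_diff: int = DEFAULT_MAX_INTRA_DIFF
                   ) -> list[CopyVariant]:
    """Single-linkage clustering of clones at <= max_intra_diff substitutions.

    Clones of different lengths (InDel-bearing) are never merged.  Each
    cluster is collapsed to a per-column majority consensus (ties broken
    to the alphabetically smallest base).  Supports partition the clone
    set.  Variants are returned by descending support, ties broken by
    longer consensus then lexicographic consensus.
    """
    clones = list(cs.clones)
    for c in clones:
        if c.is_gapped:
            raise AlignmentError(f"clone {c.id!r} contains gaps")
    n = len(clones)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming_or_inf(clones[i].residues, clones[j].residues) \
                    <= max_intra_diff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[SequenceRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(clones[i])
    variants = []
    for members in groups.values():
        length = len(members[0].residues)
        cols = []
        for pos in range(length):
            counts: dict[str, int] = {}
            for m in members:
                counts[m.residues[pos]] = counts.get(m.residues[pos], 0) + 1
            best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            cols.append(best)
        consensus = SequenceRecord(
            id=f"{cs.accession_name}_variant", residues="".join(cols),
            taxon=cs.taxon, molecule="ITS")
        variants.append(CopyVariant(consensus=consensus, support=len(members)))
    variants.sort(key=lambda v: (-v.support, -v.length_bp,
                                 v.consensus.residues))
    for i, v in enumerate(variants, start=1):
        v.consensus = replace(v.consensus, id=f"{cs.accession_name}_v{i}")
    return variants


def type_variants(variants: Sequence[CopyVariant],
                  length_threshold: int = DEFAULT_LENGTH_THRESHOLD
                  ) -> list[CopyVariant]:
    """Assign length classes and α/β rank labels.

    Short (< threshold) copies take α labels, long ones β labels.
    Classes with two or more members are numbered by descending support
    (α1, α2, ...).  A singleton class is numbered 1 only when it holds
    the accession's top-supported variant; otherwise — and for
    single-variant accessions — the bare letter is used.
    """
    if not variants:
        raise ValueError("no variants to type")
    variants = sorted(variants, key=lambda v: (-v.support, -v.length_bp,
                                               v.consensus.residues))
    top = variants[0]
    for v in variants:
        v.length_class = "short" if v.length_bp < length_threshold else "long"
    single = len(variants) == 1
    for letter, cls in (("α", "short"), ("β", "long")):
        members = [v for v in variants if v.length_class == cls]
        if not members:
            continue
        if single:
            members[0].rank_label = letter
        elif len(members) == 1:
            members[0].rank_label = (f"{letter}1" if members[0] is top
                                     else letter)
        else:
            for i, v in enumerate(members, start=1):
                v.rank_label = f"{letter}{i}"
    for v in variants:
        base = v.consensus.id.rsplit("_v", 1)[0]
        v.consensus = replace(v.consensus, id=f"{base}-{v.rank_label}")
    return variants


def heterozygosity(cs: CloneSet, variants: Sequence[CopyVariant]) -> float:
    """Percentage of clones not carrying the top-supported variant.

    100 x (n_clones - max support) / n_clones, to two decimals.
    """
    if cs.n_clones == 0:
        raise ValueError("empty clone set")
    supports = [v.support for v in variants]
    if sum(supports) != cs.n_clones:
        raise ValueError("variant supports do not partition the clone set")
    return round(100.0 * (cs.n_clones - max(supports)) / cs.n_clones, 2)


def diff_pair(a: SequenceRecord, b: SequenceRecord,
              scoring: Scoring = DEFAULT_SCORING
              ) -> tuple[int, list[IndelEvent]]:
    """SNP count and InDel list between two sequences (global alignment).

    Substitution columns count as SNPs; maximal gap runs are reported as
    InDel events; columns containing N are skipped.
    """
    aln = global_align(a, b, scoring)
    ra, rb = aln.records[0].residues, aln.records[1].residues
    snps = 0
    indels: list[IndelEvent] = []
    run_start = None
    run_kind = None
    for col, (x, y) in enumerate(zip(ra, rb)):
        kind = None
        if x == "-":
            kind = "insertion"
        elif y == "-":
            kind = "deletion"
        if kind is not None:
            if run_kind == kind:
                pass
            else:
                if run_kind is not None:
                    indels.append(IndelEvent(run_start, col - run_start,
                                             run_kind))
                run_start, run_kind = col, kind
            continue
        if run_kind is not None:
            indels.append(IndelEvent(run_start, col - run_start, run_kind))
            run_start = run_kind = None
        if x == "N" or y == "N":
            continue
        if x != y:
            snps += 1
    if run_kind is not None:
        indels.append(IndelEvent(run_start, len(ra) - run_start, run_kind))
    return snps, indels


def classify_thirteenmer(seq: SequenceRecord, reference: SequenceRecord,
                         known_alleles: Sequence[str] = KNOWN_THIRTEENMERS,
                         scoring: Scoring = DEFAULT_SCORING) -> str:
    """Classify the 13-bp insertion allele of a sequence.

    The locus is located by aligning to a long-type reference carrying
    one of the known alleles.  Returns the matching allele, a
    "novel:<13-mer>" label, or "absent" for short-type sequences whose
    alignment shows a 13-bp gap at the locus.
    """
    ref_seq = reference.residues
    locus = None
    for allele in known_alleles:
        pos = ref_seq.find(allele)
        if pos >= 0:
            locus = (pos, pos + len(allele))
            break
    if locus is None:
        # fall back: best Hamming match of any known allele on the reference
        best = None
        for allele in known_alleles:
            for pos in range(len(ref_seq) - len(allele) + 1):
                d = sum(x != y for x, y in
                        zip(ref_seq[pos:pos + len(allele)], allele))
                if best is None or d < best[0]:
                    best = (d, pos, len(allele))
        if best is None:
            raise ValueError("reference shorter than the 13-bp allele")
        locus = (best[1], best[1] + best[2])
    aln = global_align(reference, seq, scoring)
    ref_row, seq_row = aln.records[0].residues, aln.records[1].residues
    # alignment columns covering the reference locus
    cols = []
    ri = 0
    for col, c in enumerate(ref_row):
        if c != "-":
            if locus[0] <= ri < locus[1]:
                cols.append(col)
            ri += 1
    window = "".join(seq_row[c] for c in cols)
    # gap runs of >= 13 columns in the query row; the aligner may place
    # the deletion a few columns off the reference locus
    runs = []
    start = None
    for col, c in enumerate(seq_row + "X"):
        if c == "-":
            if start is None:
                start = col
        elif start is not None:
            if col - start >= 13:
                runs.append((start, col))
            start = None
    overlapping = [r for r in runs if r[0] <= cols[-1] and r[1] > cols[0]]
    if len(runs) - len(overlapping) >= 1 and overlapping:
        raise ValueError(f"{seq.id}: multiple 13-bp gap runs; locus ambiguous")
    if overlapping or window.count("-") == len(window):
        return "absent"
    window = window.replace("-", "")  # partial erosion of the insertion
    if window in known_alleles:
        return window
    return f"novel:{window}"


def build_catalogue(cs: CloneSet,
                    max_intra_diff: int = DEFAULT_MAX_INTRA_DIFF,
                    length_threshold: int = DEFAULT_LENGTH_THRESHOLD,
                    long_reference: SequenceRecord | None = None
                    ) -> VariantCatalogue:
    """Cluster, type and summarize one accession's clone set."""
    variants = type_variants(cluster_clones(cs, max_intra_diff),
                             length_threshold)
    het = heterozygosity(cs, variants)
    allele = "absent"
    if long_reference is not None:
        for v in variants:
            if v.length_class == "long":
                allele = classify_thirteenmer(v.consensus, long_reference)
                break
    return VariantCatalogue(accession_name=cs.accession_name,
                            variants=variants, heterozygosity_pct=het,
                            thirteenmer_allele=allele)
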