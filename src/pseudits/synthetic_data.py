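"""Forward simulator for ITS clone sets, relic copies and cpDNA haplotypes.

Emulates the data structure the analysis assumes: a short-type (~611 bp)
ancestral functional ITS and a long-type (~624 bp) ancestor carrying a
13-bp insertion; accessions that are either pure (one functional copy)
or hybrid (a short-type major copy plus a minor copy that is usually a
long-type pseudogene relic, occasionally a second functional copy);
clone sampling with a binomial minor-copy fraction and rare PCR
miscalls; pseudogene evolution with an elevated, GC-eroding
substitution process, motif knockouts and small indels; recombinant
relics spliced from the two copy types; and two maternal cpDNA
haplotype pools (clade I low-diversity, clade II more variable with a
subclade) for trnL-trnF and trnT-trnL.

Every draw flows through one explicitly threaded numpy Generator, so a
SimConfig (including its seed) fixes the output byte for byte.  Rates
are stated modelling assumptions, not measured values; see the package
methods note for the rationale behind each default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clone_analysis import KNOWN_THIRTEENMERS
from .pseudogene_screen import MOTIFS
from .seqio import (CloneSet, ItsRegions, Scoring, DEFAULT_SCORING,
                    SequenceRecord, global_align, write_fasta)

BASES = np.array(list("ACGT"))

#: Fixed region layout of the synthetic short-type ancestor (611 bp).
SHORT_REGIONS = ItsRegions(its1=(0, 220), r58s=(220, 380), its2=(380, 611))
#: Offsets of the three conserved motifs inside the ancestor.
MOTIF_OFFSETS = {"motif1": 230, "motif2": 290, "motif3": 340}
#: 13-bp insertion locus (inside ITS1) of the long-type ancestor.
THIRTEENMER_POS = 100


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs; probabilities in [0, 1]."""

    seed: int = 0
    n_accessions: int = 33
    clone_n_range: tuple[int, int] = (7, 20)
    #: probability a sampled clone carries the minor copy (binomial)
    minor_fraction: float = 0.15
    #: functional substitution rate, events/site since the ancestor
    base_substitution_rate: float = 0.003
    #: multiplier on the functional rate for pseudogene copies
    pseudogenization_rate: float = 20.0
    #: probability a pseudogene substitution targets A/T (GC erosion)
    gc_erosion_bias: float = 0.8
    #: per-motif probability a pseudogene's motif is knocked out
    motif_knockout_prob: float = 0.5
    #: pseudogene indel events/site
    indel_rate: float = 0.001
    #: probability a pure accession's lineage is long-type
    thirteenmer_insert_prob: float = 0.15
    #: probability a hybrid's minor copy is a pseudogene (vs functional)
    minor_pseudogene_prob: float = 0.8
    #: probability a pseudogene relic is recombinant
    recomb_prob: float = 0.2
    #: probability an accession is a hybrid carrying a minor copy
    hybridization_prob: float = 0.4
    #: divergence (subs/site) between the clade I and clade II cpDNA pools
    cpdna_divergence: float = 0.01
    #: among clade-II mothers, probability the relic is pseudogroup 2
    pattern3_prob: float = 3.0 / 7.0
    #: per-clone probability of one PCR miscall substitution
    pcr_error_prob: float = 0.05
    #: diagnostic substitutions separating the long-type ancestor
    n_diagnostic_subs: int = 20
    #: shared marker substitutions defining each pseudogroup lineage
    n_pseudogroup_markers: int = 8
    trnLF_length: int = 921
    trnTL_length: int = 1078

    def __post_init__(self):
        for name in ("minor_fraction", "gc_erosion_bias",
                     "motif_knockout_prob", "thirteenmer_insert_prob",
                     "minor_pseudogene_prob", "recomb_prob",
                     "hybridization_prob", "pattern3_prob",
                     "pcr_error_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class AccessionTruth:
    accession_name: str
    maternal_clade: str                  # "clade I" | "clade II"
    composition: str                     # pure_short | pure_long |
                                         # hybrid_functional | hybrid_pseudogene
    functional_classes: tuple[str, ...]
    pseudogene_id: str | None = None
    pseudogene_sampled: bool = False
    pseudogroup: str | None = None
    recombinant: bool = False
    recomb_breakpoint: int | None = None  # alignment column of the splice
    category: str = "aAA"
    minor_support: int = 0
    n_clones: int = 0


@dataclass
class AccessionSim:
    clone_set: CloneSet
    trnLF: SequenceRecord
    trnTL: SequenceRecord
    truth: AccessionTruth


@dataclass
class SimDataset:
    config: SimConfig
    short_ref: SequenceRecord
    long_ref: SequenceRecord
    regions: ItsRegions
    accessions: list[AccessionSim]
    outgroup_its: SequenceRecord = None
    outgroup_trnLF: SequenceRecord = None
    outgroup_trnTL: SequenceRecord = None

    @property
    def truths(self) -> list[AccessionTruth]:
        return [a.truth for a in self.accessions]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def simulate_ancestors(cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[SequenceRecord, SequenceRecord, ItsRegions]:
    """Build the annotated short-type and long-type ancestral ITS.

    The short ancestor is 611 bp with a GC-rich spacer background and
    the three conserved motifs verbatim in its 5.8S; the long ancestor
    adds one of the known 13-bp alleles inside ITS1 plus diagnostic
    substitutions, giving 624 bp.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = SHORT_REGIONS.its2[1]
    seq = list(_random_seq(rng, n, gc=0.60))
    for mid, off in MOTIF_OFFSETS.items():
        seq[off:off + len(MOTIFS[mid])] = list(MOTIFS[mid])
    short = "".join(seq)
    allele = KNOWN_THIRTEENMERS[rng.integers(0, len(KNOWN_THIRTEENMERS))]
    long_seq = list(short[:THIRTEENMER_POS] + allele
                    + short[THIRTEENMER_POS:])
    protected = _protected_positions(short, offset_shift=0)
    candidates = [i for i in range(len(long_seq))
                  if not (THIRTEENMER_POS <= i < THIRTEENMER_POS + 13)
                  and (i - 13 if i >= THIRTEENMER_POS + 13 else i)
                  not in protected]
    picks = rng.choice(len(candidates), size=cfg.n_diagnostic_subs,
                       replace=False)
    # diagnostic substitutions are GC-preserving swaps: the long type is a
    # functional lineage, so its divergence keeps base composition intact
    swap = {"G": "C", "C": "G", "A": "T", "T": "A"}
    for p in picks:
        i = candidates[p]
        long_seq[i] = swap[long_seq[i]]
    short_ref = SequenceRecord(id="short_ancestor", residues=short,
                               molecule="ITS")
    long_ref = SequenceRecord(id="long_ancestor",
                              residues="".join(long_seq), molecule="ITS")
    return short_ref, long_ref, SHORT_REGIONS


def _protected_positions(residues: str, offset_shift: int = 0) -> set[int]:
    """Positions of the best motif occurrences (shielded in functional copies)."""
    protected: set[int] = set()
    for motif in MOTIFS.values():
        best_d, best_pos = len(motif) + 1, -1
        for start in range(len(residues) - len(motif) + 1):
            d = sum(x != y for x, y in zip(residues[start:start + len(motif)],
                                           motif))
            if d < best_d:
                best_d, best_pos = d, start
        if best_pos >= 0:
            protected.update(range(best_pos, best_pos + len(motif)))
    return protected


def evolve_copy(ref: SequenceRecord, kind: str, cfg: SimConfig,
                rng: np.random.Generator,
                copy_id: str | None = None) -> SequenceRecord:
    """Evolve one ITS copy from an ancestral reference.

    functional: substitutions at the base rate, motif sites protected,
    GC-preserving proposals (G<->C, A<->T swaps).  pseudogene: rate x
    pseudogenization_rate with the GC-erosion target bias, motifs
    knocked out with motif_knockout_prob each, and small (1–2 bp)
    indels at indel_rate.
    """
    if kind not in ("functional", "pseudogene"):
        raise ValueError(f"unknown copy kind {kind!r}")
    seq = list(ref.residues)
    protected = _protected_positions(ref.residues)
    rate = cfg.base_substitution_rate
    if kind == "pseudogene":
        rate *= cfg.pseudogenization_rate
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    swap = {"G": "C", "C": "G", "A": "T", "T": "A"}
    for i in hit:
        i = int(i)
        if kind == "functional":
            if i in protected:
                continue
            seq[i] = swap[seq[i]]
        else:
            if rng.random() < cfg.gc_erosion_bias:
                seq[i] = rng.choice([b for b in "AT" if b != seq[i]] or ["A"])
            else:
                seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    if kind == "pseudogene":
        for motif in MOTIFS.values():
            if rng.random() < cfg.motif_knockout_prob:
                start = ref.residues.find(motif)
                if start < 0:
                    continue
                picks = rng.choice(len(motif), size=3, replace=False)
                for p in picks:
                    i = start + int(p)
                    seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
        n_indels = rng.poisson(cfg.indel_rate * len(seq))
        for _ in range(n_indels):
            length = 1 if rng.random() < 0.7 else 2
            if rng.random() < 0.5 and len(seq) > length + 1:
                pos = int(rng.integers(0, len(seq) - length))
                del seq[pos:pos + length]
            else:
                pos = int(rng.integers(0, len(seq)))
                seq[pos:pos] = list(_random_seq(rng, length, gc=0.4))
    return SequenceRecord(id=copy_id or f"{ref.id}_{kind}",
                          residues="".join(seq), molecule="ITS")


def make_recombinant(shortseq: SequenceRecord, longseq: SequenceRecord,
                     breakpoint: int, scoring: Scoring = DEFAULT_SCORING,
                     copy_id: str | None = None) -> SequenceRecord:
    """Splice two copies at an alignment column.

    Left of the breakpoint comes from shortseq, right from longseq
    (columns of their pairwise global alignment).  breakpoint 0 returns
    longseq's residues; breakpoint == alignment length returns shortseq's.
    """
    aln = global_align(shortseq, longseq, scoring)
    if not 0 <= breakpoint <= aln.length:
        raise ValueError(f"breakpoint {breakpoint} outside alignment span "
                         f"[0, {aln.length}]")
    left = aln.records[0].residues[:breakpoint]
    right = aln.records[1].residues[breakpoint:]
    residues = (left + right).replace("-", "")
    return SequenceRecord(id=copy_id or f"{shortseq.id}x{longseq.id}",
                          residues=residues, molecule="ITS")


def _mutate(residues: str, rng: np.random.Generator, n_subs: int) -> str:
    seq = list(residues)
    if n_subs <= 0:
        return residues
    picks = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for p in picks:
        i = int(p)
        seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(seq)


@dataclass
class _CpdnaPools:
    """Maternal haplotype pools for the two cpDNA regions."""

    ancestor_LF: str
    ancestor_TL: str
    cladeI_LF: str
    cladeI_TL: str
    cladeII_LF: str
    cladeII_TL: str
    subclade_LF: str
    subclade_TL: str
    outgroup_LF: str
    outgroup_TL: str


def _build_cpdna_pools(cfg: SimConfig, rng: np.random.Generator) -> _CpdnaPools:
    anc_lf = _random_seq(rng, cfg.trnLF_length, gc=0.35)
    anc_tl = _random_seq(rng, cfg.trnTL_length, gc=0.35)
    total = cfg.trnLF_length + cfg.trnTL_length
    n_div = max(4, int(round(cfg.cpdna_divergence * total)))
    # clade I sits close to the ancestor but carries its own shared markers
    ci_lf = _mutate(anc_lf, rng, max(2, n_div // 4))
    ci_tl = _mutate(anc_tl, rng, max(2, n_div // 4))
    cii_lf = _mutate(anc_lf, rng, n_div)
    cii_tl = _mutate(anc_tl, rng, n_div)
    sub_lf = _mutate(cii_lf, rng, 3)
    sub_tl = _mutate(cii_tl, rng, 3)
    out_lf = _mutate(anc_lf, rng, int(0.05 * cfg.trnLF_length))
    out_tl = _mutate(anc_tl, rng, int(0.05 * cfg.trnTL_length))
    return _CpdnaPools(anc_lf, anc_tl, ci_lf, ci_tl, cii_lf, cii_tl,
                       sub_lf, sub_tl, out_lf, out_tl)


def _category(composition: str, maternal: str) -> str:
    if composition == "pure_short":
        return "aAA"
    if composition == "pure_long":
        return "bBB"
    if composition == "hybrid_functional":
        return "aAA"
    return "aAA*B" if maternal == "clade I" else "bAA*B"


def sample_accession(cfg: SimConfig, rng: np.random.Generator,
                     name: str, ancestors: tuple, pg_refs: dict,
                     pools: _CpdnaPools) -> AccessionSim:
    """Draw one accession: copy composition, clones, cpDNA, truth entry."""
    short_ref, long_ref, _regions = ancestors
    maternal = "clade I" if rng.random() < 0.5 else "clade II"
    is_hybrid = rng.random() < cfg.hybridization_prob
    pseudogroup = None
    pseudo_id = None
    recombinant = False
    breakpoint = None
    if not is_hybrid:
        long_lineage = rng.random() < cfg.thirteenmer_insert_prob
        composition = "pure_long" if long_lineage else "pure_short"
        ref = long_ref if long_lineage else short_ref
        copies = [evolve_copy(ref, "functional", cfg, rng,
                              copy_id=f"{name}_major")]
        functional_classes = ("long",) if long_lineage else ("short",)
    else:
        major = evolve_copy(short_ref, "functional", cfg, rng,
                            copy_id=f"{name}_major")
        if rng.random() < cfg.minor_pseudogene_prob:
            composition = "hybrid_pseudogene"
            if maternal == "clade I":
                pseudogroup = "pseudogroup 2"
            else:
                pseudogroup = ("pseudogroup 2"
                               if rng.random() < cfg.pattern3_prob
                               else "pseudogroup 1")
            pg_ref = pg_refs[pseudogroup]
            pseudo_id = f"{name}_minor"
            if rng.random() < cfg.recomb_prob:
                recombinant = True
                aln_len = global_align(short_ref, pg_ref).length
                breakpoint = int(rng.integers(aln_len // 4,
                                              3 * aln_len // 4))
                base = make_recombinant(short_ref, pg_ref, breakpoint,
                                        copy_id=pseudo_id)
            else:
                base = pg_ref
            minor = evolve_copy(base, "pseudogene", cfg, rng,
                                copy_id=pseudo_id)
            functional_classes = ("short",)
        else:
            composition = "hybrid_functional"
            minor = evolve_copy(long_ref, "functional", cfg, rng,
                                copy_id=f"{name}_minor")
            functional_classes = ("short", "long")
        copies = [major, minor]
    n = int(rng.integers(cfg.clone_n_range[0], cfg.clone_n_range[1] + 1))
    if len(copies) == 2:
        minor_support = int(rng.binomial(n, cfg.minor_fraction))
        minor_support = min(minor_support, n - 1)
    else:
        minor_support = 0
    clones = []
    for k in range(n):
        src = copies[1] if k < minor_support else copies[0]
        residues = src.residues
        if rng.random() < cfg.pcr_error_prob:
            residues = _mutate(residues, rng, 1)
        clones.append(SequenceRecord(id=f"{name}_clone{k + 1}",
                                     residues=residues, molecule="ITS"))
    # maternal cpDNA haplotype with private variation
    if maternal == "clade I":
        lf_base, tl_base = pools.cladeI_LF, pools.cladeI_TL
        private = 1
    else:
        in_sub = rng.random() < 0.4
        lf_base = pools.subclade_LF if in_sub else pools.cladeII_LF
        tl_base = pools.subclade_TL if in_sub else pools.cladeII_TL
        private = 3
    trnLF = SequenceRecord(
        id=name, residues=_mutate(lf_base, rng, int(rng.integers(0, private + 1))),
        molecule="trnL-trnF")
    trnTL = SequenceRecord(
        id=name, residues=_mutate(tl_base, rng, int(rng.integers(0, private + 1))),
        molecule="trnT-trnL")
    truth = AccessionTruth(
        accession_name=name, maternal_clade=maternal,
        composition=composition, functional_classes=functional_classes,
        pseudogene_id=pseudo_id,
        pseudogene_sampled=(pseudo_id is not None and minor_support > 0),
        pseudogroup=pseudogroup, recombinant=recombinant,
        recomb_breakpoint=breakpoint,
        category=_category(composition, maternal),
        minor_support=minor_support, n_clones=n)
    return AccessionSim(
        clone_set=CloneSet(accession_name=name, clones=tuple(clones)),
        trnLF=trnLF, trnTL=trnTL, truth=truth)


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Simulate a full study: ancestors, pseudogroup lineages, accessions."""
    rng = np.random.default_rng(cfg.seed)
    short_ref, long_ref, regions = simulate_ancestors(cfg, rng)
    # two relic lineages: shared marker substitutions on the long ancestor
    pg_refs = {}
    for pg in ("pseudogroup 1", "pseudogroup 2"):
        pg_refs[pg] = SequenceRecord(
            id=pg.replace(" ", ""),
            residues=_mutate(long_ref.residues, rng,
                             cfg.n_pseudogroup_markers),
            molecule="ITS")
    pools = _build_cpdna_pools(cfg, rng)
    accessions = [
        sample_accession(cfg, rng, f"ACC{i + 1:03d}",
                         (short_ref, long_ref, regions), pg_refs, pools)
        for i in range(cfg.n_accessions)
    ]
    out_its = SequenceRecord(
        id="outgroup", residues=_mutate(long_ref.residues, rng,
                                        int(0.08 * len(long_ref))),
        molecule="ITS")
    return SimDataset(
        config=cfg, short_ref=short_ref, long_ref=long_ref, regions=regions,
        accessions=accessions, outgroup_its=out_its,
        outgroup_trnLF=SequenceRecord(id="outgroup",
                                      residues=pools.outgroup_LF,
                                      molecule="trnL-trnF"),
        outgroup_trnTL=SequenceRecord(id="outgroup",
                                      residues=pools.outgroup_TL,
                                      molecule="trnT-trnL"))


def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    """Emit clones/*.fasta, cpdna/*.fasta, truth.json and metadata.tsv."""
    outdir = Path(outdir)
    (outdir / "clones").mkdir(parents=True, exist_ok=True)
    (outdir / "cpdna").mkdir(parents=True, exist_ok=True)
    rows = []
    lf_records, tl_records = [], []
    for acc in ds.accessions:
        write_fasta(acc.clone_set.clones,
                    outdir / "clones" / f"{acc.truth.accession_name}.fasta")
        lf_records.append(acc.trnLF)
        tl_records.append(acc.trnTL)
        rows.append({
            "accession_name": acc.truth.accession_name,
            "clone_number": acc.clone_set.n_clones,
            "maternal_clade": acc.truth.maternal_clade,
            "composition": acc.truth.composition,
        })
    lf_records.append(ds.outgroup_trnLF)
    tl_records.append(ds.outgroup_trnTL)
    write_fasta(lf_records, outdir / "cpdna" / "trnL-trnF.fasta")
    write_fasta(tl_records, outdir / "cpdna" / "trnT-trnL.fasta")
    write_fasta([ds.short_ref, ds.long_ref, ds.outgroup_its],
                outdir / "ancestors.fasta")
    truth = {t.accession_name: dataclasses.asdict(t) for t in ds.truths}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    header = "\t".join(rows[0].keys())
    lines = [header] + ["\t".join(str(v) for v in r.values()) for r in rows]
    (outdir / "metadata.tsv").write_text("\n".join(lines) + "\n")
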