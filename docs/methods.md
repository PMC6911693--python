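# Methods

This note documents the models and procedures behind `pseudits`, the
assumptions they make, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate.

## The biological setting and its operationalization

Nuclear ribosomal DNA occurs in tandem arrays that concerted evolution
normally homogenizes.  When homogenization is incomplete — after
hybridization, polyploidization, or with multiple NOR loci — an
individual can carry, besides its functional ITS copies, relic copies
released from selective constraint.  Relics accumulate substitutions
faster, drift AT-rich (loss of the GC bias maintained in functional
rDNA), degrade the conserved 5.8S motifs, fold into less stable
secondary structures, and may change length.  `pseudits` turns each of
these signatures into an explicit, thresholded criterion and combines
them into a reproducible verdict, then asks whether the relics'
phylogenetic placement (pseudogroups in the ITS tree) tracks the
maternally inherited chloroplast haplotype (clades I/II of the
trnL-trnF + trnT-trnL tree) — the footprint expected if relics enter a
lineage through its seed parent.

## Variant typing

* **Clustering.** Single linkage on substitution distance with a
  configurable tolerance, default 2, absorbing PCR miscalls into their
  source copy.  Clones of different lengths are never merged: a 1-bp
  indel is treated as a real variant boundary, because the analysis
  treats copies differing by a single substitution as distinct when
  their support is consistent, and because per-cluster majority-rule
  consensus is only well defined column-wise at equal length.  The
  tolerance is exposed (`max_intra_diff`) since the boundary between
  "PCR noise" and "real 1-SNP copy" is a judgement call.
* **Heterozygosity.** Defined as the percentage of clones *not*
  carrying the top-supported variant, reported to two decimals.  This
  is the definition that reproduces the published per-accession values
  exactly from clone counts (1/7 → 14.29 %, 8/20 → 40 %, 1/19 → 5.26 %,
  4/16 → 25 %, 9/20 → 45 %); it is an inference from that arithmetic,
  not a formula quoted from the study.
* **Length classes and labels.** Short vs long at 618 bp, the midpoint
  of the observed 611 vs 624–631 gap.  Classes with ≥ 2 members are
  numbered by support (α1, α2 / β1, β2); a singleton class is numbered
  only when it holds the accession's majority copy, matching the
  published labelling (e.g. an accession with a 611-bp majority and a
  624-bp minority is α1 + β).

## Pseudogene screen

* **GC content** per region over A/C/G/T only (N excluded from numerator
  and denominator).
* **Motifs.** The three angiosperm-conserved 5.8S motifs
  (GAATTGCAGAATCC, TTTGAACGCA, CGATGAAGAACGTAGC) searched as best
  Hamming occurrences within the annotated 5.8S ± 5 bp; found iff
  ≤ `motif_max_mismatch` (default 1) substitutions.
* **Folding model.** Minimum free energy over nested structures under a
  deliberately simplified nearest-neighbor model (packaged, versioned
  in `data/energy_model.json`): a stack of two adjacent pairs
  contributes −(s₁+s₂) with strengths GC = 1.65, AU = 0.55, GU = 0.25
  (so GC/GC = −3.3, AU/AU = −1.1, GU/GU = −0.5, mixed stacks additive);
  each hairpin-closing pair costs +4.0; hairpin loops need ≥ 3 unpaired
  bases; all other loops and unpaired bases are free.  DNA is folded as
  its transcript (T→U).  Computed by an O(n³) interval DP (numba), with
  traceback.  These are *not* full thermodynamic (Turner) energies and
  are never interpreted absolutely: the screen uses only the
  minor-minus-major difference, so constant model bias cancels.  An
  `energy_fn` hook lets users substitute an external folding engine.
* **Decision rule.** pseudogene iff `motif_loss` OR ≥ 2 of
  {`gc_deficit`: GC lower than the major copy by ≥ 0.02 in ≥ 1 of
  ITS1/5.8S/ITS2; `mfe_deficit`: full-ITS MFE less stable by ≥ 2.0
  model units; `length_anomaly`: > 3 bp off the modal class length}.
  Motif loss is diagnostic on its own (a degraded ribosomal gene copy);
  the soft criteria require corroboration because each can arise singly
  from ordinary divergence between functional copies.  The δ defaults
  were calibrated on the simulator so that functional–functional
  contrasts stay below threshold while relic contrasts exceed it; they
  live in `ScreenThresholds` and in the pipeline config.
* **Single-copy accessions** have no internal contrast and are screened
  against the median profile of all majority copies of their length
  class (`consensus_profile`).

## Recombination scan (MaxChi)

Informative sites are alignment columns where the two candidate parents
differ and the query matches exactly one (gap/N columns dropped).  For
every cut between consecutive informative sites the 2×2 left/right ×
parent-A/B table's chi-square (no continuity correction) is computed;
the maximum over cuts is the statistic, its cut the breakpoint estimate
(reported both as a cut index and as the midpoint alignment column).
Significance by permutation of the site assignments,
p = (1 + #{permuted maxima ≥ observed}) / (1 + N), which cannot return
0.  MaxChi was chosen as the single detector because it is
self-contained and admits an exact small-instance oracle; it stands in
for multi-method ensemble detectors, and presence calls should be read
as a re-analysis, not a replication of any particular tool.

## Phylogenies

Distance trees deliberately replace likelihood/Bayesian machinery: at
within-genus divergences the clade structure of interest is recoverable
by neighbor-joining on K2P distances, and every step then has an exact
oracle (NJ is consistent on additive matrices).  Details: pairwise
deletion for gaps/N (preserving signal at the 13-bp indel); saturated
pairs (non-positive log argument) set to 1.05× the largest finite
distance with a warning; deterministic Q-criterion tie-breaking by
taxon label; negative NJ branch lengths clamped to 0 with the deficit
moved to the sister edge; bootstrap by site resampling with bipartition
frequencies mapped onto the full-data tree; rooting on a user-named
outgroup; clades labelled as the smallest clade containing an anchor
set, flagged when it swallows another label's anchor.  Gamma rate
heterogeneity is not modelled — an accepted approximation of this
stand-in.

## Concordance

Pattern ids are a pure function of (pseudogroup, cpDNA clade):
(pg 2, I) → 1, (pg 1, II) → 2, (pg 2, II) → 3, anything else
unclassified.  Association between pseudogroup and clade is tested by
permuting clade labels and comparing the r×c chi-square (add-one
p-value).  The evolutionary categories operationalize the maternal
superscript as cpDNA clade membership: aAA (short functional only),
bBB (long functional only), aAA\*B / bAA\*B (short functional +
long-type relic via a clade-I / clade-II mother).  Accessions with two
functional copies and no relic are aAA with a hybrid flag rather than a
fifth category; accessions whose relics fall in both pseudogroups are
emitted as unclassified with a note.

## The simulator: what it emulates, and what it does not

`synthetic_data` generates a 611-bp short-type ancestor (annotated
ITS1 0–220, 5.8S 220–380 with the three motifs verbatim, ITS2 380–611;
60 % GC background) and a long-type ancestor adding one known 13-bp
allele inside ITS1 plus 20 GC-preserving diagnostic substitutions
(624 bp).  Accessions are pure (one functional lineage; long-type with
probability 0.15) or hybrid (probability 0.4 — matching 14/33
polymorphic accessions); a hybrid's minor copy is a relic with
probability 0.8 (11/14) or a second functional copy; relics are
recombinant splices with probability 0.2 (2/11); clade-II mothers give
pseudogroup-2 relics with probability 3/7 (the observed pattern-3 vs
pattern-2 ratio), clade-I mothers always pseudogroup 2.  Functional
copies evolve at 3·10⁻³ substitutions/site with GC-preserving proposals
and protected motifs; relics at 20× that rate with a 0.8 probability of
an AT-targeted (GC-eroding) substitution, per-motif knockout
probability 0.5, and 10⁻³ indels/site (1–2 bp).  Clones are drawn with
a binomial minor fraction (0.15, near the mean of the published
per-accession values) plus a 5 % chance of one PCR miscall per clone.
cpDNA pools: clade I close to the ancestor, clade II carrying ~1 %
shared divergence plus a subclade, an outgroup at 5 %.  One numpy
Generator is threaded through everything; a `SimConfig` fixes the
output byte for byte.  The substitution rates are stated assumptions —
the source study publishes none.

Not emulated: explicit gene-conversion dynamics across generations,
polyploid subgenome phasing, chromatogram-level noise, alignment
ambiguity from repetitive sequence, and rate variation among sites.
Passing recovery tests therefore demonstrate that the pipeline's logic
is correct under its own model of the data, not that real clone sets
are this clean.

## Numerical and determinism choices

0-based half-open coordinates everywhere.  Alignment scoring
match +1 / mismatch −1 / gap open −4 / extend −1 (a gap of length L
costs open + (L−1)·extend), ties broken substitution > gap-in-b >
gap-in-a.  The progressive MSA canonically re-orders its input before
building the k-mer/UPGMA guide tree, so column content is independent
of record order.  Consensus ties go to the alphabetically smallest
base.  All permutation tests and bootstraps take explicit seeds; the
pipeline writes every seed and threshold it used into its report and a
sha256 MANIFEST of every artifact.

## Problem sizes used in the test suite

The recovery tests run 200 simulated accessions for screen
sensitivity/specificity, ~25 replicate studies for planted-breakpoint
recovery, 12 replicate studies for maternal-clade monophyly, 1000
random sequences (length ≤ 12) against the exhaustive folding oracle,
100 random 6-taxon additive matrices for NJ, and 1000 null trials for
MaxChi calibration — sizes chosen so the whole suite completes in about
a minute while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

The folding energies are model units, not kcal/mol; absolute MFE values
are not comparable to thermodynamic folders.  The screen's thresholds
are calibrated to the simulator's conditions and should be re-examined
on real data with known relics.  NJ topology is a stand-in for
likelihood trees; deep or rate-heterogeneous divergences would warrant
the real thing.  MaxChi detects single dominant breakpoints;
multi-crossover mosaics are out of scope.
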