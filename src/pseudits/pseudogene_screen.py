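"""Multi-criterion ITS pseudogene screening.

A relic (non-functional) rDNA copy evolves without the constraints that
keep functional ITS sequences GC-rich, structured and motif-bearing.
The screen therefore profiles every consensus copy on four axes —
per-region GC content, presence of the three angiosperm-conserved 5.8S
motifs, predicted secondary-structure minimum free energy (MFE), and
length — and classifies minor copies relative to their accession's
major (top-supported) copy.

The folding energies come from a deliberately simplified
nearest-neighbor stacking model (packaged as a versioned data file),
not from a full thermodynamic rule set: the screen only ever compares a
minor copy with its major copy, so constant model bias cancels.  An
external folding engine's energies can be substituted through the
``energy_fn`` hook of :func:`profile_copy`.
"""

from __future__ import annotations

import functools
import importlib.resources
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _kernels
from .clone_analysis import CopyVariant
from .seqio import ItsRegions, SequenceRecord

#: The three angiosperm-conserved 5.8S motifs used as functionality
#: diagnostics.
MOTIFS: Mapping[str, str] = {
    "motif1": "GAATTGCAGAATCC",
    "motif2": "TTTGAACGCA",
    "motif3": "CGATGAAGAACGTAGC",
}

#: Slack (bp) around the annotated 5.8S interval when searching motifs.
MOTIF_SLACK = 5

_PAIR_NAMES = ("GC", "CG", "AU", "UA", "GU", "UG")


def _load_energy_model() -> dict:
    path = importlib.resources.files("pseudits").joinpath(
        "data", "energy_model.json")
    return json.loads(path.read_text())


@functools.lru_cache(maxsize=1)
def _energy_tables() -> tuple[np.ndarray, np.ndarray, float]:
    model = _load_energy_model()
    pair_type = np.full((5, 5), -1, dtype=np.int64)
    enc = {"A": 0, "C": 1, "G": 2, "U": 3}
    for idx, name in enumerate(_PAIR_NAMES):
        pair_type[enc[name[0]], enc[name[1]]] = idx
    strengths = model["pair_strengths"]
    stack = np.zeros((6, 6))
    for i, pi in enumerate(_PAIR_NAMES):
        for j, pj in enumerate(_PAIR_NAMES):
            stack[i, j] = -(strengths[pi] + strengths[pj])
    return pair_type, stack, float(model["hairpin_penalty"])


@dataclass
class MotifHit:
    found: bool
    mismatches: int
    position: int  # ungapped 0-based start of the best occurrence; -1 if none


@dataclass
class RegionProfile:
    """GC, length, motif and MFE profile of one ITS copy."""

    copy_id: str
    gc: dict[str, float]          # ITS1, 5.8S, ITS2, full -> fraction
    length: dict[str, int]
    motif_hits: dict[str, MotifHit]
    mfe: dict[str, float]         # ITS1, ITS2, full -> model energy (<= 0)
    length_class: str | None = None


@dataclass
class ScreenThresholds:
    """Decision thresholds for the pseudogene rule (simulator-calibrated)."""

    gc_delta: float = 0.02        # required GC deficit in >= 1 spacer region
    mfe_delta: float = 2.0        # required full-ITS destabilization (model units)
    length_tolerance: int = 3     # bp around the modal class length
    motif_max_mismatch: int = 1
    modal_lengths: dict[str, int] = field(
        default_factory=lambda: {"short": 611, "long": 624})


@dataclass
class PseudogeneCall:
    copy_id: str
    criteria: dict[str, bool]     # motif_loss, gc_deficit, mfe_deficit, length_anomaly
    deltas: dict[str, float]
    verdict: str                  # "pseudogene" | "functional"


def gc_content(seq: SequenceRecord | str, interval: tuple[int, int]) -> float:
    """(G+C) / (A+C+G+T) over a half-open interval; N excluded entirely."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    s, e = interval
    if not (0 <= s <= e <= len(residues)):
        raise ValueError(f"interval {interval} outside sequence of length "
                         f"{len(residues)}")
    window = residues[s:e]
    counted = sum(window.count(b) for b in "ACGT")
    if counted == 0:
        raise ValueError(f"interval {interval}: no countable bases")
    return (window.count("G") + window.count("C")) / counted


def scan_motifs(seq: SequenceRecord | str, regions: ItsRegions,
                motifs: Mapping[str, str] = MOTIFS,
                max_mismatch: int = 1) -> dict[str, MotifHit]:
    """Best Hamming-distance occurrence of each conserved motif.

    The search window is the annotated 5.8S interval widened by
    MOTIF_SLACK on both sides; a motif is found iff its best occurrence
    has <= max_mismatch substitutions (leftmost best occurrence wins).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    lo = max(0, regions.r58s[0] - MOTIF_SLACK)
    hi = min(len(residues), regions.r58s[1] + MOTIF_SLACK)
    window = residues[lo:hi]
    hits: dict[str, MotifHit] = {}
    for mid, motif in motifs.items():
        best_d, best_pos = len(motif) + 1, -1
        for start in range(0, len(window) - len(motif) + 1):
            d = sum(x != y for x, y in zip(window[start:start + len(motif)],
                                           motif))
            if d < best_d:
                best_d, best_pos = d, lo + start
        found = best_pos >= 0 and best_d <= max_mismatch
        hits[mid] = MotifHit(found=found,
                             mismatches=best_d if best_pos >= 0 else -1,
                             position=best_pos)
    return hits


def fold_mfe(seq: SequenceRecord | str,
             return_structure: bool = False):
    """Minimum free energy over nested secondary structures.

    DNA is folded as its RNA transcript (T read as U).  The model:
    stacking energies for adjacent nested pairs from the packaged table,
    +hairpin penalty per hairpin-closing pair (loops need >= 3 unpaired
    bases), all other loops and unpaired bases contribute 0.  The open
    chain scores 0, so the MFE is always <= 0.

    With return_structure=True also returns the optimal pair list.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    enc = _kernels.encode_seq(residues.replace("T", "U"))
    pair_type, stack, hairpin = _energy_tables()
    n = len(enc)
    if n < 5:
        return (0.0, []) if return_structure else 0.0
    V, Y, YX = _kernels.fold_fill(enc, pair_type, stack, hairpin)
    mfe = float(min(0.0, Y[0, n - 1]))
    if not return_structure:
        return mfe
    pairs: list[tuple[int, int]] = []
    if mfe < 0.0:
        _traceback_Y(enc, pair_type, stack, hairpin, V, Y, YX, 0, n - 1, pairs)
    return mfe, sorted(pairs)


_EPS = 1e-9


def _traceback_Y(seq, pair_type, stack, hairpin, V, Y, YX, i, j, pairs):
    if j - i < 4 or Y[i, j] >= _kernels.POS_INF:
        return
    if abs(Y[i, j] - V[i, j]) < _EPS:
        _traceback_V(seq, pair_type, stack, hairpin, V, Y, YX, i, j, pairs)
    else:
        _traceback_YX(seq, pair_type, stack, hairpin, V, Y, YX, i, j, pairs)


def _traceback_YX(seq, pair_type, stack, hairpin, V, Y, YX, i, j, pairs):
    target = YX[i, j]
    if j - i >= 5 and abs(Y[i + 1, j] - target) < _EPS:
        _traceback_Y(seq, pair_type, stack, hairpin, V, Y, YX, i + 1, j, pairs)
        return
    for k in range(i + 4, j):
        if V[i, k] >= _kernels.POS_INF:
            continue
        rest = 0.0
        rest_pairs = False
        if k + 1 < j and Y[k + 1, j] < 0.0:
            rest = Y[k + 1, j]
            rest_pairs = True
        if abs(V[i, k] + rest - target) < _EPS:
            _traceback_V(seq, pair_type, stack, hairpin, V, Y, YX, i, k, pairs)
            if rest_pairs:
                _traceback_Y(seq, pair_type, stack, hairpin, V, Y, YX,
                             k + 1, j, pairs)
            return
    raise AssertionError("traceback failed (YX)")


def _traceback_V(seq, pair_type, stack, hairpin, V, Y, YX, i, j, pairs):
    pairs.append((i, j))
    target = V[i, j]
    if abs(target - hairpin) < _EPS:
        return
    if j - i >= 6:
        pt = pair_type[seq[i], seq[j]]
        pt_in = pair_type[seq[i + 1], seq[j - 1]]
        if pt_in >= 0 and V[i + 1, j - 1] < _kernels.POS_INF and \
                abs(stack[pt, pt_in] + V[i + 1, j - 1] - target) < _EPS:
            _traceback_V(seq, pair_type, stack, hairpin, V, Y, YX,
                         i + 1, j - 1, pairs)
            return
        if abs(YX[i + 1, j - 1] - target) < _EPS:
            _traceback_YX(seq, pair_type, stack, hairpin, V, Y, YX,
                          i + 1, j - 1, pairs)
            return
    raise AssertionError("traceback failed (V)")


def profile_copy(copy: CopyVariant | SequenceRecord, regions: ItsRegions,
                 motif_max_mismatch: int = 1,
                 energy_fn: Callable[[str], float] | None = None
                 ) -> RegionProfile:
    """Assemble the GC / length / motif / MFE profile of one ITS copy.

    energy_fn, if given, replaces the packaged folding model (it receives
    the region's residues and must return an energy).
    """
    if isinstance(copy, CopyVariant):
        record = copy.consensus
        length_class = copy.length_class
    else:
        record = copy
        length_class = None
    fold = energy_fn if energy_fn is not None else fold_mfe
    intervals = regions.as_dict()
    gc = {name: gc_content(record, iv) for name, iv in intervals.items()}
    length = {name: iv[1] - iv[0] for name, iv in intervals.items()}
    mfe = {name: float(fold(record.residues[iv[0]:iv[1]]))
           for name, iv in intervals.items() if name in ("ITS1", "ITS2", "full")}
    hits = scan_motifs(record, regions, max_mismatch=motif_max_mismatch)
    return RegionProfile(copy_id=record.id, gc=gc, length=length,
                         motif_hits=hits, mfe=mfe, length_class=length_class)


def classify_pseudogene(minor: RegionProfile, major: RegionProfile,
                        thresholds: ScreenThresholds | None = None
                        ) -> PseudogeneCall:
    """Pseudogene decision rule for a minor copy vs its major copy.

    Criteria: motif_loss (any conserved motif unfound), gc_deficit (GC
    lower than the major copy by >= gc_delta in at least one of ITS1 /
    5.8S / ITS2), mfe_deficit (full-ITS folding less stable by >=
    mfe_delta), length_anomaly (length off the modal class length by
    more than length_tolerance).  Verdict is pseudogene iff motif_loss
    or at least two of the other three criteria hold.
    """
    thresholds = thresholds or ScreenThresholds()
    if set(minor.gc) != set(major.gc) or set(minor.mfe) != set(major.mfe):
        raise ValueError("profiles cover different region sets")
    motif_loss = any(not h.found for h in minor.motif_hits.values())
    gc_deltas = {r: major.gc[r] - minor.gc[r] for r in ("ITS1", "5.8S", "ITS2")}
    gc_deficit = any(d >= thresholds.gc_delta for d in gc_deltas.values())
    mfe_delta = minor.mfe["full"] - major.mfe["full"]
    mfe_deficit = mfe_delta >= thresholds.mfe_delta
    cls = minor.length_class or "short"
    modal = thresholds.modal_lengths.get(cls)
    length_delta = (minor.length["full"] - modal) if modal is not None else 0
    length_anomaly = abs(length_delta) > thresholds.length_tolerance
    criteria = {"motif_loss": motif_loss, "gc_deficit": gc_deficit,
                "mfe_deficit": mfe_deficit, "length_anomaly": length_anomaly}
    n_other = sum((gc_deficit, mfe_deficit, length_anomaly))
    verdict = "pseudogene" if (motif_loss or n_other >= 2) else "functional"
    deltas = {f"gc_{r}": d for r, d in gc_deltas.items()}
    deltas["mfe_full"] = mfe_delta
    deltas["length"] = float(length_delta)
    return PseudogeneCall(copy_id=minor.copy_id, criteria=criteria,
                          deltas=deltas, verdict=verdict)


def consensus_profile(profiles: Sequence[RegionProfile]) -> RegionProfile:
    """Element-wise median profile of a set of copies.

    Used as the comparison baseline for accessions holding a single ITS
    copy (no within-accession major/minor contrast): such copies are
    screened against the collection-wide consensus profile of their
    length class.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    gc = {r: float(np.median([p.gc[r] for p in profiles]))
          for r in profiles[0].gc}
    length = {r: int(np.median([p.length[r] for p in profiles]))
              for r in profiles[0].length}
    mfe = {r: float(np.median([p.mfe[r] for p in profiles]))
           for r in profiles[0].mfe}
    hits = {m: MotifHit(found=True, mismatches=0, position=-1)
            for m in profiles[0].motif_hits}
    return RegionProfile(copy_id="<consensus>", gc=gc, length=length,
                         motif_hits=hits, mfe=mfe,
                         length_class=profiles[0].length_class)
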