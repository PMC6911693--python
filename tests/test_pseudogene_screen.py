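"""GC content, motif scanning, the folding model (with an exhaustive
structure-enumeration oracle) and the pseudogene decision rule."""

import numpy as np
import pytest

from pseudits.pseudogene_screen import (MOTIFS, ScreenThresholds,
                                        classify_pseudogene, fold_mfe,
                                        gc_content, profile_copy,
                                        scan_motifs)
from pseudits.seqio import ItsRegions, SequenceRecord

# ---------------------------------------------------------------------------
# independent folding oracle: enumerate every nested structure


_PAIRS = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"),
          ("G", "U"), ("U", "G")}
_STRENGTH = {frozenset(("G", "C")): 1.65, frozenset(("A", "U")): 0.55,
             frozenset(("G", "U")): 0.25}


def _structure_energy(seq, pairs):
    """Energy of a structure under the same model, computed independently:
    stacks are -(strength(outer)+strength(inner)); each hairpin-closing
    pair (no enclosed pairs) costs +4."""
    pairs = set(pairs)
    e = 0.0
    for (i, j) in pairs:
        if (i + 1, j - 1) in pairs:
            e -= (_STRENGTH[frozenset((seq[i], seq[j]))]
                  + _STRENGTH[frozenset((seq[i + 1], seq[j - 1]))])
        if not any(i < k < l < j for (k, l) in pairs):
            e += 4.0
    return e


def _enumerate_structures(seq, i, j):
    """All sets of nested pairs on seq[i..j] (hairpin loops >= 3)."""
    if j - i < 4:
        yield frozenset()
        return
    # i unpaired
    for s in _enumerate_structures(seq, i + 1, j):
        yield s
    # i paired with k
    for k in range(i + 4, j + 1):
        if (seq[i], seq[k]) not in _PAIRS:
            continue
        for inner in _enumerate_structures(seq, i + 1, k - 1):
            for outer in _enumerate_structures(seq, k + 1, j):
                yield inner | outer | {(i, k)}


def brute_force_mfe(residues):
    seq = residues.replace("T", "U")
    best = 0.0
    for s in _enumerate_structures(seq, 0, len(seq) - 1):
        best = min(best, _structure_energy(seq, s))
    return best


# ---------------------------------------------------------------------------


class TestGcContent:
    def test_all_gc(self):
        assert gc_content("GGCC", (0, 4)) == 1.0

    def test_no_gc(self):
        assert gc_content("ATAT", (0, 4)) == 0.0

    def test_motif1_gc(self):
        m = MOTIFS["motif1"]
        assert gc_content(m, (0, len(m))) == pytest.approx(6 / 14)

    def test_n_excluded(self):
        assert gc_content("GCNN", (0, 4)) == 1.0

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            gc_content("NNNN", (0, 4))


REGIONS = ItsRegions(its1=(0, 30), r58s=(30, 110), its2=(110, 140))


def _with_motifs(rng):
    seq = list("".join(rng.choice(list("ACGT"), size=140)))
    seq[35:35 + 14] = list(MOTIFS["motif1"])
    seq[60:60 + 10] = list(MOTIFS["motif2"])
    seq[80:80 + 16] = list(MOTIFS["motif3"])
    return "".join(seq)


class TestScanMotifs:
    def test_verbatim_all_found(self, rng):
        hits = scan_motifs(_with_motifs(rng), REGIONS)
        assert all(h.found and h.mismatches == 0 for h in hits.values())
        assert hits["motif1"].position == 35

    def test_one_substitution_tolerated(self, rng):
        seq = list(_with_motifs(rng))
        seq[62] = "A" if seq[62] != "A" else "C"
        hits = scan_motifs("".join(seq), REGIONS, max_mismatch=1)
        assert hits["motif2"].found and hits["motif2"].mismatches == 1

    def test_deleted_motif_not_found(self, rng):
        seq = list(_with_motifs(rng))
        seq[80:96] = list("A" * 16)  # overwrite motif 3
        hits = scan_motifs("".join(seq), REGIONS, max_mismatch=1)
        assert not hits["motif3"].found

    def test_search_restricted_to_58s(self, rng):
        # motif in ITS2, far outside the 5.8S window, must not be found
        seq = list("A" * 140)
        seq[120:120 + 10] = list(MOTIFS["motif2"])
        hits = scan_motifs("".join(seq), REGIONS, max_mismatch=1)
        assert not hits["motif2"].found


class TestFoldMfe:
    def test_unpairable_sequence_zero(self):
        assert fold_mfe("AAAAAAAAAA") == 0.0

    def test_gc_hairpin(self):
        # 3-pair GC hairpin with two GC/GC stacks: 2*(-3.3) + 4.0
        assert fold_mfe("GGGAAACCC") == pytest.approx(-2.6)
        assert fold_mfe("GGGAAACCC") == pytest.approx(
            brute_force_mfe("GGGAAACCC"))

    def test_reverse_complement_pairs(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(5):
            s = "".join(rng.choice(list("ACGT"), size=12))
            rc = "".join(comp[c] for c in reversed(s))
            assert fold_mfe(s + "AAA" + rc) < 0.0

    def test_matches_enumeration_small(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 13))
            s = "".join(rng.choice(list("ACGU"), size=n))
            assert fold_mfe(s) == pytest.approx(brute_force_mfe(s)), s

    def test_monotone_under_extension(self, rng):
        for _ in range(10):
            s = "".join(rng.choice(list("ACGU"), size=30))
            ext = s + "".join(rng.choice(list("ACGU"), size=5))
            assert fold_mfe(ext) <= fold_mfe(s) + 1e-9

    def test_structure_energy_consistent(self, rng):
        """Returned pair list re-scores to the reported energy."""
        for _ in range(10):
            s = "".join(rng.choice(list("GCAU"), size=25))
            e, pairs = fold_mfe(s, return_structure=True)
            assert _structure_energy(s.replace("T", "U"), pairs) == \
                pytest.approx(e)


class TestClassify:
    def _profile(self, rng, **tweaks):
        seq = _with_motifs(rng)
        from pseudits.clone_analysis import CopyVariant
        cv = CopyVariant(consensus=SequenceRecord(id="p", residues=seq),
                         support=5, length_class="short")
        prof = profile_copy(cv, REGIONS)
        for key, val in tweaks.items():
            region, attr = key
            getattr(prof, attr)[region] = val
        return prof

    def test_reflexive_functional(self, rng):
        p = self._profile(rng)
        thr = ScreenThresholds(modal_lengths={"short": 140, "long": 153})
        assert classify_pseudogene(p, p, thr).verdict == "functional"

    def test_motif_loss_overrides(self, rng):
        import copy
        major = self._profile(rng)
        minor = copy.deepcopy(major)
        minor.motif_hits["motif2"].found = False
        thr = ScreenThresholds(modal_lengths={"short": 140, "long": 153})
        call = classify_pseudogene(minor, major, thr)
        assert call.criteria["motif_loss"]
        assert call.verdict == "pseudogene"

    def test_two_soft_criteria_needed(self, rng):
        import copy
        major = self._profile(rng)
        thr = ScreenThresholds(modal_lengths={"short": 140, "long": 153})
        # GC deficit alone: still functional
        minor = copy.deepcopy(major)
        minor.gc["ITS1"] = major.gc["ITS1"] - 0.05
        assert classify_pseudogene(minor, major, thr).verdict == "functional"
        # GC deficit + MFE deficit: pseudogene despite intact motifs
        minor2 = copy.deepcopy(minor)
        minor2.mfe["full"] = major.mfe["full"] + 5.0
        call = classify_pseudogene(minor2, major, thr)
        assert not call.criteria["motif_loss"]
        assert call.verdict == "pseudogene"

    def test_region_mismatch_error(self, rng):
        import copy
        major = self._profile(rng)
        minor = copy.deepcopy(major)
        del minor.gc["ITS1"]
        with pytest.raises(ValueError):
            classify_pseudogene(minor, major)


def test_profile_copy_reflects_gc_knockdown(rng, ancestors):
    short_ref, _, regions = ancestors
    from pseudits.clone_analysis import CopyVariant
    ref_cv = CopyVariant(consensus=short_ref, support=5, length_class="short")
    ref_prof = profile_copy(ref_cv, regions)
    seq = list(short_ref.residues)
    changed = 0
    for i in range(*regions.its1):
        if seq[i] in "GC" and changed < 20:
            seq[i] = "A"
            changed += 1
    mut = CopyVariant(consensus=SequenceRecord(id="mut", residues="".join(seq)),
                      support=1, length_class="short")
    mut_prof = profile_copy(mut, regions)
    assert mut_prof.gc["ITS1"] < ref_prof.gc["ITS1"]
    assert mut_prof.gc["5.8S"] == pytest.approx(ref_prof.gc["5.8S"])
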