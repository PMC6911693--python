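"""Cytonuclear concordance: connection patterns and evolutionary categories.

Chloroplast DNA is maternally inherited, so when an accession's ITS
relic (pseudogene) clusters with one pseudogroup while its cpDNA sits
in a particular maternal clade, the pairing is a footprint of the
hybridization that deposited the relic.  Three connection patterns are
recognised: (1) pseudogroup 2 with maternal clade I, (2) pseudogroup 1
with clade II, (3) pseudogroup 2 with clade II.  Each accession is also
placed into one of four evolutionary categories — aAA (short-type
functional only), bBB (long-type functional only), aAA*B / bAA*B
(short-type functional plus a long-type relic, inherited through a
clade-I or clade-II mother respectively); the a/b superscripts are
operationalized as cpDNA clade I vs II membership.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .errors import ConcordanceError

PATTERN_RULES = {
    ("pseudogroup 2", "clade I"): 1,
    ("pseudogroup 1", "clade II"): 2,
    ("pseudogroup 2", "clade II"): 3,
}


@dataclass
class ConnectionPattern:
    accession_name: str
    pseudogroup: str   # "pseudogroup 1" | "pseudogroup 2" | "none"
    cpdna_clade: str   # "clade I" | "clade II" | "other"
    pattern_id: int | str = "unclassified"


@dataclass
class EvolCategory:
    accession_name: str
    category: str      # aAA | aAA*B | bAA*B | bBB
    hybrid_flag: bool = False
    note: str = ""


@dataclass
class AccessionSummary:
    """Inputs to the category rule for one accession."""

    accession_name: str
    functional_classes: tuple[str, ...]   # length classes of functional copies
    pseudogene_classes: tuple[str, ...] = ()
    pseudogroups: tuple[str, ...] = ()
    cpdna_clade: str = "other"


def build_patterns(pseudogroup_by_accession: Mapping[str, str],
                   clade_by_accession: Mapping[str, str]
                   ) -> list[ConnectionPattern]:
    """One ConnectionPattern per pseudogene-bearing accession.

    pseudogroup_by_accession maps accessions carrying a pseudogene to
    their pseudogroup label; every such accession must have a cpDNA
    clade.  Pattern ids follow PATTERN_RULES; other combinations are
    "unclassified".
    """
    patterns = []
    for accession in sorted(pseudogroup_by_accession):
        group = pseudogroup_by_accession[accession]
        if accession not in clade_by_accession:
            raise ConcordanceError(
                f"accession {accession!r} has no cpDNA clade")
        clade = clade_by_accession[accession]
        pid = PATTERN_RULES.get((group, clade), "unclassified")
        patterns.append(ConnectionPattern(
            accession_name=accession, pseudogroup=group,
            cpdna_clade=clade, pattern_id=pid))
    return patterns


def association_test(patterns: Sequence[ConnectionPattern],
                     n_permutations: int = 999, seed: int = 0
                     ) -> tuple[float, "np.ndarray", list[str], list[str]]:
    """Permutation chi-square test of pseudogroup x cpDNA-clade association.

    Returns (p_value, contingency table, row labels, column labels);
    p uses the add-one estimator over clade-label shuffles.
    """
    groups = sorted({p.pseudogroup for p in patterns})
    clades = sorted({p.cpdna_clade for p in patterns})
    if len(groups) < 2 or len(clades) < 2:
        raise ConcordanceError("need >= 2 pseudogroups and >= 2 clades "
                               "represented")
    gi = {g: i for i, g in enumerate(groups)}
    ci = {c: i for i, c in enumerate(clades)}
    rows = np.array([gi[p.pseudogroup] for p in patterns])
    cols = np.array([ci[p.cpdna_clade] for p in patterns])
    table = np.zeros((len(groups), len(clades)), dtype=int)
    np.add.at(table, (rows, cols), 1)
    if np.count_nonzero(table) <= 1:
        raise ConcordanceError("degenerate contingency table")

    def stat(r, c):
        t = np.zeros_like(table)
        np.add.at(t, (r, c), 1)
        # chi-square without continuity correction; zero-margin rows and
        # columns cannot occur here because labels come from the data
        return float(chi2_contingency(t, correction=False).statistic) \
            if t.min() >= 0 else 0.0

    observed = stat(rows, cols)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if stat(rows, rng.permutation(cols)) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return p, table, groups, clades


def classify_evolutionary_category(summary: AccessionSummary) -> EvolCategory:
    """Place an accession into the proposed evolutionary scheme.

    bBB: long-type functional copies only.  aAA: short-type functional
    only with no pseudogene.  aAA*B / bAA*B: short-type functional plus
    a long-type pseudogene, with a clade-I / clade-II mother.  Accessions
    holding two functional copies and no pseudogene are aAA with a
    hybrid flag; combinations outside the scheme (e.g. an accession in
    both pseudogroups) come back "unclassified" with a note.
    """
    if not summary.functional_classes:
        raise ConcordanceError(
            f"{summary.accession_name}: no functional ITS copy")
    fc = set(summary.functional_classes)
    has_pseudo = bool(summary.pseudogene_classes)
    if not has_pseudo:
        if fc == {"long"}:
            return EvolCategory(summary.accession_name, "bBB")
        hybrid = len(summary.functional_classes) > 1
        note = "two functional ITS copies (hybrid)" if hybrid else ""
        return EvolCategory(summary.accession_name, "aAA",
                            hybrid_flag=hybrid, note=note)
    if len(set(summary.pseudogroups)) > 1:
        return EvolCategory(summary.accession_name, "unclassified",
                            note="pseudogenes in multiple pseudogroups")
    if "short" in fc and "long" in set(summary.pseudogene_classes):
        if summary.cpdna_clade == "clade I":
            return EvolCategory(summary.accession_name, "aAA*B")
        if summary.cpdna_clade == "clade II":
            return EvolCategory(summary.accession_name, "bAA*B")
        return EvolCategory(summary.accession_name, "unclassified",
                            note=f"cpDNA clade {summary.cpdna_clade!r}")
    if fc == {"long"}:
        return EvolCategory(summary.accession_name, "bBB",
                            note="long-type functional with pseudogene")
    # short functional + short-type pseudogene: the relic is a partly
    # homogenized long-type copy; treat by maternal clade as above
    if summary.cpdna_clade == "clade I":
        return EvolCategory(summary.accession_name, "aAA*B",
                            note="short-type pseudogene")
    if summary.cpdna_clade == "clade II":
        return EvolCategory(summary.accession_name, "bAA*B",
                            note="short-type pseudogene")
    return EvolCategory(summary.accession_name, "unclassified",
                        note="pseudogene with unresolved maternal clade")
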