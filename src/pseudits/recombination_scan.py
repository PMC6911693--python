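"""Maximum chi-square (MaxChi) recombination breakpoint scan.

Detects recombinant ITS copies — e.g. a short-type relic carrying a
long-type segment — by scanning a query against two candidate parental
sequences.  At parent-informative alignment columns (parents differ,
query matches exactly one) the query receives an A/B parentage
assignment; every cut between consecutive informative sites induces a
2x2 table (left/right x A/B) whose chi-square statistic, without
continuity correction, peaks at a true crossover.  Significance comes
from a permutation test with an add-one estimator (so p is never 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ScanError
from .seqio import Alignment, Scoring, DEFAULT_SCORING, SequenceRecord, \
    progressive_msa


@dataclass(frozen=True)
class InformativeSite:
    column: int       # alignment column
    assignment: str   # "A" | "B"


@dataclass
class BreakpointResult:
    query_id: str
    parents: tuple[str, str]
    best_breakpoint: int       # alignment column (midpoint of flanking sites)
    best_cut_index: int        # sites[:k] left, sites[k:] right
    chi2_max: float
    p_value: float
    informative_sites: int


def informative_sites(aln: Alignment) -> list[InformativeSite]:
    """Parent-informative columns of a {query, parentA, parentB} alignment.

    Columns with any gap or N are excluded; the remaining columns are
    kept where parentA != parentB and the query matches exactly one of
    them.  Raises ScanError with < 2 informative sites.
    """
    if len(aln.records) != 3:
        raise ScanError("informative_sites needs a 3-row alignment "
                        "(query, parentA, parentB)")
    q, pa, pb = (r.residues for r in aln.records)
    sites = []
    for col, (cq, ca, cb) in enumerate(zip(q, pa, pb)):
        if "-" in (cq, ca, cb) or "N" in (cq, ca, cb):
            continue
        if ca == cb:
            continue
        if cq == ca:
            sites.append(InformativeSite(col, "A"))
        elif cq == cb:
            sites.append(InformativeSite(col, "B"))
    if len(sites) < 2:
        raise ScanError(f"scan impossible: only {len(sites)} informative "
                        "site(s)")
    return sites


def _max_chi2(assign: np.ndarray) -> tuple[float, int]:
    """Maximum 2x2 chi-square over all cuts of a 0/1 assignment vector."""
    m = len(assign)
    total_b = int(assign.sum())
    total_a = m - total_b
    best, best_k = 0.0, 1
    left_b = 0
    for k in range(1, m):
        left_b += int(assign[k - 1])
        left_a = k - left_b
        right_a = total_a - left_a
        right_b = total_b - left_b
        # chi2 = N (ad-bc)^2 / (r1 r2 c1 c2)
        r1, r2 = k, m - k
        c1, c2 = total_a, total_b
        denom = r1 * r2 * c1 * c2
        if denom == 0:
            continue
        det = left_a * right_b - left_b * right_a
        chi2 = m * det * det / denom
        if chi2 > best:
            best, best_k = chi2, k
    return best, best_k


def _max_chi2_rows(assign_rows: np.ndarray) -> np.ndarray:
    """Row-wise maximum chi-square for a (n_rows, m) 0/1 matrix."""
    n, m = assign_rows.shape
    total_b = assign_rows.sum(axis=1)
    total_a = m - total_b
    left_b = np.cumsum(assign_rows, axis=1)[:, :-1]
    ks = np.arange(1, m)
    left_a = ks[None, :] - left_b
    right_a = total_a[:, None] - left_a
    right_b = total_b[:, None] - left_b
    det = left_a * right_b - left_b * right_a
    denom = (ks * (m - ks))[None, :] * (total_a * total_b)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, m * det.astype(float) ** 2 / denom, 0.0)
    return chi2.max(axis=1)


def maxchi_scan(sites: Sequence[InformativeSite],
                n_permutations: int = 999,
                seed: int = 0,
                query_id: str = "query",
                parents: tuple[str, str] = ("parentA", "parentB")
                ) -> BreakpointResult:
    """MaxChi breakpoint scan over parentage-informative sites.

    p_value = (1 + #{permuted maxima >= observed}) / (1 + n_permutations),
    permuting the site assignments with the given seed.
    """
    if len(sites) < 4:
        raise ScanError(f"need >= 4 informative sites, got {len(sites)}")
    if n_permutations < 99:
        raise ScanError("n_permutations must be >= 99")
    assign = np.array([1 if s.assignment == "B" else 0 for s in sites],
                      dtype=np.int64)
    chi2_max, best_k = _max_chi2(assign)
    rng = np.random.default_rng(seed)
    perm = np.stack([rng.permutation(assign) for _ in range(n_permutations)])
    perm_max = _max_chi2_rows(perm)
    p = (1 + int((perm_max >= chi2_max - 1e-12).sum())) / (1 + n_permutations)
    cols = [s.column for s in sites]
    breakpoint_col = (cols[best_k - 1] + cols[best_k]) // 2
    return BreakpointResult(query_id=query_id, parents=parents,
                            best_breakpoint=breakpoint_col,
                            best_cut_index=best_k,
                            chi2_max=float(chi2_max), p_value=float(p),
                            informative_sites=len(sites))


def scan_triplet(query: SequenceRecord, parent_a: SequenceRecord,
                 parent_b: SequenceRecord, n_permutations: int = 999,
                 seed: int = 0, scoring: Scoring = DEFAULT_SCORING
                 ) -> BreakpointResult:
    """Align a (query, parentA, parentB) triple and run the MaxChi scan."""
    aln = progressive_msa([query, parent_a, parent_b], scoring)
    # progressive_msa preserves input order
    sites = informative_sites(aln)
    return maxchi_scan(sites, n_permutations=n_permutations, seed=seed,
                       query_id=query.id,
                       parents=(parent_a.id, parent_b.id))
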