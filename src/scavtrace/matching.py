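"""Percent-identity matching of gut ASVs against biomarker sequences.

All sequences are fragments of the same 16S V3-V5 amplicon, so comparison
uses optimal *global* pairwise alignment (Needleman-Wunsch, via
biopython's PairwiseAligner).  Percent identity is the number of identical
aligned columns divided by the full alignment length including gap
columns — the stricter, reproducible convention.  A gut ASV matches a
biomarker when its top hit reaches the identity threshold (default
>= 97%, inclusive).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

from Bio import Align

__all__ = [
    "AlignmentResult",
    "MatchResult",
    "make_aligner",
    "align_identity",
    "top_hit",
    "match_all",
]

DEFAULT_THRESHOLD = 97.0

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_query: str
    aligned_ref: str
    n_identical: int
    alignment_length: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_identical / self.alignment_length


@dataclass(frozen=True)
class MatchResult:
    query_asv_id: str
    biomarker_id: str
    identity_pct: float
    n_identical: int
    is_match: bool


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    end_gaps_free: bool = False,
) -> Align.PairwiseAligner:
    """Global nucleotide aligner.

    Defaults (+1/-1, gap open -2, extend -0.5) make gapless alignment
    optimal for substitution-only variants of equal length, so identity
    arithmetic on such pairs is exact.  ``end_gaps_free`` switches to
    semi-global alignment for length-variant inputs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if end_gaps_free:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def align_identity(
    query: str, ref: str, aligner: Align.PairwiseAligner | None = None
) -> AlignmentResult:
    """Optimal global alignment and its percent identity.

    ``N`` never counts as identical, even against another ``N``.
    """
    for name, seq in (("query", query), ("ref", ref)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{name} has characters outside ACGTN: {sorted(bad)}")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(query.upper(), ref.upper())[0]
    aligned_q, aligned_r = str(alignment[0]), str(alignment[1])
    n_identical = sum(
        1
        for cq, cr in zip(aligned_q, aligned_r)
        if cq == cr and cq not in ("-", "N")
    )
    return AlignmentResult(
        aligned_query=aligned_q,
        aligned_ref=aligned_r,
        n_identical=n_identical,
        alignment_length=len(aligned_q),
    )


def top_hit(
    query_id: str,
    query: str,
    refs: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    aligner: Align.PairwiseAligner | None = None,
) -> MatchResult:
    """Best-identity reference for one query.

    Ties are broken deterministically: higher identity, then more
    identical columns, then lexicographically smallest reference id.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if aligner is None:
        aligner = make_aligner()
    best_id = None
    best: AlignmentResult | None = None
    for ref_id in sorted(refs):
        res = align_identity(query, refs[ref_id], aligner=aligner)
        if best is None or (res.identity_pct, res.n_identical) > (
            best.identity_pct,
            best.n_identical,
        ):
            best_id, best = ref_id, res
    assert best is not None and best_id is not None
    return MatchResult(
        query_asv_id=query_id,
        biomarker_id=best_id,
        identity_pct=best.identity_pct,
        n_identical=best.n_identical,
        is_match=best.identity_pct >= threshold,
    )


def match_all(
    queries: Mapping[str, str],
    biomarkers: Mapping[str, str],
    threshold: float = DEFAULT_THRESHOLD,
    aligner: Align.PairwiseAligner | None = None,
) -> list[MatchResult]:
    """Top-hit match of every query; keep those at or above the threshold.

    Returns the list of matches (one per matching query).  Bookkeeping —
    the number of matching queries and of distinct biomarkers hit — is
    available from :func:`match_counts`.
    """
    if not queries or not biomarkers:
        raise ValueError("both sequence sets must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    results = []
    for query_id in queries:
        hit = top_hit(query_id, queries[query_id], biomarkers, threshold, aligner)
        if hit.is_match:
            results.append(hit)
    return results


def match_counts(matches: list[MatchResult]) -> dict[str, int]:
    return {
        "n_matched_queries": len({m.query_asv_id for m in matches}),
        "n_biomarkers_hit": len({m.biomarker_id for m in matches}),
    }
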