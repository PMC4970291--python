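"""Pairwise global alignment and percent identity.

Alignments are computed with edlib (unit-cost edit distance, i.e. the
alignment minimising substitutions + inserted + deleted bases), which
keeps all-against-all comparison of thousands of unique amplicons
tractable.  Identity is reported over the alignment with terminal gap
runs excluded, so a read a few bases shorter than its template is not
penalised at the ends:

    identity = matches / (matches + mismatches + insertions + deletions) * 100

Insertions are bases present in the query but not the reference;
deletions the reverse.  For the minimal-cost alignment these four counts
are uniquely determined even when several optimal paths exist.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple

import edlib

__all__ = [
    "AlignmentResult",
    "align_pair",
    "pairwise_identity",
    "align_to_best_reference",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Best-reference alignment statistics for one query sequence."""

    query_id: str
    ref_id: str
    alignment_length: int
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    #: raw edit distance of the full global alignment, terminal gaps included
    edit_distance: int = 0

    @property
    def identity(self) -> float:
        """Percent identity over the terminal-gap-trimmed alignment."""
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.matches / self.alignment_length

    @property
    def n_errors(self) -> int:
        """Mismatched plus inserted plus deleted bases."""
        return self.mismatches + self.insertions + self.deletions


def _cigar_counts(cigar: str) -> Tuple[int, int, int, int]:
    """(matches, mismatches, insertions, deletions) from an extended CIGAR,
    with terminal gap runs ('I'/'D' at either end) excluded."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    m = mm = ins = dele = 0
    for n, op in ops:
        if op == "=":
            m += n
        elif op == "X":
            mm += n
        elif op == "I":
            ins += n
        elif op == "D":
            dele += n
        else:  # 'M' never emitted by edlib's extended CIGAR
            raise ValueError(f"ambiguous CIGAR op {op!r}")
    return m, mm, ins, dele


def align_pair(
    query: str, ref: str, query_id: str = "query", ref_id: str = "ref"
) -> AlignmentResult:
    """Globally align two sequences and tabulate match/error counts."""
    if not query or not ref:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(query, ref, mode="NW", task="path")
    m, mm, ins, dele = _cigar_counts(res["cigar"])
    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        alignment_length=m + mm + ins + dele,
        matches=m,
        mismatches=mm,
        insertions=ins,
        deletions=dele,
        edit_distance=int(res["editDistance"]),
    )


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two sequences under global alignment.

    Terminal gaps are excluded from the denominator.  Because several
    alignments can share the optimal cost, the pair is aligned in a
    canonical (lexicographic) order so that the result is exactly
    symmetric.
    """
    if b < a:
        a, b = b, a
    return align_pair(a, b).identity


def _ref_items(refs) -> Iterable[Tuple[str, str]]:
    """Normalise a reference collection to (name, sequence) pairs.

    Accepts a mapping, a sequence of pairs, or any object exposing
    ``items()`` (e.g. ReferenceSet).
    """
    if isinstance(refs, Mapping):
        return list(refs.items())
    if hasattr(refs, "items"):
        return list(refs.items())
    return list(refs)


def align_to_best_reference(
    query: str, refs, query_id: str = "query"
) -> AlignmentResult:
    """Align a query against every reference; return the highest-identity hit.

    Ties are broken by reference input order.
    """
    if not query:
        raise ValueError("empty query")
    items = list(_ref_items(refs))
    if not items:
        raise ValueError("empty reference set")
    best: AlignmentResult | None = None
    for name, seq in items:
        r = align_pair(query, seq, query_id=query_id, ref_id=name)
        if best is None or r.identity > best.identity:
            best = r
    assert best is not None
    return best


def semiglobal_identity(query: str, ref: str) -> float:
    """Percent identity of ``query`` aligned freely within ``ref`` (infix mode).

    Used for chimera-half matching, where a fragment should align to a
    portion of a full-length reference without end penalties.
    """
    if not query or not ref:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(query, ref, mode="HW", task="path")
    m, mm, ins, dele = _cigar_counts(res["cigar"])
    total = m + mm + ins + dele
    return 100.0 * m / total if total else 0.0
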