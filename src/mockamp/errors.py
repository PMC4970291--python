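"""Sequencing error-rate estimation against known references.

In a mock community the true 16S sequences are known, so the error rate
is directly measurable: align every unique read to its best-matching
reference and count mismatched, inserted and deleted bases, weighting
each unique sequence by its read count.  Chimeric sequences are PCR
artefacts rather than sequencing errors, so they are flagged (by a
simple reference-based bimera test — valid here precisely because the
true parents are all known) and excluded from the rate by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .align import (
    AlignmentResult,
    align_to_best_reference,
    semiglobal_identity,
    _ref_items,
)
from .derep import UniqueSeqTable

__all__ = ["ErrorReport", "error_rate", "flag_chimera"]


@dataclass
class ErrorReport:
    """Abundance-weighted error rate of a unique-sequence table."""

    overall_rate: float
    per_sample_rates: Dict[str, float]
    reads_assessed: int
    chimeras_excluded: int
    alignments: pd.DataFrame = field(repr=False, default=None)

    @property
    def overall_rate_pct(self) -> float:
        return 100.0 * self.overall_rate


def flag_chimera(
    query: str,
    refs,
    n_breakpoints: int = 8,
    margin: float = 2.0,
    min_fragment: int = 15,
) -> Tuple[bool, Optional[Tuple[str, str]]]:
    """Reference-based bimera test.

    The query is split at ``n_breakpoints`` evenly spaced interior
    positions; for each split, the best-matching reference of the left
    and right fragments is found (fragments aligned in infix mode, so a
    fragment may match any portion of a full-length reference).  The
    query is flagged as chimeric when some split's two parents differ
    and the length-weighted two-parent identity beats the best
    single-reference identity by at least ``margin`` percentage points.
    A chimera of two identical parents is undetectable by construction
    and is not flagged.

    Returns ``(flag, (left_parent, right_parent) or None)``.
    """
    items = list(_ref_items(refs))
    if len(items) < 2:
        raise ValueError("chimera flagging needs at least two references")
    best_single = align_to_best_reference(query, items).identity
    L = len(query)
    best_gain = 0.0
    best_parents: Optional[Tuple[str, str]] = None
    for k in range(1, n_breakpoints + 1):
        b = round(L * k / (n_breakpoints + 1))
        if b < min_fragment or L - b < min_fragment:
            continue
        left, right = query[:b], query[b:]
        idl, pl = max(
            ((semiglobal_identity(left, seq), name) for name, seq in items),
            key=lambda t: t[0],
        )
        idr, pr = max(
            ((semiglobal_identity(right, seq), name) for name, seq in items),
            key=lambda t: t[0],
        )
        if pl == pr:
            continue
        combined = (idl * b + idr * (L - b)) / L
        gain = combined - best_single
        if gain >= margin and gain > best_gain:
            best_gain = gain
            best_parents = (pl, pr)
    return (best_parents is not None), best_parents


def error_rate(
    table: UniqueSeqTable,
    refs,
    exclude_chimeras: bool = True,
    chimera_margin: float = 2.0,
    chimera_prescreen_identity: float = 98.0,
) -> ErrorReport:
    """Abundance-weighted per-base error rate of a count table vs references.

    rate = sum over unique sequences of count x (mismatches + insertions
    + deletions) / sum of count x alignment length, with chimera-flagged
    sequences excluded (their reads are tallied separately).  Sequences
    whose best single-reference identity is already at least
    ``chimera_prescreen_identity`` cannot gain the flagging margin and
    skip the bimera test.
    """
    if table.n_unique == 0:
        raise ValueError("empty count table")
    items = list(_ref_items(refs))
    if not items:
        raise ValueError("empty reference set")

    rows: List[dict] = []
    err_w: Dict[str, float] = {s: 0.0 for s in table.samples}
    len_w: Dict[str, float] = {s: 0.0 for s in table.samples}
    total_err = 0.0
    total_len = 0.0
    reads_assessed = 0
    chimeras_excluded = 0
    for seq, row in table.counts.iterrows():
        aln = align_to_best_reference(seq, items, query_id=seq[:12])
        pooled = int(row.sum())
        is_chimera = False
        if exclude_chimeras and aln.identity < chimera_prescreen_identity:
            is_chimera, _ = flag_chimera(seq, items, margin=chimera_margin)
        rows.append(
            dict(
                ref=aln.ref_id,
                identity=aln.identity,
                errors=aln.n_errors,
                alignment_length=aln.alignment_length,
                pooled_count=pooled,
                chimera=is_chimera,
            )
        )
        if is_chimera:
            chimeras_excluded += pooled
            continue
        reads_assessed += pooled
        total_err += pooled * aln.n_errors
        total_len += pooled * aln.alignment_length
        for s in table.samples:
            c = int(row[s])
            if c:
                err_w[s] += c * aln.n_errors
                len_w[s] += c * aln.alignment_length

    overall = total_err / total_len if total_len else 0.0
    per_sample = {
        s: (err_w[s] / len_w[s] if len_w[s] else 0.0) for s in table.samples
    }
    alignments = pd.DataFrame(rows, index=pd.Index(table.sequences, name="sequence"))
    return ErrorReport(
        overall_rate=overall,
        per_sample_rates=per_sample,
        reads_assessed=reads_assessed,
        chimeras_excluded=chimeras_excluded,
        alignments=alignments,
    )
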