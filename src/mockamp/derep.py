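"""Unique-sequence count tables, rarefaction, and cross-sample
singleton/doubleton removal.

The filtering step here is the pipeline's central idea: after pooling
all replicate samples, a *cross-sample singleton* is a unique sequence
read exactly once over all samples, a *doubleton* exactly twice.  Such
sequences are overwhelmingly sequencing/PCR artefacts for deeply
sequenced communities, and discarding them before distance-matrix
construction both removes most of the error mass and shrinks the
clustering problem dramatically.

"Cluster" at this stage means an exact-identity group of reads (the
pre-OTU unique-sequence clusters whose size spectrum the diagnostics
module analyses), not a 97 %-similarity OTU.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "UniqueSeqTable",
    "FilterReport",
    "dereplicate",
    "remove_rare",
    "rarefy",
    "cluster_size_spectrum",
]


@dataclass
class UniqueSeqTable:
    """Unique sequences (exact string identity) x per-sample read counts.

    ``counts`` is indexed by the sequence string itself; rows are kept in
    descending pooled-count order (ties: lexicographic) so that derived
    sequence ids are stable and deterministic.
    """

    counts: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sequence keys in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.counts = self.counts.astype(int)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> List[str]:
        return list(self.counts.index)

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def pooled(self) -> pd.Series:
        """Cross-sample (pooled) count of each unique sequence."""
        return self.counts.sum(axis=1)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def indexed(self) -> Tuple[pd.DataFrame, Dict[str, str]]:
        """Counts re-indexed by compact ids plus the id -> sequence map."""
        ids = [f"u{i + 1:06d}" for i in range(len(self.counts))]
        counts = self.counts.copy()
        id_to_seq = dict(zip(ids, counts.index))
        counts.index = pd.Index(ids, name="id")
        return counts, id_to_seq

    def _sorted(self) -> "UniqueSeqTable":
        pooled = self.counts.sum(axis=1)
        order = sorted(
            self.counts.index, key=lambda s: (-pooled[s], s)
        )
        return UniqueSeqTable(self.counts.loc[order], self.provenance)


def dereplicate(reads_by_sample: Mapping[str, Iterable[str]]) -> UniqueSeqTable:
    """Collapse per-sample reads into a unique-sequence count table.

    ``reads_by_sample`` maps sample name to an iterable of sequence
    strings (ids, if any, are dropped: identity is by exact string).
    Total reads are conserved: each distinct string's per-sample count
    is the number of times it was read in that sample.
    """
    if not reads_by_sample:
        raise ValueError("no samples provided")
    counters: Dict[str, Counter] = {}
    for sample, reads in reads_by_sample.items():
        counters[sample] = Counter(reads)
    if not any(counters.values()):
        raise ValueError("no reads in any sample")
    df = pd.DataFrame(counters).fillna(0).astype(int)
    df = df[list(reads_by_sample)]  # preserve sample order
    table = UniqueSeqTable(df, provenance="raw")
    return table._sorted()


@dataclass(frozen=True)
class FilterReport:
    """Accounting of a rare-sequence removal step."""

    threshold: int
    sequences_removed: int
    sequences_retained: int
    reads_removed: int
    reads_retained: int
    sample_totals_before: Dict[str, int]
    sample_totals_after: Dict[str, int]


def remove_rare(
    table: UniqueSeqTable, min_pooled_count: int
) -> Tuple[UniqueSeqTable, FilterReport]:
    """Drop unique sequences whose cross-sample pooled count is below a floor.

    ``min_pooled_count=2`` removes cross-sample singletons;
    ``min_pooled_count=3`` also removes doubletons; ``1`` is the
    identity.  Per-sample counts of retained sequences are untouched.
    """
    if min_pooled_count < 1:
        raise ValueError("min_pooled_count must be >= 1")
    pooled = table.pooled()
    keep = pooled >= min_pooled_count
    before = table.sample_totals()
    filtered = UniqueSeqTable(
        table.counts.loc[keep],
        provenance=f"{table.provenance}|min_count={min_pooled_count}",
    )
    after = filtered.sample_totals()
    report = FilterReport(
        threshold=min_pooled_count,
        sequences_removed=int((~keep).sum()),
        sequences_retained=int(keep.sum()),
        reads_removed=int(pooled[~keep].sum()),
        reads_retained=int(pooled[keep].sum()),
        sample_totals_before={s: int(before[s]) for s in table.samples},
        sample_totals_after={s: int(after[s]) for s in table.samples},
    )
    return filtered, report


def rarefy(table: UniqueSeqTable, depth: int, seed: int = 0) -> UniqueSeqTable:
    """Subsample each sample, without replacement, to exactly ``depth`` reads.

    A single multivariate-hypergeometric draw per sample (one draw per
    seed, not an average over draws).  Samples below ``depth`` raise an
    error naming the offending sample.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    for s in table.samples:
        if totals[s] < depth:
            raise ValueError(
                f"sample {s!r} has {int(totals[s])} reads, fewer than "
                f"rarefaction depth {depth}"
            )
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.samples:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.counts.index)[table.samples]
    df = df.loc[df.sum(axis=1) > 0]
    return UniqueSeqTable(df, provenance=f"{table.provenance}|rarefied={depth}")._sorted()


def cluster_size_spectrum(table: UniqueSeqTable) -> Dict[int, int]:
    """Tally pooled cluster sizes: size n -> number of unique sequences read n times.

    Mass conservation holds: sum over (size x frequency) equals the
    table's total reads.
    """
    if table.n_unique == 0:
        raise ValueError("empty table has no spectrum")
    pooled = table.pooled()
    spectrum = Counter(int(c) for c in pooled if c > 0)
    return dict(sorted(spectrum.items()))
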