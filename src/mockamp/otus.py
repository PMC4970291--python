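"""OTU clustering at a distance cutoff and alpha diversity.

Unique sequences are clustered into operational taxonomic units by
average-neighbour (average-linkage, UPGMA-style) agglomeration: the
closest pair of clusters is merged repeatedly while their mean
inter-cluster distance stays at or below the cutoff (0.03 for "97 %
similarity").  Distances are ``1 - identity/100`` from global
alignment.  The diversity panel reports, per sample, observed richness,
the bias-corrected Chao1 richness estimate, Shannon entropy (natural
log) and the unbiased inverse Simpson index, summarised as mean +/- SEM
across replicate samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import edlib
import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1, chao1_ci

from .align import _cigar_counts

__all__ = [
    "DistanceMatrix",
    "OTUTable",
    "DiversityReport",
    "ChaoEstimate",
    "pairwise_distances",
    "cluster_otus",
    "alpha_diversity",
    "estimated_total_otus",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sequence distances in [0, 1], zero diagonal."""

    ids: List[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)


def _aligned_distance(a: str, b: str, k: int = -1) -> float:
    """1 - identity/100 under global alignment; 1.0 if distance exceeds cap k."""
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return 1.0
    m, mm, ins, dele = _cigar_counts(res["cigar"])
    total = m + mm + ins + dele
    return 1.0 - (m / total if total else 0.0)


def pairwise_distances(
    seqs: Mapping[str, str], max_distance: Optional[float] = None
) -> DistanceMatrix:
    """All-pairs alignment distances for a set of named sequences.

    With ``max_distance`` set, alignment of a pair is abandoned early
    once its distance provably exceeds that bound and the pair is
    recorded at distance 1.0; any bound at or above the clustering
    cutoff leaves the resulting OTUs unchanged while making large
    (thousands of sequences) matrices affordable.
    """
    ids = list(seqs)
    if not ids:
        raise ValueError("no sequences")
    strs = [seqs[i] for i in ids]
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        li = len(strs[i])
        for j in range(i + 1, n):
            if max_distance is not None:
                k = int(math.ceil(max_distance * max(li, len(strs[j])))) + 1
            else:
                k = -1
            d = _aligned_distance(strs[i], strs[j], k=k)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=ids, data=D)


@dataclass
class OTUTable:
    """OTU -> member sequences and per-sample read counts."""

    members: Dict[str, List[str]]
    counts: pd.DataFrame  # index: OTU id, columns: samples
    cutoff: float

    @property
    def otu_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def cluster_otus(
    dm: DistanceMatrix,
    cutoff: float,
    counts: Optional[pd.DataFrame] = None,
) -> OTUTable:
    """Average-neighbour clustering of a distance matrix at a cutoff.

    Repeatedly merges the pair of clusters with the smallest average
    inter-cluster distance while that distance is <= cutoff; ties are
    broken in favour of the pair containing the smallest member indices
    (input order), making the result deterministic.  ``counts`` gives
    per-sample counts per sequence id (one pseudo-sample of ones when
    omitted); OTU counts are the sums over members, so read totals are
    conserved.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    n = len(dm)
    if counts is None:
        counts = pd.DataFrame({"all": np.ones(n, dtype=int)}, index=dm.ids)
    missing = set(dm.ids) - set(counts.index)
    if missing:
        raise ValueError(f"counts missing ids: {sorted(missing)[:3]}...")

    # Lance-Williams average-linkage agglomeration with a merge cutoff.
    D = dm.data.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    groups: Dict[int, List[int]] = {i: [i] for i in range(n)}
    while active.sum() > 1:
        # argmin scans row-major, so equal minima resolve to the
        # smallest (i, j) index pair automatically
        flat = np.argmin(D)
        i, j = divmod(int(flat), n)
        if D[i, j] > cutoff:
            break
        if i > j:
            i, j = j, i
        # average-linkage update of row/col i as the merged cluster
        new_row = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        groups[i].extend(groups.pop(j))

    clusters = [sorted(groups[i]) for i in sorted(groups) if active[i]]
    # deterministic OTU numbering: by decreasing total count, then first member
    otu_rows = []
    for members_idx in clusters:
        ids = [dm.ids[k] for k in members_idx]
        row = counts.loc[ids].sum(axis=0)
        otu_rows.append((ids, row))
    otu_rows.sort(key=lambda t: (-int(t[1].sum()), t[0][0]))
    members = {}
    data = {}
    for k, (ids, row) in enumerate(otu_rows, start=1):
        oid = f"Otu{k:04d}"
        members[oid] = ids
        data[oid] = row
    counts_df = pd.DataFrame(data).T
    counts_df = counts_df[list(counts.columns)].astype(int)
    counts_df.index.name = "otu"
    return OTUTable(members=members, counts=counts_df, cutoff=cutoff)


def _inverse_simpson(counts: np.ndarray) -> float:
    """Unbiased finite-sample inverse Simpson 1 / sum[n_i(n_i-1)/(N(N-1))].

    Undefined (NaN) for single-read samples and for communities where
    every OTU has exactly one read (zero denominator).
    """
    N = counts.sum()
    if N < 2:
        return float("nan")
    denom = (counts * (counts - 1)).sum() / (N * (N - 1))
    return float(1.0 / denom) if denom > 0 else float("nan")


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class DiversityReport:
    """Per-sample alpha-diversity panel with across-sample mean +/- SEM."""

    per_sample: pd.DataFrame  # rows: samples; cols: metrics
    summary: pd.DataFrame  # rows: metrics; cols: mean, sem

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])

    def sem(self, metric: str) -> float:
        return float(self.summary.loc[metric, "sem"])


METRICS = ["observed_otus", "chao", "shannon", "inverse_simpson", "n1", "n2"]


def alpha_diversity(otus: OTUTable) -> DiversityReport:
    """Observed richness, Chao1 (bias-corrected), Shannon and inverse Simpson.

    Chao1 = S_obs + n1(n1-1) / (2(n2+1)) with n1/n2 the number of
    OTUs seen once/twice in the sample; always >= S_obs and defined for
    n2 = 0.  Samples with zero reads are rejected.
    """
    if otus.n_otus == 0:
        raise ValueError("empty OTU table")
    rows = {}
    for s in otus.counts.columns:
        c = otus.counts[s].to_numpy()
        N = int(c.sum())
        if N == 0:
            raise ValueError(f"sample {s!r} has zero reads; diversity undefined")
        pos = c[c > 0]
        rows[s] = {
            "observed_otus": float(len(pos)),
            "chao": float(chao1(c.astype(int), bias_corrected=True)),
            "shannon": _shannon(pos.astype(float)),
            "inverse_simpson": _inverse_simpson(pos.astype(float)),
            "n1": float((pos == 1).sum()),
            "n2": float((pos == 2).sum()),
        }
    per_sample = pd.DataFrame(rows).T[METRICS]
    n = len(per_sample)
    summary = pd.DataFrame(
        {
            "mean": per_sample.mean(axis=0),
            "sem": per_sample.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else 0.0,
        }
    )
    return DiversityReport(per_sample=per_sample, summary=summary)


@dataclass(frozen=True)
class ChaoEstimate:
    """Chao1 richness estimate with its 95 % confidence interval.

    Stands in for parametric total-richness estimators: a nonparametric
    lower-bound-style estimate from singleton/doubleton OTU counts.
    """

    estimate: float
    ci_low: float
    ci_high: float


def estimated_total_otus(otus: OTUTable) -> ChaoEstimate:
    """Chao1 estimate of total OTU richness from pooled OTU counts."""
    if otus.n_otus == 0:
        raise ValueError("empty OTU table")
    pooled = otus.counts.sum(axis=1).to_numpy().astype(int)
    est = float(chao1(pooled, bias_corrected=True))
    lo, hi = chao1_ci(pooled, bias_corrected=True)
    return ChaoEstimate(estimate=est, ci_low=float(lo), ci_high=float(hi))
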