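"""Nearest-reference taxonomy for a defined community.

Because every true member of a mock community is known, taxonomy can be
assigned by nearest reference instead of a database classifier: an
OTU's representative sequence (its most abundant member, ties broken
lexicographically) is aligned to every reference and labelled with the
genus of the best hit when identity clears a threshold (default 80 %),
otherwise "unclassified".  Reads assigned to the non-bacterial control
member (the archaeon) are tallied and excluded from the bacterial
relative-abundance summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import pandas as pd

from .align import align_to_best_reference
from .derep import UniqueSeqTable
from .otus import OTUTable

__all__ = [
    "UNCLASSIFIED",
    "TaxonomySummary",
    "assign_otu",
    "otu_representative",
    "assign_all",
    "summarize_relative_abundance",
]

UNCLASSIFIED = "unclassified"


def assign_otu(
    representative: str, refs, min_identity: float = 80.0
) -> Tuple[str, float]:
    """Genus label of the best-identity reference, or "unclassified".

    Returns ``(label, identity)``; the label falls back to the
    reference name when the reference set carries no taxon map.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must lie in (0, 100]")
    aln = align_to_best_reference(representative, refs)
    taxa = getattr(refs, "taxa", None) or {}
    label = taxa.get(aln.ref_id, aln.ref_id)
    if aln.identity < min_identity:
        return UNCLASSIFIED, aln.identity
    return label, aln.identity


def otu_representative(
    otu_members, table: UniqueSeqTable, id_to_seq: Optional[Mapping[str, str]] = None
) -> str:
    """Most abundant member sequence of an OTU; ties to the lexicographically
    smallest sequence."""
    pooled = table.pooled()
    seqs = [id_to_seq[m] if id_to_seq else m for m in otu_members]
    return min(seqs, key=lambda s: (-int(pooled[s]), s))


def assign_all(
    otus: OTUTable,
    table: UniqueSeqTable,
    refs,
    min_identity: float = 80.0,
    id_to_seq: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assign every OTU: returns a frame (otu, genus, identity, representative)."""
    rows = {}
    for oid, members in otus.members.items():
        rep = otu_representative(members, table, id_to_seq)
        label, ident = assign_otu(rep, refs, min_identity)
        rows[oid] = {"genus": label, "identity": ident, "representative": rep[:60]}
    df = pd.DataFrame(rows).T.loc[otus.otu_ids]
    df.index.name = "otu"
    df["identity"] = df["identity"].astype(float)
    return df


@dataclass
class TaxonomySummary:
    """Mean relative abundance of each genus across replicate samples.

    ``per_sample`` holds genus x sample fractions over *bacterial* reads
    (plus the unclassified bin); fractions sum to 1 per sample.  Reads
    hitting non-bacterial control references are reported separately as
    ``archaeal_fraction`` of all reads.
    """

    per_sample: pd.DataFrame
    mean: pd.Series
    sem: pd.Series
    unclassified_mean: float
    archaeal_fraction: float
    min_identity: float


def summarize_relative_abundance(
    otus: OTUTable,
    assignments: pd.DataFrame,
    refs=None,
    min_identity: float = 80.0,
) -> TaxonomySummary:
    """Per-genus mean relative abundances across samples (plus unclassified).

    ``assignments`` is the ``assign_all`` frame (or any frame with a
    ``genus`` column indexed by OTU id, covering all OTUs).  Genera
    mapped to non-bacterial references are excluded from the fractions
    and accounted as the archaeal control fraction.
    """
    missing = set(otus.otu_ids) - set(assignments.index)
    if missing:
        raise ValueError(f"assignments missing OTUs: {sorted(missing)[:3]}...")
    genus = assignments["genus"]
    nonbact_genera = set()
    if refs is not None and getattr(refs, "taxa", None):
        nonbact_genera = {
            refs.taxa[n] for n in refs.sequences if not refs.is_bacterial[n]
        }
    counts = otus.counts.copy()
    counts["__genus"] = genus.loc[counts.index]
    by_genus = counts.groupby("__genus").sum()

    total_all = by_genus.to_numpy().sum()
    arch_rows = [g for g in by_genus.index if g in nonbact_genera]
    archaeal = float(by_genus.loc[arch_rows].to_numpy().sum() / total_all) if total_all else 0.0
    bact = by_genus.drop(index=arch_rows)
    sample_totals = bact.sum(axis=0)
    if (sample_totals == 0).any():
        bad = [s for s in bact.columns if sample_totals[s] == 0]
        raise ValueError(f"no bacterial reads in samples {bad}")
    frac = bact / sample_totals
    mean = frac.mean(axis=1).sort_values(ascending=False)
    n = frac.shape[1]
    sem = (frac.std(axis=1, ddof=1) / (n**0.5)).reindex(mean.index) if n > 1 else mean * 0.0
    frac = frac.loc[mean.index]
    uncl = float(mean.get(UNCLASSIFIED, 0.0))
    return TaxonomySummary(
        per_sample=frac,
        mean=mean,
        sem=sem,
        unclassified_mean=uncl,
        archaeal_fraction=archaeal,
        min_identity=min_identity,
    )
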