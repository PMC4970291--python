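"""End-to-end three-way validation of an amplicon run.

``validate`` runs the whole comparison the mock-community experiment is
built around: dereplicate, rarefy, then branch the data three ways —
all sequences, cross-sample singletons removed, singletons and
doubletons removed — and for each branch measure the error rate against
the references, cluster OTUs at the similarity cutoff, compute the
alpha-diversity panel, assign taxonomy and summarise genus abundances.
The consolidated summary table has one row per branch, mirroring how
the validation results are usually tabulated, and the spectrum fit
comparison quantifies how filtering straightens the log-log
cluster-size spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import io as mio
from .derep import UniqueSeqTable, dereplicate, rarefy, remove_rare
from .diagnostics import FitComparison, filtering_improves_fit
from .errors import ErrorReport, error_rate
from .io import PipelineConfig
from .otus import (
    ChaoEstimate,
    OTUTable,
    alpha_diversity,
    cluster_otus,
    estimated_total_otus,
    pairwise_distances,
)
from .simulate import ReferenceSet, SimConfig, mock_reference_set, simulate_run
from .taxonomy import TaxonomySummary, assign_all, summarize_relative_abundance

__all__ = ["BranchResult", "ValidationReport", "validate", "BRANCH_LABELS"]

BRANCH_LABELS = {1: "all", 2: "no_singletons", 3: "no_singletons_doubletons"}


@dataclass
class BranchResult:
    """All per-branch artefacts for one filtering threshold."""

    threshold: int
    label: str
    table: UniqueSeqTable
    error: ErrorReport
    otus: OTUTable
    diversity: "pd.DataFrame"
    diversity_summary: pd.DataFrame
    chao_total: ChaoEstimate
    assignments: pd.DataFrame
    taxonomy: TaxonomySummary


@dataclass
class ValidationReport:
    """Consolidated three-way comparison."""

    summary: pd.DataFrame
    branches: Dict[int, BranchResult]
    fit_comparison: FitComparison
    config: PipelineConfig
    refs: ReferenceSet

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.tsv", "w") as fh:
            fh.write(f"# mockamp stage=validate seed={self.config.seed}\n")
            self.summary.to_csv(fh, sep="\t")
        for t, br in self.branches.items():
            mio.write_shared(br.otus, outdir / f"shared_{br.label}.tsv", seed=self.config.seed)
            br.assignments.to_csv(outdir / f"taxonomy_{br.label}.tsv", sep="\t")
            genus = pd.DataFrame(
                {"mean_fraction": br.taxonomy.mean, "sem": br.taxonomy.sem}
            )
            genus.index.name = "genus"
            genus.to_csv(outdir / f"genus_{br.label}.tsv", sep="\t")
        self.config.to_file(outdir / "config.txt")


def _load_reads(config: PipelineConfig) -> Dict[str, List[str]]:
    """Reads per sample from a directory of FASTA/FASTQ files.

    With a ``groups.tsv`` present, all records are pooled and split by
    the read id -> sample map; otherwise each file is one sample named
    by its stem.
    """
    d = Path(config.reads_dir)
    files = sorted(
        p
        for p in d.iterdir()
        if p.suffix.lower() in (".fasta", ".fa", ".fastq", ".fq")
        and p.stem.lower() not in ("refs", "reference", "references")
    )
    if not files:
        raise ValueError(f"no FASTA/FASTQ files in {d}")

    def _read(p: Path) -> Dict[str, str]:
        if p.suffix.lower() in (".fastq", ".fq"):
            return mio.read_fastq(p)
        return mio.read_fasta(p)

    groups_path = d / "groups.tsv"
    if groups_path.exists():
        groups = mio.read_group_file(groups_path)
        by_sample: Dict[str, List[str]] = {}
        for p in files:
            for rid, seq in _read(p).items():
                if rid not in groups:
                    raise ValueError(f"read {rid!r} missing from {groups_path}")
                by_sample.setdefault(groups[rid], []).append(seq)
        return dict(sorted(by_sample.items()))
    return {p.stem: list(_read(p).values()) for p in files}


def _load_refs(config: PipelineConfig) -> ReferenceSet:
    seqs = mio.read_fasta(config.refs_fasta)
    taxa = {n: n.split("_")[0] for n in seqs}
    return ReferenceSet(sequences=seqs, taxa=taxa)


def validate(
    config: PipelineConfig,
    refs: Optional[ReferenceSet] = None,
    reads_by_sample: Optional[Dict[str, List[str]]] = None,
) -> ValidationReport:
    """Run the full three-way (all / no singletons / no singletons+doubletons)
    validation and return the consolidated report.

    Inputs come from, in order of precedence: the ``refs`` /
    ``reads_by_sample`` arguments, the paths in ``config``, or a
    simulation under the configured artefact rates.
    """
    if refs is None:
        if config.refs_fasta:
            refs = _load_refs(config)
        else:
            refs = mock_reference_set(
                length=config.template_length, seed=(config.seed + 1001) % 2**31
            )
    if reads_by_sample is None:
        if config.reads_dir:
            reads_by_sample = _load_reads(config)
        else:
            sim_cfg = SimConfig(
                n_samples=config.n_samples,
                depth=config.depth,
                sub_rate=config.sub_rate,
                ins_rate=config.ins_rate,
                del_rate=config.del_rate,
                chimera_prob=config.chimera_prob,
                noise_prob=config.noise_prob,
                bad_read_prob=config.bad_read_prob,
                bad_read_multiplier=config.bad_read_multiplier,
                error_heterogeneity=config.error_heterogeneity,
                noise_pool_size=config.noise_pool_size,
                seed=config.seed,
            )
            reads_by_sample = simulate_run(refs, sim_cfg).sequences_by_sample()

    raw = dereplicate(reads_by_sample)
    if config.rarefy_before_filter:
        base = rarefy(raw, config.rarefaction_depth, seed=(config.seed + 7) % 2**31)
    else:
        base = raw
    fit_comparison = filtering_improves_fit(base, thresholds=config.thresholds)

    branches: Dict[int, BranchResult] = {}
    rows = []
    for t in config.thresholds:
        branch_table, _ = remove_rare(base, t)
        if not config.rarefy_before_filter:
            branch_table = rarefy(
                branch_table, config.rarefaction_depth, seed=(config.seed + 7) % 2**31
            )
        label = BRANCH_LABELS.get(t, f"min_count_{t}")
        err = error_rate(branch_table, refs)
        counts, id_to_seq = branch_table.indexed()
        dm = pairwise_distances(
            id_to_seq, max_distance=max(3 * config.otu_cutoff, 0.1)
        )
        otus = cluster_otus(dm, config.otu_cutoff, counts=counts)
        div = alpha_diversity(otus)
        chao_total = estimated_total_otus(otus)
        assignments = assign_all(
            otus, branch_table, refs,
            min_identity=config.assignment_min_identity, id_to_seq=id_to_seq,
        )
        taxo = summarize_relative_abundance(
            otus, assignments, refs=refs, min_identity=config.assignment_min_identity
        )
        branches[t] = BranchResult(
            threshold=t, label=label, table=branch_table, error=err, otus=otus,
            diversity=div.per_sample, diversity_summary=div.summary,
            chao_total=chao_total, assignments=assignments, taxonomy=taxo,
        )
        s = div.summary
        rows.append(
            {
                "branch": label,
                "min_pooled_count": t,
                "unique_seqs": branch_table.n_unique,
                "reads": branch_table.total_reads(),
                "observed_otus": s.loc["observed_otus", "mean"],
                "observed_otus_sem": s.loc["observed_otus", "sem"],
                "chao": s.loc["chao", "mean"],
                "chao_sem": s.loc["chao", "sem"],
                "estimated_total_otus": chao_total.estimate,
                "shannon": s.loc["shannon", "mean"],
                "shannon_sem": s.loc["shannon", "sem"],
                "inverse_simpson": s.loc["inverse_simpson", "mean"],
                "inverse_simpson_sem": s.loc["inverse_simpson", "sem"],
                "error_rate_pct": err.overall_rate_pct,
                "unclassified_pct": 100.0 * taxo.unclassified_mean,
                "spectrum_r2": fit_comparison.r_squared.get(t),
            }
        )
    summary = pd.DataFrame(rows).set_index("branch")
    return ValidationReport(
        summary=summary,
        branches=branches,
        fit_comparison=fit_comparison,
        config=config,
        refs=refs,
    )
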