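"""File formats: FASTA/FASTQ, group files, count tables, shared-style
OTU tables and the pipeline configuration.

All tables are TSV with a header row; files written by the pipeline
start with a ``#`` provenance comment recording the stage, parameters
and seed, which readers skip.  Sequences are normalised to upper case
on input; FASTQ qualities are parsed but unused downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .derep import UniqueSeqTable
from .otus import OTUTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_group_file",
    "write_group_file",
    "read_count_table",
    "write_count_table",
    "write_shared",
    "PipelineConfig",
]


def _read_seqs(path, fmt: str) -> Dict[str, str]:
    path = Path(path)
    out: Dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in out:
                raise ValueError(f"duplicate record id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    except ValueError as e:
        raise ValueError(f"{path}: malformed {fmt.upper()}: {e}") from e
    if not out:
        raise ValueError(f"{path}: no {fmt.upper()} records found")
    return out


def read_fasta(path) -> Dict[str, str]:
    """Named sequences from a FASTA file, upper-cased; CRLF-safe."""
    return _read_seqs(path, "fasta")


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> Dict[str, str]:
    """Named sequences from a FASTQ file (qualities parsed, then dropped)."""
    return _read_seqs(path, "fastq")


def write_fastq(seqs: Mapping[str, str], path, quality: int = 40) -> None:
    """Write sequences as FASTQ with a flat per-base quality."""
    records = []
    for name, s in seqs.items():
        rec = SeqRecord(Seq(s), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_group_file(path) -> Dict[str, str]:
    """Two-column TSV mapping read id -> sample name."""
    df = pd.read_csv(path, sep="\t", header=None, names=["read_id", "sample"],
                     comment="#", dtype=str)
    if df["read_id"].duplicated().any():
        dup = df.loc[df["read_id"].duplicated(), "read_id"].iloc[0]
        raise ValueError(f"{path}: duplicate read id {dup!r} in group file")
    return dict(zip(df["read_id"], df["sample"]))


def write_group_file(groups: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, sample in groups.items():
            fh.write(f"{rid}\t{sample}\n")


def _provenance_line(stage: str, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# mockamp stage={stage} {kv}".rstrip()


def write_count_table(
    table: UniqueSeqTable, tsv_path, fasta_path=None, stage: str = "counts", **params
) -> None:
    """Count table as TSV (rows: sequence ids) plus a companion FASTA.

    The sequence strings live in the FASTA; the TSV carries ids so it
    stays reviewable.  A provenance comment precedes the header.
    """
    counts, id_to_seq = table.indexed()
    with open(tsv_path, "w") as fh:
        fh.write(_provenance_line(stage, provenance=table.provenance, **params) + "\n")
        counts.to_csv(fh, sep="\t")
    if fasta_path is not None:
        write_fasta(id_to_seq, fasta_path)


def read_count_table(tsv_path, fasta_path) -> UniqueSeqTable:
    """Rebuild a UniqueSeqTable from a count TSV and its companion FASTA."""
    counts = pd.read_csv(tsv_path, sep="\t", comment="#", index_col=0)
    seqs = read_fasta(fasta_path)
    missing = set(counts.index) - set(seqs)
    if missing:
        raise ValueError(f"{fasta_path}: missing sequences for ids {sorted(missing)[:3]}")
    counts.index = pd.Index([seqs[i] for i in counts.index])
    return UniqueSeqTable(counts.astype(int))


def write_shared(otus: OTUTable, path, stage: str = "cluster", **params) -> None:
    """Shared-style OTU table: one row per (sample, OTU) count matrix."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(stage, cutoff=otus.cutoff, **params) + "\n")
        df = otus.counts.T
        df.index.name = "sample"
        df.to_csv(fh, sep="\t")


@dataclass
class PipelineConfig:
    """End-to-end validation parameters.

    Round-trips losslessly through a key=value file.  When ``reads_dir``
    is unset the pipeline simulates its input instead of reading it.
    """

    reads_dir: str = ""
    refs_fasta: str = ""
    rarefaction_depth: int = 6654
    thresholds: Tuple[int, ...] = (1, 2, 3)
    otu_cutoff: float = 0.03
    assignment_min_identity: float = 80.0
    rarefy_before_filter: bool = True
    seed: int = 0
    # simulation parameters, used when reads_dir is empty
    n_samples: int = 12
    depth: int = 8000
    template_length: int = 250
    sub_rate: float = 0.002
    ins_rate: float = 0.0002
    del_rate: float = 0.0002
    chimera_prob: float = 0.01
    noise_prob: float = 0.05
    bad_read_prob: float = 0.1
    bad_read_multiplier: float = 25.0
    error_heterogeneity: float = 1.2
    noise_pool_size: int = 1000

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# mockamp pipeline configuration\n")
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: bad config line {line!r}")
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "thresholds":
                kwargs[f.name] = tuple(int(x) for x in v.split(",") if x)
            elif f.type in ("int",):
                kwargs[f.name] = int(v)
            elif f.type in ("float",):
                kwargs[f.name] = float(v)
            elif f.type in ("bool",):
                kwargs[f.name] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = v
        return cls(**kwargs)
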