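"""Ground-truthed amplicon read simulation.

The real validation experiment sequenced twelve replicate amplifications
of a defined 20-member community; those reads are not redistributable,
so every downstream stage is exercised on simulated runs with a known
truth table instead.  The simulator draws full-length amplicons (the
analysis operates on assembled contigs, so paired-end assembly is not
modelled) from a set of reference templates and layers on the artefact
classes seen in real amplicon data:

* per-base substitution and single-base insertion/deletion errors,
* PCR chimeras joining the prefix of one template to the suffix of
  another at a uniform interior breakpoint,
* per-template amplification efficiency multipliers (primer-binding
  bias), and
* a low-frequency noise tail of unalignable junk reads drawn from a
  random contaminant pool (cross-run contamination / library
  artefacts), mostly cross-sample singletons with a few recurring
  doubletons/tripletons.

Every read is recorded in a truth table (source template, chimera
parents and breakpoint, noise flag, injected error counts) so that
estimators can be checked against the injected ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import MockMember, packaged_members

__all__ = [
    "ReferenceSet",
    "SimConfig",
    "SimulatedRun",
    "generate_references",
    "mock_reference_set",
    "simulate_run",
    "synthetic_spectrum_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {c: i for i, c in enumerate("ACGT")}


def _to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


@dataclass
class ReferenceSet:
    """Named 16S gene templates with abundance weights and amplification bias.

    A genome may contribute more than one distinct template (divergent
    intragenomic 16S copies).  ``template_weights`` carry the expected
    relative template abundance (copies per genome x genome dosage);
    ``efficiency`` multiplies the weight to model primer-binding bias.
    """

    sequences: Dict[str, str]
    template_weights: Dict[str, float] = field(default_factory=dict)
    efficiency: Dict[str, float] = field(default_factory=dict)
    taxa: Dict[str, str] = field(default_factory=dict)
    is_bacterial: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference set has no sequences")
        for name, seq in self.sequences.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"reference {name!r} is empty or non-ACGT")
        self.template_weights = {
            n: float(self.template_weights.get(n, 1.0)) for n in self.sequences
        }
        if any(w < 0 for w in self.template_weights.values()):
            raise ValueError("template weights must be non-negative")
        if not any(w > 0 for w in self.template_weights.values()):
            raise ValueError("at least one template weight must be positive")
        self.efficiency = {
            n: float(self.efficiency.get(n, 1.0)) for n in self.sequences
        }
        if any(not 0 <= e <= 1 for e in self.efficiency.values()):
            raise ValueError("efficiencies must lie in [0, 1]")
        self.taxa = {n: self.taxa.get(n, n) for n in self.sequences}
        self.is_bacterial = {
            n: bool(self.is_bacterial.get(n, True)) for n in self.sequences
        }

    @property
    def names(self) -> List[str]:
        return list(self.sequences)

    def items(self):
        return self.sequences.items()

    def __len__(self) -> int:
        return len(self.sequences)

    def sampling_probabilities(self) -> np.ndarray:
        """Weight x efficiency, renormalised: template draw distribution."""
        p = np.array(
            [self.template_weights[n] * self.efficiency[n] for n in self.sequences]
        )
        total = p.sum()
        if total <= 0:
            raise ValueError("all templates have zero effective abundance")
        return p / total


def _mutate_fixed(arr: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly ``n_subs`` distinct positions to a different base."""
    out = arr.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    shift = rng.integers(1, 4, size=n_subs)
    idx = np.array([_IDX[chr(c)] for c in out[pos]], dtype=np.int64)
    out[pos] = _BASES[(idx + shift) % 4]
    return out


def generate_references(
    n_templates: int,
    length: int = 250,
    divergence_spec: Optional[Mapping[Tuple[int, int], float]] = None,
    seed: int = 0,
) -> ReferenceSet:
    """Generate random templates, optionally constraining pairwise identities.

    ``divergence_spec`` maps a template index pair ``(i, j)`` to a target
    identity fraction in (0, 1]; template ``j`` is then derived from
    template ``i`` by substituting ``round((1 - identity) * length)``
    positions, which realises the target to within a percentage point
    under global alignment.  Unconstrained templates are independent
    uniform-random sequences, whose mutual identity sits far below any
    OTU-merging cutoff.  A template index may take part in at most one
    constraint; anything else is rejected as contradictory.
    """
    if n_templates < 2:
        raise ValueError("need at least two templates")
    spec = dict(divergence_spec or {})
    used: set[int] = set()
    for (i, j), ident in spec.items():
        if not (0 < ident <= 1):
            raise ValueError(f"identity target {ident} outside (0, 1]")
        if i == j or not (0 <= i < n_templates and 0 <= j < n_templates):
            raise ValueError(f"bad template pair ({i}, {j})")
        if i in used or j in used:
            raise ValueError("contradictory divergence_spec: template reused")
        used.update((i, j))

    rng = np.random.default_rng(seed)
    arrs: Dict[int, np.ndarray] = {}
    for i in range(n_templates):
        if i not in arrs:
            arrs[i] = _BASES[rng.integers(0, 4, size=length)]
    for (i, j), ident in spec.items():
        n_subs = int(round((1.0 - ident) * length))
        arrs[j] = _mutate_fixed(arrs[i], n_subs, rng)

    width = max(2, len(str(n_templates)))
    seqs = {f"T{i + 1:0{width}d}": _to_str(arrs[i]) for i in range(n_templates)}
    return ReferenceSet(sequences=seqs)


#: default amplification-efficiency multipliers for the members whose V1
#: primer-binding sites carry mismatches and that are therefore observed
#: at ~1/100 and ~1/20 of their nominal share
DEFAULT_LOW_EFFICIENCY = {"Desulfovibrio": 0.01, "Coriobacterium": 0.046}


def mock_reference_set(
    members: Optional[Sequence[MockMember]] = None,
    length: int = 250,
    seed: int = 0,
    divergent_copy_identity: float = 0.94,
    divergent_copy_genus: str = "Haemophilus",
    low_efficiency: Optional[Mapping[str, float]] = None,
) -> ReferenceSet:
    """Synthetic 16S templates emulating the 20-member mock community.

    One random template per member, except the genus named in
    ``divergent_copy_genus`` (by default the Haemophilus member, whose
    two genomic 16S copies are only ~94 % identical and cluster as
    separate OTUs): it contributes two templates at
    ``divergent_copy_identity``.  Because the mock is balanced so every
    member contributes equal 16S copies, each member gets total weight
    1, split over its templates.  ``low_efficiency`` maps genus ->
    amplification efficiency for primer-mismatch bias (defaults emulate
    the under-amplified members with V1 primer-binding mismatches).
    """
    if members is None:
        members = packaged_members()
    rng = np.random.default_rng(seed)
    low_eff = (
        dict(DEFAULT_LOW_EFFICIENCY) if low_efficiency is None else dict(low_efficiency)
    )
    seqs: Dict[str, str] = {}
    weights: Dict[str, float] = {}
    eff: Dict[str, float] = {}
    taxa: Dict[str, str] = {}
    bact: Dict[str, bool] = {}
    for m in members:
        base = _BASES[rng.integers(0, 4, size=length)]
        if m.genus == divergent_copy_genus:
            n_subs = int(round((1.0 - divergent_copy_identity) * length))
            copies = [base, _mutate_fixed(base, n_subs, rng)]
        else:
            copies = [base]
        w = 1.0 / len(copies)
        for k, arr in enumerate(copies, start=1):
            name = f"{m.genus}_{k}"
            seqs[name] = _to_str(arr)
            weights[name] = w
            eff[name] = float(low_eff.get(m.genus, 1.0))
            taxa[name] = m.genus
            bact[name] = m.is_bacterial
    return ReferenceSet(
        sequences=seqs,
        template_weights=weights,
        efficiency=eff,
        taxa=taxa,
        is_bacterial=bact,
    )


@dataclass(frozen=True)
class SimConfig:
    """Run-shape and artefact-rate parameters for a simulated run.

    Defaults mirror the validation design: 12 replicate samples of one
    community.  Error rates are per base; ``chimera_prob`` and
    ``noise_prob`` are per read.
    """

    n_samples: int = 12
    depth: int = 1000
    sub_rate: float = 0.002
    ins_rate: float = 0.0002
    del_rate: float = 0.0002
    chimera_prob: float = 0.01
    noise_prob: float = 0.05
    #: fraction of reads with degraded base quality; their per-base error
    #: rates are multiplied by ``bad_read_multiplier``.  Real runs carry
    #: their error mass in a quality tail of reads, which is what makes
    #: cross-sample singleton removal so effective: the bad reads are
    #: nearly all unique.
    bad_read_prob: float = 0.1
    bad_read_multiplier: float = 25.0
    #: junk reads are drawn (with replacement) from a pool of this many
    #: random contaminant sequences, so a few recur as cross-sample
    #: doubletons/tripletons the way low-level cross-run contamination does
    noise_pool_size: int = 1000
    #: sigma of the lognormal per-position substitution-rate multipliers
    #: (mean-normalised per template).  Real short-read runs have strongly
    #: position/motif-dependent error rates; heterogeneity spreads error
    #: variants over intermediate cluster sizes instead of pure singletons.
    #: 0 gives a uniform per-base rate.
    error_heterogeneity: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.depth < 1:
            raise ValueError("n_samples and depth must be >= 1")
        for attr in ("sub_rate", "ins_rate", "del_rate", "chimera_prob", "noise_prob"):
            v = getattr(self, attr)
            if not 0 <= v <= 1:
                raise ValueError(f"{attr}={v} outside [0, 1]")
        if self.error_heterogeneity < 0:
            raise ValueError("error_heterogeneity must be >= 0")
        if self.noise_pool_size < 1:
            raise ValueError("noise_pool_size must be >= 1")
        if not 0 <= self.bad_read_prob <= 1:
            raise ValueError("bad_read_prob outside [0, 1]")
        if self.bad_read_multiplier < 1:
            raise ValueError("bad_read_multiplier must be >= 1")


@dataclass
class SimulatedRun:
    """Reads per sample plus the per-read ground truth."""

    reads: Dict[str, List[Tuple[str, str]]]
    truth: pd.DataFrame
    config: SimConfig

    @property
    def samples(self) -> List[str]:
        return list(self.reads)

    def sequences_by_sample(self) -> Dict[str, List[str]]:
        return {s: [seq for _, seq in pairs] for s, pairs in self.reads.items()}


def _inject_errors(
    arr: np.ndarray,
    sub_p: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, int, int, int]:
    """Apply per-base substitutions (position-specific rates ``sub_p``) and
    single-base indels to a template copy."""
    out = arr
    sub_mask = rng.random(len(out)) < sub_p
    n_sub = int(sub_mask.sum())
    if n_sub:
        out = out.copy()
        pos = np.flatnonzero(sub_mask)
        idx = np.array([_IDX[chr(c)] for c in out[pos]])
        out[pos] = _BASES[(idx + rng.integers(1, 4, size=n_sub)) % 4]
    n_ins = n_del = 0
    if cfg.del_rate > 0 or cfg.ins_rate > 0:
        del_mask = rng.random(len(out)) < cfg.del_rate
        ins_mask = rng.random(len(out)) < cfg.ins_rate
        n_del = int(del_mask.sum())
        n_ins = int(ins_mask.sum())
        if n_del or n_ins:
            pieces: List[np.ndarray] = []
            ins_bases = _BASES[rng.integers(0, 4, size=n_ins)]
            it = iter(ins_bases)
            for i, b in enumerate(out):
                if not del_mask[i]:
                    pieces.append(out[i : i + 1])
                if ins_mask[i]:
                    pieces.append(np.array([next(it)], dtype=np.uint8))
            out = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    return out, n_sub, n_ins, n_del


def simulate_run(refs: ReferenceSet, cfg: SimConfig) -> SimulatedRun:
    """Draw ``cfg.depth`` reads for each of ``cfg.n_samples`` samples.

    Per read: with ``chimera_prob`` a two-parent chimera is formed (then
    sequenced with the same per-base error model); with ``noise_prob`` a
    junk read is drawn from the run's random contaminant pool; otherwise
    a template is drawn from the weight x efficiency distribution and
    copied with per-base errors (position-specific substitution rates
    when ``error_heterogeneity`` > 0).  Identical (refs, cfg) give
    identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    names = refs.names
    arrs = [_to_arr(refs.sequences[n]) for n in names]
    probs = refs.sampling_probabilities()
    mean_len = int(round(np.mean([len(a) for a in arrs])))

    # run-level per-position substitution-rate profiles, one per template;
    # mean-normalised so each template's expected error rate is sub_rate
    sub_profiles: List[np.ndarray] = []
    for a in arrs:
        if cfg.error_heterogeneity > 0 and cfg.sub_rate > 0:
            mult = rng.lognormal(0.0, cfg.error_heterogeneity, size=len(a))
            mult /= mult.mean()
        else:
            mult = np.ones(len(a))
        sub_profiles.append(np.minimum(cfg.sub_rate * mult, 1.0))

    noise_pool: List[np.ndarray] = []
    if cfg.noise_prob > 0:
        noise_pool = [
            _BASES[rng.integers(0, 4, size=mean_len)]
            for _ in range(cfg.noise_pool_size)
        ]

    reads: Dict[str, List[Tuple[str, str]]] = {}
    truth_rows: List[dict] = []
    for si in range(cfg.n_samples):
        sample = f"S{si + 1:02d}"
        pairs: List[Tuple[str, str]] = []
        for ri in range(cfg.depth):
            rid = f"{sample}_r{ri + 1:05d}"
            u = rng.random()
            if u < cfg.chimera_prob:
                # parents drawn independently from the same distribution
                ia = int(rng.choice(len(names), p=probs))
                ib = int(rng.choice(len(names), p=probs))
                la, lb = len(arrs[ia]), len(arrs[ib])
                bp = int(rng.integers(1, min(la, lb)))
                raw = np.concatenate([arrs[ia][:bp], arrs[ib][bp:]])
                raw_p = np.concatenate([sub_profiles[ia][:bp], sub_profiles[ib][bp:]])
                bad = bool(rng.random() < cfg.bad_read_prob)
                if bad:
                    raw_p = np.minimum(raw_p * cfg.bad_read_multiplier, 1.0)
                out, n_sub, n_ins, n_del = _inject_errors(raw, raw_p, cfg, rng)
                pairs.append((rid, _to_str(out)))
                truth_rows.append(
                    dict(
                        read_id=rid, sample=sample, source=names[ia],
                        source2=names[ib], is_chimera=True, breakpoint=bp,
                        is_noise=False, bad_read=bad,
                        n_sub=n_sub, n_ins=n_ins, n_del=n_del,
                    )
                )
            elif u < cfg.chimera_prob + cfg.noise_prob:
                ic = int(rng.integers(0, len(noise_pool)))
                pairs.append((rid, _to_str(noise_pool[ic])))
                truth_rows.append(
                    dict(
                        read_id=rid, sample=sample, source=f"contam{ic:04d}",
                        source2="", is_chimera=False, breakpoint=-1,
                        is_noise=True, bad_read=False,
                        n_sub=0, n_ins=0, n_del=0,
                    )
                )
            else:
                it = int(rng.choice(len(names), p=probs))
                p_arr = sub_profiles[it]
                bad = bool(rng.random() < cfg.bad_read_prob)
                if bad:
                    p_arr = np.minimum(p_arr * cfg.bad_read_multiplier, 1.0)
                out, n_sub, n_ins, n_del = _inject_errors(arrs[it], p_arr, cfg, rng)
                pairs.append((rid, _to_str(out)))
                truth_rows.append(
                    dict(
                        read_id=rid, sample=sample, source=names[it],
                        source2="", is_chimera=False, breakpoint=-1,
                        is_noise=False, bad_read=bad,
                        n_sub=n_sub, n_ins=n_ins, n_del=n_del,
                    )
                )
        reads[sample] = pairs
    truth = pd.DataFrame(truth_rows)
    return SimulatedRun(reads=reads, truth=truth, config=cfg)


def synthetic_spectrum_table(
    spectrum: Mapping[int, int],
    n_samples: int = 2,
    seq_length: int = 16,
) -> "pd.DataFrame":
    """Synthetic unique-sequence count table realising a given cluster-size
    spectrum exactly.

    For each (size, frequency) entry, ``frequency`` distinct synthetic
    sequences are created with pooled count ``size``, spread as evenly
    as possible over ``n_samples`` samples.  Used to exercise
    spectrum-shape diagnostics on a controlled trend (e.g. a power law
    with an injected singleton excess) rather than on simulator output.
    Returns the counts frame from which a UniqueSeqTable can be built.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rows = {}
    idx = 0
    for size, freq in sorted(spectrum.items()):
        if size < 1 or freq < 0:
            raise ValueError(f"invalid spectrum entry {size}:{freq}")
        for _ in range(freq):
            # deterministic distinct sequence from the row index
            digits = []
            v = idx
            for _ in range(seq_length):
                digits.append("ACGT"[v % 4])
                v //= 4
            seq = "".join(digits)
            base, rem = divmod(size, n_samples)
            rows[seq] = [base + (1 if k < rem else 0) for k in range(n_samples)]
            idx += 1
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"S{k + 1:02d}" for k in range(n_samples)]
    )
    return df
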