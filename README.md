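# mockamp

Mock-community validation of V1–V3 16S rRNA amplicon sequencing
pipelines: design a copy-balanced mock community, simulate (or ingest)
multi-sample amplicon runs with a known ground truth, remove
cross-sample singleton/doubleton sequences, and quantify what that
filtering does to the sequencing error rate, OTU richness, alpha
diversity and taxonomic assignment.

## Who this is for

Microbiome researchers who sequence the long V1–V3 region (~490 bp) on
short-read instruments. Long amplicons buy taxonomic resolution at the
price of a heavy tail of erroneous, chimeric and contaminant sequences
— most of which occur exactly once or twice across an entire run.
`mockamp` implements and stress-tests the curation step that handles
them: *unreferenced removal of cross-sample singletons and doubletons
before OTU clustering*, validated against a community whose composition
is known exactly.

## The method

**Balanced mock design.** With Avogadro's number N_A and a mean
double-stranded base-pair mass of 650 g·mol⁻¹, one microgram of a
genome of *L* bp contains

```
copies/µg = 10⁻⁶ · N_A / (650 · L)  ≈  9.2646×10¹⁴ / L
```

genome copies. The mass of member *i*'s DNA that contributes a target
number of 16S gene copies is

```
mass_i = target_copies / (c_i · copies/µg_i)
```

where c_i is the member's 16S copies per genome; giving every member
the same target makes each contribute an equal share (5 % for 20
members) of the stock's 16S copies.

**Cross-sample filtering.** After pooling all replicate samples and
dereplicating to exact-identity unique sequences, a *cross-sample
singleton* (doubleton) is a sequence read exactly once (twice) over all
samples. Samples are first rarefied to a common depth, then analysed
three ways: all sequences, singletons removed, singletons + doubletons
removed.

**Error rate.** Each unique sequence is globally aligned to its
best-matching known reference; the error rate is the abundance-weighted
fraction of mismatched + inserted + deleted bases over aligned bases,
with reference-flagged chimeras excluded.

**OTUs and diversity.** Average-neighbour clustering at distance 0.03
(97 % similarity) groups sequences into OTUs; per sample the panel
reports observed richness S_obs, bias-corrected Chao1
`S_obs + n₁(n₁−1)/(2(n₂+1))`, Shannon entropy `−Σ pᵢ ln pᵢ` and the
unbiased inverse Simpson `1/Σ[nᵢ(nᵢ−1)/(N(N−1))]`, summarised as mean ±
SEM over the replicates.

**Spectrum diagnostics.** The frequency of unique-sequence cluster
sizes on log/log axes is near-linear for clean data; artefacts bend the
low end. OLS and lowess fits quantify the deviation and the improvement
after filtering.

Because the real MiSeq reads behind this design are not
redistributable, the package ships a ground-truthed simulator
(`mockamp.simulate`) whose runs carry a per-read truth table, so every
estimator is validated against known inputs.

## Worked example

`examples/07_full_validation.py` runs the full three-way comparison on
a simulated 12-replicate run (800 reads/sample, rarefied to 700):

```
                          unique_seqs  reads  observed_otus      chao  shannon  inverse_simpson  error_rate_pct  unclassified_pct
branch
all                              4084   8400        127.250  3627.403    3.625           26.072           0.793             5.337
no_singletons                     364   4680         30.333    59.444    3.028           19.722           0.098             2.933
no_singletons_doubletons           84   4120         21.333    22.458    2.929           18.735           0.020             0.414
```

Reading top to bottom: the unfiltered data sees ~127 OTUs per sample
where only 20 bacterial OTUs truly exist (19 genomes, one of which
carries two 16S copies ~94 % identical that cluster separately), with a
0.79 % per-base error rate and 5.3 % unclassifiable reads. Removing
cross-sample singletons, then doubletons, pulls observed richness to
~21, cuts the error rate 40-fold and nearly empties the unclassified
bin — while keeping roughly half the reads and all community members.

The other `examples/` scripts each demonstrate one capability (design
arithmetic, simulation, filtering accounting, error rates, OTU
clustering + diversity, spectrum diagnostics) and print a short
interpretation with their numbers.

A `mockamp` command-line tool wraps the same functions
(`design`, `simulate`, `derep`, `filter`, `error`, `cluster`,
`diversity`, `diagnose`, `validate`); run `mockamp --help`.

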