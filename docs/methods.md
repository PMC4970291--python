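# Methods

This note records the models, parameter choices and numerical
conventions behind `mockamp`, and what the simulation-based tests do
and do not establish about real data.

## Community design arithmetic

The copies-per-microgram calculator uses the standard dsDNA molarity
formula with N_A = 6.022×10²³ mol⁻¹ and 650 g·mol⁻¹ per base pair,
i.e. `9.2646×10¹⁴ / genome_size`. Published per-microgram estimates for
the bundled 20-member table (19 bacteria plus one archaeon kept as a
non-specific-amplification control) are reproduced to ±1 in the third
significant digit; a one-unit discrepancy in one row is consistent with
truncation rather than rounding at the source, so the regression test
compares values after rounding the computed number to three significant
figures.

## Alignment and identity

All sequence comparison goes through unit-cost global alignment
(edlib): the alignment minimising substitutions + inserted + deleted
bases. Identity is `matches / alignment columns` with terminal gap runs
excluded, so length differences at the ends are not penalised. Two
consequences are handled explicitly:

* Several alignments can share the optimal cost, and the trimmed
  identity can differ between them. `pairwise_identity` therefore
  aligns each pair in a canonical (lexicographic) order, making it
  exactly symmetric; the raw edit distance, which is path-independent,
  is also exposed on every `AlignmentResult`.
* For all-against-all distance matrices, alignment of a pair is
  abandoned once its distance provably exceeds a cap (`max_distance`);
  such pairs are recorded at distance 1.0. Any cap at or above the
  clustering cutoff leaves the resulting OTUs unchanged while making
  matrices of thousands of sequences affordable.

Unit cost was chosen over a scored scheme (e.g. match +1 / mismatch −1
/ gap −2) because a highly optimised implementation exists for it, the
per-base error definition (each mismatched, inserted or deleted base is
one error) maps onto it directly, and on the near-identical pairs that
matter here the two schemes produce the same alignments.

## Chimera flagging

A deliberately simple reference-based bimera test, valid in the mock
setting because the true parents are known: split the query at evenly
spaced interior breakpoints, find the best reference for each fragment
(infix alignment, so a fragment may match any portion of a reference),
and flag when the two parents differ and the length-weighted two-parent
identity beats the best single-reference identity by ≥ 2 percentage
points. Sequences already ≥ 98 % identical to a single reference cannot
reach that margin and skip the test. A chimera of two identical parents
is undetectable by construction and is deliberately not flagged. This
is not a re-implementation of general-purpose de novo chimera
detectors.

## Filtering, rarefaction and stage order

Cross-sample singletons/doubletons are defined on pooled counts over
all samples, not per sample. Rarefaction is a single
multivariate-hypergeometric draw per sample per seed (no averaging over
draws). The default stage order is rarefy → filter, with a
configuration flag (`rarefy_before_filter=False`) to swap it, since
either order is defensible; the filter-then-rarefy branch rarefies each
threshold branch independently. "Cluster" in the spectrum diagnostics
means an exact-identity unique-sequence group, not a 97 % OTU.

## Clustering and diversity

OTUs are built by average-neighbour agglomeration: merge the pair of
clusters with the smallest average inter-cluster distance while it is
≤ the cutoff (0.03 by default). Ties resolve to the smallest index
pair, making the partition deterministic; the implementation
(Lance–Williams updates) is cross-checked in tests against both a
from-scratch naive oracle and an independent hierarchical-clustering
library. Because average linkage is monotone, merging-with-cutoff is
equivalent to cutting the full dendrogram at the cutoff height.

Diversity conventions: Chao1 uses the bias-corrected form with (n₂+1)
in the denominator (defined at n₂ = 0); Shannon uses natural log;
inverse Simpson uses the unbiased finite-sample form and returns an
explicit undefined marker (NaN) for single-read samples or when every
OTU is a singleton; a zero-read sample is an error, not a number. The
"estimated total OTUs" column is the pooled bias-corrected Chao1 with
its 95 % confidence interval, a nonparametric stand-in for
mixture-model richness estimators, and is labelled as such.

## Spectrum diagnostics

The log/log cluster-size spectrum is fit by unweighted OLS over the
distinct-size points and by lowess with the classic defaults (span 2/3,
3 robustifying iterations); a weighted regression is available behind a
flag but not the default. The improvement-after-filtering comparison
reports r² per threshold and flags monotone improvement; it is marked
not-evaluable when a branch has fewer than three distinct sizes.

## The simulator: what it emulates

`simulate_run` produces full-length amplicons (the analysis operates on
assembled contigs; paired-end overlap assembly is upstream and not
modelled) from a reference set with:

* **Substitution errors** at per-base rate `sub_rate` (default 0.002),
  modulated two ways: per-position lognormal rate multipliers
  (`error_heterogeneity` = 1.2, mean-normalised per template), because
  short-read error rates are strongly position/motif-dependent and this
  is what populates intermediate cluster sizes with recurring error
  variants; and a read-quality mixture (`bad_read_prob` = 0.1 of reads
  at `bad_read_multiplier` = 25× the rate), because real runs carry
  their error mass in a quality tail. The tail is what makes
  cross-sample singleton removal so effective: bad reads are nearly
  all unique, and each typically lands > 3 % away from its template,
  inflating observed OTU counts until filtered.
* **Single-base indels** at rates `ins_rate` = `del_rate` = 2×10⁻⁴.
* **Chimeras** at `chimera_prob` = 0.01 per read: prefix of one
  template joined to the suffix of another at a uniform interior
  breakpoint, parents drawn from the same weighted distribution, then
  sequenced with the same error model.
* **A contaminant noise tail** at `noise_prob` = 0.05 per read, drawn
  with replacement from a pool of `noise_pool_size` = 1000 random
  sequences. Pool draws make a few contaminants recur as cross-sample
  doubletons/tripletons — the behaviour of low-level cross-run
  contamination — which is what doubleton removal (threshold 3)
  specifically cleans up after singleton removal has done the bulk of
  the work.
* **Amplification bias**: per-template efficiency multipliers. The
  default mock reference set gives two members strongly reduced
  efficiencies (0.01 and 0.046), emulating members whose V1
  primer-binding sites carry mismatches and that are consequently
  detected far below their nominal 5 % input share.

The synthetic mock reference set mirrors the community's structure: one
random 250 bp template per member, equal per-member template weight
(the community is balanced by 16S copies, so equal dosage × copies is
constant), and one member contributing two copies at 94 % identity —
which is why 19 bacterial genomes yield 20 bacterial OTUs at the 0.03
cutoff.

**What it does not emulate:** quality scores, motif-specific indel
hotspots, PCR-cycle dynamics, abundance variation between members
(the mock is balanced by design), and between-run index hopping beyond
the random contaminant pool. Template length (250 bp) and per-sample
depth in tests (hundreds) are scaled down from the real amplicon
(~490 bp) and run depth (6654/sample after rarefaction); per-sample
depth controls how strongly artefacts inflate richness, so absolute
OTU counts from simulations are not predictions for any real run —
only the directional comparisons (filtered vs unfiltered) and the
estimator validations transfer.

One known divergence: on this simulator the spectrum-fit r² is not
guaranteed to improve monotonically with filtering, because a balanced
community at moderate depth produces fewer distinct cluster sizes than
a deep real run. The r²-improvement property is therefore exercised on
a controlled fixture (an exact power-law spectrum with an injected
singleton excess, `synthetic_spectrum_table`), which isolates the
low-end deviation the diagnostic is designed to expose; on simulator
output the tests assert the weaker, robust signature that the
singleton class sits above the power-law trend fitted to the rest of
the spectrum.

## Taxonomy

Nearest-reference assignment replaces database classification because
the community is defined: an OTU's representative (most abundant member
sequence; ties to the lexicographically smallest) is labelled with the
genus of its best-identity reference when identity ≥ 80 %, else
"unclassified". Reads assigned to the archaeal control are counted
separately and excluded from bacterial relative-abundance summaries.

## Problem sizes and determinism

The acceptance script and the heaviest test run 12 samples × 800 reads
rarefied to 700 — deep enough for ≥ 5-fold unfiltered richness
inflation while a full three-way validation completes in about two
minutes; the exact-depth rarefaction contract (6654 reads/sample) is
exercised on a constructed count table. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configurations give byte-identical outputs, including written reports.
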