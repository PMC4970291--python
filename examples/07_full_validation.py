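"""The full three-way validation on a simulated 12-replicate run.

Reproduces the central comparison: analyse the same rarefied data (1)
with all sequences, (2) with cross-sample singletons removed, and (3)
with singletons and doubletons removed, and tabulate error rate,
richness, diversity and unclassified fraction per branch.

Takes a couple of minutes at this scale.
"""

from mockamp import PipelineConfig, validate

cfg = PipelineConfig(n_samples=12, depth=800, rarefaction_depth=700, seed=20)
report = validate(cfg)

cols = ["unique_seqs", "reads", "observed_otus", "chao",
        "shannon", "inverse_simpson", "error_rate_pct", "unclassified_pct"]
print(report.summary[cols].round(3).to_string())
print()
print("reading the table top to bottom: each filtering step strictly lowers")
print("the error rate and pulls observed richness toward the 20 true")
print("bacterial OTUs, while the unclassified share collapses -- artefact")
print("removal without losing the real community signal.")
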