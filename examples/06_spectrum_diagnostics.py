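"""Log-log cluster-size spectrum: regression and lowess diagnostics.

Plotting log10(cluster size) against log10(frequency of that size)
exposes the artefact excess at sizes 1-2 as a deviation from the
otherwise near-linear trend; removing those classes restores the fit.
"""

import numpy as np

from mockamp import (
    UniqueSeqTable,
    fit_spectrum,
    filtering_improves_fit,
    synthetic_spectrum_table,
)
from mockamp.derep import cluster_size_spectrum

# an exact power-law spectrum (freq = 4096 / size^2) with an injected
# excess of singleton artefacts
spectrum = {2**i: 4 ** (6 - i) for i in range(7)}
spectrum[1] += 20000
table = UniqueSeqTable(synthetic_spectrum_table(spectrum))

fit = fit_spectrum(cluster_size_spectrum(table))
print("unfiltered spectrum:")
print(f"  OLS slope {fit.linear.slope:.2f}, r^2 {fit.linear.r_squared:.3f}, "
      f"residual SE {fit.linear.residual_se:.3f}")
dev = fit.lowess[:, 1] - fit.linear.predict(fit.points[:, 0])
print(f"  lowess-vs-line deviation is largest at the smallest cluster size "
      f"(size 1: {dev[0]:+.2f} log units)")

cmp = filtering_improves_fit(table)
print("r^2 after filtering at pooled-count thresholds 1/2/3: "
      + ", ".join(f"{t}: {r:.3f}" for t, r in cmp.r_squared.items()))
print(f"monotone improvement: {cmp.monotone_improvement}")
print("the singleton excess bends the low end of the spectrum; dropping the")
print("rare classes leaves the underlying power law and a near-perfect fit.")
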