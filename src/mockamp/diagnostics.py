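"""Cluster-size spectrum diagnostics on log/log axes.

For a deeply sequenced defined community, the frequency of
unique-sequence cluster sizes is close to a power law, so plotting
log10(cluster size) against log10(frequency of that size) gives a near
line.  Sequencing artefacts pile up at cluster sizes 1-2 and bend the
low end of the spectrum away from that line; both an ordinary
least-squares fit and a lowess smooth make the deviation visible, and
removing cross-sample singletons/doubletons improves the linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .derep import UniqueSeqTable, cluster_size_spectrum, remove_rare

__all__ = [
    "LinearFit",
    "SpectrumFit",
    "FitComparison",
    "loglog_spectrum",
    "fit_linear",
    "lowess_fit",
    "fit_spectrum",
    "filtering_improves_fit",
]


def loglog_spectrum(spectrum: Mapping[int, int]) -> np.ndarray:
    """(log10 size, log10 frequency) points, sorted by size.

    Zero-frequency entries are dropped rather than logged; sizes and
    retained frequencies must be >= 1.
    """
    if not spectrum:
        raise ValueError("empty spectrum")
    pts = []
    for size, freq in sorted(spectrum.items()):
        if freq == 0:
            continue
        if size < 1 or freq < 0:
            raise ValueError(f"invalid spectrum entry {size}:{freq}")
        pts.append((np.log10(size), np.log10(freq)))
    return np.array(pts)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    residual_se: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x) + self.intercept


def fit_linear(points: np.ndarray) -> LinearFit:
    """Ordinary least squares on (x, y) points; r^2 is the coefficient of
    determination, residual SE is sqrt(SS_res / (n - 2))."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 3:
        raise ValueError("need at least 3 points for a linear fit")
    x, y = points[:, 0], points[:, 1]
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rse = float(np.sqrt((resid**2).sum() / (len(x) - 2)))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residual_se=rse,
    )


def lowess_fit(
    points: np.ndarray, fraction: float = 2.0 / 3.0, iterations: int = 3
) -> np.ndarray:
    """Lowess smooth (tricube-weighted local linear regression) of the points.

    Classic defaults: a 2/3 span and 3 robustifying iterations.
    Returns the smoothed (x, y_hat) array at the input x positions.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 4:
        raise ValueError("need at least 4 points for lowess")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(points)
    if int(np.ceil(fraction * n)) < 2:
        raise ValueError("fraction too small: windows hold fewer than 2 points")
    out = sm.nonparametric.lowess(
        points[:, 1], points[:, 0], frac=fraction, it=iterations, delta=0.0
    )
    return np.asarray(out)


@dataclass
class SpectrumFit:
    """A spectrum's log-log points with their linear and lowess fits."""

    points: np.ndarray
    linear: Optional[LinearFit]
    lowess: Optional[np.ndarray]
    lowess_fraction: float
    lowess_iterations: int


def fit_spectrum(
    spectrum: Mapping[int, int],
    fraction: float = 2.0 / 3.0,
    iterations: int = 3,
) -> SpectrumFit:
    """Log-log points plus OLS and lowess fits (None when too few points)."""
    pts = loglog_spectrum(spectrum)
    linear = fit_linear(pts) if len(pts) >= 3 else None
    low = lowess_fit(pts, fraction, iterations) if len(pts) >= 4 else None
    return SpectrumFit(
        points=pts,
        linear=linear,
        lowess=low,
        lowess_fraction=fraction,
        lowess_iterations=iterations,
    )


@dataclass
class FitComparison:
    """r^2 of the log-log linear fit under successive rare-sequence filters."""

    r_squared: Dict[int, Optional[float]]  # threshold -> r^2 (None: too few points)
    evaluable: bool
    monotone_improvement: Optional[bool]


def filtering_improves_fit(
    table: UniqueSeqTable, thresholds: Sequence[int] = (1, 2, 3)
) -> FitComparison:
    """Compare spectrum-fit quality across pooled-count filter thresholds.

    For each threshold the table is filtered, its cluster-size spectrum
    refit by OLS on log-log axes, and the r^2 values compared; the
    comparison is marked not-evaluable when any branch has fewer than 3
    distinct cluster sizes.
    """
    r2: Dict[int, Optional[float]] = {}
    for t in thresholds:
        sub, _ = remove_rare(table, t)
        if sub.n_unique == 0:
            r2[t] = None
            continue
        pts = loglog_spectrum(cluster_size_spectrum(sub))
        r2[t] = fit_linear(pts).r_squared if len(pts) >= 3 else None
    vals = [r2[t] for t in thresholds]
    evaluable = all(v is not None for v in vals)
    monotone = None
    if evaluable:
        monotone = all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    return FitComparison(r_squared=r2, evaluable=evaluable, monotone_improvement=monotone)
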