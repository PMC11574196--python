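"""Heteroplasmy classification from h-value distributions.

The final-timepoint h distribution of a segregating population is
trimodal: a left peak of NeonGreen-homoplasmic cells, a middle peak of
heteroplasmic cells, and a right peak of mKate2-homoplasmic cells.  We
fit a three-component Gaussian mixture by EM and place the homoplasmy
thresholds at the intersection points of adjacent weighted component
densities, reproducing the cutoff construction that yields the standard
0.33 / 0.71 pair.  For 24-h dark/bright scoring of end-point colonies a
kernel-density valley between the two intensity modes is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

CLASS_HOMO_NG = "homo_NG"
CLASS_HET = "heteroplasmic"
CLASS_HOMO_MKATE = "homo_mKate"


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component on the h scale."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def density(self, x) -> np.ndarray:
        return self.weight * stats.norm.pdf(x, self.mean, self.sd)


@dataclass(frozen=True)
class ThresholdPair:
    """Low/high homoplasmy cutoffs on the h scale."""

    low: float = 0.33
    high: float = 0.71

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high < 1.0:
            raise ValueError("thresholds must satisfy 0 < low < high < 1")


DEFAULT_THRESHOLDS = ThresholdPair(0.33, 0.71)


def fit_three_gaussians(
    h_values,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[GaussianComponent]:
    """Fit a 3-component normal mixture to h values by EM.

    Initialization is deterministic: component means start at the 1/6,
    3/6 and 5/6 sample quantiles with equal weights and the sample
    variance, so the fit is reproducible given the data.  Components are
    returned ordered by mean.  Near-degenerate output (a component
    collapsing to negligible weight or vanishing spread) is reported in
    the raised error or left to the caller to inspect.
    """
    x = np.asarray(h_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 30:
        raise ValueError("need at least 30 h values for a 3-component fit")
    if (x < 0).any() or (x > 1).any():
        raise ValueError("h values must lie in [0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all h values identical (sd -> 0)")
    means_init = np.quantile(x, [1 / 6, 3 / 6, 5 / 6]).reshape(-1, 1)
    var = x.var()
    gm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        means_init=means_init,
        weights_init=np.full(3, 1 / 3),
        precisions_init=np.full((3, 1, 1), 1.0 / var),
        reg_covar=1e-10,
    )
    gm.fit(x.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(lower bound {gm.lower_bound_:.6g}); inspect the data for degeneracy"
        )
    comps = [
        GaussianComponent(float(w), float(m[0]), float(np.sqrt(c[0, 0])))
        for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_)
    ]
    return sorted(comps, key=lambda c: c.mean)


def intersection(a: GaussianComponent, b: GaussianComponent) -> float:
    """Crossing point of two weighted Gaussian densities between their means.

    Solves ``w_a N(x; mu_a, sd_a) = w_b N(x; mu_b, sd_b)`` — a quadratic
    in x for unequal sd, linear for equal sd — and returns the root that
    lies strictly between the two means, falling back to bisection of
    the log-density difference when the closed form yields none.
    """
    if not a.mean < b.mean:
        raise ValueError("components must be passed in increasing order of mean")
    # log(w_a) - log(sd_a) - (x-mu_a)^2 / (2 sd_a^2) = same for b
    c2 = 1.0 / (2 * b.sd**2) - 1.0 / (2 * a.sd**2)
    c1 = a.mean / a.sd**2 - b.mean / b.sd**2
    c0 = (
        np.log(a.weight / a.sd)
        - np.log(b.weight / b.sd)
        - a.mean**2 / (2 * a.sd**2)
        + b.mean**2 / (2 * b.sd**2)
    )
    roots: list[float]
    if abs(c2) < 1e-14:
        roots = [] if abs(c1) < 1e-14 else [-c0 / c1]
    else:
        disc = c1**2 - 4 * c2 * c0
        if disc < 0:
            roots = []
        else:
            s = np.sqrt(disc)
            roots = [(-c1 - s) / (2 * c2), (-c1 + s) / (2 * c2)]
    between = [r for r in roots if a.mean < r < b.mean]
    if between:
        return float(between[0] if len(between) == 1 else min(between, key=lambda r: abs(r - (a.mean + b.mean) / 2)))

    def logdiff(x: float) -> float:
        return (
            np.log(a.weight / a.sd)
            - (x - a.mean) ** 2 / (2 * a.sd**2)
            - np.log(b.weight / b.sd)
            + (x - b.mean) ** 2 / (2 * b.sd**2)
        )

    lo, hi = a.mean + 1e-9, b.mean - 1e-9
    if logdiff(lo) * logdiff(hi) > 0:
        raise ValueError(
            "no intersection strictly between the component means "
            "(extreme weight imbalance or identical components)"
        )
    return float(optimize.brentq(logdiff, lo, hi))


def thresholds_from_components(components: list[GaussianComponent]) -> ThresholdPair:
    """Homoplasmy thresholds from the two adjacent-component intersections."""
    if len(components) != 3:
        raise ValueError("expected exactly three components")
    lo, mid, hi = sorted(components, key=lambda c: c.mean)
    return ThresholdPair(intersection(lo, mid), intersection(mid, hi))


def classify_h(h: float, thresholds: ThresholdPair = DEFAULT_THRESHOLDS) -> str:
    """Assign one h value to homo_NG / heteroplasmic / homo_mKate.

    Boundary values count as heteroplasmic (strict inequalities), so the
    three classes partition [0, 1].
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    if h < thresholds.low:
        return CLASS_HOMO_NG
    if h > thresholds.high:
        return CLASS_HOMO_MKATE
    return CLASS_HET


def classify_many(h_values, thresholds: ThresholdPair = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized :func:`classify_h`; NaN h values map to the empty string."""
    h = np.asarray(h_values, dtype=float)
    out = np.full(h.shape, CLASS_HET, dtype=object)
    out[h < thresholds.low] = CLASS_HOMO_NG
    out[h > thresholds.high] = CLASS_HOMO_MKATE
    out[np.isnan(h)] = ""
    return out


def valley_threshold(intensities, grid_size: int = 512) -> float:
    """Intensity cutoff at the KDE valley between the two dominant modes.

    Density is a Gaussian KDE with Silverman bandwidth; modes are local
    maxima exceeding 10 % of the global maximum.  Used for the 24-h
    dark/bright ('signal' vs 'no signal') scoring, where the threshold
    is the lowest point of the valley between the two peaks.  Unimodal
    input raises (no valley).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values for a valley threshold")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no valley")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_max & (dens[interior] >= 0.1 * dens.max())]
    # boundary modes
    if dens[0] >= dens[1] and dens[0] >= 0.1 * dens.max():
        peaks = np.concatenate([[0], peaks])
    if dens[-1] >= dens[-2] and dens[-1] >= 0.1 * dens.max():
        peaks = np.concatenate([peaks, [grid_size - 1]])
    # merge plateau-adjacent indices
    if peaks.size:
        keep = [peaks[0]]
        for p in peaks[1:]:
            if p - keep[-1] > 1:
                keep.append(p)
        peaks = np.array(keep)
    if peaks.size < 2:
        raise ValueError("distribution is not bimodal: no valley between two modes")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    left, right = int(top2.min()), int(top2.max())
    valley = left + int(np.argmin(dens[left : right + 1]))
    return float(grid[valley])


def fraction_heteroplasmic(h_values, thresholds: ThresholdPair = DEFAULT_THRESHOLDS) -> float:
    """Fraction of cells in a colony classified heteroplasmic."""
    h = np.asarray(h_values, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValueError("no h values")
    return float(np.mean(classify_many(h, thresholds) == CLASS_HET))
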