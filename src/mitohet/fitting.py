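"""Fitting the segregation model to a homoplasmy time course.

The observable is the fraction of homoplasmic cells at the timepoints
0, 1.5, 3, 4.5, 6, 7.5 h of a segregating population.  The empirical
curve is first smoothed with a logistic (sigmoid) fit, and the two free
model parameters — ``ndau`` (copies passed to the daughter) and
``nspl`` (fission–fusion fragments) — are then estimated by a
least-squares grid search: for every (ndau, nspl) pair the simulator is
run ``n_replicates`` times, the replicate-mean homoplasmic fraction is
compared to the empirical curve at the five timepoints 1.5–7.5 h (t = 0
is 0 for every heteroplasmic founder and carries no information), and
the pair minimising the summed squared distance wins.

The public surface follows the model/results idiom::

    model = SegregationModel(curve, n_copies=32)
    res = model.fit(seed=1)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import (
    DEFAULT_THRESHOLDS,
    SimConfig,
    homoplasmic_fraction,
    simulate_population,
)

logger = logging.getLogger(__name__)

#: comparison timepoints of the least-squares criterion (hours)
FIT_TIMEPOINTS = (1.5, 3.0, 4.5, 6.0, 7.5)

ClassificationMode = Union[Literal["strict"], tuple[float, float]]


@dataclass(frozen=True)
class HomoplasmyCurve:
    """Homoplasmic fraction per timepoint."""

    times: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.size != f.size or t.size == 0:
            raise ValueError("times and fractions must be equal-length and non-empty")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "fractions", tuple(float(x) for x in f))

    def at(self, times: Sequence[float]) -> np.ndarray:
        """Fractions at the requested times (exact grid match required)."""
        lookup = dict(zip(self.times, self.fractions))
        try:
            return np.array([lookup[float(t)] for t in times])
        except KeyError as err:
            raise KeyError(f"timepoint {err} not on the curve grid {self.times}") from err


@dataclass(frozen=True)
class SigmoidFit:
    """Logistic fit f(t) = L / (1 + exp(-r (t - t0)))."""

    L: float
    r: float
    t0: float
    fitted: tuple[float, ...]
    degenerate: bool = False

    def __call__(self, t) -> np.ndarray:
        return _logistic(np.asarray(t, dtype=float), self.L, self.r, self.t0)


def _logistic(t, L, r, t0):
    return L / (1.0 + np.exp(-r * (t - t0)))


def fit_sigmoid(curve: HomoplasmyCurve) -> SigmoidFit:
    """Least-squares logistic fit with 0 < L <= 1 and r > 0.

    A flat curve (no rise) leaves the rate unidentifiable; the fit is
    then flagged degenerate and the constant level is returned as L
    with the fitted values equal to the data.
    """
    t = np.asarray(curve.times)
    f = np.asarray(curve.fractions)
    if t.size < 4:
        raise ValueError("need at least 4 points for a sigmoid fit")
    if np.ptp(f) < 1e-12:
        logger.warning("flat homoplasmy curve: sigmoid rate unidentifiable")
        return SigmoidFit(max(float(f[0]), 1e-12), np.nan, np.nan, tuple(f), degenerate=True)
    p0 = (max(f.max(), 0.05), 1.0, float(t[np.argmin(np.abs(f - f.max() / 2))]))
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            f,
            p0=p0,
            bounds=([1e-9, 1e-9, t.min() - 20.0], [1.0, 50.0, t.max() + 20.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = f - _logistic(t, *p0)
        raise RuntimeError(
            f"sigmoid fit failed to converge; residuals at start {np.round(resid, 4)}"
        ) from err
    L, r, t0 = (float(v) for v in popt)
    return SigmoidFit(L, r, t0, tuple(float(v) for v in _logistic(t, L, r, t0)))


def simulate_curve(
    config: SimConfig,
    mode: ClassificationMode = DEFAULT_THRESHOLDS,
) -> HomoplasmyCurve:
    """Replicate-mean homoplasmic fraction at every snapshot time.

    Runs ``config.n_replicates`` independent populations (replicate r
    seeded with ``config.seed + r``) and averages the per-snapshot
    homoplasmic fractions.
    """
    acc = np.zeros(config.n_generations + 1)
    times: np.ndarray | None = None
    for r in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + r)
        snaps = simulate_population(config, rng)
        if times is None:
            times = np.array([s.time_h for s in snaps])
        acc += np.array([homoplasmic_fraction(s, mode) for s in snaps])
    assert times is not None
    return HomoplasmyCurve(tuple(times), tuple(acc / config.n_replicates))


@dataclass(frozen=True)
class SegregationResults:
    """Grid-search results: the SSE surface and the best-fitting pair.

    ``grid`` has one row per (ndau, nspl) pair with the summed squared
    distance and the simulated mean fraction at each comparison
    timepoint.  Ties on the minimum break toward smaller ndau, then
    smaller nspl.
    """

    model: "SegregationModel"
    grid: pd.DataFrame
    best_ndau: int
    best_nspl: int
    sigmoid: SigmoidFit | None
    target: tuple[float, ...]
    n_replicates: int
    seed: int

    @property
    def best_sse(self) -> float:
        row = self.grid[(self.grid.ndau == self.best_ndau) & (self.grid.nspl == self.best_nspl)]
        return float(row.sse.iloc[0])

    def sse_matrix(self) -> pd.DataFrame:
        """SSE surface pivoted to an (ndau x nspl) matrix."""
        return self.grid.pivot(index="ndau", columns="nspl", values="sse")

    def ridge(self, factor: float = 2.0) -> pd.DataFrame:
        """Pairs whose SSE lies within ``factor`` x the grid minimum."""
        return self.grid[self.grid.sse <= factor * self.grid.sse.min()].copy()

    def summary(self) -> str:
        lines = [
            "Segregation model fit (least-squares grid search)",
            "=" * 50,
            f"copy number n          : {self.model.n_copies}",
            f"classification         : {self.model.mode}",
            f"replicates per pair    : {self.n_replicates}   seed: {self.seed}",
            f"grid                   : ndau {min(self.model.ndau_range)}-{max(self.model.ndau_range)}, "
            f"nspl {min(self.model.nspl_range)}-{max(self.model.nspl_range)} "
            f"({len(self.grid)} pairs)",
            f"comparison timepoints  : {FIT_TIMEPOINTS} h",
            f"target fractions       : {np.round(self.target, 4)}",
            "-" * 50,
            f"best ndau              : {self.best_ndau}",
            f"best nspl              : {self.best_nspl}",
            f"best SSE               : {self.best_sse:.6f}",
            f"pairs within 2x minimum: {len(self.ridge())}",
        ]
        if self.sigmoid is not None and not self.sigmoid.degenerate:
            lines.append(
                f"sigmoid smoothing      : L={self.sigmoid.L:.4f} r={self.sigmoid.r:.4f} "
                f"t0={self.sigmoid.t0:.4f}"
            )
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """SSE surface as a heatmap (ndau rows, nspl columns)."""
        import matplotlib.pyplot as plt

        mat = self.sse_matrix()
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            mat.values,
            origin="lower",
            aspect="auto",
            extent=(
                min(mat.columns) - 0.5,
                max(mat.columns) + 0.5,
                min(mat.index) - 0.5,
                max(mat.index) + 0.5,
            ),
        )
        ax.set_xlabel("nspl (fragments per shuffling event)")
        ax.set_ylabel("ndau (copies to daughter)")
        ax.plot(self.best_nspl, self.best_ndau, "r*", markersize=12)
        ax.figure.colorbar(im, ax=ax, label="summed squared distance")
        return ax


class SegregationModel:
    """Segregation model for a homoplasmy time course.

    Parameters
    ----------
    empirical : HomoplasmyCurve
        Observed homoplasmic fraction per timepoint (must cover the
        comparison grid 1.5–7.5 h).
    n_copies : int
        mtDNA copies per simulated cell.
    mode : "strict" or (low, high)
        How simulated cells are scored homoplasmic; the default applies
        the empirical h thresholds to the true allele fractions, to
        match an empirically thresholded target curve.
    smooth : bool
        Compare against the sigmoid-smoothed curve (default) or the raw
        fractions.
    per_run_sse : bool
        Average the replicate curves before computing the SSE (default)
        or sum the per-run SSEs instead.
    ndau_range, nspl_range : sequences of int
        Grid to search; defaults 1..n/2 and 1..n.
    """

    def __init__(
        self,
        empirical: HomoplasmyCurve,
        n_copies: int = 32,
        mode: ClassificationMode = DEFAULT_THRESHOLDS,
        smooth: bool = True,
        per_run_sse: bool = False,
        ndau_range: Sequence[int] | None = None,
        nspl_range: Sequence[int] | None = None,
        founder_pattern="mixed",
        founder_fraction1: float = 0.5,
        generation_hours: float = 1.5,
    ) -> None:
        self.empirical = empirical
        self.n_copies = int(n_copies)
        self.mode = mode
        self.smooth = smooth
        self.per_run_sse = per_run_sse
        self.ndau_range = list(ndau_range) if ndau_range is not None else list(range(1, n_copies // 2 + 1))
        self.nspl_range = list(nspl_range) if nspl_range is not None else list(range(1, n_copies + 1))
        if not self.ndau_range or not self.nspl_range:
            raise ValueError("empty parameter ranges")
        for nd in self.ndau_range:
            if not 1 <= nd <= self.n_copies // 2:
                raise ValueError(f"ndau={nd} outside [1, {self.n_copies // 2}]")
        for ns in self.nspl_range:
            if not 1 <= ns <= self.n_copies:
                raise ValueError(f"nspl={ns} outside [1, {self.n_copies}]")
        self.founder_pattern = founder_pattern
        self.founder_fraction1 = founder_fraction1
        self.generation_hours = generation_hours

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col="time_h", fraction_col="fraction", **kw):
        """Build from a tidy table with timepoint and fraction columns."""
        df = df.sort_values(time_col)
        curve = HomoplasmyCurve(tuple(df[time_col]), tuple(df[fraction_col]))
        return cls(curve, **kw)

    def _target(self) -> tuple[np.ndarray, SigmoidFit | None]:
        if self.smooth:
            sig = fit_sigmoid(self.empirical)
            if sig.degenerate:
                return self.empirical.at(FIT_TIMEPOINTS), sig
            return sig(np.array(FIT_TIMEPOINTS)), sig
        return self.empirical.at(FIT_TIMEPOINTS), None

    def fit(self, n_replicates: int = 10, seed: int = 0) -> SegregationResults:
        """Least-squares grid search over (ndau, nspl).

        Every pair is simulated with the same replicate seeds
        ``seed + r``, so re-running with the same seed reproduces the
        surface exactly.
        """
        target, sig = self._target()
        n_gen = int(round(max(FIT_TIMEPOINTS) / self.generation_hours))
        records = []
        for ndau in self.ndau_range:
            for nspl in self.nspl_range:
                cfg = SimConfig(
                    n_copies=self.n_copies,
                    ndau=ndau,
                    nspl=nspl,
                    founder_pattern=self.founder_pattern,
                    founder_fraction1=self.founder_fraction1,
                    n_generations=n_gen,
                    generation_hours=self.generation_hours,
                    n_replicates=n_replicates,
                    seed=seed,
                )
                if self.per_run_sse:
                    sse = 0.0
                    mean_acc = np.zeros(len(FIT_TIMEPOINTS))
                    for r in range(n_replicates):
                        one = replace(cfg, n_replicates=1, seed=seed + r)
                        sim = simulate_curve(one, self.mode).at(FIT_TIMEPOINTS)
                        sse += float(np.sum((sim - target) ** 2))
                        mean_acc += sim
                    sim_mean = mean_acc / n_replicates
                else:
                    sim_mean = simulate_curve(cfg, self.mode).at(FIT_TIMEPOINTS)
                    sse = float(np.sum((sim_mean - target) ** 2))
                rec = {"ndau": ndau, "nspl": nspl, "sse": sse}
                rec.update({f"sim_t{t:g}": v for t, v in zip(FIT_TIMEPOINTS, sim_mean)})
                records.append(rec)
        grid = pd.DataFrame(records)
        # ties break toward smaller ndau then smaller nspl
        ordered = grid.sort_values(["sse", "ndau", "nspl"], kind="mergesort")
        best = ordered.iloc[0]
        return SegregationResults(
            model=self,
            grid=grid,
            best_ndau=int(best.ndau),
            best_nspl=int(best.nspl),
            sigmoid=sig,
            target=tuple(float(v) for v in target),
            n_replicates=n_replicates,
            seed=seed,
        )
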