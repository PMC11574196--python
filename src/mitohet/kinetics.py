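"""Turnover and transfer kinetics.

Two small estimators sit here.  First, the fluorescence decay fit for
translation-shutoff (chloramphenicol) experiments: once synthesis of the
mtDNA-encoded fusion protein stops, the per-cell signal relaxes as

    I(t) = A exp(-k t) + C,

where ``k`` (per hour) is the protein turnover rate and ``C`` the
background plateau the signal settles on.  Second, the nucleoid-transfer
estimator: given the mean number of mtDNA foci crossing the mother–bud
neck per 5-minute observation window and the duration for which mother
and daughter mitochondrial networks stay connected, the number of
nucleoids transmitted per division is

    n = foci_rate / window_min * exchange_min

(1.18 foci / 5 min over a 47.5-min exchange gives 11.2 per division).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit I(t) = A exp(-k t) + C."""

    k: float
    amplitude: float
    offset: float
    k_sem: float
    no_decay: bool = False

    def __call__(self, t) -> np.ndarray:
        return self.amplitude * np.exp(-self.k * np.asarray(t, dtype=float)) + self.offset


def _decay(t, A, k, C):
    return A * np.exp(-k * t) + C


def fit_decay(times, intensities) -> DecayFit:
    """Nonlinear least-squares fit of an exponential decay with offset.

    ``times`` in hours spanning at least 2 h, at least 5 points.  The
    rate's standard error comes from the fit covariance.  A series with
    no resolvable decay (flat, or fitted k ~ 0) is returned flagged
    ``no_decay`` rather than raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need at least 5 matched (time, intensity) points")
    if np.ptp(t) < 2.0:
        raise ValueError("time course must span at least 2 h")
    if not (y > 0).any():
        raise ValueError("intensities are nowhere positive")
    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        logger.warning("constant intensity series: no decay to fit")
        return DecayFit(k=0.0, amplitude=0.0, offset=float(y.mean()), k_sem=np.nan, no_decay=True)
    A0 = max(y[0] - y[-1], 1e-6)
    k0 = 1.0 / max(np.ptp(t) / 3.0, 1e-3)
    C0 = max(y.min(), 0.0)
    try:
        popt, pcov = curve_fit(
            _decay,
            t,
            y,
            p0=(A0, k0, C0),
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"decay fit did not converge: {err}") from err
    A, k, C = (float(v) for v in popt)
    k_sem = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    if k <= 0:
        logger.warning("fitted rate k=%.4g <= 0: flagged as no-decay", k)
        return DecayFit(k=k, amplitude=A, offset=C, k_sem=k_sem, no_decay=True)
    return DecayFit(k=k, amplitude=A, offset=C, k_sem=k_sem)


def mean_foci_rate(crossings_per_window) -> float:
    """Mean mtDNA foci crossing the bud neck per observation window."""
    c = np.asarray(crossings_per_window, dtype=float)
    if c.size == 0:
        raise ValueError("no observation windows")
    return float(c.mean())


def nucleoids_per_division(
    foci_rate: float, window_min: float = 5.0, exchange_min: float = 47.5
) -> float:
    """Nucleoids transmitted per division, to one decimal.

    Scales the per-window crossing rate to the full content-exchange
    period: ``foci_rate / window_min * exchange_min``.
    """
    if foci_rate < 0 or window_min <= 0 or exchange_min <= 0:
        raise ValueError("rates and durations must be positive (foci_rate may be 0)")
    return round(foci_rate / window_min * exchange_min, 1)


@dataclass(frozen=True)
class TransferEstimate:
    """Nucleoid-transfer estimate and its ingredients."""

    foci_rate: float
    window_min: float = 5.0
    exchange_min: float = 47.5

    @property
    def nucleoids_per_division(self) -> float:
        return nucleoids_per_division(self.foci_rate, self.window_min, self.exchange_min)
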