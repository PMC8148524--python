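"""Secondary models: temperature dependence of the rate constant k.

Two alternatives are fitted per treatment:

* Arrhenius, ``k = k0 exp(-Ea / (R T))`` with T in kelvin, linearized as
  ``ln k = ln k0 - Ea/(R T)`` and solved by OLS of ln k on 1/T.  Ea is the
  activation energy (J/mol); higher Ea means oxidation is more sensitive
  to temperature.
* Log-logistic, ``k = m' ln(1 + exp(c (T - Tc)))`` with T in Celsius and
  m' fixed at 1 by default.  This empirical form needs no activation-energy
  concept; it is fitted by unweighted least squares on the k scale using a
  deterministic coarse grid search followed by local refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDesignError, DomainError, FitFailureError

#: Universal gas constant, J mol^-1 K^-1.
R_GAS: float = 8.314

# Deterministic initialization grid for the log-logistic fit.
_C_GRID = np.linspace(0.01, 0.6, 60)
_TC_GRID = np.linspace(-10.0, 90.0, 101)


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters for one treatment."""

    treatment: str
    ea: float        # activation energy, J/mol
    k0: float        # pre-exponential factor, 1/day
    r2: float        # of the ln k vs 1/T regression
    n_temps: int

    def k_at(self, temperature_k: float | np.ndarray) -> np.ndarray:
        """Predicted k (1/day) at an absolute temperature in kelvin."""
        return self.k0 * np.exp(-self.ea / (R_GAS * np.asarray(temperature_k, float)))


@dataclass(frozen=True)
class LogLogisticFit:
    """Log-logistic parameters for one treatment."""

    treatment: str
    c: float         # 1/degC
    tc: float        # degC
    m_prime: float
    r2: float        # on the k scale
    n_temps: int

    def k_at(self, temperature_c: float | np.ndarray) -> np.ndarray:
        """Predicted k (1/day) at a temperature in Celsius."""
        t = np.asarray(temperature_c, dtype=float)
        return self.m_prime * np.log1p(np.exp(self.c * (t - self.tc)))


def fit_arrhenius(
    pairs: Sequence[tuple[float, float]], *, treatment: str = ""
) -> ArrheniusFit:
    """OLS of ln k on 1/T (T in kelvin): Ea = -slope * R, k0 = exp(intercept).

    Raises
    ------
    DomainError
        Any k <= 0.
    DegenerateDesignError
        Fewer than 2 distinct temperatures.
    """
    temps = np.array([p[0] for p in pairs], dtype=float)
    ks = np.array([p[1] for p in pairs], dtype=float)
    if np.any(ks <= 0):
        raise DomainError("rate constants must be positive for ln k regression")
    if np.unique(temps).size < 2:
        raise DegenerateDesignError("need >= 2 distinct temperatures")
    x = 1.0 / temps
    y = np.log(ks)
    if temps.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue ** 2
    return ArrheniusFit(
        treatment=treatment,
        ea=float(-slope * R_GAS),
        k0=float(math.exp(intercept)),
        r2=float(r2),
        n_temps=int(np.unique(temps).size),
    )


def _ll_residuals(params: np.ndarray, temps: np.ndarray, ks: np.ndarray,
                  m_fixed: bool) -> np.ndarray:
    if m_fixed:
        c, tc = params
        m = 1.0
    else:
        c, tc, m = params
    return m * np.log1p(np.exp(np.clip(c * (temps - tc), -700, 700))) - ks


def fit_log_logistic(
    pairs: Sequence[tuple[float, float]], *, m_prime_fixed: bool = True,
    treatment: str = "",
) -> LogLogisticFit:
    """Least squares on the k scale for the log-logistic temperature model.

    Initialization scans a fixed c x Tc grid (c in [0.01, 0.6] 1/degC, Tc in
    [-10, 90] degC), then refines the best grid point with a
    Levenberg-Marquardt-type local solver.  Fully deterministic.

    Raises
    ------
    DomainError
        Any k <= 0.
    DegenerateDesignError
        Fewer pairs than free parameters + 1.
    FitFailureError
        Local refinement fails; carries the best grid point.
    """
    temps = np.array([p[0] for p in pairs], dtype=float)
    ks = np.array([p[1] for p in pairs], dtype=float)
    n_free = 2 if m_prime_fixed else 3
    if temps.size < n_free + 1:
        raise DegenerateDesignError(
            f"need >= {n_free + 1} pairs for {n_free} free parameters"
        )
    if np.any(ks <= 0):
        raise DomainError("rate constants must be positive")

    best_sse = np.inf
    best = (float(_C_GRID[0]), float(_TC_GRID[0]))
    for c in _C_GRID:
        pred = np.log1p(np.exp(np.clip(c * (temps[None, :] - _TC_GRID[:, None]),
                                       -700, 700)))
        sse = np.sum((pred - ks) ** 2, axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best_sse:
            best_sse = float(sse[i])
            best = (float(c), float(_TC_GRID[i]))

    x0 = np.array(best if m_prime_fixed else (*best, 1.0))
    try:
        res = optimize.least_squares(
            _ll_residuals, x0, args=(temps, ks, m_prime_fixed), method="lm",
            xtol=1e-14, ftol=1e-14,
        )
    except Exception as exc:
        raise FitFailureError(f"log-logistic refinement failed: {exc}",
                              best_params=best) from exc
    if not np.all(np.isfinite(res.x)):
        raise FitFailureError("log-logistic refinement diverged", best_params=best)
    if m_prime_fixed:
        c, tc = res.x
        m = 1.0
    else:
        c, tc, m = res.x
    pred = m * np.log1p(np.exp(c * (temps - tc)))
    sse = float(np.sum((pred - ks) ** 2))
    sst = float(np.sum((ks - ks.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse < 1e-20 else 0.0)
    return LogLogisticFit(
        treatment=treatment, c=float(c), tc=float(tc), m_prime=float(m),
        r2=float(r2), n_temps=int(np.unique(temps).size),
    )


def secondary_table(
    agg: pd.DataFrame, *, kelvin_offset: float = 273.15
) -> pd.DataFrame:
    """Fit both secondary models per treatment from an aggregated rate table
    (columns treatment, temperature_c, k_mean) and return a tidy frame with
    columns treatment, ea, k0, r2_arr, c, tc, r2_ll."""
    rows = []
    for treatment, sub in agg.groupby("treatment", sort=False):
        pairs_k = list(zip(sub["temperature_c"] + kelvin_offset, sub["k_mean"]))
        pairs_c = list(zip(sub["temperature_c"], sub["k_mean"]))
        arr = fit_arrhenius(pairs_k, treatment=treatment)
        ll = fit_log_logistic(pairs_c, treatment=treatment)
        rows.append((treatment, arr.ea, arr.k0, arr.r2, ll.c, ll.tc, ll.r2))
    return pd.DataFrame(
        rows, columns=["treatment", "ea", "k0", "r2_arr", "c", "tc", "r2_ll"]
    )


def write_secondary_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.8g")
    return path
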