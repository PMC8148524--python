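"""First-order kinetics of TBARS formation.

At constant temperature the TBARS index grows exponentially,
``TBARS(t) = TBARS0 * exp(k t)``, so the rate constant k (1/day) is the
slope of the ordinary least-squares regression of ln TBARS(%) on storage
day.  Fits are produced per (treatment, temperature, replicate) series and
aggregated to mean +/- SD over replicates, the statistic the published
rate-constant table reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import PERCENT, KineticDataset, to_percent
from .errors import DegenerateDesignError, DomainError, InsufficientDataError


@dataclass(frozen=True)
class RateFit:
    """First-order rate constant for one TBARS time series."""

    treatment: str
    temperature_c: float
    replicate: int | str
    k: float                 # 1/day
    intercept_log: float     # ln TBARS(%) at day 0
    r2: float
    rmse_log: float
    n_points: int


@dataclass
class RateTable:
    """Replicate-level fits plus per-(treatment, temperature) aggregates."""

    fits: list[RateFit]
    errors: dict[tuple[str, float, int], Exception] = field(default_factory=dict)

    def aggregated(self) -> pd.DataFrame:
        """Mean and sample SD of k (and mean R2) over replicates."""
        frame = pd.DataFrame(
            [(f.treatment, f.temperature_c, f.replicate, f.k, f.r2) for f in self.fits],
            columns=["treatment", "temperature_c", "replicate", "k", "r2"],
        )
        agg = (
            frame.groupby(["treatment", "temperature_c"], sort=False)
            .agg(k_mean=("k", "mean"), k_sd=("k", "std"), r2_mean=("r2", "mean"),
                 n_replicates=("k", "size"))
            .reset_index()
        )
        agg["k_sd"] = agg["k_sd"].fillna(0.0)  # single replicate -> SD 0
        return agg

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.aggregated().to_csv(path, index=False, float_format="%.8g")
        return path


def fit_first_order(
    days: np.ndarray, tbars_pct: np.ndarray, *, fix_intercept: bool = False,
    treatment: str = "", temperature_c: float = float("nan"),
    replicate: int | str = 1,
) -> RateFit:
    """Fit ``ln TBARS(%) = intercept + k * day`` by OLS.

    With ``fix_intercept`` the intercept is pinned at ln(100) — the literal
    reading of the first-order model with TBARS0 = 100% — and k is the
    least-squares slope through that point.  The default free-intercept fit
    matches model selection by log-linear regression quality.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 points.
    DomainError
        Any nonpositive TBARS value.
    DegenerateDesignError
        All days identical.
    """
    days = np.asarray(days, dtype=float)
    y = np.asarray(tbars_pct, dtype=float)
    if days.size < 3:
        raise InsufficientDataError(f"need >= 3 points, got {days.size}")
    if np.any(y <= 0):
        raise DomainError("TBARS values must be positive for log-linear fitting")
    if np.unique(days).size < 2:
        raise DegenerateDesignError("all storage days identical")
    if np.unique(days).size != days.size:
        raise DomainError("duplicate storage days within one series")

    logy = np.log(y)
    if fix_intercept:
        b0 = math.log(100.0)
        k = float(np.dot(days, logy - b0) / np.dot(days, days))
    else:
        slope, b0, _, _, _ = stats.linregress(days, logy)
        k, b0 = float(slope), float(b0)
    resid = logy - (b0 + k * days)
    sse = float(np.dot(resid, resid))
    sst = float(np.sum((logy - logy.mean()) ** 2))
    if sst < 1e-30:
        r2 = 1.0 if sse < 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - sse / sst)
    return RateFit(
        treatment=treatment,
        temperature_c=temperature_c,
        replicate=replicate,
        k=k,
        intercept_log=b0,
        r2=r2,
        rmse_log=math.sqrt(sse / days.size),
        n_points=int(days.size),
    )


def rate_table(dataset: KineticDataset, *, fix_intercept: bool = False) -> RateTable:
    """Fit every (treatment, temperature, replicate) series in the dataset.

    The dataset is normalized to percent scale if needed.  Groups that fail
    the fit preconditions are collected in ``RateTable.errors`` rather than
    aborting the whole table.
    """
    if dataset.records and dataset.scale != PERCENT:
        dataset = to_percent(dataset)
    fits: list[RateFit] = []
    errors: dict[tuple[str, float, int], Exception] = {}
    for (treatment, temp, rep), recs in dataset.groups().items():
        recs = sorted(recs, key=lambda r: r.day)
        days = np.array([r.day for r in recs])
        vals = np.array([r.tbars for r in recs])
        try:
            fits.append(
                fit_first_order(
                    days, vals, fix_intercept=fix_intercept,
                    treatment=treatment, temperature_c=temp, replicate=rep,
                )
            )
        except Exception as exc:  # noqa: BLE001 - collected per group
            errors[(treatment, temp, rep)] = exc
    return RateTable(fits=fits, errors=errors)
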