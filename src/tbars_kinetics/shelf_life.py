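"""Integrated shelf-life prediction and external validation.

Combining the first-order primary model with a secondary model gives a
prediction of TBARS(%) at any time-temperature pair:

* Arrhenius route:    TBARS = 100 exp( k0 exp(-Ea/(R T_K)) * t )
* log-logistic route: TBARS = 100 exp( ln(1 + exp(c (T_C - Tc))) * t )

External validation holds out one storage temperature entirely, fits the
primary and secondary models on the remaining temperatures, predicts every
held-out observation, and scores the observed-vs-predicted agreement with
an adjusted R2 (from the observed-on-predicted regression) and an RMSE on
raw paired errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset_io import KELVIN_OFFSET, PERCENT, KineticDataset, to_percent
from .errors import ConfigurationError, DegenerateDesignError, DomainError
from .primary_kinetics import rate_table
from .secondary_models import (
    ArrheniusFit,
    LogLogisticFit,
    fit_arrhenius,
    fit_log_logistic,
)

ARRHENIUS = "arrhenius"
LOG_LOGISTIC = "log_logistic"


@dataclass
class ValidationReport:
    """Observed-vs-predicted agreement metrics for one model."""

    model: str
    n: int
    r2_adj: float
    rmse: float
    slope: float
    intercept: float
    per_treatment: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            "r2_adj": self.r2_adj,
            "rmse": self.rmse,
            "slope": self.slope,
            "intercept": self.intercept,
            "per_treatment": self.per_treatment,
        }


def predict_tbars(
    fit: ArrheniusFit | LogLogisticFit,
    temperature_c: float,
    day: float | np.ndarray,
    *,
    kelvin_offset: float = KELVIN_OFFSET,
) -> np.ndarray:
    """TBARS(%) predicted at a temperature and storage time, TBARS0 = 100%.

    Arrhenius fits are evaluated in kelvin (``temperature_c + kelvin_offset``),
    log-logistic fits directly in Celsius.
    """
    day = np.asarray(day, dtype=float)
    if np.any(day < 0):
        raise DomainError("storage day must be >= 0")
    if isinstance(fit, ArrheniusFit):
        k = fit.k_at(temperature_c + kelvin_offset)
    else:
        k = fit.k_at(temperature_c)
    return 100.0 * np.exp(k * day)


def shelf_life_days(
    fit: ArrheniusFit | LogLogisticFit,
    temperature_c: float,
    threshold_pct: float,
    *,
    kelvin_offset: float = KELVIN_OFFSET,
) -> float:
    """Convenience inversion: days until TBARS reaches ``threshold_pct``.

    Not validated against any published shelf-life figure; provided for
    exploratory use only.
    """
    if threshold_pct <= 100.0:
        raise DomainError("threshold must exceed the initial 100%")
    if isinstance(fit, ArrheniusFit):
        k = float(fit.k_at(temperature_c + kelvin_offset))
    else:
        k = float(fit.k_at(temperature_c))
    if k <= 0:
        return math.inf
    return math.log(threshold_pct / 100.0) / k


def validate_external(predicted, observed, *, model: str = "") -> ValidationReport:
    """Score prediction quality on paired held-out observations.

    ``r2_adj`` adjusts the observed-on-predicted regression R2 for a single
    predictor: ``1 - (1 - R2)(n - 1)/(n - 2)``.  ``rmse`` is computed on the
    raw paired errors ``observed - predicted`` (not regression residuals).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise DomainError(
            f"length mismatch: {pred.size} predicted vs {obs.size} observed"
        )
    n = pred.size
    if n < 3:
        raise DomainError("need >= 3 pairs for validation metrics")
    if np.ptp(pred) == 0:
        raise DegenerateDesignError("zero variance in predictions")
    res = stats.linregress(pred, obs)
    r2 = res.rvalue ** 2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return ValidationReport(
        model=model, n=int(n), r2_adj=float(r2_adj), rmse=rmse,
        slope=float(res.slope), intercept=float(res.intercept),
    )


def holdout_pipeline(
    dataset: KineticDataset,
    holdout_temperature_c: float,
    model: str = ARRHENIUS,
    *,
    fix_intercept: bool = False,
    kelvin_offset: float = KELVIN_OFFSET,
) -> ValidationReport:
    """Full external-validation pipeline at one held-out temperature.

    Fits per-series rate constants on the non-holdout temperatures,
    aggregates them to mean k per (treatment, temperature), fits the chosen
    secondary model per treatment, predicts every held-out observation, and
    returns a pooled :class:`ValidationReport` with per-treatment metrics
    attached (where a treatment has >= 3 held-out pairs).
    """
    if model not in (ARRHENIUS, LOG_LOGISTIC):
        raise ConfigurationError(f"unknown model {model!r}")
    if holdout_temperature_c not in dataset.temperatures_c:
        raise ConfigurationError(
            f"holdout temperature {holdout_temperature_c} degC absent from dataset "
            f"(has {dataset.temperatures_c})"
        )
    if dataset.scale != PERCENT:
        dataset = to_percent(dataset)
    train = KineticDataset(
        records=[r for r in dataset if r.temperature_c != holdout_temperature_c]
    )
    if len({r.temperature_c for r in train}) < 3:
        raise ConfigurationError("need >= 3 non-holdout temperatures")

    agg = rate_table(train, fix_intercept=fix_intercept).aggregated()
    fits: dict[str, ArrheniusFit | LogLogisticFit] = {}
    for treatment, sub in agg.groupby("treatment", sort=False):
        if model == ARRHENIUS:
            pairs = list(zip(sub["temperature_c"] + kelvin_offset, sub["k_mean"]))
            fits[treatment] = fit_arrhenius(pairs, treatment=treatment)
        else:
            pairs = list(zip(sub["temperature_c"], sub["k_mean"]))
            fits[treatment] = fit_log_logistic(pairs, treatment=treatment)

    held = [r for r in dataset if r.temperature_c == holdout_temperature_c
            and r.treatment in fits]
    pred = np.array([
        float(predict_tbars(fits[r.treatment], r.temperature_c, r.day,
                            kelvin_offset=kelvin_offset))
        for r in held
    ])
    obs = np.array([r.tbars for r in held])
    report = validate_external(pred, obs, model=model)
    for treatment in dict.fromkeys(r.treatment for r in held):
        mask = np.array([r.treatment == treatment for r in held])
        if mask.sum() >= 3 and np.ptp(pred[mask]) > 0:
            sub = validate_external(pred[mask], obs[mask], model=model)
            report.per_treatment[treatment] = {
                "n": sub.n, "r2_adj": sub.r2_adj, "rmse": sub.rmse,
                "slope": sub.slope, "intercept": sub.intercept,
            }
    return report
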