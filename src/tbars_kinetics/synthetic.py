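"""Synthetic TBARS datasets with the statistical structure the analysis assumes.

The generator reproduces the study design — 14 treatment arms (control plus
13 extracts), triplicate series, storage at 4/8/12/16/20 degC for 13 days
at <= 12 degC and 5 days at 16/20 degC — with TBARS(%) growing
exponentially at a temperature-dependent rate plus multiplicative lognormal
measurement noise (additive on the log scale, so the log-linear primary fit
is the correctly specified estimator).

``published_like_truth`` derives a ground truth from the packaged published
rate constants: per-treatment Ea recomputed by the Arrhenius OLS (the
printed table's k0 and one printed Ea are internally inconsistent with the
printed k's and are not usable as a generative truth) and k0 back-solved so
that k(4 degC) equals the published value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import (
    KELVIN_OFFSET,
    PERCENT,
    KineticDataset,
    TbarsRecord,
    load_published_rate_constants,
)
from .errors import DomainError
from .secondary_models import R_GAS, fit_arrhenius

ARRHENIUS = "arrhenius"
LOG_LOGISTIC = "log_logistic"


@dataclass(frozen=True)
class TreatmentTruth:
    """True secondary model of one treatment arm."""

    kind: str                       # "arrhenius" or "log_logistic"
    params: tuple[float, float]     # (ea J/mol, k0 1/day) or (c 1/degC, tc degC)

    def k_at(self, temperature_c: float, kelvin_offset: float = KELVIN_OFFSET) -> float:
        if self.kind == ARRHENIUS:
            ea, k0 = self.params
            return k0 * np.exp(-ea / (R_GAS * (temperature_c + kelvin_offset)))
        c, tc = self.params
        return float(np.log1p(np.exp(c * (temperature_c - tc))))


@dataclass
class SyntheticTruth:
    """Ground-truth kinetic parameters and noise model for the generator."""

    treatments: dict[str, TreatmentTruth]
    noise_sigma: float = 0.05   # SD of the log-scale (multiplicative) noise
    replicates: int = 3
    seed: int = 0
    kelvin_offset: float = KELVIN_OFFSET

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")
        for name, t in self.treatments.items():
            if t.kind == ARRHENIUS and (t.params[0] <= 0 or t.params[1] <= 0):
                raise DomainError(f"{name}: ea and k0 must be positive")
            if t.kind == LOG_LOGISTIC and t.params[0] <= 0:
                raise DomainError(f"{name}: c must be positive")


@dataclass
class StorageDesign:
    """Which temperatures are run, for how long, and when samples are taken."""

    temperatures_c: list[float] = field(default_factory=lambda: [4, 8, 12, 16, 20])
    duration_days: dict[float, int] = field(default_factory=dict)
    sampling_days: dict[float, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.temperatures_c:
            self.duration_days.setdefault(t, 13 if t <= 12 else 5)
        for t in self.temperatures_c:
            self.sampling_days.setdefault(
                t, list(range(self.duration_days[t] + 1))
            )
        for t in self.temperatures_c:
            days = self.sampling_days[t]
            if 0 not in days:
                raise DomainError(f"sampling grid at {t} degC must include day 0")
            if max(days) > self.duration_days[t]:
                raise DomainError(
                    f"sampling at {t} degC exceeds the {self.duration_days[t]}-day "
                    "storage duration"
                )


def simulate_dataset(truth: SyntheticTruth, design: StorageDesign) -> KineticDataset:
    """Draw one dataset: ``tbars = 100 exp(k(T) t) exp(eps)``,
    ``eps ~ N(0, sigma^2)`` independent across records; day-0 records are
    exactly 100.  Reproducible given ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    records: list[TbarsRecord] = []
    for name, arm in truth.treatments.items():
        for temp in design.temperatures_c:
            k = arm.k_at(temp, truth.kelvin_offset)
            for rep in range(1, truth.replicates + 1):
                for day in design.sampling_days[temp]:
                    if day == 0:
                        value = 100.0
                    else:
                        eps = rng.normal(0.0, truth.noise_sigma)
                        value = 100.0 * np.exp(k * day + eps)
                    records.append(
                        TbarsRecord(name, float(temp), rep, float(day),
                                    float(value), PERCENT)
                    )
    return KineticDataset(records=records)


def published_like_truth(
    *, noise_sigma: float = 0.05, replicates: int = 3, seed: int = 0,
    kelvin_offset: float = KELVIN_OFFSET,
) -> SyntheticTruth:
    """A 14-treatment Arrhenius truth anchored to the published rate table.

    Per treatment, Ea is the OLS recomputation from the published k's at the
    printed kelvins, and k0 is chosen so that the evaluated k at 4 degC
    (under ``kelvin_offset``) equals the published k at 277 K.
    """
    table = load_published_rate_constants()
    arms: dict[str, TreatmentTruth] = {}
    for extract, sub in table.groupby("extract", sort=False):
        fit = fit_arrhenius(
            list(zip(sub["temperature_k"], sub["k_mean"])), treatment=extract
        )
        k4 = float(sub.loc[sub["temperature_k"] == 277, "k_mean"].iloc[0])
        k0 = k4 * np.exp(fit.ea / (R_GAS * (4.0 + kelvin_offset)))
        arms[extract] = TreatmentTruth(kind=ARRHENIUS, params=(fit.ea, float(k0)))
    return SyntheticTruth(
        treatments=arms, noise_sigma=noise_sigma, replicates=replicates,
        seed=seed, kelvin_offset=kelvin_offset,
    )
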