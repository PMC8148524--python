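"""Dummy-coded multiple linear regression and antioxidant-assay statistics.

Treatment effects on oxidation are compared by regressing ln TBARS(%) on
storage day, temperature (degC) and 13 treatment indicators, with the
control arm as the uncoded reference level.  A more negative treatment
coefficient means stronger inhibition of lipid oxidation.  Coefficient
significance uses the raw two-sided t-test p-values (p <= 0.05); a
Holm-adjusted column is emitted alongside for users who want family-wise
control.

The module also computes the Pearson correlation between the DPPH
radical-scavenging activity and the total phenolic content of the extracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset_io import PERCENT, TREATMENTS, KineticDataset, to_percent
from .errors import CollinearityError, DegenerateDesignError, DomainError


@dataclass
class MlrFit:
    """Fitted dummy-coded regression of ln TBARS(%) on day, temperature and
    treatment indicators."""

    intercept: float
    coef_time: float
    coef_temperature: float
    coef_treatment: dict[str, float]
    standard_errors: dict[str, float]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    p_values_holm: dict[str, float]
    r2: float
    n: int
    params: pd.Series        # full coefficient vector in design order

    def summary_frame(self) -> pd.DataFrame:
        rows = [("intercept", self.intercept, self.p_values["intercept"]),
                ("day", self.coef_time, self.p_values["day"]),
                ("temperature_c", self.coef_temperature,
                 self.p_values["temperature_c"])]
        rows += [(t, b, self.p_values[t]) for t, b in self.coef_treatment.items()]
        return pd.DataFrame(rows, columns=["term", "coefficient", "p_value"])


def _design(dataset: KineticDataset) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    frame = dataset.to_frame()
    treatments = [t for t in TREATMENTS if t in set(frame["treatment"])]
    extra = sorted(set(frame["treatment"]) - set(treatments))
    treatments += extra
    if treatments[0] != "control" or "control" not in treatments:
        raise DomainError("control treatment absent: no reference level")
    X = pd.DataFrame({
        "intercept": 1.0,
        "day": frame["day"].to_numpy(float),
        "temperature_c": frame["temperature_c"].to_numpy(float),
    })
    for t in treatments[1:]:
        X[t] = (frame["treatment"] == t).astype(float)
    y = np.log(frame["tbars"].to_numpy(float))
    return X, y, treatments[1:]


def fit_mlr_dummy(dataset: KineticDataset) -> MlrFit:
    """OLS of ln TBARS(%) on day, temperature_c and (k-1) treatment dummies.

    Raises
    ------
    DomainError
        No control arm, or nonpositive TBARS values.
    CollinearityError
        Rank-deficient design; names the offending columns.
    """
    if dataset.records and dataset.scale != PERCENT:
        dataset = to_percent(dataset)
    frame = dataset.to_frame()
    if (frame["tbars"] <= 0).any():
        raise DomainError("all TBARS values must be positive for the log model")
    X, y, dummy_names = _design(dataset)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full column rank
        offending = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {X.shape[1]})",
            columns=offending,
        )
    res = sm.OLS(y, X).fit()
    pvals = dict(res.pvalues)
    holm = dict(zip(
        dummy_names,
        multipletests([pvals[t] for t in dummy_names], method="holm")[1],
    ))
    return MlrFit(
        intercept=float(res.params["intercept"]),
        coef_time=float(res.params["day"]),
        coef_temperature=float(res.params["temperature_c"]),
        coef_treatment={t: float(res.params[t]) for t in dummy_names},
        standard_errors=dict(res.bse),
        t_stats=dict(res.tvalues),
        p_values=pvals,
        p_values_holm=holm,
        r2=float(res.rsquared),
        n=int(res.nobs),
        params=res.params,
    )


def rank_treatment_effects(fit: MlrFit) -> list[tuple[str, float, float, bool]]:
    """Treatments ordered by coefficient ascending (most negative = strongest
    oxidation inhibition first); each entry is (treatment, coefficient,
    p_value, significant at p <= 0.05).  Ties break on the treatment name."""
    entries = [
        (t, b, fit.p_values[t], fit.p_values[t] <= 0.05)
        for t, b in fit.coef_treatment.items()
    ]
    return sorted(entries, key=lambda e: (e[1], e[0]))


def dpph_tpc_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between the DPPH and total
    phenolic content columns of an extract assay table."""
    if len(table) < 3:
        raise DomainError("need >= 3 extracts for a correlation")
    x = table["dpph_umol_te_g"].to_numpy(float)
    y = table["tpc_mg_gae_g"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDesignError("zero variance in an assay column")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_mlr_table(fit: MlrFit, path: str | Path) -> Path:
    """Write the ranked treatment effects plus time/temperature/intercept
    rows as a tidy CSV."""
    path = Path(path)
    ranked = rank_treatment_effects(fit)
    rows = [(t, b, p) for (t, b, p, _) in ranked]
    rows += [("temperature_c", fit.coef_temperature,
              fit.p_values["temperature_c"]),
             ("day", fit.coef_time, fit.p_values["day"]),
             ("intercept", fit.intercept, fit.p_values["intercept"])]
    pd.DataFrame(rows, columns=["term", "coefficient", "p_value"]).to_csv(
        path, index=False, float_format="%.8g"
    )
    return path
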