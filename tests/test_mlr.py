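"""Dummy-coded MLR treatment comparison and assay correlation."""

import math

import numpy as np
import pandas as pd
import pytest

import tbars_kinetics as tk
from tbars_kinetics.errors import CollinearityError, DegenerateDesignError, DomainError


def make_mlr_dataset(betas, *, sigma=0.0, seed=0, b0=4.4, b_time=0.14,
                     b_temp=0.06, replicates=1, days=range(6),
                     temps=(4, 8, 12, 16, 20)):
    rng = np.random.default_rng(seed)
    rows = []
    for t in ["control"] + list(betas):
        for T in temps:
            for rep in range(1, replicates + 1):
                for d in days:
                    ln = (b0 + b_time * d + b_temp * T + betas.get(t, 0.0)
                          + (rng.normal(0, sigma) if sigma else 0.0))
                    rows.append((t, T, rep, d, math.exp(ln)))
    return tk.dataset_from_tuples(rows)


def test_noiseless_generative_recovery_is_exact():
    betas = {"bay leaf": -0.8}
    fit = tk.fit_mlr_dummy(make_mlr_dataset(betas))
    assert fit.intercept == pytest.approx(4.4, abs=1e-10)
    assert fit.coef_time == pytest.approx(0.14, abs=1e-10)
    assert fit.coef_temperature == pytest.approx(0.06, abs=1e-10)
    assert fit.coef_treatment["bay leaf"] == pytest.approx(-0.8, abs=1e-10)


def test_design_width_is_16_for_14_treatments():
    betas = {t: -0.1 for t in tk.TREATMENTS if t != "control"}
    fit = tk.fit_mlr_dummy(make_mlr_dataset(betas, days=range(3),
                                            temps=(4, 20)))
    assert len(fit.coef_treatment) == 13
    # intercept + day + temperature + 13 dummies
    assert len(fit.params) == 16


def test_matches_normal_equations_oracle():
    betas = {"clove": -0.5, "garlic": -0.2}
    ds = make_mlr_dataset(betas, sigma=0.3, seed=1)
    fit = tk.fit_mlr_dummy(ds)
    frame = ds.to_frame()
    X = np.column_stack([
        np.ones(len(frame)), frame.day, frame.temperature_c,
        (frame.treatment == "clove").astype(float),
        (frame.treatment == "garlic").astype(float),
    ])
    y = np.log(frame.tbars.to_numpy())
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
    assert fit.coef_time == pytest.approx(beta[1], abs=1e-10)
    assert fit.coef_treatment["clove"] == pytest.approx(beta[3], abs=1e-10)


def test_noisy_estimates_within_3_se_of_truth():
    betas = {t: b for t, b in zip(
        [t for t in tk.TREATMENTS if t != "control"],
        np.linspace(-0.9, -0.05, 13))}
    fit = tk.fit_mlr_dummy(make_mlr_dataset(betas, sigma=0.3, seed=42,
                                            replicates=3))
    for t, truth in betas.items():
        se = fit.standard_errors[t]
        assert abs(fit.coef_treatment[t] - truth) < 3 * se


def test_control_absent_is_reference_error():
    rows = [("clove", 4, 1, d, 100 * math.exp(0.1 * d)) for d in range(4)]
    with pytest.raises(DomainError, match="control"):
        tk.fit_mlr_dummy(tk.dataset_from_tuples(rows))


def test_collinear_design_names_columns():
    # single temperature with a single day grid: temperature column constant,
    # perfectly collinear with the intercept
    betas = {"clove": -0.5}
    ds = make_mlr_dataset(betas, temps=(4,))
    with pytest.raises(CollinearityError) as err:
        tk.fit_mlr_dummy(ds)
    assert err.value.columns


def test_ranking_most_negative_first_and_order_invariant():
    betas = {"bay leaf": -0.87, "allspice": -0.5, "onion": -0.02}
    ds = make_mlr_dataset(betas, sigma=0.05, seed=3, replicates=2)
    fit = tk.fit_mlr_dummy(ds)
    ranked = tk.rank_treatment_effects(fit)
    assert ranked[0][0] == "bay leaf"
    assert [r[0] for r in ranked] == ["bay leaf", "allspice", "onion"]
    # row order of the input does not change the ranking
    shuffled = tk.KineticDataset(records=list(ds.records[::-1]))
    ranked2 = tk.rank_treatment_effects(tk.fit_mlr_dummy(shuffled))
    assert [(t, pytest.approx(b)) for t, b, _, _ in ranked] == \
        [(t, b) for t, b, _, _ in ranked2]


def test_null_effects_flagged_nonsignificant():
    ds = make_mlr_dataset({"clove": 0.0, "garlic": 0.0}, sigma=0.4, seed=8)
    ranked = tk.rank_treatment_effects(tk.fit_mlr_dummy(ds))
    assert all(p > 0.05 and not sig for _, _, p, sig in ranked)


def test_adding_constant_shifts_only_intercept():
    betas = {"clove": -0.5}
    ds = make_mlr_dataset(betas, sigma=0.2, seed=5)
    fit = tk.fit_mlr_dummy(ds)
    boosted = tk.KineticDataset(records=[
        tk.TbarsRecord(r.treatment, r.temperature_c, r.replicate, r.day,
                       r.tbars * math.e, r.scale) for r in ds])
    fit2 = tk.fit_mlr_dummy(boosted)
    assert fit2.intercept == pytest.approx(fit.intercept + 1.0, abs=1e-10)
    assert fit2.coef_time == pytest.approx(fit.coef_time, abs=1e-10)
    assert fit2.coef_treatment["clove"] == pytest.approx(
        fit.coef_treatment["clove"], abs=1e-10)


def test_unbiasedness_across_simulations():
    """Mean estimate over repeated noisy simulations stays within 0.5 SE of
    the generating coefficient (scaled-down replication count)."""
    truth = -0.4
    estimates, ses = [], []
    for seed in range(60):
        fit = tk.fit_mlr_dummy(make_mlr_dataset({"clove": truth}, sigma=0.3,
                                                seed=seed, days=range(4),
                                                temps=(4, 12, 20)))
        estimates.append(fit.coef_treatment["clove"])
        ses.append(fit.standard_errors["clove"])
    mean_est = np.mean(estimates)
    se_of_mean = np.mean(ses) / math.sqrt(len(estimates))
    assert abs(mean_est - truth) < 3 * se_of_mean  # unbiased at 3 sigma
    assert abs(mean_est - truth) < 0.5 * np.mean(ses)


# -- assay correlation -------------------------------------------------------

def test_packaged_assay_table_correlation_rounds_to_098():
    r, p = tk.dpph_tpc_correlation(tk.load_extract_assays())
    assert round(r, 2) == 0.98
    assert p < 1e-6


def test_proportional_columns_give_r_1():
    table = pd.DataFrame({"dpph_umol_te_g": [1.0, 2.0, 3.0, 4.0],
                          "tpc_mg_gae_g": [10.0, 20.0, 30.0, 40.0]})
    r, _ = tk.dpph_tpc_correlation(table)
    assert r == pytest.approx(1.0)


def test_matches_textbook_formula():
    table = pd.DataFrame({"dpph_umol_te_g": [5.0, 9.0, 2.0, 7.0],
                          "tpc_mg_gae_g": [1.2, 3.1, 0.4, 2.2]})
    x, y = table.dpph_umol_te_g.to_numpy(), table.tpc_mg_gae_g.to_numpy()
    dx, dy = x - x.mean(), y - y.mean()
    expected = np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2))
    r, _ = tk.dpph_tpc_correlation(table)
    assert r == pytest.approx(expected, abs=1e-12)


def test_degenerate_assay_columns():
    table = pd.DataFrame({"dpph_umol_te_g": [1.0, 1.0, 1.0],
                          "tpc_mg_gae_g": [1.0, 2.0, 3.0]})
    with pytest.raises(DegenerateDesignError):
        tk.dpph_tpc_correlation(table)
    with pytest.raises(DomainError):
        tk.dpph_tpc_correlation(table.iloc[:2])
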