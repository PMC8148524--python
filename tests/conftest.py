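import numpy as np
import pytest

import tbars_kinetics as tk


@pytest.fixture(scope="session")
def published_rates():
    return tk.load_published_rate_constants()


@pytest.fixture(scope="session")
def published_params():
    return tk.load_published_secondary_params()


@pytest.fixture(scope="session")
def control_pairs_kelvin(published_rates):
    sub = published_rates[published_rates.extract == "control"]
    return list(zip(sub.temperature_k, sub.k_mean))


@pytest.fixture(scope="session")
def control_pairs_celsius(control_pairs_kelvin):
    return [(t - 273.0, k) for t, k in control_pairs_kelvin]


def exponential_dataset(ks: dict[str, dict[float, float]], days=range(6),
                        replicates=1, scale="percent"):
    """Noiseless first-order dataset: one entry per treatment/temperature."""
    rows = []
    for treatment, temps in ks.items():
        for temp, k in temps.items():
            for rep in range(1, replicates + 1):
                for d in days:
                    rows.append((treatment, temp, rep, d, 100.0 * np.exp(k * d)))
    return tk.dataset_from_tuples(rows, scale=scale)


@pytest.fixture()
def clean_two_by_two():
    """2 treatments x 2 temperatures x 3 replicates of clean exponentials."""
    ks = {"control": {4.0: 0.15, 20.0: 0.6},
          "clove": {4.0: 0.07, 20.0: 0.24}}
    return exponential_dataset(ks, replicates=3)


@pytest.fixture(scope="session")
def noiseless_study_dataset():
    """Noiseless single-replicate dataset at the full study design."""
    truth = tk.published_like_truth(noise_sigma=0.0, replicates=1, seed=1)
    return tk.simulate_dataset(truth, tk.StorageDesign())
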