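"""MLP regression comparator for TBARS prediction.

A single-hidden-layer perceptron maps (storage day, temperature, 14
treatment indicators) — 16 inputs — to TBARS(%).  Training minimizes the
sum-of-squares error with a BFGS quasi-Newton optimizer (analytic
gradients) for at most ``max_epochs`` iterations; the data are split
2:1:1 into training/validation/test subsets, the validation subset selects
the best iterate (early stopping with a patience window), and model
selection over an architecture grid keeps the networks with the lowest
validation error.

Hidden activations: tanh, logistic, exponential.  Output activations:
identity, exponential.  The continuous inputs (day, temperature) are
z-scored; indicator columns are left 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import optimize

from .dataset_io import PERCENT, TREATMENTS, KineticDataset
from .errors import EncodingError, SplitError, TrainingFailureError

_HIDDEN_ACTS = ("tanh", "exponential", "logistic")
_OUTPUT_ACTS = ("identity", "exponential")


@dataclass(frozen=True)
class AnnSpec:
    """Architecture and training settings for one network."""

    n_hidden: int
    hidden_activation: str = "tanh"
    output_activation: str = "exponential"
    max_epochs: int = 200
    seed: int = 0
    patience: int = 25

    def __post_init__(self) -> None:
        if not 3 <= self.n_hidden <= 10:
            raise ValueError("n_hidden must be in [3, 10]")
        if self.hidden_activation not in _HIDDEN_ACTS:
            raise ValueError(f"hidden activation must be one of {_HIDDEN_ACTS}")
        if self.output_activation not in _OUTPUT_ACTS:
            raise ValueError(f"output activation must be one of {_OUTPUT_ACTS}")

    @property
    def name(self) -> str:
        return f"MLP 16-{self.n_hidden}-1"


@dataclass
class FeatureEncoding:
    """Design matrix (standardized) + target vector for the network."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    center: np.ndarray
    scale: np.ndarray
    treatments: list[str] = field(default_factory=list)


@dataclass
class AnnFit:
    """A trained network with its split and subset metrics."""

    spec: AnnSpec
    weights: np.ndarray
    split_ids: np.ndarray            # 0 train / 1 validation / 2 test per row
    performance: dict[str, float]    # Pearson r per subset
    error: dict[str, float]          # SOS error per subset
    r2: float                        # on the full data
    rmse: float
    n_iter: int

    @property
    def validation_error(self) -> float:
        return self.error["validation"]


def encode_features(
    dataset: KineticDataset, treatments: list[str] | None = None
) -> FeatureEncoding:
    """Encode a percent-scale dataset into the 16-column design matrix:
    day, temperature_c, then one treatment indicator per arm in canonical
    order (control first).  Day and temperature are z-scored using
    full-data statistics; indicators stay 0/1."""
    if dataset.scale != PERCENT:
        raise EncodingError("dataset must be on percent scale")
    if treatments is None:
        treatments = [t for t in TREATMENTS if t in set(dataset.treatments)]
        extra = [t for t in dataset.treatments if t not in treatments]
        treatments += extra
    index = {t: i for i, t in enumerate(treatments)}
    n = len(dataset)
    X = np.zeros((n, 2 + len(treatments)))
    y = np.empty(n)
    for i, rec in enumerate(dataset):
        if rec.treatment not in index:
            raise EncodingError(f"unknown treatment label {rec.treatment!r}")
        X[i, 0] = rec.day
        X[i, 1] = rec.temperature_c
        X[i, 2 + index[rec.treatment]] = 1.0
        y[i] = rec.tbars
    center = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    for j in (0, 1):
        center[j] = X[:, j].mean()
        sd = X[:, j].std()
        scale[j] = sd if sd > 0 else 1.0
    Xs = (X - center) / scale
    cols = ["day", "temperature_c"] + [f"is_{t}" for t in treatments]
    return FeatureEncoding(X=Xs, y=y, columns=cols, center=center, scale=scale,
                           treatments=list(treatments))


def split_221(
    n: int, seed: int, stratify: np.ndarray | None = None
) -> np.ndarray:
    """Assign each of n rows to train (0) / validation (1) / test (2) in a
    2:1:1 ratio (+-1 row), optionally stratified within groups."""
    rng = np.random.default_rng(seed)
    ids = np.zeros(n, dtype=int)
    if stratify is None:
        perm = rng.permutation(n)
        n_va, n_te = n // 4, n // 4
        ids[perm[:n_va]] = 1
        ids[perm[n_va:n_va + n_te]] = 2
    else:
        stratify = np.asarray(stratify)
        for g in np.unique(stratify):
            idx = np.flatnonzero(stratify == g)
            ids[idx] = split_221(idx.size, int(rng.integers(2**31)))
    for sub in (0, 1, 2):
        if not np.any(ids == sub):
            raise SplitError(f"subset {sub} is empty with n={n}")
    return ids


# -- network internals -------------------------------------------------------

def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    if name == "exponential":
        return np.exp(np.clip(z, -50, 50))
    return z  # identity


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return 1.0 - a * a
    if name == "logistic":
        return a * (1.0 - a)
    if name == "exponential":
        return a
    return np.ones_like(a)


def _unpack(w: np.ndarray, n_in: int, h: int):
    i = 0
    W1 = w[i:i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + h]; i += h
    b2 = w[i]
    return W1, b1, W2, b2


def _forward(w: np.ndarray, X: np.ndarray, spec: AnnSpec):
    W1, b1, W2, b2 = _unpack(w, X.shape[1], spec.n_hidden)
    a = _act(spec.hidden_activation, X @ W1.T + b1)
    z2 = a @ W2 + b2
    return _act(spec.output_activation, z2), a, z2


def _loss_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray, spec: AnnSpec):
    yhat, a, z2 = _forward(w, X, spec)
    err = yhat - y
    loss = float(err @ err)
    dz2 = 2.0 * err * _act_deriv(spec.output_activation, yhat)
    gW2 = a.T @ dz2
    gb2 = dz2.sum()
    dz1 = np.outer(dz2, _unpack(w, X.shape[1], spec.n_hidden)[2]) \
        * _act_deriv(spec.hidden_activation, a)
    gW1 = dz1.T @ X
    gb1 = dz1.sum(axis=0)
    return loss, np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])


def predict(fit: AnnFit, X: np.ndarray) -> np.ndarray:
    """Network predictions for an encoded design matrix."""
    return _forward(fit.weights, X, fit.spec)[0]


def train_mlp(
    spec: AnnSpec, enc: FeatureEncoding, split_ids: np.ndarray | None = None,
    stratify: np.ndarray | None = None,
) -> AnnFit:
    """Train one network by BFGS on the training subset, selecting the
    iterate with the lowest validation error (patience-limited)."""
    X, y = enc.X, enc.y
    if X.shape[0] < 40:
        raise SplitError(f"need >= 40 records to split, got {X.shape[0]}")
    if split_ids is None:
        split_ids = split_221(X.shape[0], spec.seed, stratify=stratify)
    tr, va = split_ids == 0, split_ids == 1

    rng = np.random.default_rng(spec.seed)
    n_in, h = X.shape[1], spec.n_hidden
    w0 = rng.normal(0.0, 0.3, size=n_in * h + 2 * h + 1)
    # start the output bias at the target mean so the first iterate is sane
    w0[-1] = np.log(max(y[tr].mean(), 1e-6)) \
        if spec.output_activation == "exponential" else y[tr].mean()

    state = {"best_val": np.inf, "best_w": w0.copy(), "since": 0, "iters": 0}

    def cb(xk):
        state["iters"] += 1
        val = _loss_grad(xk, X[va], y[va], spec)[0]
        if val < state["best_val"] - 1e-12:
            state["best_val"] = val
            state["best_w"] = xk.copy()
            state["since"] = 0
        else:
            state["since"] += 1
            if state["since"] >= spec.patience:
                raise StopIteration

    res = optimize.minimize(
        _loss_grad, w0, args=(X[tr], y[tr], spec), jac=True, method="BFGS",
        callback=cb, options={"maxiter": spec.max_epochs, "gtol": 1e-10},
    )
    # final iterate may beat the last callback snapshot
    final_val = _loss_grad(res.x, X[va], y[va], spec)[0]
    w = res.x if final_val < state["best_val"] else state["best_w"]
    if not np.all(np.isfinite(w)) or not np.isfinite(
        _loss_grad(w, X[tr], y[tr], spec)[0]
    ):
        raise TrainingFailureError(f"{spec.name}: non-finite loss")

    yhat = _forward(w, X, spec)[0]
    perf: dict[str, float] = {}
    err: dict[str, float] = {}
    for label, mask in (("training", tr), ("validation", va),
                        ("test", split_ids == 2)):
        e = yhat[mask] - y[mask]
        err[label] = float(e @ e)
        perf[label] = (
            float(np.corrcoef(y[mask], yhat[mask])[0, 1])
            if np.ptp(y[mask]) > 0 and np.ptp(yhat[mask]) > 0 else 1.0
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((yhat - y) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return AnnFit(
        spec=spec, weights=w, split_ids=split_ids, performance=perf, error=err,
        r2=r2, rmse=float(np.sqrt(sse / y.size)), n_iter=state["iters"],
    )


def default_spec_grid(
    max_epochs: int = 200, seed: int = 0, hidden_range: tuple[int, int] = (3, 10)
) -> list[AnnSpec]:
    """The 20-network selection grid: hidden sizes crossed with tanh and
    exponential hidden activations (exponential output), topped up with
    tanh/identity variants."""
    lo, hi = hidden_range
    specs = [
        AnnSpec(h, act, "exponential", max_epochs=max_epochs, seed=seed)
        for h, act in product(range(lo, hi + 1), ("tanh", "exponential"))
    ]
    specs += [
        AnnSpec(h, "tanh", "identity", max_epochs=max_epochs, seed=seed)
        for h in range(lo, hi + 1, 2)
    ]
    return specs[:20]


def select_best_networks(
    specs: list[AnnSpec], enc: FeatureEncoding, n_keep: int = 5,
    split_seed: int | None = None, stratify: np.ndarray | None = None,
) -> list[AnnFit]:
    """Train every spec on a shared split and keep the ``n_keep`` networks
    with the lowest validation error (ascending).  Individual training
    failures are dropped, not fatal."""
    if n_keep > len(specs):
        raise ValueError("n_keep exceeds the number of candidate specs")
    seed = specs[0].seed if split_seed is None else split_seed
    split_ids = split_221(enc.X.shape[0], seed, stratify=stratify)
    fits: list[AnnFit] = []
    for spec in specs:
        try:
            fits.append(train_mlp(spec, enc, split_ids=split_ids))
        except TrainingFailureError:
            continue
    fits.sort(key=lambda f: (f.validation_error, f.spec.name))
    return fits[:n_keep]


def fits_to_table(fits: list[AnnFit]):
    """Summarize ranked fits as a tidy frame (one row per network)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "structure": f.spec.name,
                "hidden_activation": f.spec.hidden_activation,
                "output_activation": f.spec.output_activation,
                "training_perf": f.performance["training"],
                "validation_perf": f.performance["validation"],
                "test_perf": f.performance["test"],
                "training_error": f.error["training"],
                "validation_error": f.error["validation"],
                "test_error": f.error["test"],
                "r2": f.r2,
                "rmse": f.rmse,
                "bfgs_iterations": f.n_iter,
            }
            for f in fits
        ]
    )
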