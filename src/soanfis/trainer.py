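"""Hybrid training loop: SO searches the Gaussian premise parameters while
the linear consequents are re-solved by least squares inside every strength
evaluation (strength = negative training RMSE)."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anfis import AnfisModel, FuzzyRule, init_model_from_fcm, predict, solve_consequents
from .metrics import MetricsReport, ModelCombo, compute_metrics
from .so import Bounds, SOConfig, optimize

__all__ = [
    "TrainerConfig",
    "TrainedModel",
    "encode_premises",
    "decode_premises",
    "training_strength",
    "split_train_test",
    "train",
]

#: sigma search range as fractions of each feature's observed range.
SIGMA_FRACTION_MIN = 0.01
SIGMA_FRACTION_MAX = 1.0


@dataclass(frozen=True)
class TrainerConfig:
    so: SOConfig = field(default_factory=SOConfig)
    n_rules: int = 3
    ridge: float = 1e-8
    test_fraction: float = 0.20
    split_seed: int | None = None
    fuzzifier: float = 2.0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_rules < 1:
            raise ValueError("n_rules must be >= 1")


@dataclass
class TrainedModel:
    model: AnfisModel
    train_metrics: MetricsReport
    test_metrics: MetricsReport
    so_trace: pd.DataFrame
    train_index: np.ndarray
    test_index: np.ndarray


def encode_premises(model: AnfisModel, X: np.ndarray) -> tuple[np.ndarray, Bounds]:
    """Flatten premises into an SO search vector with data-driven bounds.

    Layout is rule-major, centers before widths within each rule:
    [c_11..c_1m, s_11..s_1m, c_21..., ...], giving D = 2 * n_rules * m.
    Center bounds are each training feature's [min, max]; width bounds are
    [1%, 100%] of the feature's range (with a positive floor for constant
    features).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty training data")
    if X.shape[1] != model.n_inputs:
        raise ValueError("training data arity does not match model")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    sig_lo = np.where(span > 0, SIGMA_FRACTION_MIN * span, 1e-6)
    sig_hi = np.where(span > 0, SIGMA_FRACTION_MAX * span, 1.0)
    vec, lower, upper = [], [], []
    for rule in model.rules:
        vec.extend(rule.centers)
        vec.extend(rule.widths)
        lower.extend(lo)
        lower.extend(sig_lo)
        upper.extend(hi)
        upper.extend(sig_hi)
    return np.array(vec, dtype=float), Bounds(np.array(lower), np.array(upper))


def decode_premises(vector: np.ndarray, template: AnfisModel) -> AnfisModel:
    """Inverse of :func:`encode_premises`; consequents are left unset."""
    vector = np.asarray(vector, dtype=float)
    n, m = template.n_rules, template.n_inputs
    if vector.shape != (2 * n * m,):
        raise ValueError(f"expected vector of length {2 * n * m}, got {vector.shape}")
    rules = []
    for i in range(n):
        chunk = vector[2 * m * i: 2 * m * (i + 1)]
        centers, widths = chunk[:m], chunk[m:]
        if np.any(widths <= 0):
            raise ValueError("decoded widths must be positive")
        rules.append(FuzzyRule(centers.copy(), widths.copy()))
    return AnfisModel(rules, list(template.input_names), template.target_name)


def training_strength(vector: np.ndarray, X_train: np.ndarray,
                      y_train: np.ndarray, template: AnfisModel,
                      ridge: float = 1e-8) -> float:
    """Negative training RMSE of the candidate premises (consequents re-solved)."""
    model = decode_premises(vector, template)
    solve_consequents(model, X_train, y_train, ridge=ridge)
    resid = predict(model, X_train) - np.asarray(y_train, dtype=float)
    return -float(np.sqrt(np.mean(resid ** 2)))


def split_train_test(table: pd.DataFrame, config: TrainerConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform random split into ceil((1 - f) n) train / rest test rows."""
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(config.split_seed)
    perm = rng.permutation(n)
    n_train = math.ceil((1.0 - config.test_fraction) * n)
    train_pos, test_pos = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return table.iloc[train_pos], table.iloc[test_pos]


def train(table: pd.DataFrame, combo: ModelCombo, config: TrainerConfig,
          target: str | None = None) -> TrainedModel:
    """Full hybrid fit for one input combination.

    Restricts the feature table to the combo's columns, splits, builds an
    FCM-initialized model, then runs SO over the encoded premise vector with
    the FCM premises injected into the initial forest.  The best vector is
    decoded, its consequents re-solved on the training rows, and metrics are
    reported on both partitions.
    """
    if target is None:
        target = "target" if "target" in table.columns else table.columns[-1]
    missing = [c for c in combo.inputs if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks combo columns: {missing}")
    train_df, test_df = split_train_test(table, config)
    X_train = train_df.loc[:, list(combo.inputs)].to_numpy(dtype=float)
    y_train = train_df.loc[:, target].to_numpy(dtype=float)
    X_test = test_df.loc[:, list(combo.inputs)].to_numpy(dtype=float)
    y_test = test_df.loc[:, target].to_numpy(dtype=float)

    fcm_model = init_model_from_fcm(
        X_train, y_train, config.n_rules, input_names=list(combo.inputs),
        target_name=target, fuzzifier=config.fuzzifier,
        seed=config.so.rng_seed, ridge=config.ridge)
    x0, bounds = encode_premises(fcm_model, X_train)
    x0 = bounds.clip(x0)

    def strength(vec: np.ndarray) -> float:
        return training_strength(vec, X_train, y_train, fcm_model, ridge=config.ridge)

    best, trace = optimize(strength, bounds, config.so, seeds=[x0])
    model = decode_premises(best.position, fcm_model)
    solve_consequents(model, X_train, y_train, ridge=config.ridge)

    trace = trace.copy()
    trace["best_rmse"] = -trace["best_strength"]
    train_metrics = compute_metrics(y_train, predict(model, X_train))
    test_metrics = compute_metrics(y_test, predict(model, X_test))
    return TrainedModel(model=model, train_metrics=train_metrics,
                        test_metrics=test_metrics, so_trace=trace,
                        train_index=train_df.index.to_numpy(),
                        test_index=test_df.index.to_numpy())
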