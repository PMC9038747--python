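"""First-order Takagi-Sugeno fuzzy inference.

Gaussian memberships, product firing, weighted-average defuzzification,
fuzzy c-means rule initialization, and ridge least-squares estimation of
the linear consequents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FuzzyRule",
    "AnfisModel",
    "gaussian_membership",
    "rule_firing",
    "firing_matrix",
    "infer",
    "predict",
    "fcm_cluster",
    "init_model_from_fcm",
    "solve_consequents",
]

#: Total-firing level below which inference falls back to the nearest rule.
FIRING_UNDERFLOW = 1e-300


def gaussian_membership(x, c: float, sigma: float):
    """Gaussian membership exp(-((x - c)/sigma)^2 / 2), in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (np.asarray(x, dtype=float) - c) / sigma
    return np.exp(-0.5 * z * z)


@dataclass
class FuzzyRule:
    """One TSK rule: Gaussian premises per input plus a linear consequent.

    ``consequents`` holds the slopes for each input followed by the
    intercept (length m + 1), or None before estimation.
    """

    centers: np.ndarray
    widths: np.ndarray
    consequents: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.centers.shape != self.widths.shape or self.centers.ndim != 1:
            raise ValueError("centers and widths must be 1-D arrays of equal length")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")
        if self.consequents is not None:
            self.consequents = np.asarray(self.consequents, dtype=float)
            if self.consequents.shape != (self.centers.size + 1,):
                raise ValueError("consequents must have length m + 1")

    @property
    def n_inputs(self) -> int:
        return self.centers.size

    def output(self, x: np.ndarray) -> float:
        if self.consequents is None:
            raise ValueError("rule consequents are unset")
        return float(self.consequents[:-1] @ np.asarray(x, float) + self.consequents[-1])

    def copy(self) -> "FuzzyRule":
        return FuzzyRule(self.centers.copy(), self.widths.copy(),
                         None if self.consequents is None else self.consequents.copy())


@dataclass
class AnfisModel:
    """A bank of TSK rules sharing the same inputs."""

    rules: list[FuzzyRule]
    input_names: list[str] = field(default_factory=list)
    target_name: str = "target"

    def __post_init__(self):
        if not self.rules:
            raise ValueError("model needs at least one rule")
        m = self.rules[0].n_inputs
        if any(r.n_inputs != m for r in self.rules):
            raise ValueError("all rules must share the input count")
        if not self.input_names:
            self.input_names = [f"x{j + 1}" for j in range(m)]
        if len(self.input_names) != m:
            raise ValueError("input_names length must match rule arity")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_inputs(self) -> int:
        return self.rules[0].n_inputs

    def copy(self) -> "AnfisModel":
        return AnfisModel([r.copy() for r in self.rules],
                          list(self.input_names), self.target_name)

    # -- JSON round trip (bit-exact: floats survive repr round-tripping) --

    def to_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "target_name": self.target_name,
            "rules": [
                {
                    "centers": r.centers.tolist(),
                    "widths": r.widths.tolist(),
                    "consequents": None if r.consequents is None else r.consequents.tolist(),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AnfisModel":
        rules = [FuzzyRule(r["centers"], r["widths"], r.get("consequents"))
                 for r in doc["rules"]]
        return cls(rules, list(doc["input_names"]), doc["target_name"])

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AnfisModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if "{" in text:
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls.from_dict(doc)


def rule_firing(x: Sequence[float], rule: FuzzyRule) -> float:
    """Product of per-input memberships at x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (rule.n_inputs,):
        raise ValueError(f"expected {rule.n_inputs} inputs, got {x.shape}")
    memberships = [gaussian_membership(xj, c, s)
                   for xj, c, s in zip(x, rule.centers, rule.widths)]
    return float(np.prod(memberships))


def firing_matrix(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Firing strengths, shape (n_samples, n_rules)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} columns, got {X.shape[1]}")
    centers = np.array([r.centers for r in model.rules])  # (k, m)
    widths = np.array([r.widths for r in model.rules])
    z = (X[:, None, :] - centers[None, :, :]) / widths[None, :, :]
    return np.exp(-0.5 * np.sum(z * z, axis=2))


def _nearest_rule(model: AnfisModel, x: np.ndarray) -> int:
    """Index of the rule with the smallest width-scaled distance to x."""
    d2 = [np.sum(((x - r.centers) / r.widths) ** 2) for r in model.rules]
    return int(np.argmin(d2))


def infer(model: AnfisModel, x: Sequence[float]) -> float:
    """Firing-weighted average of rule outputs at a single point."""
    x = np.asarray(x, dtype=float)
    mu = firing_matrix(model, x[None, :])[0]
    total = mu.sum()
    if total < FIRING_UNDERFLOW:
        return model.rules[_nearest_rule(model, x)].output(x)
    outputs = np.array([r.output(x) for r in model.rules])
    return float(mu @ outputs / total)


def predict(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Vectorized inference over rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = firing_matrix(model, X)
    coefs = np.array([r.consequents for r in model.rules])  # (k, m + 1)
    outputs = X @ coefs[:, :-1].T + coefs[:, -1]            # (n, k)
    totals = mu.sum(axis=1)
    ok = totals >= FIRING_UNDERFLOW
    y = np.empty(X.shape[0])
    with np.errstate(invalid="ignore"):
        y[ok] = np.sum(mu[ok] * outputs[ok], axis=1) / totals[ok]
    for i in np.nonzero(~ok)[0]:
        y[i] = outputs[i, _nearest_rule(model, X[i])]
    return y


def fcm_cluster(X: np.ndarray, k: int, fuzzifier: float = 2.0,
                tol: float = 1e-6, max_iter: int = 300,
                seed: int | None = None):
    """Fuzzy c-means: returns (centers (k, m), memberships (n, k), objective trace).

    Standard fixed-point iteration; membership rows sum to 1; points
    coincident with a center are hard-assigned to it.  Converges when the
    largest center shift drops below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError("need at least k samples")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    centers = np.zeros((k, X.shape[1]))
    objective = []
    for _ in range(max_iter):
        um = u ** fuzzifier
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = np.maximum(
            np.sum((X[:, None, :] - new_centers[None, :, :]) ** 2, axis=2), 0.0)
        objective.append(float(np.sum(um * d2)))
        zero = d2 <= 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (fuzzifier - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = 0.0
            u[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    return centers, u, np.array(objective)


def init_model_from_fcm(X: np.ndarray, y: np.ndarray, k: int,
                        input_names: Sequence[str] | None = None,
                        target_name: str = "target",
                        fuzzifier: float = 2.0, tol: float = 1e-6,
                        max_iter: int = 300, seed: int | None = None,
                        ridge: float = 1e-8) -> AnfisModel:
    """One rule per FCM cluster; widths are membership-weighted feature sds.

    Widths are floored at 1% of each feature's observed range (or a small
    absolute floor for constant features) so degenerate clusters cannot
    produce zero-width memberships.  Consequents are then estimated by
    :func:`solve_consequents`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    centers, u, _ = fcm_cluster(X, k, fuzzifier=fuzzifier, tol=tol,
                                max_iter=max_iter, seed=seed)
    span = X.max(axis=0) - X.min(axis=0)
    floor = np.where(span > 0, 0.01 * span,
                     np.maximum(1e-3, 1e-3 * np.abs(centers).max(axis=0)))
    rules = []
    for i in range(k):
        w = u[:, i]
        wsum = w.sum()
        if wsum > 0:
            var = (w[:, None] * (X - centers[i]) ** 2).sum(axis=0) / wsum
        else:
            var = np.zeros(X.shape[1])
        widths = np.maximum(np.sqrt(var), floor)
        rules.append(FuzzyRule(centers[i], widths))
    names = list(input_names) if input_names else None
    model = AnfisModel(rules, names or [], target_name)
    return solve_consequents(model, X, y, ridge=ridge)


def solve_consequents(model: AnfisModel, X: np.ndarray, y: np.ndarray,
                      ridge: float = 1e-8) -> AnfisModel:
    """Estimate all rule consequents jointly by ridge least squares.

    Each sample contributes its normalized firing weights times [x, 1] per
    rule (the classic TSK consequent layer); the global system is solved
    with Tikhonov regularization so it is always well-posed.  Premises are
    left untouched; the model is modified in place and returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    k = model.n_rules
    mu = firing_matrix(model, X)
    totals = mu.sum(axis=1)
    wbar = np.empty_like(mu)
    ok = totals >= FIRING_UNDERFLOW
    wbar[ok] = mu[ok] / totals[ok, None]
    for i in np.nonzero(~ok)[0]:
        wbar[i] = 0.0
        wbar[i, _nearest_rule(model, X[i])] = 1.0
    ext = np.hstack([X, np.ones((n, 1))])               # (n, m + 1)
    phi = (wbar[:, :, None] * ext[:, None, :]).reshape(n, k * (m + 1))
    # ridge as augmented rows keeps the solve well-conditioned in raw units
    p = k * (m + 1)
    aug = np.vstack([phi, np.sqrt(ridge) * np.eye(p)])
    rhs = np.concatenate([y, np.zeros(p)])
    beta = np.linalg.lstsq(aug, rhs, rcond=None)[0].reshape(k, m + 1)
    for i, rule in enumerate(model.rules):
        rule.consequents = beta[i]
    return model
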