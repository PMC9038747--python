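"""Goodness-of-fit criteria and combo-evaluation reporting.

Five statistics are computed per (observed, predicted) pair: squared
correlation R^2, RMSE, the scatter index SI = RMSE / mean(observed), the
summed-relative-error delta% and an NSE-style efficiency.  The NSE default
("as-printed") normalizes by deviations of the observations around the
*predicted* mean; the conventional form (observed mean) is available as
``nse_mode="standard"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "ModelCombo",
    "STANDARD_COMBOS",
    "compute_metrics",
    "error_distribution",
    "evaluate_combos",
    "ComboReport",
]


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rmse: float
    si: float
    delta_pct: float
    nse: float
    n: int
    nse_mode: str = "as-printed"

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "si": self.si,
                "delta_pct": self.delta_pct, "nse": self.nse, "n": self.n,
                "nse_mode": self.nse_mode}


@dataclass(frozen=True)
class ModelCombo:
    """A named subset of the five candidate inputs."""

    name: str
    inputs: tuple[str, ...]

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("combo needs at least one input")


#: The six input combinations evaluated against each other.
STANDARD_COMBOS: dict[str, ModelCombo] = {
    "w1": ModelCombo("w1", ("Ir", "P_e", "RH_avg", "T_emp", "S_sh")),
    "w2": ModelCombo("w2", ("Ir", "P_e", "RH_avg", "S_sh")),
    "w3": ModelCombo("w3", ("Ir", "P_e", "T_emp", "S_sh")),
    "w4": ModelCombo("w4", ("Ir", "P_e", "RH_avg", "T_emp")),
    "w5": ModelCombo("w5", ("Ir", "T_emp", "RH_avg", "S_sh")),
    "w6": ModelCombo("w6", ("T_emp", "P_e", "S_sh")),
}


def compute_metrics(observed, predicted, nse_mode: str = "as-printed") -> MetricsReport:
    """All five criteria for one observed/predicted pair.

    R^2 is the squared Pearson correlation; delta% is the summed absolute
    error over the summed observations, times 100.
    """
    w = np.asarray(observed, dtype=float)
    z = np.asarray(predicted, dtype=float)
    if w.shape != z.shape or w.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    n = w.size
    if n < 2:
        raise ValueError("need at least two samples")
    if nse_mode not in ("as-printed", "standard"):
        raise ValueError(f"unknown nse_mode {nse_mode!r}")
    wbar, zbar = w.mean(), z.mean()
    sw = np.sqrt(np.sum((w - wbar) ** 2))
    sz = np.sqrt(np.sum((z - zbar) ** 2))
    if sw == 0:
        raise ValueError("observed vector is constant; R^2 undefined")
    if sz == 0:
        r2 = 0.0 if not np.allclose(z, w) else 1.0
    else:
        r = np.sum((w - wbar) * (z - zbar)) / (sw * sz)
        r2 = float(np.clip(r * r, 0.0, 1.0))
    rmse = float(np.sqrt(np.mean((w - z) ** 2)))
    si = rmse / wbar if wbar != 0 else np.inf if rmse > 0 else 0.0
    delta = float(np.sum(np.abs(z - w)) / np.sum(w) * 100.0)
    ref = zbar if nse_mode == "as-printed" else wbar
    denom = np.sum((w - ref) ** 2)
    if denom == 0:
        nse = 1.0 if rmse == 0 else -np.inf
    else:
        nse = float(1.0 - np.sum((w - z) ** 2) / denom)
    return MetricsReport(r2=r2, rmse=rmse, si=float(si), delta_pct=delta,
                         nse=nse, n=n, nse_mode=nse_mode)


def error_distribution(observed, predicted, thresholds_pct) -> pd.DataFrame:
    """Fraction of samples whose relative error falls below each threshold.

    The relative error is |z - w| / |w| * 100; samples with w == 0 are
    excluded with a warning.  Output columns: threshold_pct, fraction.
    """
    w = np.asarray(observed, dtype=float)
    z = np.asarray(predicted, dtype=float)
    if w.shape != z.shape:
        raise ValueError("length mismatch")
    nonzero = w != 0
    if not nonzero.all():
        warnings.warn(f"excluding {np.sum(~nonzero)} samples with observed value 0")
    w, z = w[nonzero], z[nonzero]
    rel = np.abs(z - w) / np.abs(w) * 100.0
    rows = [(float(t), float(np.mean(rel < t)) if rel.size else np.nan)
            for t in thresholds_pct]
    return pd.DataFrame(rows, columns=["threshold_pct", "fraction"])


@dataclass
class ComboReport:
    """Per-combo train/test metrics plus the winning combo."""

    table: pd.DataFrame
    best_combo: str
    models: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_combos(table: pd.DataFrame, combos, config,
                    target: str | None = None) -> ComboReport:
    """Train one model per input combination on an identical split and seed.

    Emits one train and one test metrics row per combo; the best combo is
    the one with the lowest test RMSE (ties: higher test R^2, then the order
    the combos were given in).
    """
    from .trainer import train

    if isinstance(combos, dict):
        combos = list(combos.values())
    rows = []
    models = {}
    results = []
    for combo in combos:
        fitted = train(table, combo, config, target=target)
        models[combo.name] = fitted
        for split, rep in (("train", fitted.train_metrics),
                           ("test", fitted.test_metrics)):
            rows.append({"combo": combo.name, "split": split, **rep.as_dict()})
        results.append((combo.name, fitted.test_metrics.rmse,
                        fitted.test_metrics.r2))
    best = min(enumerate(results), key=lambda t: (t[1][1], -t[1][2], t[0]))[1][0]
    report = pd.DataFrame(rows)
    return ComboReport(table=report, best_combo=best, models=models)
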