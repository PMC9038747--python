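"""Synthetic feature tables, packaged fixture tables, and table I/O.

The generator draws the five climate/irrigation features uniformly within
configurable ranges (the seasonal water-consumption range is anchored to
the study region's observed [3950, 4945.2] m^3/ha; the others are plausible
mid-latitude defaults) and plants a known TSK fuzzy surface as the target,
optionally with Gaussian noise — so every downstream module has a ground
truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anfis import AnfisModel, FuzzyRule, predict

__all__ = [
    "FEATURES",
    "DEFAULT_RANGES",
    "GeneratorSpec",
    "default_true_model",
    "generate_features",
    "generate_targets",
    "generate_table",
    "load_fixture",
    "read_table",
    "write_table",
]

FEATURES = ("Ir", "T_emp", "RH_avg", "S_sh", "P_e")

#: Feature ranges; Ir is data-anchored, the others are invented defaults.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Ir": (3950.0, 4945.2),     # m^3/ha, observed min/max
    "T_emp": (10.0, 35.0),      # degC
    "RH_avg": (30.0, 80.0),     # %
    "S_sh": (6.0, 14.0),        # h
    "P_e": (0.0, 60.0),         # mm
}


def default_true_model(inputs=("Ir", "P_e", "RH_avg", "S_sh"),
                       target_name: str = "target") -> AnfisModel:
    """The planted 3-rule TSK surface used by default.

    Rules sit at 25/50/75% of each input's range with widths of 50% of the
    range; consequent slopes are scaled inversely to the input ranges so
    every input contributes comparable output variance.
    """
    lo = np.array([DEFAULT_RANGES[f][0] for f in inputs])
    hi = np.array([DEFAULT_RANGES[f][1] for f in inputs])
    span = hi - lo
    rules = []
    slope_signs = [
        np.array([1.0, 0.6, -0.8, 0.5][: len(inputs)]),
        np.array([-0.5, 1.0, 0.7, -0.6][: len(inputs)]),
        np.array([0.8, -0.7, 0.5, 1.0][: len(inputs)]),
    ]
    intercepts = [10.0, 30.0, -15.0]
    for q, signs, b in zip((0.25, 0.5, 0.75), slope_signs, intercepts):
        centers = lo + q * span
        widths = 0.50 * span
        slopes = 20.0 * signs / span
        rules.append(FuzzyRule(centers, widths,
                               np.append(slopes, b)))
    return AnfisModel(rules, list(inputs), target_name)


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic table."""

    n_samples: int = 120
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    true_model: AnfisModel | None = None
    noise_sd: float = 0.02           # fraction of the clean-target range
    correlation: float = 0.0         # equicorrelation of the Gaussian copula
    seed: int | None = None
    target_name: str = "target"

    def __post_init__(self):
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (-0.2 < self.correlation < 1.0):
            raise ValueError("correlation must lie in (-0.2, 1)")
        for name, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    def model(self) -> AnfisModel:
        if self.true_model is not None:
            return self.true_model
        return default_true_model(target_name=self.target_name)


def generate_features(spec: GeneratorSpec) -> pd.DataFrame:
    """Uniform-marginal features within the spec's ranges, plus row_id.

    Features are independent by default; a nonzero ``correlation`` couples
    them through an equicorrelated Gaussian copula while leaving the
    uniform marginals intact.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, len(FEATURES)
    if spec.correlation != 0.0 and n > 0:
        from scipy.stats import norm

        cov = np.full((m, m), spec.correlation)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(m), cov, size=n,
                                    method="cholesky")
        quantiles = norm.cdf(z)
    else:
        quantiles = rng.random((n, m))
    data = {"row_id": np.arange(n)}
    for j, name in enumerate(FEATURES):
        lo, hi = spec.ranges[name]
        data[name] = lo + quantiles[:, j] * (hi - lo)
    return pd.DataFrame(data)


def generate_targets(table: pd.DataFrame,
                     spec: GeneratorSpec) -> tuple[pd.DataFrame, AnfisModel]:
    """Plant the spec's TSK surface (plus noise) as the target column.

    Noise sd is ``noise_sd`` times the clean-target range; the noise stream
    is seeded independently of the feature stream (offset seed) so the same
    features can be reused under different noise draws.  Returns the table
    copy with the target set, alongside the planted model.
    """
    model = spec.model()
    missing = [c for c in model.input_names if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks planted-model inputs: {missing}")
    X = table.loc[:, list(model.input_names)].to_numpy(dtype=float)
    out = table.copy()
    clean = predict(model, X) if len(table) else np.array([])
    if spec.noise_sd > 0 and len(table):
        rng = np.random.default_rng(
            None if spec.seed is None else spec.seed + 1)
        scale = np.ptp(clean)
        noise = rng.normal(0.0, spec.noise_sd * scale, size=clean.shape)
        out[spec.target_name] = clean + noise
    else:
        out[spec.target_name] = clean
    return out, model


def generate_table(spec: GeneratorSpec) -> tuple[pd.DataFrame, AnfisModel]:
    """Features plus planted targets in one call."""
    return generate_targets(generate_features(spec), spec)


# --------------------------------------------------------------------------
# Packaged fixture tables (printed values, transcribed digit-for-digit).

_TABLE4 = [
    # treatment, event, Q_lps, t_min, Ig_mm, In_mm, AE_pct
    ("BI",   1,  8.71, 150, 95.0,  29.9, 31.2),
    ("BI",   2, 10.30, 200, 149.8, 27.8, 26.2),
    ("BI",   3, 10.63, 220, 170.2, 33.3, 28.1),
    ("BI",   4, 10.53, 250, 205.7, 44.8, 21.8),
    ("NSI",  1,  8.61,  93, 74.3,  57.5, 77.4),
    ("NSI",  2,  8.62,  82, 86.7,  64.4, 74.3),
    ("NSI",  3,  8.65,  80, 91.2,  65.0, 69.3),
    ("NSI",  4,  8.15,  68, 93.3,  71.6, 64.8),
    ("TSFI", 1,  7.25, 110, 129.0, 78.9, 66.7),
    ("TSFI", 2,  9.26,  94, 123.1, 79.5, 61.6),
    ("TSFI", 3,  9.23,  90, 108.4, 73.0, 51.2),
    ("TSFI", 4,  9.15,  80, 100.6, 55.5, 45.0),
]

_TABLE5 = [
    # treatment, yield_kg_ha, wue_kg_m3, reduction_applied_water_pct
    ("BI",   30000.0, 4.01, np.nan),
    ("NSI",  35000.0, 7.14, 42.8),
    ("TSFI", 32000.0, 5.24, 22.7),
]

_TABLE7 = [
    ("w1", "Ir,P_e,RH_avg,T_emp,S_sh"),
    ("w2", "Ir,P_e,RH_avg,S_sh"),
    ("w3", "Ir,P_e,T_emp,S_sh"),
    ("w4", "Ir,P_e,RH_avg,T_emp"),
    ("w5", "Ir,T_emp,RH_avg,S_sh"),
    ("w6", "T_emp,P_e,S_sh"),
]

FIXTURES = ("table4_events", "table5_summary", "table7_combos")


def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged printed tables as a DataFrame."""
    if name == "table4_events":
        return pd.DataFrame(
            _TABLE4,
            columns=["treatment", "event", "Q_lps", "t_min",
                     "Ig_mm", "In_mm", "AE_pct"])
    if name == "table5_summary":
        return pd.DataFrame(
            _TABLE5,
            columns=["treatment", "yield_kg_ha", "wue_kg_m3",
                     "reduction_applied_water_pct"])
    if name == "table7_combos":
        df = pd.DataFrame(_TABLE7, columns=["model", "inputs"])
        df["inputs"] = df["inputs"].str.split(",")
        return df
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")


# --------------------------------------------------------------------------
# Feature-table I/O.

def write_table(table: pd.DataFrame, path) -> None:
    """CSV out: comma-separated, '.' decimal, 12 significant digits."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_table(path, require_target: bool = True) -> pd.DataFrame:
    """CSV in: requires the five feature columns (and a non-feature column
    to serve as target unless ``require_target=False``); preserves unknown
    columns and row order; reports non-numeric cells by row and column."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    extra = [c for c in df.columns if c not in FEATURES and c != "row_id"]
    if require_target and not extra:
        raise ValueError("no target column found beside the five features")
    for col in FEATURES:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
        if coerced.isna().any():
            row = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = coerced
    return df
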