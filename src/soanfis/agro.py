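"""Irrigation and agronomy arithmetic.

Water-use efficiency, application efficiency, the shaded-strip daily water
requirement, and the treatment-comparison report used for the headline
numbers.  All formulas compute from their inputs; printed fixture values
are never silently "corrected".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaterBalance",
    "IrrigationEvent",
    "TreatmentSummary",
    "water_use_efficiency",
    "application_efficiency",
    "applied_depth",
    "applied_depth_from_flow",
    "nsi_daily_requirement",
    "compare_treatments",
    "classify_cv",
    "read_events_csv",
    "read_summary_csv",
    "summaries_from_frames",
]


@dataclass(frozen=True)
class WaterBalance:
    """Seasonal water budget per hectare (all terms m^3/ha)."""

    yield_kg_ha: float
    irrigation: float
    effective_rainfall: float = 0.0
    soil_depletion: float = 0.0

    def __post_init__(self):
        for name in ("yield_kg_ha", "irrigation", "effective_rainfall", "soil_depletion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.irrigation + self.effective_rainfall + self.soil_depletion <= 0:
            raise ValueError("total applied water must be positive")


@dataclass(frozen=True)
class IrrigationEvent:
    """One irrigation: inlet flow, cutoff, applied and stored depths, AE."""

    treatment: str
    event: int
    inlet_flow_lps: float | None = None
    cutoff_min: float | None = None
    depth_applied_mm: float | None = None
    net_requirement_mm: float | None = None
    ae_pct: float | None = None

    def __post_init__(self):
        if self.ae_pct is not None and not (0.0 <= self.ae_pct <= 100.0):
            raise ValueError("ae_pct must lie in [0, 100]")
        for name in ("inlet_flow_lps", "cutoff_min", "depth_applied_mm",
                     "net_requirement_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TreatmentSummary:
    """Per-treatment aggregates for the comparison report."""

    name: str
    yield_kg_ha: float | None = None
    wue_kg_m3: float | None = None
    applied_m3_ha: float | None = None
    events: list[IrrigationEvent] = field(default_factory=list)

    def mean_ae(self) -> float | None:
        vals = [e.ae_pct for e in self.events if e.ae_pct is not None]
        return float(np.mean(vals)) if vals else None


def water_use_efficiency(wb: WaterBalance) -> float:
    """Yield over total applied water (irrigation + rainfall + depletion), kg/m^3."""
    return wb.yield_kg_ha / (wb.effective_rainfall + wb.irrigation + wb.soil_depletion)


def application_efficiency(d_z: float, d_app: float) -> float:
    """Stored over applied depth, as a percentage."""
    if d_app <= 0:
        raise ValueError("applied depth must be positive")
    if d_z < 0:
        raise ValueError("stored depth must be non-negative")
    if d_z > d_app:
        warnings.warn("stored depth exceeds applied depth; AE > 100%")
    return d_z / d_app * 100.0


def applied_depth(volume_l: float, area_m2: float) -> float:
    """Applied depth in mm from inlet volume (L) and irrigated area (m^2)."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    if volume_l < 0:
        raise ValueError("volume must be non-negative")
    return volume_l / area_m2


def applied_depth_from_flow(flow_lps: float, minutes: float, area_m2: float) -> float:
    """Applied depth in mm for a constant inlet flow over a cutoff time."""
    return applied_depth(flow_lps * minutes * 60.0, area_m2)


def nsi_daily_requirement(et_c: float, h_s: float) -> float:
    """Daily water requirement under a shaded strip: ET_c * (h_s + 0.15(1 - h_s)).

    ``h_s`` is the canopy shading fraction; values outside the agronomically
    typical [0.5, 0.7] band draw a warning but are computed.
    """
    if not (0.0 <= h_s <= 1.0):
        raise ValueError("shading fraction must lie in [0, 1]")
    if et_c < 0:
        raise ValueError("ET_c must be non-negative")
    if not (0.5 <= h_s <= 0.7):
        warnings.warn("shading fraction outside the typical 0.5-0.7 range")
    return et_c * (h_s + 0.15 * (1.0 - h_s))


def compare_treatments(summaries: list[TreatmentSummary],
                       reference: str) -> pd.DataFrame:
    """Reference-vs-other differences used for the headline comparisons.

    For each non-reference treatment: the WUE difference (reference minus
    other, kg/m^3), the yield increase as a percentage of the *reference*
    yield, each treatment's mean event AE, and the relative mean-AE increase
    (again on the reference's mean).  Missing fields yield NaNs with a
    warning rather than errors.
    """
    by_name = {s.name: s for s in summaries}
    if reference not in by_name:
        raise ValueError(f"reference treatment {reference!r} not present")
    ref = by_name[reference]
    rows = []
    for s in summaries:
        if s.name == reference:
            continue
        row = {"treatment": s.name, "reference": reference}
        if ref.wue_kg_m3 is not None and s.wue_kg_m3 is not None:
            row["wue_diff_kg_m3"] = ref.wue_kg_m3 - s.wue_kg_m3
        else:
            warnings.warn(f"WUE missing for {s.name} or {reference}")
            row["wue_diff_kg_m3"] = np.nan
        if ref.yield_kg_ha and s.yield_kg_ha is not None:
            row["yield_increase_pct"] = (
                (ref.yield_kg_ha - s.yield_kg_ha) / ref.yield_kg_ha * 100.0)
        else:
            warnings.warn(f"yield missing for {s.name} or {reference}")
            row["yield_increase_pct"] = np.nan
        ae_ref, ae_other = ref.mean_ae(), s.mean_ae()
        row["mean_ae_ref_pct"] = np.nan if ae_ref is None else ae_ref
        row["mean_ae_pct"] = np.nan if ae_other is None else ae_other
        if ae_ref and ae_other is not None:
            row["ae_increase_pct"] = (ae_ref - ae_other) / ae_ref * 100.0
        else:
            row["ae_increase_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def classify_cv(cv: float) -> str:
    """Variation-coefficient class: <15% low, 15-35% moderate, >35% great."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv < 15.0:
        return "low"
    if cv <= 35.0:
        return "moderate"
    return "great"


EVENT_COLUMNS = ["treatment", "event", "Q_lps", "t_min", "Ig_mm", "In_mm", "AE_pct"]
SUMMARY_COLUMNS = ["treatment", "yield_kg_ha", "wue_kg_m3"]


def read_events_csv(path) -> pd.DataFrame:
    """Read a per-event irrigation table; requires the standard columns."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events CSV missing columns: {missing}")
    return df


def read_summary_csv(path) -> pd.DataFrame:
    """Read a per-treatment summary table; requires the standard columns."""
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary CSV missing columns: {missing}")
    return df


def summaries_from_frames(summary: pd.DataFrame,
                          events: pd.DataFrame | None = None) -> list[TreatmentSummary]:
    """Assemble :class:`TreatmentSummary` objects from the CSV frames."""
    out = []
    for _, row in summary.iterrows():
        s = TreatmentSummary(
            name=str(row["treatment"]),
            yield_kg_ha=float(row["yield_kg_ha"]),
            wue_kg_m3=float(row["wue_kg_m3"]),
            applied_m3_ha=(float(row["applied_m3_ha"])
                           if "applied_m3_ha" in summary.columns
                           and pd.notna(row.get("applied_m3_ha")) else None),
        )
        if events is not None:
            sub = events[events["treatment"] == s.name]
            s.events = [
                IrrigationEvent(
                    treatment=s.name, event=int(e["event"]),
                    inlet_flow_lps=float(e["Q_lps"]), cutoff_min=float(e["t_min"]),
                    depth_applied_mm=float(e["Ig_mm"]),
                    net_requirement_mm=float(e["In_mm"]), ae_pct=float(e["AE_pct"]))
                for _, e in sub.iterrows()
            ]
        out.append(s)
    return out
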