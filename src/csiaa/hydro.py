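"""Water-column context parameters from CTD and nutrient profiles.

* N* — the dissolved-inorganic-nitrogen anomaly
  N* = (NO₃⁻ + NO₂⁻ + NH₄⁺) − 16·PO₄³⁻ + 2.9 (µmol/kg); values below
  −3 diagnose denitrification, above +2 nitrogen fixation.
* Oxygen saturation from the Weiss (1970) solubility fit and apparent
  oxygen utilization AOU = O₂(saturation) − O₂(measured).
* Trapezoidal dissolved-oxygen inventories over the measured depth span.
* Brunt-Väisälä (buoyancy) frequency from an EOS-80 surface-pressure
  density profile, reported in cycles/h on layer midpoints.

Depth convention: meters, positive downward, no extrapolation beyond the
shallowest or deepest measurement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, UndefinedResultError
from .io import CTDProfile, NutrientProfile

G = 9.81  # m/s²

#: µmol of O₂ per mL of gas at STP (ideal molar volume 22.392 L/mol)
UMOL_PER_ML_O2 = 44.659


class NStarClass(str, enum.Enum):
    DENITRIFICATION = "denitrification"
    INTERMEDIATE = "intermediate"
    N_FIXATION = "n_fixation"


def n_star(nh4_um: float, no2_um: float, no3_um: float, po4_um: float) -> float:
    """Nitrogen anomaly N* (µmol/kg) from nutrient concentrations (µM)."""
    conc = (nh4_um, no2_um, no3_um, po4_um)
    if any(c < 0 for c in conc):
        raise DomainError(f"nutrient concentrations must be ≥ 0, got {conc}")
    return (no3_um + no2_um + nh4_um) - 16.0 * po4_um + 2.9


def classify_n_star(value: float) -> NStarClass:
    """< −3 → denitrification; > 2 → nitrogen fixation; else intermediate.

    The boundary values −3 and 2 themselves fall in the intermediate band.
    """
    if value < -3.0:
        return NStarClass.DENITRIFICATION
    if value > 2.0:
        return NStarClass.N_FIXATION
    return NStarClass.INTERMEDIATE


def o2_saturation(temp_c: float, sal_psu: float) -> float:
    """Equilibrium O₂ concentration (µmol/L) after Weiss (1970).

    The solubility fit is evaluated in mL/L and converted with
    1 mL O₂ = 44.659 µmol.
    """
    if not (-2.0 <= temp_c <= 40.0):
        raise DomainError(f"temperature {temp_c} °C outside [-2, 40]")
    if not (0.0 <= sal_psu <= 42.0):
        raise DomainError(f"salinity {sal_psu} outside [0, 42]")
    t = (temp_c + 273.15) / 100.0
    ln_c = (-173.4292 + 249.6339 / t + 143.3483 * math.log(t) - 21.8492 * t
            + sal_psu * (-0.033096 + 0.014259 * t - 0.0017000 * t * t))
    return math.exp(ln_c) * UMOL_PER_ML_O2


def aou(temp_c: float, sal_psu: float, o2_measured_um: float) -> float:
    """Apparent oxygen utilization (µM); negative means supersaturation."""
    if o2_measured_um < 0:
        raise DomainError(f"measured O₂ must be ≥ 0, got {o2_measured_um}")
    return o2_saturation(temp_c, sal_psu) - o2_measured_um


def oxygen_inventory(profile: CTDProfile) -> float:
    """Trapezoidal O₂ inventory (mmol/m² = mM/m²) over the measured span.

    µM is mmol/m³, so integrating over depth in meters yields mmol/m².
    No extrapolation above the shallowest or below the deepest record.
    """
    if len(profile) < 2:
        raise UndefinedResultError("oxygen inventory needs at least 2 depths")
    return float(np.trapezoid(profile.data["o2_um"].to_numpy(), profile.depths))


def density_eos80(sal_psu, temp_c):
    """Seawater density ρ(S, T) at surface pressure (kg/m³), EOS-80.

    The 1-atm International Equation of State of Seawater (UNESCO 1983
    polynomial).  Adequate for shallow casts where pressure effects on
    density are negligible.
    """
    t = np.asarray(temp_c, float)
    s = np.asarray(sal_psu, float)
    rho_w = (999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
             + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5)
    a = (8.24493e-1 - 4.0899e-3 * t + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3 + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


def brunt_vaisala_from_density(depth_m, rho) -> dict[float, float]:
    """Buoyancy frequency (cycles/h) on layer midpoints from a density profile.

    N² = (g/ρ̄)·Δρ/Δz with depth positive downward, so stable stratification
    (density increasing with depth) gives N² > 0.  Unstable layers are
    clamped to 0 cycles/h.
    """
    depth = np.asarray(depth_m, float)
    rho = np.asarray(rho, float)
    if depth.size < 2:
        raise UndefinedResultError("buoyancy frequency needs at least 2 depths")
    dz = np.diff(depth)
    if np.any(dz <= 0):
        raise DomainError("depths must be strictly increasing")
    rho_mid = 0.5 * (rho[:-1] + rho[1:])
    n2 = G * np.diff(rho) / (rho_mid * dz)        # s⁻²
    n = np.sqrt(np.clip(n2, 0.0, None))           # s⁻¹
    cycles_h = n / (2.0 * math.pi) * 3600.0
    midpoints = 0.5 * (depth[:-1] + depth[1:])
    return {float(d): float(v) for d, v in zip(midpoints, cycles_h)}


def brunt_vaisala(profile: CTDProfile) -> dict[float, float]:
    """Buoyancy frequency (cycles/h) from a CTD profile via EOS-80 density."""
    if len(profile) < 2:
        raise UndefinedResultError("buoyancy frequency needs at least 2 depths")
    rho = density_eos80(profile.data["sal_psu"].to_numpy(),
                        profile.data["temp_c"].to_numpy())
    return brunt_vaisala_from_density(profile.depths, rho)


# ---------------------------------------------------------------------------
# per-station aggregation
# ---------------------------------------------------------------------------

@dataclass
class HydroResult:
    station: str
    n_star: dict[float, float] = field(default_factory=dict)
    n_star_class: dict[float, NStarClass] = field(default_factory=dict)
    aou: dict[float, float] = field(default_factory=dict)
    o2_inventory: float | None = None
    bv_freq: dict[float, float] = field(default_factory=dict)


def compute_hydro(ctd: CTDProfile | None = None,
                  nutrients: NutrientProfile | None = None) -> HydroResult:
    """All water-column context parameters for one station."""
    if ctd is None and nutrients is None:
        raise UndefinedResultError("need at least one of CTD or nutrient profile")
    station = (ctd or nutrients).station
    res = HydroResult(station=station)
    if nutrients is not None:
        for _, row in nutrients.data.iterrows():
            value = n_star(row["nh4_um"], row["no2_um"], row["no3_um"], row["po4_um"])
            res.n_star[float(row["depth_m"])] = value
            res.n_star_class[float(row["depth_m"])] = classify_n_star(value)
    if ctd is not None:
        for _, row in ctd.data.iterrows():
            res.aou[float(row["depth_m"])] = aou(row["temp_c"], row["sal_psu"], row["o2_um"])
        if len(ctd) >= 2:
            res.o2_inventory = oxygen_inventory(ctd)
            res.bv_freq = brunt_vaisala(ctd)
    return res


def hydro_to_frames(results: list[HydroResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-depth frame, per-station summary frame) for CSV export."""
    depth_rows, station_rows = [], []
    for r in results:
        depths = sorted(set(r.n_star) | set(r.aou) | set(r.bv_freq))
        for d in depths:
            depth_rows.append({
                "station": r.station, "depth_m": d,
                "n_star": r.n_star.get(d),
                "n_star_class": r.n_star_class[d].value if d in r.n_star_class else None,
                "aou_um": r.aou.get(d),
                "bv_cycles_h": r.bv_freq.get(d),
            })
        station_rows.append({
            "station": r.station,
            "o2_inventory_mm_m2": r.o2_inventory,
            "bv_max_cycles_h": max(r.bv_freq.values()) if r.bv_freq else None,
        })
    return pd.DataFrame(depth_rows), pd.DataFrame(station_rows)
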