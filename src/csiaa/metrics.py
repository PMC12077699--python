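"""Amino-acid δ¹⁵N/δ¹³C-derived metrics for particulate organic matter.

Implements the standard compound-specific isotope toolbox:

* trophic position from the Glu/Phe pair (metazoan food chains) and the
  Ala/Phe pair (protozoan-dominated chains),
  TP = (δ¹⁵N_tr − δ¹⁵N_src − β) / TDF + 1;
* the ΣV heterotrophic-resynthesis index — the mean absolute deviation of
  the seven trophic amino acids' δ¹⁵N from their mean — and its
  conventional classification (< 1 non-degraded, 1–2 metazoan resynthesis,
  > 2 microbial resynthesis);
* mole-percent-weighted total-hydrolysable-amino-acid (THAA) δ¹⁵N and δ¹³C;
* Phe-normalized δ¹⁵N values (δ¹⁵N_x − δ¹⁵N_Phe);
* apparent fractionation relative to Glu, ε_x/Glu = δ¹⁵N_x − δ¹⁵N_Glu.

All internal arithmetic is full precision; rounding to the 1-decimal
precision conventional in published tables happens only at report time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping

import pandas as pd

from .amino_acids import SIGMA_V_AA, SOURCE_AA, TROPHIC_AA
from .exceptions import DomainError, UndefinedResultError
from .io import AminoAcidSample, DEFAULT_CONSTANTS, TrophicConstants


class SigmaVClass(str, enum.Enum):
    NON_DEGRADED = "non_degraded"
    METAZOAN_RESYNTHESIS = "metazoan_resynthesis"
    MICROBIAL_RESYNTHESIS = "microbial_resynthesis"


def _d15n_map(sample) -> Mapping[str, float]:
    return sample.d15n if isinstance(sample, AminoAcidSample) else dict(sample)


def group_amino_acids(sample) -> tuple[set[str], set[str], set[str]]:
    """Split the amino acids present in *sample* into (trophic, source, other)."""
    present = set(_d15n_map(sample))
    return present & TROPHIC_AA, present & SOURCE_AA, present - TROPHIC_AA - SOURCE_AA


def _check_finite(*values: float) -> None:
    if not all(math.isfinite(v) for v in values):
        raise DomainError(f"non-finite δ¹⁵N input: {values}")


def tp_metazoan(d15n_glu: float, d15n_phe: float,
                constants: TrophicConstants = DEFAULT_CONSTANTS) -> float:
    """Metazoan trophic position from the Glu/Phe δ¹⁵N pair."""
    _check_finite(d15n_glu, d15n_phe)
    return (d15n_glu - d15n_phe - constants.beta_glu_phe) / constants.tdf_glu_phe + 1.0


def tp_protozoan(d15n_ala: float, d15n_phe: float,
                 constants: TrophicConstants = DEFAULT_CONSTANTS) -> float:
    """Protozoan trophic position from the Ala/Phe δ¹⁵N pair."""
    _check_finite(d15n_ala, d15n_phe)
    return (d15n_ala - d15n_phe - constants.beta_ala_phe) / constants.tdf_ala_phe + 1.0


def sigma_v(sample, min_aa: int = 3) -> float:
    """ΣV: mean absolute deviation of trophic-AA δ¹⁵N from their mean (‰).

    Uses whichever of the seven trophic amino acids are present; at least
    *min_aa* are required (default 3), otherwise the result is undefined.
    """
    values = _d15n_map(sample)
    avail = [values[aa] for aa in sorted(SIGMA_V_AA & set(values))]
    if len(avail) < max(min_aa, 1):
        raise UndefinedResultError(
            f"ΣV needs ≥ {min_aa} trophic amino acids, found {len(avail)}"
        )
    centre = fmean(avail)
    return fmean(abs(v - centre) for v in avail)


def sigma_v_n(sample) -> int:
    """Number of trophic amino acids available for ΣV in *sample*."""
    return len(SIGMA_V_AA & set(_d15n_map(sample)))


def classify_sigma_v(value: float) -> SigmaVClass:
    """Conventional ΣV thresholds; the 1–2 band is taken as closed."""
    if value < 0:
        raise DomainError(f"ΣV cannot be negative, got {value}")
    if value < 1.0:
        return SigmaVClass.NON_DEGRADED
    if value <= 2.0:
        return SigmaVClass.METAZOAN_RESYNTHESIS
    return SigmaVClass.MICROBIAL_RESYNTHESIS


def thaa_weighted(sample: AminoAcidSample, isotope: str = "d15N") -> float:
    """Mole-percent-weighted THAA mean δ value (‰).

    Weights are renormalized over the amino acids that carry both an isotope
    value and a mol%, so partial panels are handled gracefully; exact-100%
    inputs are unaffected.
    """
    if isotope == "d15N":
        values = sample.d15n
    elif isotope == "d13C":
        values = sample.d13c or {}
    else:
        raise ValueError(f"isotope must be 'd15N' or 'd13C', got {isotope!r}")
    mol = sample.mol_pct or {}
    shared = sorted(set(values) & set(mol))
    if not shared:
        raise UndefinedResultError(
            f"THAA δ undefined: no amino acid has both {isotope} and mol%"
        )
    total = sum(mol[aa] for aa in shared)
    return sum(values[aa] * mol[aa] for aa in shared) / total


def phe_normalize(sample) -> dict[str, float]:
    """δ¹⁵N_x − δ¹⁵N_Phe for every amino acid present; Phe maps to 0."""
    values = _d15n_map(sample)
    if "Phe" not in values:
        raise UndefinedResultError("Phe-normalization undefined: Phe absent")
    ref = values["Phe"]
    return {aa: v - ref for aa, v in values.items()}


def epsilon_to_glu(sample) -> dict[str, float]:
    """Apparent fractionation ε_x/Glu = δ¹⁵N_x − δ¹⁵N_Glu; Glu maps to 0."""
    values = _d15n_map(sample)
    if "Glu" not in values:
        raise UndefinedResultError("ε_x/Glu undefined: Glu absent")
    ref = values["Glu"]
    return {aa: v - ref for aa, v in values.items()}


# ---------------------------------------------------------------------------
# per-sample aggregation
# ---------------------------------------------------------------------------

@dataclass
class CsiaaResult:
    """All amino-acid-isotope metrics for one sample (None = undefined)."""

    sample_id: str
    bay: str = ""
    station: str = ""
    depth_m: float = float("nan")
    matrix: str = ""
    tp_metazoan: float | None = None
    tp_protozoan: float | None = None
    sigma_v: float | None = None
    sigma_v_n: int = 0
    sigma_v_class: SigmaVClass | None = None
    d15n_thaa: float | None = None
    d13c_thaa: float | None = None
    phe_normalized: dict[str, float] = field(default_factory=dict)
    epsilon_to_glu: dict[str, float] = field(default_factory=dict)
    d15n_phe: float | None = None
    d15n_thr: float | None = None


def compute_metrics(sample: AminoAcidSample,
                    constants: TrophicConstants = DEFAULT_CONSTANTS,
                    min_aa: int = 3) -> CsiaaResult:
    """Compute every defined metric for one sample; undefined ones stay None."""
    res = CsiaaResult(
        sample_id=sample.sample_id, bay=sample.bay, station=sample.station,
        depth_m=sample.depth_m, matrix=sample.matrix,
        d15n_phe=sample.d15n.get("Phe"), d15n_thr=sample.d15n.get("Thr"),
    )
    d = sample.d15n
    if "Glu" in d and "Phe" in d:
        res.tp_metazoan = tp_metazoan(d["Glu"], d["Phe"], constants)
    if "Ala" in d and "Phe" in d:
        res.tp_protozoan = tp_protozoan(d["Ala"], d["Phe"], constants)
    res.sigma_v_n = sigma_v_n(sample)
    try:
        res.sigma_v = sigma_v(sample, min_aa=min_aa)
        res.sigma_v_class = classify_sigma_v(res.sigma_v)
    except UndefinedResultError:
        pass
    for attr, iso in (("d15n_thaa", "d15N"), ("d13c_thaa", "d13C")):
        try:
            setattr(res, attr, thaa_weighted(sample, iso))
        except UndefinedResultError:
            pass
    try:
        res.phe_normalized = phe_normalize(sample)
    except UndefinedResultError:
        pass
    try:
        res.epsilon_to_glu = epsilon_to_glu(sample)
    except UndefinedResultError:
        pass
    return res


def results_to_frame(results: Iterable[CsiaaResult]) -> pd.DataFrame:
    """One row per sample; NA marks undefined metrics.  Column names stable."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id, "bay": r.bay, "station": r.station,
            "depth_m": r.depth_m, "matrix": r.matrix,
            "tp_metazoan": r.tp_metazoan, "tp_protozoan": r.tp_protozoan,
            "sigma_v": r.sigma_v, "sigma_v_n": r.sigma_v_n,
            "sigma_v_class": r.sigma_v_class.value if r.sigma_v_class else None,
            "d15n_thaa": r.d15n_thaa, "d13c_thaa": r.d13c_thaa,
            "d15n_phe": r.d15n_phe, "d15n_thr": r.d15n_thr,
        }
        for aa, v in sorted(r.phe_normalized.items()):
            row[f"phe_norm_{aa}"] = v
        for aa, v in sorted(r.epsilon_to_glu.items()):
            row[f"eps_glu_{aa}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
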