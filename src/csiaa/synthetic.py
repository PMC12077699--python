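"""Synthetic-data generators with known truth for every pipeline stage.

These generators embody the forward model that the estimators invert:

* a trophic-chain model in which each amino acid's δ¹⁵N starts from a
  producer baseline and gains its trophic discrimination factor (TDF) per
  trophic step, so a noiseless consumer at true TP is recovered exactly by
  the TP estimators;
* a heterotrophic-degradation scenario that perturbs the seven trophic
  amino acids with fixed-magnitude, random-sign offsets (each amino acid is
  enriched or depleted by ≈ s_deg), raising ΣV into the microbial band;
* Gaussian tracer mixtures with known source proportions for the Bayesian
  mixing model;
* depth-structured CTD/nutrient profiles with a logistic thermocline and
  oxycline mimicking a stratified upwelling-bay water column.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amino_acids import CANONICAL_AA, TROPHIC_AA
from .exceptions import DomainError
from .io import AminoAcidSample, CTDProfile, EndMember, EndMemberSet, NutrientProfile

#: default per-trophic-step δ¹⁵N enrichment (‰).  Glu and Ala carry the
#: canonical estimator TDFs; the remaining trophic amino acids get a common
#: 5.0‰ (they only affect ΣV-style dispersion, not TP recovery); source
#: amino acids are conserved; Thr depletes slightly with transfer.
DEFAULT_TDF: dict[str, float] = {
    "Glu": 7.6, "Ala": 4.5,
    "Val": 5.0, "Leu": 5.0, "Ile": 5.0, "Pro": 5.0, "Asp": 5.0,
    "Phe": 0.0, "Lys": 0.0, "Ser": 0.0, "Tyr": 0.0,
    "Gly": 0.0, "Thr": -2.0,
}

#: typical mol% composition of hydrolysable amino acids in marine POM
DEFAULT_MOL_PCT: dict[str, float] = {
    "Gly": 15.0, "Ala": 12.0, "Asp": 11.0, "Glu": 11.0, "Leu": 8.0,
    "Ser": 8.0, "Thr": 7.0, "Val": 7.0, "Lys": 6.0, "Ile": 5.0,
    "Pro": 5.0, "Phe": 3.0, "Tyr": 2.0,
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class TrophicChainConfig:
    """Forward model of per-amino-acid δ¹⁵N along a trophic chain.

    The producer baseline satisfies Glu = Phe + 3.4‰ and Ala = Phe + 3.2‰,
    so ``true_tp = 1`` is self-consistent with the TP estimators; the other
    trophic amino acids sit at Phe + 3.3‰ (common mean to within 0.1‰).
    """

    baseline_d15n_phe: float = 15.0
    baseline_d15n_no3: float = 14.8
    per_aa_tdf: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TDF))
    true_tp: float = 1.0
    noise_sd: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be ≥ 0")
        unknown = set(self.per_aa_tdf) - set(CANONICAL_AA)
        if unknown:
            raise DomainError(f"per_aa_tdf has non-canonical codes {sorted(unknown)}")

    def baseline(self) -> dict[str, float]:
        phe = self.baseline_d15n_phe
        base = {
            "Phe": phe, "Glu": phe + 3.4, "Ala": phe + 3.2,
            "Val": phe + 3.3, "Leu": phe + 3.3, "Ile": phe + 3.3,
            "Pro": phe + 3.3, "Asp": phe + 3.3,
            "Ser": phe - 1.0, "Lys": phe + 1.0, "Tyr": phe - 0.5,
            "Gly": phe - 2.0, "Thr": phe - 0.5,
        }
        return base


def simulate_consumer(config: TrophicChainConfig,
                      rng: np.random.Generator | int | None = None,
                      sample_id: str = "SYN", bay: str = "SYN", station: str = "SYN",
                      depth_m: float = 5.0, matrix: str = "suspended") -> AminoAcidSample:
    """One consumer sample at ``config.true_tp`` with Gaussian measurement noise.

    δ¹⁵N_aa = baseline_aa + TDF_aa · (true_tp − 1) + Normal(0, noise_sd).
    """
    if config.true_tp < 1.0:
        raise DomainError(f"true_tp must be ≥ 1, got {config.true_tp}")
    gen = _rng(config.seed if rng is None else rng)
    base = config.baseline()
    steps = config.true_tp - 1.0
    d15n = {}
    for aa in CANONICAL_AA:
        mean = base[aa] + config.per_aa_tdf.get(aa, 0.0) * steps
        d15n[aa] = mean + (gen.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
    return AminoAcidSample(
        sample_id=sample_id, bay=bay, station=station, depth_m=depth_m,
        matrix=matrix, d15n=d15n,
        d15n_sd={aa: config.noise_sd for aa in CANONICAL_AA},
        mol_pct=dict(DEFAULT_MOL_PCT),
    )


def simulate_degraded(config: TrophicChainConfig, s_deg: float = 3.0,
                      rng: np.random.Generator | int | None = None,
                      **sample_kwargs) -> AminoAcidSample:
    """Microbially reworked sample: trophic amino acids shifted by ±s_deg.

    Each of the seven trophic amino acids is independently enriched or
    depleted by the characteristic magnitude *s_deg* (random sign), on top
    of the trophic-chain values, modelling the scatter that heterotrophic
    resynthesis imprints on Tr-AA δ¹⁵N.
    """
    if s_deg < 0:
        raise DomainError("s_deg must be ≥ 0")
    gen = _rng(config.seed if rng is None else rng)
    sample = simulate_consumer(config, rng=gen, **sample_kwargs)
    for aa in sorted(TROPHIC_AA):
        sign = 1.0 if gen.random() < 0.5 else -1.0
        sample.d15n[aa] += sign * s_deg
    return sample


def simulate_mixture(sources: EndMemberSet, proportions: Sequence[float],
                     n_obs: int, rng: np.random.Generator | int | None = None,
                     tracers: Sequence[str] | None = None) -> pd.DataFrame:
    """Observations from the process-error mixture forward model.

    Each tracer is drawn Normal(Σ p_k μ_kt, Σ p_k² σ_kt²), matching the
    likelihood assumed by the mixing model.
    """
    p = np.asarray(proportions, float)
    if p.shape != (len(sources),) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise DomainError(f"proportions must lie on the {len(sources)}-simplex")
    gen = _rng(rng)
    tracers = tuple(tracers) if tracers is not None else sources.tracer_names
    mu, sd = sources.means_sds(tracers)
    mean = p @ mu
    scale = np.sqrt((p ** 2) @ (sd ** 2))
    data = gen.normal(mean, scale, size=(n_obs, len(tracers)))
    return pd.DataFrame(data, columns=list(tracers))


def default_endmembers() -> EndMemberSet:
    """Synthetic stand-in end-member set for the four POM source classes.

    Tracers are Phe-normalized δ¹⁵N of Ala and Thr.  The values are
    plausible literature-scale numbers for phytoplankton, zooplankton,
    microbially degraded organic matter (MDOM) and fecal pellets — a
    synthetic construction for exercising the mixing model, not a
    measured compilation.
    """
    return EndMemberSet(sources=(
        EndMember("fecal_pellets", {"ala_phe": (8.0, 2.0, 12), "thr_phe": (-10.0, 2.0, 12)}),
        EndMember("mdom", {"ala_phe": (6.0, 2.0, 15), "thr_phe": (-2.0, 2.0, 15)}),
        EndMember("phytoplankton", {"ala_phe": (3.2, 1.0, 20), "thr_phe": (-6.0, 1.5, 20)}),
        EndMember("zooplankton", {"ala_phe": (10.0, 1.5, 18), "thr_phe": (-8.0, 2.0, 18)}),
    ))


@dataclass
class ProfileConfig:
    """Logistic-in-depth water-column structure with measurement noise.

    Default asymptotes keep every generated value inside the ranges
    characteristic of a stratified upwelling bay: temperature 13–21 °C,
    dissolved oxygen 11–370 µM, with the thermocline/oxycline centred
    around 18–20 m.
    """

    station: str = "SYN1"
    depths: tuple[float, ...] = (5.0, 20.0, 35.0, 45.0)
    temp_surface: float = 19.0
    temp_deep: float = 13.5
    thermocline_mid_m: float = 18.0
    thermocline_steepness_m: float = 5.0
    o2_surface: float = 350.0
    o2_deep: float = 20.0
    oxycline_mid_m: float = 20.0
    oxycline_steepness_m: float = 6.0
    sal_surface: float = 33.8
    sal_deep: float = 34.6
    ph_surface: float = 8.3
    ph_deep: float = 7.8
    no3_surface: float = 1.0
    no3_deep: float = 20.0
    po4_surface: float = 0.8
    po4_deep: float = 3.0
    nh4_mean: float = 0.8
    no2_surface: float = 0.2
    no2_deep: float = 0.8
    temp_noise: float = 0.05
    o2_noise: float = 2.0
    nutrient_noise: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.depths, self.depths[1:])):
            raise DomainError("depths must be strictly increasing")


def _logistic(depth, surface, deep, mid, steep):
    depth = np.asarray(depth, float)
    return deep + (surface - deep) / (1.0 + np.exp((depth - mid) / steep))


def simulate_profiles(config: ProfileConfig,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[CTDProfile, NutrientProfile]:
    """A matched CTD + nutrient cast for one station."""
    gen = _rng(config.seed if rng is None else rng)
    d = np.asarray(config.depths, float)
    temp = _logistic(d, config.temp_surface, config.temp_deep,
                     config.thermocline_mid_m, config.thermocline_steepness_m)
    o2 = _logistic(d, config.o2_surface, config.o2_deep,
                   config.oxycline_mid_m, config.oxycline_steepness_m)
    sal = _logistic(d, config.sal_surface, config.sal_deep,
                    config.thermocline_mid_m, config.thermocline_steepness_m)
    ph = _logistic(d, config.ph_surface, config.ph_deep,
                   config.oxycline_mid_m, config.oxycline_steepness_m)
    if config.temp_noise > 0:
        temp = temp + gen.normal(0, config.temp_noise, d.size)
    if config.o2_noise > 0:
        o2 = np.clip(o2 + gen.normal(0, config.o2_noise, d.size), 0.0, None)
    ctd = CTDProfile(station=config.station, data=pd.DataFrame({
        "depth_m": d, "temp_c": temp, "sal_psu": sal, "o2_um": o2, "ph": ph,
    }))
    frac = (d - d.min()) / (d.max() - d.min()) if d.size > 1 else np.zeros_like(d)
    noise = (lambda: gen.normal(0, config.nutrient_noise, d.size)) \
        if config.nutrient_noise > 0 else (lambda: 0.0)
    nut = NutrientProfile(station=config.station, data=pd.DataFrame({
        "depth_m": d,
        "nh4_um": np.clip(config.nh4_mean + noise(), 0.0, None),
        "no2_um": np.clip(config.no2_surface + (config.no2_deep - config.no2_surface) * frac
                          + noise(), 0.0, None),
        "no3_um": np.clip(config.no3_surface + (config.no3_deep - config.no3_surface) * frac
                          + noise(), 0.0, None),
        "po4_um": np.clip(config.po4_surface + (config.po4_deep - config.po4_surface) * frac
                          + noise(), 0.0, None),
    }))
    return ctd, nut
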