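"""Domain types and tidy-CSV input/output.

All tabular interchange uses long-format UTF-8 CSV (RFC 4180, "." decimal
separator).  The amino-acid table has one row per sample × amino acid ×
isotope, so partial panels need no sentinel values — a missing amino acid is
simply an absent row.  Floats are written with Python's shortest-repr
formatting and therefore round-trip bit-exactly.

Types
-----
AminoAcidSample
    One particulate-organic-matter sample's per-amino-acid isotope values
    (δ¹⁵N in ‰ vs. air, optional δ¹³C in ‰ vs. VPDB, optional mol%).
CTDProfile / NutrientProfile
    Depth-ordered physical and chemical records for one station.
EndMember / EndMemberSet
    Tracer means ± SD characterising candidate organic-matter sources.
TrophicConstants
    β offsets and trophic discrimination factors for the two
    trophic-position estimators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .amino_acids import is_canonical, normalize_code
from .exceptions import DomainError, DuplicationError, FormatError

logger = logging.getLogger(__name__)

MATRICES = ("suspended", "sinking")

#: plausibility window for single amino-acid δ¹⁵N values (‰ vs. air)
D15N_WINDOW = (-50.0, 60.0)

AA_TABLE_COLUMNS = (
    "sample_id", "bay", "station", "depth_m", "matrix",
    "aa", "isotope", "value_permil", "sd_permil", "mol_pct",
)
CTD_COLUMNS = ("station", "depth_m", "temp_c", "sal_psu", "o2_um", "ph")
NUTRIENT_COLUMNS = ("station", "depth_m", "nh4_um", "no2_um", "no3_um", "po4_um")
ENDMEMBER_COLUMNS = ("source", "tracer", "mean", "sd", "n")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidSample:
    sample_id: str
    bay: str
    station: str
    depth_m: float
    matrix: str
    d15n: dict[str, float]
    d15n_sd: dict[str, float] = field(default_factory=dict)
    d13c: dict[str, float] | None = None
    mol_pct: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise DomainError(f"depth must be non-negative, got {self.depth_m}")
        if self.matrix not in MATRICES:
            raise FormatError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")
        self.d15n = {normalize_code(aa): float(v) for aa, v in self.d15n.items()}
        self.d15n_sd = {normalize_code(aa): float(v) for aa, v in self.d15n_sd.items()}
        if self.d13c is not None:
            self.d13c = {normalize_code(aa): float(v) for aa, v in self.d13c.items()}
        if self.mol_pct is not None:
            self.mol_pct = {normalize_code(aa): float(v) for aa, v in self.mol_pct.items()}
        lo, hi = D15N_WINDOW
        for aa, v in self.d15n.items():
            if not math.isfinite(v) or not lo <= v <= hi:
                raise FormatError(
                    f"sample {self.sample_id}: d15N[{aa}] = {v} outside sanity window {D15N_WINDOW}"
                )
        for aa, v in self.d15n_sd.items():
            if v < 0:
                raise FormatError(f"sample {self.sample_id}: negative SD for {aa}")
        if self.mol_pct is not None and self.mol_pct:
            if any(v <= 0 for v in self.mol_pct.values()):
                raise FormatError(f"sample {self.sample_id}: mol%% values must be > 0")
            total = sum(self.mol_pct.values())
            # ±0.5 absolute tolerance accommodates rounding in published tables
            if abs(total - 100.0) > 0.5:
                raise FormatError(
                    f"sample {self.sample_id}: mol%% sums to {total:.3f}, expected 100 ± 0.5"
                )

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(self.d15n)


def _validated_profile_frame(df: pd.DataFrame, station: str, value_checks) -> pd.DataFrame:
    if df["depth_m"].duplicated().any():
        dup = df.loc[df["depth_m"].duplicated(), "depth_m"].iloc[0]
        raise DuplicationError(f"station {station}: duplicate depth {dup} m")
    if (df["depth_m"] < 0).any():
        raise FormatError(f"station {station}: negative depth")
    for col, (lo, hi) in value_checks.items():
        bad = df[(df[col] < lo) | (df[col] > hi)]
        if len(bad):
            raise FormatError(
                f"station {station}: {col} = {bad[col].iloc[0]} outside [{lo}, {hi}]"
            )
    return df.sort_values("depth_m", kind="mergesort").reset_index(drop=True)


@dataclass
class CTDProfile:
    """Depth-sorted CTD records (one station).  Depth in m, positive downward."""

    station: str
    data: pd.DataFrame  # columns: depth_m, temp_c, sal_psu, o2_um, ph (optional)

    _CHECKS = {"temp_c": (-2.0, 40.0), "sal_psu": (0.0, 42.0), "o2_um": (0.0, math.inf)}

    def __post_init__(self) -> None:
        self.data = _validated_profile_frame(self.data.copy(), self.station, self._CHECKS)

    @property
    def depths(self):
        return self.data["depth_m"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class NutrientProfile:
    """Depth-sorted nutrient records (one station), concentrations in µM."""

    station: str
    data: pd.DataFrame  # columns: depth_m, nh4_um, no2_um, no3_um, po4_um

    _CHECKS = {c: (0.0, math.inf) for c in ("nh4_um", "no2_um", "no3_um", "po4_um")}

    def __post_init__(self) -> None:
        self.data = _validated_profile_frame(self.data.copy(), self.station, self._CHECKS)

    @property
    def depths(self):
        return self.data["depth_m"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class EndMember:
    """One candidate source with tracer means ± SD (and optional n)."""

    source_name: str
    tracers: Mapping[str, tuple[float, float, int | None]]

    def __post_init__(self) -> None:
        for tracer, (mean, sd, n) in self.tracers.items():
            if sd <= 0:
                raise DomainError(f"{self.source_name}/{tracer}: sd must be > 0, got {sd}")
            if n is not None and n <= 0:
                raise DomainError(f"{self.source_name}/{tracer}: n must be positive")


@dataclass(frozen=True)
class EndMemberSet:
    sources: tuple[EndMember, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise FormatError("end-member set is empty")
        names = [s.source_name for s in self.sources]
        if len(set(names)) != len(names):
            raise DuplicationError("duplicate source names in end-member set")
        tracer_sets = {frozenset(s.tracers) for s in self.sources}
        if len(tracer_sets) != 1:
            raise FormatError("all sources must share the same tracer names")

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.source_name for s in self.sources)

    @property
    def tracer_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.sources[0].tracers))

    def __len__(self) -> int:
        return len(self.sources)

    def means_sds(self, tracers: Sequence[str] | None = None):
        """Return (K × T) arrays of tracer means and SDs, source-ordered."""
        import numpy as np

        tracers = tuple(tracers) if tracers is not None else self.tracer_names
        mu = np.array([[s.tracers[t][0] for t in tracers] for s in self.sources], float)
        sd = np.array([[s.tracers[t][1] for t in tracers] for s in self.sources], float)
        return mu, sd


@dataclass(frozen=True)
class TrophicConstants:
    """β offsets and trophic discrimination factors (TDF), all in ‰.

    Defaults are the canonical literature values: Glu−Phe producer offset
    β = 3.4‰ with TDF 7.6‰ per step (metazoan estimator) and Ala−Phe
    β = 3.2‰ with TDF 4.5‰ (protozoan estimator).
    """

    beta_glu_phe: float = 3.4
    tdf_glu_phe: float = 7.6
    beta_ala_phe: float = 3.2
    tdf_ala_phe: float = 4.5

    def __post_init__(self) -> None:
        if self.tdf_glu_phe <= 0 or self.tdf_ala_phe <= 0:
            raise DomainError("trophic discrimination factors must be strictly positive")


DEFAULT_CONSTANTS = TrophicConstants()


# ---------------------------------------------------------------------------
# amino-acid table I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")


def read_aa_table(path, strict: bool = True) -> list[AminoAcidSample]:
    """Read a long-format amino-acid isotope table.

    One row per sample × amino acid × isotope (``isotope`` ∈ {d15N, d13C}).
    Unknown amino-acid codes raise :class:`FormatError` in strict mode and
    are dropped with a logged warning otherwise.  Duplicate
    (sample_id, aa, isotope) rows always raise :class:`DuplicationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "bay": str, "station": str},
                     float_precision="round_trip")
    _require_columns(df, [c for c in AA_TABLE_COLUMNS if c not in ("sd_permil", "mol_pct")], path)
    if "sd_permil" not in df.columns:
        df["sd_permil"] = float("nan")
    if "mol_pct" not in df.columns:
        df["mol_pct"] = float("nan")

    bad = ~df["aa"].map(is_canonical)
    dropped_samples: set[str] = set()
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]  # +2: header + 0-base
        codes = sorted(df.loc[bad, "aa"].unique())
        if strict:
            raise FormatError(
                f"{path}: unknown amino-acid code(s) {codes} at row(s) {rows}"
            )
        logger.warning("%s: dropping %d row(s) with unknown amino-acid code(s) %s",
                       path, int(bad.sum()), codes)
        dropped_samples = set(df.loc[bad, "sample_id"])
        df = df[~bad]
    df = df.assign(aa=df["aa"].map(normalize_code))

    dup = df.duplicated(subset=["sample_id", "aa", "isotope"])
    if dup.any():
        key = df.loc[dup, ["sample_id", "aa", "isotope"]].iloc[0].tolist()
        raise DuplicationError(f"{path}: duplicate (sample_id, aa, isotope) = {key}")

    samples = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        meta = grp.iloc[0]
        n15 = grp[grp["isotope"] == "d15N"]
        c13 = grp[grp["isotope"] == "d13C"]
        d15n = dict(zip(n15["aa"], n15["value_permil"].astype(float)))
        d15n_sd = {aa: float(sd) for aa, sd in zip(n15["aa"], n15["sd_permil"])
                   if pd.notna(sd)}
        d13c = dict(zip(c13["aa"], c13["value_permil"].astype(float))) or None
        mol = {aa: float(m) for aa, m in zip(n15["aa"], n15["mol_pct"]) if pd.notna(m)}
        if mol and sample_id in dropped_samples and abs(sum(mol.values()) - 100.0) > 0.5:
            # dropped rows broke the 100% closure; percentages no longer trustworthy
            logger.warning("%s: sample %s mol%% discarded after dropping rows",
                           path, sample_id)
            mol = {}
        samples.append(AminoAcidSample(
            sample_id=str(sample_id), bay=str(meta["bay"]), station=str(meta["station"]),
            depth_m=float(meta["depth_m"]), matrix=str(meta["matrix"]),
            d15n=d15n, d15n_sd=d15n_sd, d13c=d13c, mol_pct=mol or None,
        ))
    return samples


def write_aa_table(samples: Iterable[AminoAcidSample], path) -> None:
    """Write samples in the long CSV layout read by :func:`read_aa_table`."""
    rows = []
    for s in samples:
        for aa in sorted(s.d15n):
            rows.append({
                "sample_id": s.sample_id, "bay": s.bay, "station": s.station,
                "depth_m": s.depth_m, "matrix": s.matrix, "aa": aa,
                "isotope": "d15N", "value_permil": s.d15n[aa],
                "sd_permil": s.d15n_sd.get(aa),
                "mol_pct": (s.mol_pct or {}).get(aa),
            })
        for aa in sorted(s.d13c or {}):
            rows.append({
                "sample_id": s.sample_id, "bay": s.bay, "station": s.station,
                "depth_m": s.depth_m, "matrix": s.matrix, "aa": aa,
                "isotope": "d13C", "value_permil": s.d13c[aa],
                "sd_permil": None, "mol_pct": None,
            })
    pd.DataFrame(rows, columns=list(AA_TABLE_COLUMNS)).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def read_profile(path, kind: str) -> list[CTDProfile] | list[NutrientProfile]:
    """Read a CTD or nutrient profile CSV into per-station, depth-sorted profiles.

    ``kind`` is ``"ctd"`` or ``"nutrient"``.  Rows may arrive in any order;
    output profiles are sorted ascending by depth, one per station.
    """
    path = Path(path)
    if kind == "ctd":
        required, cls = [c for c in CTD_COLUMNS if c != "ph"], CTDProfile
    elif kind == "nutrient":
        required, cls = list(NUTRIENT_COLUMNS), NutrientProfile
    else:
        raise ValueError(f"kind must be 'ctd' or 'nutrient', got {kind!r}")
    df = pd.read_csv(path, dtype={"station": str}, float_precision="round_trip")
    _require_columns(df, required, path)
    numeric = [c for c in required if c != "station"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and df[col].notna().any():
            raise FormatError(f"{path}: non-numeric value in column {col!r}")
        df[col] = vals
    if df["depth_m"].isna().any():
        raise FormatError(f"{path}: non-numeric or missing depth")
    return [cls(station=str(st), data=grp.drop(columns="station").reset_index(drop=True))
            for st, grp in df.groupby("station", sort=True)]


def write_profile(profiles: Sequence[CTDProfile] | Sequence[NutrientProfile], path) -> None:
    frames = []
    for p in profiles:
        frame = p.data.copy()
        frame.insert(0, "station", p.station)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# end-member I/O
# ---------------------------------------------------------------------------

def read_endmembers(path) -> EndMemberSet:
    """Read an end-member CSV with columns source, tracer, mean, sd[, n]."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"source": str, "tracer": str},
                     float_precision="round_trip")
    _require_columns(df, ("source", "tracer", "mean", "sd"), path)
    if df.duplicated(subset=["source", "tracer"]).any():
        raise DuplicationError(f"{path}: duplicate (source, tracer) row")
    sources = []
    for name, grp in df.groupby("source", sort=True):
        tracers = {}
        for _, row in grp.iterrows():
            n = int(row["n"]) if "n" in grp.columns and pd.notna(row.get("n")) else None
            tracers[str(row["tracer"])] = (float(row["mean"]), float(row["sd"]), n)
        sources.append(EndMember(source_name=str(name), tracers=tracers))
    return EndMemberSet(sources=tuple(sources))


def write_endmembers(endmembers: EndMemberSet, path) -> None:
    rows = [
        {"source": s.source_name, "tracer": t, "mean": m, "sd": sd, "n": n}
        for s in endmembers.sources
        for t, (m, sd, n) in sorted(s.tracers.items())
    ]
    pd.DataFrame(rows, columns=list(ENDMEMBER_COLUMNS)).to_csv(
        path, index=False, float_format=lambda x: repr(float(x)))
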