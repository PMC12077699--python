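"""End-to-end orchestration: validate → metrics → hydro → mixing → stats → report.

A run consumes a YAML config (input paths, constants overrides, sampler
settings, seed, output directory) and writes, per stage, stable-name CSV
outputs plus a machine-readable ``manifest.json`` carrying input hashes,
the seed, package version and per-stage status.  Every stochastic stage
derives its stream from the single run seed, so a re-run with the same seed
is byte-identical.

Sediment-trap POC downward flux is accepted as a pass-through per-bay input
(mg/m²/day), not derived from trap geometry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import CsiaaError, UndefinedResultError
from .io import (AminoAcidSample, TrophicConstants, read_aa_table,
                 read_endmembers, read_profile)
from .metrics import CsiaaResult, compute_metrics, results_to_frame
from .hydro import compute_hydro, hydro_to_frames
from .mixing import MixingModel, MixingModelSpec, summarize_contributions
from .stats import anosim, mann_whitney, subseed

logger = logging.getLogger(__name__)

TABLE1_METRICS = ("d15n_phe", "d15n_thr", "tp_metazoan", "tp_protozoan", "sigma_v")


@dataclass
class RunConfig:
    out_dir: str
    seed: int
    aa_table: str | None = None
    ctd: str | None = None
    nutrients: str | None = None
    endmembers: str | None = None
    observations: str | None = None
    constants: TrophicConstants = field(default_factory=TrophicConstants)
    min_aa: int = 3
    n_chains: int = 3
    n_iter: int = 30_000
    n_burn: int = 10_000
    thin: int = 10
    n_permutations: int = 9999
    report_decimals: int = 1
    flux_mg_m2_day: Mapping[str, float] | None = None


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    constants = TrophicConstants(**raw.pop("constants", {}))
    return RunConfig(constants=constants, **raw)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _mean_sd(values: pd.Series, decimals: int) -> tuple[float, float]:
    vals = values.dropna().to_numpy(float)
    mean = float(np.mean(vals))
    sd = 0.0 if vals.size < 2 else float(np.std(vals, ddof=1))
    return round(mean, decimals), round(sd, decimals)


def make_table1(metrics: list[CsiaaResult],
                flux: Mapping[str, float] | None = None,
                decimals: int = 1) -> pd.DataFrame:
    """Per-bay mean ± SD summary of sinking-POM samples.

    One row per bay with δ¹⁵N-Phe, δ¹⁵N-Thr, both trophic positions, ΣV
    (each as mean and sample SD, rounded at report time) and, when
    provided, the pass-through POC downward flux.
    """
    frame = results_to_frame(metrics)
    sinking = frame[frame["matrix"] == "sinking"]
    if sinking.empty:
        raise UndefinedResultError("no sinking-POM samples: Table-1 summary undefined")
    rows = []
    for bay, grp in sinking.groupby("bay", sort=True):
        row: dict[str, object] = {"bay": bay, "n_samples": len(grp)}
        for metric in TABLE1_METRICS:
            mean, sd = _mean_sd(grp[metric], decimals)
            row[f"{metric}_mean"], row[f"{metric}_sd"] = mean, sd
        if flux is not None and bay in flux:
            row["poc_flux_mg_m2_day"] = flux[bay]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_by_bay(metrics: list[CsiaaResult], decimals: int = 1) -> pd.DataFrame:
    """Mean ± SD of the headline metrics per (bay, matrix)."""
    frame = results_to_frame(metrics)
    rows = []
    for (bay, matrix), grp in frame.groupby(["bay", "matrix"], sort=True):
        row: dict[str, object] = {"bay": bay, "matrix": matrix, "n_samples": len(grp)}
        for metric in TABLE1_METRICS:
            mean, sd = _mean_sd(grp[metric], decimals)
            row[f"{metric}_mean"], row[f"{metric}_sd"] = mean, sd
        rows.append(row)
    return pd.DataFrame(rows)


def _stats_stage(samples: list[AminoAcidSample], metrics: list[CsiaaResult],
                 config: RunConfig) -> pd.DataFrame:
    """Between-bay comparisons: rank tests on the metrics, ANOSIM on
    Phe-normalized (Ala, Thr) coordinates."""
    frame = results_to_frame(metrics)
    bays = sorted(frame["bay"].unique())
    rows = []
    counter = 0
    if len(bays) == 2:
        a, b = bays
        for metric in ("tp_metazoan", "tp_protozoan", "sigma_v"):
            x = frame.loc[frame["bay"] == a, metric].dropna()
            y = frame.loc[frame["bay"] == b, metric].dropna()
            if len(x) and len(y):
                u, p = mann_whitney(x, y)
                rows.append({"test": "mann_whitney", "variable": metric,
                             "groups": f"{a} vs {b}", "statistic": u, "p_value": p,
                             "n": len(x) + len(y), "n_permutations": None,
                             "seed": config.seed})
        cols = ["phe_norm_Ala", "phe_norm_Thr"]
        if all(c in frame.columns for c in cols):
            sub = frame.dropna(subset=cols)
            labels = sub["bay"].to_numpy()
            if len(sub) >= 4 and min(np.bincount(pd.factorize(labels)[0])) >= 2:
                res = anosim(sub[cols].to_numpy(), labels,
                             n_permutations=config.n_permutations,
                             seed=int(subseed(config.seed, counter).integers(2**31)))
                rows.append({"test": "anosim", "variable": "phe_norm(Ala,Thr)",
                             "groups": f"{a} vs {b}", "statistic": res.r_statistic,
                             "p_value": res.p_value, "n": len(sub),
                             "n_permutations": res.n_permutations, "seed": config.seed})
                counter += 1
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Any stage error aborts with a stage-tagged message; the manifest then
    records which stages completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    inputs = {k: getattr(config, k) for k in
              ("aa_table", "ctd", "nutrients", "endmembers", "observations")
              if getattr(config, k)}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "stages": status,
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    samples: list[AminoAcidSample] = []
    metrics: list[CsiaaResult] = []
    try:
        stage = "validate"
        if config.aa_table:
            samples = read_aa_table(config.aa_table)
        status[stage] = "ok"

        stage = "metrics"
        if samples:
            metrics = [compute_metrics(s, config.constants, config.min_aa) for s in samples]
            results_to_frame(metrics).to_csv(out / "metrics.csv", index=False)
            status[stage] = "ok"

        stage = "hydro"
        if config.ctd or config.nutrients:
            ctds = {p.station: p for p in read_profile(config.ctd, "ctd")} if config.ctd else {}
            nuts = {p.station: p for p in read_profile(config.nutrients, "nutrient")} \
                if config.nutrients else {}
            results = [compute_hydro(ctds.get(st), nuts.get(st))
                       for st in sorted(set(ctds) | set(nuts))]
            depth_frame, station_frame = hydro_to_frames(results)
            depth_frame.to_csv(out / "hydro_depth.csv", index=False)
            station_frame.to_csv(out / "hydro_station.csv", index=False)
            status[stage] = "ok"

        stage = "mixing"
        if config.endmembers and config.observations:
            endmembers = read_endmembers(config.endmembers)
            obs = pd.read_csv(config.observations)
            spec = MixingModelSpec(
                sources=endmembers, n_chains=config.n_chains, n_iter=config.n_iter,
                n_burn=config.n_burn, thin=config.thin,
                seed=int(subseed(config.seed, 1).integers(2**31)),
            )
            fit = MixingModel(obs, spec=spec).fit()
            summarize_contributions(fit).to_csv(out / "mixing_summary.csv", index=False)
            pd.DataFrame(fit.draws, columns=fit.source_names).to_csv(
                out / "mixing_draws.csv", index=False)
            (out / "mixing_diagnostics.json").write_text(
                json.dumps(fit.diagnostics(), indent=2, sort_keys=True))
            status[stage] = "ok"

        stage = "stats"
        if metrics:
            stats_frame = _stats_stage(samples, metrics, config)
            stats_frame.to_csv(out / "stats.csv", index=False)
            status[stage] = "ok"

        stage = "report"
        if metrics:
            summarize_by_bay(metrics, config.report_decimals).to_csv(
                out / "summary_by_bay.csv", index=False)
            try:
                make_table1(metrics, config.flux_mg_m2_day,
                            config.report_decimals).to_csv(out / "table1.csv", index=False)
            except UndefinedResultError:
                logger.warning("no sinking samples; table1.csv not written")
            status[stage] = "ok"
    except Exception as exc:
        status[stage] = f"error: {exc}"
        _write_manifest()
        raise CsiaaError(f"[{stage}] {exc}") from exc

    _write_manifest()
    logger.info("run complete (seed=%d) → %s", config.seed, out)
    return out
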