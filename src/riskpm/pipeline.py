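"""End-to-end orchestration: summaries -> indices -> deterministic risk ->
Monte Carlo -> CPF, with a run manifest recording every choice made.

The pipeline is a pure function of (inputs, config, seed). Optional stages
(CPF without trajectories, Monte Carlo switched off) are skipped with a
logged warning, never silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as _io
from . import indices as _indices
from . import metals as _metals
from . import pahs as _pahs
from .cpf import GridSpec, assign_endpoints, cpf as compute_cpf
from . import montecarlo as _mc
from . import presets
from . import synthetic as _syn
from .datatypes import ExposureParams
from .summarize import summarize_zone

log = logging.getLogger("riskpm")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def build_manifest(config: dict, seed: int, input_files: dict) -> dict:
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return {
        "config_hash": cfg_hash,
        "seed": seed,
        "inputs": {k: _digest(v) for k, v in input_files.items()},
        "riskpm_version": __version__,
        "timestamp": pd.Timestamp.now().isoformat(),
    }


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every configured stage and write its tables under out_dir.

    config keys (all paths): concentrations (required), params, toxicity,
    trajectories (optional), plus lod (mapping), censor_policy, seed,
    mc: {enabled, n_iterations}, cpf: {grid: {...}, metric, threshold_pct}.
    Returns {stage: output path or DataFrame} and writes manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs = {k: config[k] for k in ("concentrations", "params", "toxicity",
                                     "trajectories") if k in config}
    manifest = build_manifest(config, seed, inputs)

    params = (_io.read_exposure_params(config["params"]) if "params" in config
              else presets.default_exposure_params())
    toxicity = (_io.read_toxicity_table(config["toxicity"])
                if "toxicity" in config else presets.default_toxicity_table())
    meas = _io.read_measurements(config["concentrations"])
    log.info("stage=read_measurements rows_in=%d", len(meas))

    outputs: dict = {"manifest": manifest}

    summaries = summarize_zone(meas, config.get("censor_policy", "half_lod"),
                               config.get("lod"))
    summaries.to_csv(out_dir / "zone_summaries.csv", index=False)
    outputs["zone_summaries"] = summaries
    log.info("stage=summarize groups=%d policy=%s", len(summaries),
             summaries.attrs["censor_policy"])

    metal_rows = summaries[summaries["species"].isin(
        [s for s in summaries["species"].unique()
         if toxicity.optional(s, "TEF") is None])]
    pah_rows = summaries[~summaries.index.isin(metal_rows.index)]

    risk = _metals.metals_risk_table(metal_rows, params, toxicity)
    risk["params_label"] = params.label
    risk.to_csv(out_dir / "metals_risk.csv", index=False)
    his = _metals.zone_hazard_indices(risk)
    his.to_csv(out_dir / "zone_hazard_index.csv", index=False)
    outputs["metals_risk"], outputs["hazard_index"] = risk, his
    log.info("stage=metals_risk rows=%d", len(risk))

    if len(pah_rows):
        teqs, ilcrs = _pahs.zone_pah_risk(pah_rows, params, toxicity)
        teq_df = pd.DataFrame(
            [(t.zone, sp, v, t.contribution_pct[sp] if t.contribution_pct else None)
             for t in teqs for sp, v in t.teq_by_species.items()],
            columns=["zone", "species", "TEQ_ng_m3", "contribution_pct"])
        ilcr_df = pd.DataFrame([(r.zone, r.ilcr, r.risk_class) for r in ilcrs],
                               columns=["zone", "ILCR", "risk_class"])
        teq_df.to_csv(out_dir / "pah_teq.csv", index=False)
        ilcr_df.to_csv(out_dir / "pah_ilcr.csv", index=False)
        outputs["teq"], outputs["ilcr"] = teq_df, ilcr_df
        log.info("stage=pah_risk zones=%d", len(ilcr_df))

    backgrounds = config.get("backgrounds", presets.SOIL_BACKGROUND_MG_KG)
    igeo_rows = _indices.igeo_table(metal_rows, backgrounds)
    pd.DataFrame([asdict(r) for r in igeo_rows]).to_csv(
        out_dir / "igeo.csv", index=False)
    fractions = _indices.composition_fractions(metal_rows)
    fractions.to_csv(out_dir / "composition_fractions.csv", index=False)
    outputs["igeo"], outputs["fractions"] = igeo_rows, fractions
    log.info("stage=indices igeo=%d", len(igeo_rows))

    mc_cfg = config.get("mc", {})
    if mc_cfg.get("enabled", True):
        outputs["mc"] = _mc_stage(summaries, params, toxicity, seed,
                                  int(mc_cfg.get("n_iterations", 10_000)), out_dir)
        log.info("stage=mc outputs=%d", len(outputs["mc"]))

    if "trajectories" in config:
        outputs["cpf"] = _cpf_stage(config, meas, params, toxicity, out_dir)
        log.info("stage=cpf cells=%d", len(outputs["cpf"]))
    else:
        log.warning("stage=cpf skipped: no trajectories configured")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outputs


def _mc_stage(summaries, params, toxicity, seed, n_iter, out_dir):
    """Monte Carlo CR for each zone's dominant carcinogen route.

    Concentration is lognormal (moment-matched to the zone summary), IR
    lognormal, BW truncated normal; ET/EF/ED fixed at the scenario values.
    """
    rows = []
    for r in summaries.itertuples():
        iur = toxicity.optional(r.species, "IUR_per_ug_m3")
        if iur is None or r.mean <= 0:
            continue
        cfg = _mc.McConfig(n_iterations=n_iter, seed=seed, distributions={
            "C_ng_m3": _mc.Dist("lognormal", r.mean, r.stdev, moments=True)
            if r.stdev > 0 else _mc.fixed(r.mean),
            "ET": _mc.fixed(params.ET), "EF": _mc.fixed(params.EF),
            "ED": _mc.fixed(params.ED),
        })
        res = _mc.mc_propagate(
            lambda C_ng_m3, ET, EF, ED:
                (C_ng_m3 / 1000.0) * ET * EF * ED / params.AT_n * iur,
            cfg, name=f"CR[{r.zone}/{r.species}]")
        rows.append((r.zone, r.species, res.mean, res.p05, res.p50, res.p95))
    df = pd.DataFrame(rows, columns=["zone", "species", "mean", "p05", "p50", "p95"])
    df.to_csv(out_dir / "mc_cancer_risk.csv", index=False)
    return df


def _cpf_stage(config, meas, params, toxicity, out_dir):
    cpf_cfg = config.get("cpf", {})
    trajectories = _io.read_trajectories(config["trajectories"])
    gcfg = cpf_cfg.get("grid", {})
    lat0 = gcfg.get("origin_lat",
                    min(p[1] for t in trajectories for p in t.points))
    lon0 = gcfg.get("origin_lon",
                    min(p[2] for t in trajectories for p in t.points))
    grid = GridSpec(origin_lat=lat0, origin_lon=lon0,
                    cell_km=gcfg.get("cell_km", 1.0),
                    n_rows=gcfg.get("n_rows", 32),
                    n_cols=gcfg.get("n_cols", 32))
    metric = cpf_cfg.get("metric", "HI")
    risk = _syn.gen_risk_days(meas, params, toxicity, metric=metric,
                              zone=cpf_cfg.get("zone"))
    assignment = assign_endpoints(trajectories, grid)
    cells = compute_cpf(assignment, risk,
                        percentile_threshold=cpf_cfg.get("threshold_pct", 75.0))
    cells.to_csv(out_dir / "cpf_grid.csv", index=False)
    return cells


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
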