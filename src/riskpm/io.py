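"""Readers and writers for concentration tables, config files and trajectories.

Concentration files are plain CSV with the header
``site_id,zone,date,species,value_ng_m3,censored`` (ISO dates, censored in
{0,1}). Trajectories come either as CSV
(``trajectory_id,direction,timestamp,lat,lon``) or as HYSPLIT-style tdump
endpoint files via :func:`read_tdump`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ALL_SPECIES,
    ExposureParams,
    SchemaError,
    ToxicityRecord,
    ToxicityTable,
    Trajectory,
    ValidationError,
    ZONES,
)

MEASUREMENT_COLUMNS = ("site_id", "zone", "date", "species", "value_ng_m3", "censored")


def read_measurements(path, schema: Optional[Mapping[str, str]] = None,
                      species_registry=ALL_SPECIES) -> pd.DataFrame:
    """Read daily speciated concentrations into a validated DataFrame.

    schema optionally maps canonical column names to file column names.
    Censored (below limit of detection) rows keep whatever value the file
    carries; substitution is the summarizer's job.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement file {path} missing column(s): {missing}")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["censored"] = df["censored"].astype(bool)

    unknown = sorted(set(df["species"]) - set(species_registry))
    if unknown:
        raise ValidationError(f"unknown species in {path}: {unknown}")
    bad_zone = sorted(set(df["zone"]) - set(ZONES))
    if bad_zone:
        raise ValidationError(f"unknown zone(s) in {path}: {bad_zone}")

    uncensored = df.loc[~df["censored"], "value_ng_m3"]
    neg = uncensored.index[uncensored < 0]
    if len(neg):
        raise ValidationError(
            f"negative concentration at row(s) {list(neg[:5])} in {path}"
        )
    dup = df.duplicated(subset=["site_id", "date", "species"])
    if dup.any():
        raise ValidationError(
            f"duplicate (site_id, date, species) at row(s) {list(df.index[dup][:5])}"
        )
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["censored"] = out["censored"].astype(int)
    out.loc[:, list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)


def _load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_exposure_params(path) -> ExposureParams:
    """Read an exposure scenario from YAML/JSON with unit-bearing keys."""
    cfg = _load_config(path)
    kwargs = {k: cfg[k] for k in ("ET", "EF", "ED", "AT_n", "AT", "IR", "BW", "CF")
              if k in cfg}
    if "label" in cfg:
        kwargs["label"] = cfg["label"]
    return ExposureParams(**kwargs)


def read_toxicity_table(path) -> ToxicityTable:
    """Read per-species toxicity values from YAML/JSON.

    Expected layout: ``{species: {RfC_mg_m3: ..., IUR_per_ug_m3: ...,
    SF_per_mg_kg_day: ..., TEF: ..., background_mg_kg: ...}}`` with any
    subset of the fields present.
    """
    cfg = _load_config(path)
    records = []
    for sp, fields in cfg.items():
        fields = fields or {}
        unknown = set(fields) - {"RfC_mg_m3", "IUR_per_ug_m3",
                                 "SF_per_mg_kg_day", "TEF", "background_mg_kg"}
        if unknown:
            raise SchemaError(f"toxicity entry {sp!r}: unknown key(s) {sorted(unknown)}")
        records.append(ToxicityRecord(species=sp, **fields))
    return ToxicityTable(records)


def read_trajectories(path) -> list[Trajectory]:
    """Read trajectories from the package CSV dialect.

    The per-trajectory endpoint interval is inferred from timestamps and
    must be constant within a trajectory.
    """
    df = pd.read_csv(path)
    required = ("trajectory_id", "direction", "timestamp", "lat", "lon")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory file {path} missing column(s): {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    out = []
    for tid, grp in df.groupby("trajectory_id", sort=False):
        grp = grp.sort_values("timestamp")
        times = grp["timestamp"].to_list()
        if len(times) != len(set(times)):
            raise ValidationError(f"trajectory {tid}: repeated timestamps")
        deltas = np.diff([t.value for t in times]) / 3.6e12  # ns -> h
        if np.any(deltas <= 0):
            raise ValidationError(f"trajectory {tid}: non-monotone timestamps")
        if not np.allclose(deltas, deltas[0], rtol=1e-6):
            raise ValidationError(f"trajectory {tid}: endpoint interval not constant")
        direction = grp["direction"].iloc[0]
        points = list(zip(times, grp["lat"].astype(float), grp["lon"].astype(float)))
        out.append(Trajectory(trajectory_id=str(tid), direction=direction,
                              points=points, interval_h=float(deltas[0])))
    return out


def write_trajectories(trajectories, path) -> None:
    rows = []
    for t in trajectories:
        for (ts, lat, lon) in t.points:
            rows.append((t.trajectory_id, t.direction,
                         pd.Timestamp(ts).strftime("%Y-%m-%d %H:%M:%S"), lat, lon))
    pd.DataFrame(rows, columns=["trajectory_id", "direction", "timestamp",
                                "lat", "lon"]).to_csv(path, index=False)


def read_tdump(path, direction: str = "backward") -> list[Trajectory]:
    """Shim for HYSPLIT tdump endpoint files.

    Only the endpoint records are parsed: trajectory number, year, month,
    day, hour, and latitude/longitude (columns 1, 3-6, 10-11 of the
    endpoint section). Header blocks are skipped by field-count.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 12:
            continue
        try:
            tnum = int(parts[0])
            yy, mm, dd, hh = (int(parts[i]) for i in range(2, 6))
            lat, lon = float(parts[9]), float(parts[10])
        except ValueError:
            continue
        year = 2000 + yy if yy < 70 else 1900 + yy
        rows.append((tnum, pd.Timestamp(year, mm, dd, hh), lat, lon))
    if not rows:
        raise SchemaError(f"no endpoint records found in {path}")
    df = pd.DataFrame(rows, columns=["trajectory_id", "timestamp", "lat", "lon"])
    out = []
    for tid, grp in df.groupby("trajectory_id"):
        grp = grp.sort_values("timestamp")
        times = grp["timestamp"].to_list()
        deltas = np.diff([t.value for t in times]) / 3.6e12
        interval = float(deltas[0]) if len(deltas) else 1.0
        points = list(zip(times, grp["lat"], grp["lon"]))
        out.append(Trajectory(trajectory_id=f"tdump-{tid}", direction=direction,
                              points=points, interval_h=interval))
    return out
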