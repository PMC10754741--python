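"""Synthetic campaign generator.

Emulates the statistical structure the analysis assumes: right-skewed
daily species concentrations (lognormal, moment-matched so the arithmetic
mean and sd hit the per-zone targets), below-detection censoring, and
air-mass trajectory bundles biased toward a prevailing wind direction
(correlated random walks). Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExposureParams, RiskSeries, ToxicityTable, Trajectory, \
    ValidationError
from . import metals as _metals
from . import pahs as _pahs


@dataclass(frozen=True)
class TrajectorySpec:
    """Bundle geometry: bearings are degrees clockwise from north (90 = east).

    prevailing_deg is the direction air comes FROM; backward trajectories
    extend from the receptor toward that direction, forward ones the
    opposite way. Default: easterly regime, 12-h endpoint interval.
    """

    prevailing_deg: float = 90.0
    spread_deg: float = 15.0
    speed_km_h: float = 2.0
    n_points: int = 13
    interval_h: float = 12.0
    receptor_lat: float = 11.1
    receptor_lon: float = -72.6

    def __post_init__(self) -> None:
        if self.spread_deg < 0:
            raise ValidationError("angular spread must be >= 0")
        if self.interval_h <= 0 or self.speed_km_h < 0 or self.n_points < 2:
            raise ValidationError("invalid trajectory spec")


@dataclass(frozen=True)
class GeneratorSpec:
    """Targets for one synthetic campaign.

    targets: (zone, species) -> (mean, sd) in ng/m3; lod: species -> limit
    of detection in ng/m3 (draws below it are flagged censored).
    """

    targets: Mapping[tuple, tuple]
    lod: Mapping[str, float] = field(default_factory=dict)
    n_days: int = 79
    start_date: str = "2022-02-01"
    seed: int = 0
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        for (zone, sp), (mean, sd) in self.targets.items():
            if mean < 0 or sd < 0:
                raise ValidationError(f"({zone},{sp}): mean and sd must be >= 0")
            if mean == 0 and sd > 0:
                raise ValidationError(f"({zone},{sp}): mean 0 with sd > 0")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched log-scale (mu, sigma) for a target arithmetic mean/sd."""
    if mean <= 0:
        raise ValidationError("moment matching needs mean > 0")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


def gen_concentrations(spec: GeneratorSpec,
                       correlation: float = 0.0) -> pd.DataFrame:
    """Daily speciated concentrations per (zone, species) target.

    Species are independent by default; correlation > 0 couples all
    species within a zone through a Gaussian copula on the log scale
    (equicorrelated), which is what the correlation-matrix analysis needs
    to see a signal. One synthetic site per zone.
    """
    if not (0 <= correlation < 1):
        raise ValidationError("correlation must be in [0, 1)")
    ss = np.random.SeedSequence(spec.seed)
    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    zones = sorted({z for z, _ in spec.targets})
    rows = []
    zone_streams = {z: np.random.default_rng(c)
                    for z, c in zip(zones, ss.spawn(len(zones)))}
    for zone in zones:
        rng = zone_streams[zone]
        species = sorted(sp for z, sp in spec.targets if z == zone)
        nsp = len(species)
        if correlation > 0 and nsp > 1:
            cov = np.full((nsp, nsp), correlation)
            np.fill_diagonal(cov, 1.0)
            z_mat = rng.multivariate_normal(np.zeros(nsp), cov,
                                            size=spec.n_days,
                                            method="cholesky")
        else:
            z_mat = rng.standard_normal((spec.n_days, nsp))
        for k, sp in enumerate(species):
            mean, sd = spec.targets[(zone, sp)]
            if mean == 0:
                values = np.zeros(spec.n_days)
            elif sd == 0:
                values = np.full(spec.n_days, mean)
            else:
                mu, sigma = lognormal_params(mean, sd)
                values = np.exp(mu + sigma * z_mat[:, k])
            lod = spec.lod.get(sp, 0.0)
            for d, v in zip(dates, values):
                rows.append((f"SYN_{zone[:2].upper()}_01", zone, d, sp,
                             float(v), bool(v < lod)))
    return pd.DataFrame(rows, columns=["site_id", "zone", "date", "species",
                                       "value_ng_m3", "censored"])


def _step_latlon(lat: float, lon: float, bearing_deg: float,
                 dist_km: float) -> tuple[float, float]:
    b = np.deg2rad(bearing_deg)
    dlat = dist_km * np.cos(b) / 110.574
    dlon = dist_km * np.sin(b) / (111.320 * np.cos(np.deg2rad(lat)))
    return lat + dlat, lon + dlon


def gen_trajectories(spec: GeneratorSpec,
                     directions: Sequence[str] = ("backward", "forward")
                     ) -> list[Trajectory]:
    """One trajectory per day and direction, as a correlated random walk.

    Each step's bearing is the prevailing direction plus Gaussian jitter
    (the angular spread); backward tracks head toward where the air came
    from, forward tracks the opposite way. Timestamps are time-ordered
    from the day's start in both cases.
    """
    ss = np.random.SeedSequence((spec.seed, 7))
    rng = np.random.default_rng(ss)
    tspec = spec.trajectory
    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    step_km = tspec.speed_km_h * tspec.interval_h
    out = []
    for day in dates:
        for direction in directions:
            base = tspec.prevailing_deg if direction == "backward" \
                else (tspec.prevailing_deg + 180.0) % 360.0
            lat, lon = tspec.receptor_lat, tspec.receptor_lon
            points = [(day, lat, lon)]
            for s in range(1, tspec.n_points):
                bearing = base + rng.normal(0.0, tspec.spread_deg)
                lat, lon = _step_latlon(lat, lon, bearing, step_km)
                points.append((day + pd.Timedelta(hours=s * tspec.interval_h),
                               lat, lon))
            out.append(Trajectory(
                trajectory_id=f"{direction[0]}{day.strftime('%Y%m%d')}",
                direction=direction, points=points,
                interval_h=tspec.interval_h))
    return out


def gen_risk_days(measurements: pd.DataFrame, params: ExposureParams,
                  toxicity: ToxicityTable, metric: str = "HI",
                  zone: Optional[str] = None) -> RiskSeries:
    """Daily receptor risk series (HI, CR or ILCR) from daily concentrations.

    CR is summed over the species that have an IUR; HI over those with an
    RfC; ILCR uses the BaP-equivalent burden of the PAHs present that day.
    """
    if metric not in ("HI", "CR", "ILCR"):
        raise ValidationError(f"metric must be HI|CR|ILCR, got {metric!r}")
    df = measurements if zone is None else measurements[measurements["zone"] == zone]
    values = {}
    for day, grp in df.groupby(df["date"].map(pd.Timestamp).map(
            lambda t: t.normalize())):
        conc = dict(zip(grp["species"], grp["value_ng_m3"]))
        if metric == "ILCR":
            pah_conc = {sp: c for sp, c in conc.items()
                        if toxicity.optional(sp, "TEF") is not None}
            t = _pahs.teq(pah_conc, toxicity)
            sf = toxicity.require("BaP", "SF_per_mg_kg_day")
            values[day] = _pahs.ilcr(t.teq_total, params, sf).ilcr
            continue
        total = 0.0
        for sp, c in conc.items():
            ec = _metals.exposure_concentration(c / 1000.0, params)
            if metric == "HI":
                rfc = toxicity.optional(sp, "RfC_mg_m3")
                if rfc is not None:
                    total += _metals.hazard_quotient(ec, rfc, params.CF)
            else:  # CR
                iur = toxicity.optional(sp, "IUR_per_ug_m3")
                if iur is not None:
                    total += _metals.cancer_risk(ec, iur)[0]
        values[day] = total
    return RiskSeries(metric=metric, values=values)


def plant_episodes(measurements: pd.DataFrame, episode_days: Sequence,
                   factor: float = 5.0) -> pd.DataFrame:
    """Scale all concentrations on the given days by a factor.

    Used to plant known high-risk episodes so threshold selection can be
    checked against ground truth.
    """
    out = measurements.copy()
    days = {pd.Timestamp(d).normalize() for d in episode_days}
    mask = out["date"].map(lambda t: pd.Timestamp(t).normalize() in days)
    out.loc[mask, "value_ng_m3"] *= factor
    return out
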