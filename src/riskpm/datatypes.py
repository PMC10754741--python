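"""Domain types and unit conventions.

Concentrations are stored in ng/m3 everywhere; conversions to ug/m3 or mg
happen only inside the risk equations, never in storage. Zones follow the
three-receptor layout of an opencast-mine monitoring campaign (North, South
and Populated zones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

ZONES = ("North", "South", "Populated")

#: PM10-bound heavy metals tracked by the package. Cr(VI) is a derived
#: species (one seventh of total Cr) but participates in every downstream
#: operation like a measured one.
METAL_SPECIES = ("Al", "Cr", "Cr(VI)", "Mn", "Cu", "Zn", "As", "Pb")

#: 13 US-EPA priority PAHs plus triphenylene.
PAH_SPECIES = (
    "Nap", "Acy", "Ace", "Flu", "Phe", "Ant", "FR", "Pyr",
    "BaA", "Tri", "IDP", "BbF", "BaP", "BkF",
)

ALL_SPECIES = METAL_SPECIES + PAH_SPECIES


class RiskpmError(Exception):
    """Base class for package errors."""


class SchemaError(RiskpmError):
    """A required column or field is missing."""


class ValidationError(RiskpmError):
    """A value violates a domain invariant."""


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class ExposureParams:
    """Inhalation exposure scenario.

    Parameters
    ----------
    ET : float
        Exposure time, hours per day.
    EF : float
        Exposure frequency, days per year.
    ED : float
        Exposure duration, years.
    AT_n : float
        Averaging time for non-lifetime metrics, hours.
    AT : float
        Averaging lifetime, days (ILCR denominator).
    IR : float
        Inhalation rate, m3 per day.
    BW : float
        Body weight, kg.
    CF : float
        Conversion factor, ug per mg (default 1000).
    """

    ET: float = 24.0
    EF: float = 350.0
    ED: float = 30.0
    AT_n: float = 70.0 * 365.0 * 24.0
    AT: float = 70.0 * 365.0
    IR: float = 20.0
    BW: float = 70.0
    CF: float = 1000.0
    label: str = "EPA residential adult"

    def __post_init__(self) -> None:
        for name in ("ET", "EF", "ED", "AT_n", "AT", "IR", "BW", "CF"):
            _require_positive(name, getattr(self, name))
        if self.EF > 366:
            raise ValidationError(f"EF must be <= 366 days/year, got {self.EF}")
        if self.ET > 24:
            raise ValidationError(f"ET must be <= 24 h/day, got {self.ET}")
        if self.ET * self.EF * self.ED > self.AT_n * (1 + 1e-12):
            raise ValidationError(
                "ET*EF*ED exceeds AT_n: exposure hours cannot exceed averaging hours"
            )

    def exposure_fraction(self) -> float:
        """ET*EF*ED / AT_n — the fraction of lifetime hours spent exposed."""
        return self.ET * self.EF * self.ED / self.AT_n


@dataclass(frozen=True)
class ToxicityRecord:
    """Per-species toxicity and reference values (nullable fields).

    Units are carried in the names: RfC in mg/m3, IUR per ug/m3, SF per
    (mg/kg/day), TEF dimensionless, soil background in mg/kg.
    """

    species: str
    RfC_mg_m3: Optional[float] = None
    IUR_per_ug_m3: Optional[float] = None
    SF_per_mg_kg_day: Optional[float] = None
    TEF: Optional[float] = None
    background_mg_kg: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("RfC_mg_m3", "IUR_per_ug_m3", "SF_per_mg_kg_day",
                     "TEF", "background_mg_kg"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{name} for {self.species} must be >= 0, got {v!r}"
                )


class ToxicityTable:
    """Mapping species -> :class:`ToxicityRecord` with required-field access."""

    def __init__(self, records: Sequence[ToxicityRecord] | Mapping[str, ToxicityRecord]):
        if isinstance(records, Mapping):
            self._records = dict(records)
        else:
            self._records = {r.species: r for r in records}

    def __contains__(self, species: str) -> bool:
        return species in self._records

    def __getitem__(self, species: str) -> ToxicityRecord:
        try:
            return self._records[species]
        except KeyError:
            raise KeyError(f"no toxicity record for species {species!r}") from None

    def get(self, species: str) -> Optional[ToxicityRecord]:
        return self._records.get(species)

    def species(self) -> list[str]:
        return list(self._records)

    def require(self, species: str, fieldname: str) -> float:
        """Return a field that must be present, else raise ValidationError."""
        rec = self.get(species)
        value = getattr(rec, fieldname) if rec is not None else None
        if value is None:
            raise ValidationError(
                f"species {species!r} has no {fieldname}, required by this operation"
            )
        return value

    def optional(self, species: str, fieldname: str) -> Optional[float]:
        rec = self.get(species)
        return getattr(rec, fieldname) if rec is not None else None


@dataclass(frozen=True)
class ZoneSummary:
    """Per-zone, per-species summary statistics in ng/m3."""

    zone: str
    species: str
    mean: float
    stdev: float
    vmax: Optional[float] = None
    vmin: Optional[float] = None
    n_days: int = 1

    def __post_init__(self) -> None:
        if self.stdev < 0:
            raise ValidationError(f"stdev must be >= 0, got {self.stdev}")
        if self.n_days < 1:
            raise ValidationError(f"n_days must be >= 1, got {self.n_days}")
        if self.vmin is not None and self.vmax is not None:
            if not (self.vmin <= self.mean <= self.vmax):
                raise ValidationError(
                    f"{self.zone}/{self.species}: min <= mean <= max violated "
                    f"({self.vmin}, {self.mean}, {self.vmax})"
                )


@dataclass
class Trajectory:
    """A forward or backward air-mass trajectory.

    points are time-ordered (timestamp, lat, lon) tuples at a constant
    interval (hours); timestamps are pandas-parseable.
    """

    trajectory_id: str
    direction: str  # "forward" | "backward"
    points: list  # [(Timestamp, lat, lon), ...]
    interval_h: float

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValidationError(
                f"direction must be forward|backward, got {self.direction!r}"
            )
        if len(self.points) < 2:
            raise ValidationError("a trajectory needs at least 2 points")
        if self.interval_h <= 0:
            raise ValidationError("interval must be > 0 hours")
        times = [p[0] for p in self.points]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"trajectory {self.trajectory_id}: timestamps not strictly increasing"
            )

    @property
    def start_time(self):
        return self.points[0][0]

    def latlon(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return np.array([[p[1], p[2]] for p in self.points], dtype=float)


@dataclass
class RiskSeries:
    """Daily risk-metric series at a receptor, with a high-risk cutoff.

    values maps day (date-like, normalized to pandas Timestamp date) to the
    metric (HI, CR or ILCR). threshold is set by the CPF step.
    """

    metric: str
    values: "Mapping"
    threshold: Optional[float] = None

    def days(self):
        return list(self.values.keys())
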