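"""Deterministic inhalation risk for PM10-bound heavy metals.

The chain is: exposure concentration EC = C*ET*EF*ED/AT_n (C in ug/m3),
hazard quotient HQ = EC/(RfC*CF), hazard index HI = sum of HQs, and
lifetime excess cancer risk CR = EC*IUR. Concentrations arrive in ng/m3
(storage convention) and are converted to ug/m3 here, nowhere else.

Cancer-risk classes follow the conventional screening thresholds:
CR < 1e-6 negligible, 1e-6..1e-4 acceptable (boundaries inclusive),
CR > 1e-4 likely harmful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .datatypes import ExposureParams, ToxicityTable, ValidationError

CR_NEGLIGIBLE = 1e-6
CR_HARMFUL = 1e-4

RISK_CLASSES = ("negligible", "acceptable", "likely_harmful")


def chromium_vi(c_total_cr: float) -> float:
    """Hexavalent-chromium concentration as one seventh of total Cr (ng/m3)."""
    if c_total_cr < 0:
        raise ValidationError(f"total Cr concentration must be >= 0, got {c_total_cr}")
    return c_total_cr / 7.0


def exposure_concentration(c_ug_m3: float, p: ExposureParams) -> float:
    """Time-weighted exposure concentration EC (ug/m3).

    EC = C*ET*EF*ED/AT_n; never exceeds C because exposure hours cannot
    exceed averaging hours.
    """
    if c_ug_m3 < 0:
        raise ValidationError(f"concentration must be >= 0, got {c_ug_m3}")
    return c_ug_m3 * p.exposure_fraction()


def hazard_quotient(ec_ug_m3: float, rfc_mg_m3: float, cf: float = 1000.0) -> float:
    """HQ = EC / (RfC * CF); HQ > 1 flags potential non-cancer risk."""
    if rfc_mg_m3 <= 0:
        raise ValidationError(f"RfC must be > 0, got {rfc_mg_m3}")
    if cf <= 0:
        raise ValidationError(f"CF must be > 0, got {cf}")
    return ec_ug_m3 / (rfc_mg_m3 * cf)


def hazard_index(hqs: Mapping[str, Optional[float]]) -> "HazardIndex":
    """Sum the non-null per-species HQs into a hazard index."""
    valid = {sp: hq for sp, hq in hqs.items() if hq is not None}
    if not valid:
        raise ValidationError("hazard_index needs at least one non-null HQ")
    hi = sum(valid.values())
    shares = {sp: (hq / hi if hi > 0 else 0.0) for sp, hq in valid.items()}
    return HazardIndex(HI=hi, contributions=shares)


@dataclass(frozen=True)
class HazardIndex:
    HI: float
    contributions: Mapping[str, float]

    @property
    def flagged(self) -> bool:
        """True when HI > 1: non-cancer effects from the mixture possible."""
        return self.HI > 1.0


def classify_cr(cr: float) -> str:
    if cr < CR_NEGLIGIBLE:
        return "negligible"
    if cr <= CR_HARMFUL:
        return "acceptable"
    return "likely_harmful"


def cancer_risk(ec_ug_m3: float, iur_per_ug_m3: float) -> tuple[float, str]:
    """CR = EC * IUR with its screening class."""
    if iur_per_ug_m3 < 0:
        raise ValidationError(f"IUR must be >= 0, got {iur_per_ug_m3}")
    cr = ec_ug_m3 * iur_per_ug_m3
    return cr, classify_cr(cr)


def metals_risk_table(zone_means_ng_m3: pd.DataFrame, params: ExposureParams,
                      toxicity: ToxicityTable) -> pd.DataFrame:
    """Full deterministic risk table from zone-mean concentrations.

    zone_means_ng_m3: tidy frame with columns zone, species, mean (ng/m3).
    Species without an RfC get a null HQ (with a warning), species without
    an IUR get a null CR; neither is silently zeroed.
    Returns columns zone, species, C_ng_m3, EC_ug_m3, HQ, CR, risk_class.
    """
    rows = []
    for r in zone_means_ng_m3.itertuples():
        c_ug = r.mean / 1000.0
        ec = exposure_concentration(c_ug, params)
        rfc = toxicity.optional(r.species, "RfC_mg_m3")
        if rfc is None:
            warnings.warn(f"no RfC for {r.species}; HQ reported as null",
                          stacklevel=2)
            hq = None
        else:
            hq = hazard_quotient(ec, rfc, params.CF)
        iur = toxicity.optional(r.species, "IUR_per_ug_m3")
        if iur is None:
            cr, cls = None, None
        else:
            cr, cls = cancer_risk(ec, iur)
        rows.append((r.zone, r.species, r.mean, ec, hq, cr, cls))
    return pd.DataFrame(rows, columns=["zone", "species", "C_ng_m3", "EC_ug_m3",
                                       "HQ", "CR", "risk_class"])


def zone_hazard_indices(risk_table: pd.DataFrame) -> pd.DataFrame:
    """Per-zone HI from a metals risk table (null HQs excluded)."""
    rows = []
    for zone, grp in risk_table.groupby("zone"):
        hqs = {r.species: r.HQ for r in grp.itertuples() if pd.notna(r.HQ)}
        hi = hazard_index(hqs)
        rows.append((zone, hi.HI, hi.flagged))
    return pd.DataFrame(rows, columns=["zone", "HI", "flagged"])
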