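"""BaP-equivalent toxicity (TEQ) and incremental lifetime cancer risk for
PM10-bound PAHs.

TEQ_total = sum(C_i * TEF_i) on the ng/m3 scale;
ILCR = TEQ_total * SF * IR * EF * ED * 1e-6 / (BW * AT), the 1e-6 factor
converting ng to mg so the slope factor's (mg/kg/day)^-1 units close.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .datatypes import ExposureParams, ToxicityTable, ValidationError

ILCR_ACCEPTABLE = 1e-6
ILCR_HIGH = 1e-4


@dataclass(frozen=True)
class TeqResult:
    zone: Optional[str]
    teq_by_species: Mapping[str, float]      # ng/m3
    teq_total: float                         # ng/m3
    contribution_pct: Optional[Mapping[str, float]]  # None when total is 0


@dataclass(frozen=True)
class IlcrResult:
    zone: Optional[str]
    ilcr: float
    risk_class: str  # acceptable | elevated | high


def teq(concentrations_ng_m3: Mapping[str, float], tefs: ToxicityTable,
        zone: Optional[str] = None) -> TeqResult:
    """BaP-equivalent concentration per congener and in total.

    Every congener present must have a TEF; a missing TEF is an error
    naming the species (silently dropping a congener would bias the total
    low).
    """
    missing = [sp for sp in concentrations_ng_m3
               if tefs.optional(sp, "TEF") is None]
    if missing:
        raise ValidationError(f"no TEF for species: {sorted(missing)}")
    per = {}
    for sp, c in concentrations_ng_m3.items():
        if c < 0:
            raise ValidationError(f"negative concentration for {sp}: {c}")
        per[sp] = c * tefs.require(sp, "TEF")
    total = sum(per.values())
    if total > 0:
        pct = {sp: 100.0 * v / total for sp, v in per.items()}
    else:
        pct = None
    return TeqResult(zone=zone, teq_by_species=per, teq_total=total,
                     contribution_pct=pct)


def classify_ilcr(ilcr: float) -> str:
    if ilcr < ILCR_ACCEPTABLE:
        return "acceptable"
    if ilcr <= ILCR_HIGH:
        return "elevated"
    return "high"


def ilcr(teq_total_ng_m3: float, p: ExposureParams, sf_per_mg_kg_day: float,
         zone: Optional[str] = None) -> IlcrResult:
    """Incremental lifetime cancer risk from the BaP-equivalent burden."""
    if p.BW <= 0 or p.AT <= 0:
        raise ValidationError("BW and AT must be strictly positive")
    if teq_total_ng_m3 < 0:
        raise ValidationError(f"TEQ must be >= 0, got {teq_total_ng_m3}")
    if sf_per_mg_kg_day < 0:
        raise ValidationError(f"SF must be >= 0, got {sf_per_mg_kg_day}")
    value = (teq_total_ng_m3 * sf_per_mg_kg_day * p.IR * p.EF * p.ED * 1e-6
             / (p.BW * p.AT))
    return IlcrResult(zone=zone, ilcr=value, risk_class=classify_ilcr(value))


def zone_pah_risk(zone_means_ng_m3, params: ExposureParams,
                  toxicity: ToxicityTable) -> tuple[list[TeqResult], list[IlcrResult]]:
    """TEQ and ILCR per zone from a tidy (zone, species, mean) frame.

    The BaP slope factor from the toxicity table drives the ILCR (additive
    BaP-equivalency: all congeners are expressed on the BaP potency scale
    first).
    """
    sf = toxicity.require("BaP", "SF_per_mg_kg_day")
    teqs, ilcrs = [], []
    for zone, grp in zone_means_ng_m3.groupby("zone"):
        conc = dict(zip(grp["species"], grp["mean"]))
        t = teq(conc, toxicity, zone=zone)
        teqs.append(t)
        ilcrs.append(ilcr(t.teq_total, params, sf, zone=zone))
    return teqs, ilcrs
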