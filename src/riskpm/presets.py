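"""Packaged parameter presets and campaign zone-summary fixtures.

Every preset here is a starting point, not a constant of nature: toxicity
reference values are compiled from US-EPA IRIS, OEHHA and provisional
sources, soil backgrounds from Colombian soil surveys, and all of them are
meant to be overridden from user config files for any serious assessment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import ToxicityRecord, ToxicityTable, ZoneSummary, ExposureParams

#: Nisbet & LaGoy BaP-equivalency factors. Triphenylene is not a priority
#: PAH and has no canonical TEF; the chrysene-class value 0.01 is used.
TEF_NISBET_LAGOY = {
    "Nap": 0.001, "Acy": 0.001, "Ace": 0.001, "Flu": 0.001,
    "Phe": 0.001, "Ant": 0.01, "FR": 0.001, "Pyr": 0.001,
    "BaA": 0.1, "Tri": 0.01, "IDP": 0.1, "BbF": 0.1,
    "BaP": 1.0, "BkF": 0.1,
}

#: Inhalation unit risks, per ug/m3. IRIS values for Cr(VI) and As; OEHHA
#: for Pb. Al, Mn, Cu and Zn have no published IUR and stay None, so their
#: cancer risk is reported as null and excluded from totals.
IUR_PER_UG_M3 = {
    "Cr(VI)": 1.2e-2,
    "As": 4.3e-3,
    "Pb": 1.2e-5,
}

#: Chronic inhalation reference concentrations, mg/m3. IRIS: Cr(VI)
#: (particulates), Mn; OEHHA chronic REL: As. Al, Cu, Zn and Pb carry
#: provisional values commonly used in PM risk screening and should be
#: replaced when a jurisdictional value exists.
RFC_MG_M3 = {
    "Al": 5.0e-3,
    "Cr(VI)": 1.0e-4,
    "Mn": 5.0e-5,
    "Cu": 2.0e-2,
    "Zn": 3.0e-1,
    "As": 1.5e-5,
    "Pb": 1.5e-4,
}

#: Soil background concentrations, mg/kg, from Colombian soil studies
#: (Sinu valley / Caribbean region surveys). No regional Al background is
#: available, so Al Igeo is reported as null.
SOIL_BACKGROUND_MG_KG = {
    "Cr(VI)": 33.0,
    "Mn": 600.0,
    "Cu": 25.0,
    "Zn": 65.0,
    "As": 15.0,
    "Pb": 10.5,
}

#: BaP inhalation cancer slope factor, per (mg/kg/day) (OEHHA).
SF_BAP_PER_MG_KG_DAY = 3.14


def default_exposure_params() -> ExposureParams:
    """EPA residential-adult scenario: ET=24 h/d, EF=350 d/y, ED=30 y,
    AT_n=70 y in hours, AT=70 y in days, IR=20 m3/d, BW=70 kg, CF=1000."""
    return ExposureParams()


def default_toxicity_table() -> ToxicityTable:
    """Merge the packaged RfC/IUR/TEF/SF/background presets into one table."""
    species = set(RFC_MG_M3) | set(IUR_PER_UG_M3) | set(TEF_NISBET_LAGOY) | set(
        SOIL_BACKGROUND_MG_KG)
    records = []
    for sp in sorted(species):
        records.append(ToxicityRecord(
            species=sp,
            RfC_mg_m3=RFC_MG_M3.get(sp),
            IUR_per_ug_m3=IUR_PER_UG_M3.get(sp),
            SF_per_mg_kg_day=SF_BAP_PER_MG_KG_DAY if sp == "BaP" else None,
            TEF=TEF_NISBET_LAGOY.get(sp),
            background_mg_kg=SOIL_BACKGROUND_MG_KG.get(sp),
        ))
    return ToxicityTable(records)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("riskpm.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def campaign_zone_summaries(kind: str = "metals") -> list[ZoneSummary]:
    """Zone-level mean/sd summaries from the 2022 monitoring campaign.

    kind is "metals" (7 heavy metals, Cr reported as Cr(VI)) or "pahs"
    (14 congeners). These are the published per-zone statistics; daily
    records are not deposited, so max/min are not carried.
    """
    if kind not in ("metals", "pahs"):
        raise ValueError(f"kind must be 'metals' or 'pahs', got {kind!r}")
    df = _load_packaged(f"zone_summaries_{kind}.csv")
    return [
        ZoneSummary(zone=r.zone, species=r.species, mean=r.mean_ng_m3,
                    stdev=r.sd_ng_m3, n_days=int(r.n_days))
        for r in df.itertuples()
    ]


def campaign_zone_table(kind: str = "metals") -> pd.DataFrame:
    """Tidy frame of campaign summaries: zone, species, mean, stdev, n_days."""
    df = _load_packaged(f"zone_summaries_{kind}.csv")
    return df.rename(columns={"mean_ng_m3": "mean", "sd_ng_m3": "stdev"})


def campaign_zone_means(kind: str = "metals") -> pd.DataFrame:
    """Wide frame of campaign means (rows=species, columns=zones), ng/m3."""
    df = _load_packaged(f"zone_summaries_{kind}.csv")
    return df.pivot(index="species", columns="zone", values="mean_ng_m3")


#: US-EPA ambient limit for airborne Cr(VI), ng/m3.
CRVI_AIR_LIMIT_NG_M3 = 12.0
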