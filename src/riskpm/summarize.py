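"""Zone-level summarization of daily speciated concentrations.

Censored (below limit of detection) values are substituted before any
statistic is computed. The default policy replaces them with LOD/2, the
most common convention for lightly censored environmental series; "zero"
and "omit" are available, and the policy used is echoed in the output so
tables are self-describing. Standard deviations are the sample (n-1)
estimator throughout.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .datatypes import ValidationError, ZoneSummary

CENSOR_POLICIES = ("half_lod", "zero", "omit")


def apply_censor_policy(df: pd.DataFrame, policy: str = "half_lod",
                        lod: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Return a copy with censored values substituted per policy.

    policy "half_lod" requires a per-species LOD mapping (ng/m3); "zero"
    sets censored values to 0; "omit" drops censored rows.
    """
    if policy not in CENSOR_POLICIES:
        raise ValidationError(f"unknown censor policy {policy!r}; "
                              f"choose one of {CENSOR_POLICIES}")
    out = df.copy()
    mask = out["censored"].astype(bool)
    if policy == "omit":
        return out.loc[~mask].reset_index(drop=True)
    if policy == "zero":
        out.loc[mask, "value_ng_m3"] = 0.0
        return out
    lod = lod or {}
    censored_species = sorted(set(out.loc[mask, "species"]))
    missing = [sp for sp in censored_species if sp not in lod]
    if missing:
        raise ValidationError(
            f"censor policy 'half_lod' needs an LOD for species {missing}"
        )
    out.loc[mask, "value_ng_m3"] = [lod[sp] / 2.0 for sp in out.loc[mask, "species"]]
    return out


def summarize_zone(measurements: pd.DataFrame, censor_policy: str = "half_lod",
                   lod: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Per-(zone, species) mean, sample stdev, max, min and day count.

    Returns a tidy frame with columns zone, species, mean, stdev, max, min,
    n_days and a ``censor_policy`` attribute recording the substitution
    applied. Raises if a (zone, species) group loses all its data to the
    "omit" policy.
    """
    n_groups_before = measurements.groupby(["zone", "species"]).ngroups
    sub = apply_censor_policy(measurements, censor_policy, lod)
    grouped = sub.groupby(["zone", "species"])["value_ng_m3"]
    out = grouped.agg(mean="mean", stdev="std", max="max", min="min",
                      n_days="count").reset_index()
    out["stdev"] = out["stdev"].fillna(0.0)  # n=1 groups
    if censor_policy == "omit" and out.shape[0] < n_groups_before:
        before = set(map(tuple, measurements[["zone", "species"]].drop_duplicates()
                         .itertuples(index=False)))
        after = set(map(tuple, out[["zone", "species"]].itertuples(index=False)))
        raise ValidationError(
            f"all values censored for {sorted(before - after)} under policy 'omit'"
        )
    out.attrs["censor_policy"] = censor_policy
    return out


def summaries_to_records(df: pd.DataFrame) -> list[ZoneSummary]:
    return [
        ZoneSummary(zone=r.zone, species=r.species, mean=r.mean, stdev=r.stdev,
                    vmax=r.max, vmin=r.min, n_days=int(r.n_days))
        for r in df.itertuples()
    ]
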