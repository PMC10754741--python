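"""Pollution indexing and source attribution: geo-accumulation index,
PAH diagnostic ratios, compositional fractions, exceedance factors and
correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

# Geo-accumulation classes, ordered; bins are half-open on the left:
# igeo <= 0 none; (0,1] unpolluted-to-moderate; (1,2] moderate; ...; >5 extreme.
IGEO_CLASSES = (
    "no_pollution",
    "unpolluted_to_moderate",
    "moderate",
    "moderate_to_heavy",
    "heavy",
    "heavy_to_extreme",
    "extreme",
)


def classify_igeo(igeo_value: float) -> str:
    if igeo_value <= 0:
        return IGEO_CLASSES[0]
    idx = int(np.ceil(igeo_value))
    return IGEO_CLASSES[min(idx, 6)]


@dataclass(frozen=True)
class IgeoResult:
    zone: Optional[str]
    species: str
    igeo: Optional[float]
    pollution_class: Optional[str]
    background: Optional[float]


def igeo(c: float, background: float) -> float:
    """Geo-accumulation index: log2(C / (1.5 * background)).

    The 1.5 factor absorbs natural background fluctuation. Both arguments
    must be in the same declared unit — this function does no conversion
    and refuses non-positive inputs.
    """
    if c <= 0:
        raise ValidationError(f"concentration must be > 0 for Igeo, got {c}")
    if background <= 0:
        raise ValidationError(f"background must be > 0 for Igeo, got {background}")
    return float(np.log2(c / (1.5 * background)))


def igeo_table(zone_means: pd.DataFrame,
               backgrounds: Mapping[str, float]) -> list[IgeoResult]:
    """Igeo per (zone, species) from a tidy (zone, species, mean) frame.

    A species with no background (e.g. Al where no regional soil survey
    value exists) yields a null Igeo with a warning, never a guess.
    """
    out = []
    for r in zone_means.itertuples():
        bg = backgrounds.get(r.species)
        if bg is None:
            warnings.warn(f"no soil background for {r.species}; Igeo null",
                          stacklevel=2)
            out.append(IgeoResult(r.zone, r.species, None, None, None))
            continue
        v = igeo(r.mean, bg)
        out.append(IgeoResult(r.zone, r.species, v, classify_igeo(v), bg))
    return out


#: Diagnostic-ratio definitions: name -> (numerator congener, other congener).
DIAGNOSTIC_RATIOS = {
    "Ant/(Ant+Phe)": ("Ant", "Phe"),
    "FR/(FR+Pyr)": ("FR", "Pyr"),
    "BbF/(BbF+BkF)": ("BbF", "BkF"),
}


def label_ratio(name: str, mean_ratio: float) -> str:
    """Source label from the conventional literature thresholds."""
    if name == "Ant/(Ant+Phe)":
        return "pyrogenic" if mean_ratio > 0.10 else "petrogenic"
    if name == "FR/(FR+Pyr)":
        return ("biomass/coal combustion" if mean_ratio > 0.60
                else "petroleum/other")
    if name == "BbF/(BbF+BkF)":
        return ("diesel-influenced" if mean_ratio > 0.50
                else "non-diesel")
    raise ValidationError(f"unknown diagnostic ratio {name!r}")


@dataclass(frozen=True)
class RatioDiagnostic:
    zone: str
    ratio_name: str
    mean: float
    stdev: float
    n_days: int
    n_omitted: int  # days dropped for a zero denominator
    source_label: str


def diagnostic_ratios(measurements: pd.DataFrame,
                      ratios: Mapping[str, tuple] = DIAGNOSTIC_RATIOS
                      ) -> list[RatioDiagnostic]:
    """Per-zone congener-pair ratios averaged over daily samples.

    Each day's ratio a/(a+b) is computed first and the daily ratios are
    then averaged (mean of ratios, not ratio of means — the two differ
    whenever concentrations covary day to day). Days where both congeners
    are zero are omitted and counted.
    """
    df = measurements.copy()
    out = []
    for name, (num_sp, den_sp) in ratios.items():
        sub = df[df["species"].isin([num_sp, den_sp])]
        wide = sub.pivot_table(index=["zone", "site_id", "date"],
                               columns="species", values="value_ng_m3")
        if num_sp not in wide.columns or den_sp not in wide.columns:
            raise ValidationError(f"ratio {name}: missing congener data")
        wide = wide.dropna(subset=[num_sp, den_sp])
        for zone, grp in wide.groupby(level="zone"):
            denom = grp[num_sp] + grp[den_sp]
            ok = denom > 0
            ratio = grp.loc[ok, num_sp] / denom[ok]
            if len(ratio) == 0:
                raise ValidationError(
                    f"ratio {name} in zone {zone}: all denominators zero")
            mean = float(ratio.mean())
            sd = float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0
            out.append(RatioDiagnostic(
                zone=zone, ratio_name=name, mean=mean, stdev=sd,
                n_days=int(ok.sum()), n_omitted=int((~ok).sum()),
                source_label=label_ratio(name, mean)))
    return out


def composition_fractions(zone_means: pd.DataFrame,
                          species_set: Optional[Sequence[str]] = None
                          ) -> pd.DataFrame:
    """Per-species percentage of the summed zone means.

    fraction_i = 100 * mean_i / sum(means), per zone. Needs at least two
    species and a positive total.
    """
    df = zone_means
    if species_set is not None:
        df = df[df["species"].isin(species_set)]
    rows = []
    for zone, grp in df.groupby("zone"):
        if grp.shape[0] < 2:
            raise ValidationError(f"zone {zone}: need >= 2 species for fractions")
        total = grp["mean"].sum()
        if total <= 0:
            raise ValidationError(f"zone {zone}: zero total concentration")
        for r in grp.itertuples():
            rows.append((zone, r.species, 100.0 * r.mean / total))
    return pd.DataFrame(rows, columns=["zone", "species", "fraction_pct"])


def exceedance_factor(mean_ng_m3: float, limit_ng_m3: float) -> float:
    """Ratio of a zone mean to a regulatory air limit (e.g. Cr(VI) 12 ng/m3)."""
    if limit_ng_m3 <= 0:
        raise ValidationError(f"limit must be > 0, got {limit_ng_m3}")
    if mean_ng_m3 < 0:
        raise ValidationError(f"mean must be >= 0, got {mean_ng_m3}")
    return mean_ng_m3 / limit_ng_m3


def correlation_matrix(measurements: pd.DataFrame,
                       species_set: Optional[Sequence[str]] = None,
                       min_pairs: int = 3
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r matrix (with two-sided p-values) over daily paired samples.

    Pairs with fewer than min_pairs common days, or a constant series, get
    a null cell. Returns (r, p) as square symmetric DataFrames with unit
    diagonal on r.
    """
    wide = measurements.pivot_table(index=["site_id", "date"], columns="species",
                                    values="value_ng_m3")
    if species_set is not None:
        wide = wide.loc[:, [s for s in species_set if s in wide.columns]]
    cols = list(wide.columns)
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i in range(n):
        for j in range(i + 1, n):
            pair = wide[[cols[i], cols[j]]].dropna()
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = res.statistic, res.pvalue
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p
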