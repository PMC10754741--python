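# Methods

## Scope and model

The package implements the standard US-EPA inhalation risk-characterization
chain for particle-bound toxicants measured at fixed receptor zones, plus
the pollution-indexing, source-attribution, uncertainty and spatial layers
that typically accompany it in mining-area campaigns.

Heavy metals follow the concentration-based route: the exposure
concentration EC_i = C_i·ET·EF·ED/AT_n time-weights the ambient
concentration by the exposure scenario, the hazard quotient divides EC by
the chronic reference concentration (RfC, with CF = 1000 µg/mg closing the
units), quotients add into a hazard index, and cancer risk is EC times the
inhalation unit risk. PAHs follow the dose-based route: congeners are
expressed as benzo[a]pyrene equivalents through toxic equivalency factors
(additive TEQ, no mixture interactions), and the incremental lifetime
cancer risk converts the inhaled BaP-equivalent dose with the BaP slope
factor; the 10⁻⁶ factor converts ng to mg. Keeping the two routes separate
(IR and BW enter only the PAH equation) mirrors the distinct regulatory
lineages of the two equation sets.

Assumptions worth stating: concentrations at the zone monitor stand for
personal exposure; risks are linear in concentration (no threshold in the
cancer slope); TEQ additivity; and the exposure scenario is a single
deterministic preset unless the Monte Carlo layer varies it.

## Data conventions

Concentrations are stored in ng/m³ everywhere; unit conversion happens only
inside the risk equations. Daily measurement tables are CSV with columns
`site_id,zone,date,species,value_ng_m3,censored`. Below-detection values are
substituted before any statistic: LOD/2 by default (the common convention
for lightly censored environmental series), `zero` or `omit` selectable,
and the policy used is echoed in the output. Per-species detection limits
are user-supplied — no instrument LODs are assumed. Standard deviations are
the sample (n−1) estimator; dates are calendar days (24-h filter samples).

Hexavalent chromium is derived as total Cr/7, the usual receptor-side
partitioning assumption for coal-mining dust, and then treated as a
first-class species.

## Presets and their provenance

Ship-with defaults, all overridable from config and echoed into outputs:

- **Exposure** ("EPA residential adult"): ET 24 h/day, EF 350 day/yr, ED
  30 yr, AT_n 70·365·24 h, AT 70·365 days, IR 20 m³/day, BW 70 kg.
- **IUR** (per µg/m³): Cr(VI) 1.2×10⁻², As 4.3×10⁻³ (IRIS), Pb 1.2×10⁻⁵
  (OEHHA). Al, Mn, Cu, Zn have no published IUR: their CR is null and
  excluded from totals, never silently zero.
- **RfC** (mg/m³): IRIS values for Cr(VI) (10⁻⁴, particulates) and Mn
  (5×10⁻⁵), the OEHHA chronic REL for As (1.5×10⁻⁵); Al, Cu, Zn and Pb
  carry provisional screening values and should be replaced when a
  jurisdictional number exists.
- **TEF**: Nisbet & LaGoy. Triphenylene has no canonical TEF; it defaults
  to the chrysene-class 0.01.
- **Soil backgrounds** (mg/kg) from Colombian regional surveys; no Al
  background exists, so Al's Igeo is null with a warning.

The packaged campaign fixtures are per-zone mean/sd summaries (ng/m³) for
7 metals and 14 PAHs at three receptor zones; daily records are not
deposited, so maxima/minima are not carried in the fixtures.

## Geo-accumulation and diagnostic ratios

Igeo = log₂(C/(1.5·B)) with the seven conventional classes, half-open on
the left (Igeo = 1 is still "unpolluted to moderate"). The operation
requires concentration and background in the same declared unit and does no
cross-media conversion; comparing air ng/m³ against soil mg/kg is a
screening convention, not a physical ratio, and the background used is
always echoed.

Diagnostic ratios are computed per day and then averaged (mean of daily
ratios, not ratio of means — the two differ whenever congeners covary, and
only the former keeps each day's ratio in [0, 1]). Days with a zero
denominator are omitted and counted. Thresholds: Ant/(Ant+Phe) > 0.10
pyrogenic; FR/(FR+Pyr) > 0.60 biomass/coal combustion; BbF/(BbF+BkF) > 0.50
diesel-influenced.

Known discrepancy: campaign write-ups of this kind report mutually
inconsistent Ant/(Ant+Phe) summaries (zone means near 0.5 alongside
"overall" values near 0.9); the package implements the formula and makes no
attempt to reconcile such summaries. Similarly, IDP's published share of
inhalation risk (16–19%) is not reproducible from the published means with
any standard TEF set (the arithmetic gives ~22–25%); the TEF table is
config-overridable for users who need a different convention.

## Risk classes and boundaries

CR: < 10⁻⁶ negligible, > 10⁻⁴ likely harmful; the literature inequalities
are strict on both sides, leaving the boundaries undefined, so the middle
interval is closed here (CR exactly 10⁻⁶ or 10⁻⁴ is "acceptable"). ILCR
uses the same cut points with classes acceptable/elevated/high.

## Monte Carlo

Each uncertain input gets a distribution: by default lognormal for
concentrations and IR (non-negative, right-skewed), truncated normal for BW,
fixed for ET/EF/ED — regulatory guidance assigns these parameters values
without printing distributions, so the families are explicit config.
Lognormals can be specified by log-scale (µ, σ) or moment-matched from an
arithmetic mean and sd: σ_log² = ln(1 + sd²/mean²), µ_log = ln(mean) −
σ_log²/2. Truncation is by rejection with a retry cap that errors naming
the parameter. The default 10,000 iterations put the Monte Carlo standard
error of a mean at ~1% of the output sd.

Percentiles use linear interpolation between order statistics (numpy
default, Hyndman–Fan type 7) — stated because tail percentiles at n = 10⁴
depend on the definition. One global seed spawns per-parameter substreams
(`numpy.random.SeedSequence.spawn`), so results are bit-reproducible and
adding a parameter does not shift another's draws. Sensitivity is the
Spearman rank correlation of each varied parameter against the output, with
a normalized squared-coefficient contribution reported alongside; a
constant output yields null coefficients, not zeros.

## CPF spatial mapping

Endpoints of forward/backward trajectories (12-h interval convention;
pooled by default) are binned into an axis-aligned grid, default 32 × 32
cells of 1 km² — the receptor-domain convention; extent and cell size are
user parameters. Projection is local equirectangular about the grid origin,
adequate below ~100 km; cells are half-open on east/north edges so every
in-bounds point lands in exactly one cell, and out-of-bounds endpoints are
counted, not dropped.

A day is high-risk when its receptor metric is **at or above** the
percentile threshold (default 75th, the convention of the CPF literature).
The inclusive comparison makes the selection exact in the boundary case
where the flagged days are exactly the top quartile. cpf_raw = m_ij/n_ij is
multiplied by a step weight to suppress cells whose evidence is a handful
of endpoints: 1.0 above 2·n̄, 0.7 down to n̄, 0.42 down to 0.5·n̄, 0.05
below, where n̄ is the mean endpoint count over nonempty cells; the
breakpoints are config-exposed. Clustering resamples each trajectory to a
common point count, scales degrees to km at the domain's mean latitude, and
runs Euclidean k-means (deterministic under seed); k is user-chosen and the
silhouette score is reported.

## Synthetic generator

The generator emulates what the analysis assumes: per-(zone, species)
lognormal daily concentrations moment-matched to target mean/sd, censoring
flags below a per-species LOD, optional equicorrelated Gaussian-copula
coupling on the log scale (to exercise correlation analysis), and
trajectory bundles as correlated random walks — per-step bearing = the
prevailing transport direction plus Gaussian jitter, fixed speed, backward
tracks extending toward where air came from. Default geometry follows the
campaign setting: easterly regime, 12-h endpoint interval, 13 points per
track.

What it does **not** emulate: temporal autocorrelation and seasonality,
inter-site heterogeneity within a zone (one synthetic site per zone),
meteorology-driven concentration–trajectory dependence, and realistic
multi-modal wind climatology. Tests that pass on synthetic data therefore
validate the arithmetic and the statistical plumbing, not the atmospheric
realism of any conclusion.

Problem sizes in the test and acceptance runs are chosen for tight
statistical control at interactive cost: 10⁴ draws for moment-recovery
checks (3-standard-error bands), 10⁵ for the uniform quantile calibration,
40-day campaigns with 10 planted episode days (exactly the top quartile,
where the 75th-percentile selection is exact), and 20 seeded replicates for
the easterly-CPF check.

## Numerical details and edge cases

- Cell binning snaps coordinates to 10⁻⁹ cell units before flooring so a
  point constructed on an edge is not pushed across it by projection
  round-off.
- A species used by an operation must carry the field that operation needs;
  missing RfC/IUR/TEF/background produce nulls with warnings or explicit
  errors (TEQ refuses to drop congeners silently).
- `hazard_index` with all-null quotients, fractions over a zero total,
  Igeo at non-positive inputs, zero-area grids and k > n clustering all
  raise validation errors rather than returning NaN.
- Pipeline outputs are a pure function of (inputs, config, seed); the run
  manifest records config hash, seed, input digests and package version.

## Limitations

Inhalation only (no dermal/ingestion routes); no enrichment factors or
receptor modelling (PMF/CMB); no meteorological simulation — trajectories
are inputs; no PSCF/CWT variants or kriging. Published headline HI/CR
values from comparable campaigns depend on supplementary exposure
parameters that are rarely printed; the packaged presets reproduce the
published cancer-risk magnitudes closely, but HI values are
preset-dependent and should be read as scenario outputs, not constants.
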