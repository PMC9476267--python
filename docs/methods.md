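# Methods

`grazekit` reimplements, as a tested pipeline, the analysis chain that links
GPS tracking of free-ranging beef cows on rugged hill-country terrain to
genotype–behaviour association: trajectory construction and outlier
cleaning, DEM annotation, eleven daily grazing-personality behaviours,
day- and cow-level filtering, and mixed-model association of the behaviours
with GRM5 variants and genotypes. Because the original commercial-farm GPS
data are not redistributable, every stage is exercised against a
synthetic-herd simulator with known ground truth; this note records the
models, defaults, and design choices, and what the synthetic results do and
do not establish.

## Trajectories and outlier cleaning

Fixes are (cow, UTC timestamp, easting, northing) in a planar metric
projection; all distances are Euclidean in that plane (no geographic CRS
math anywhere). Per-step statistics follow the usual movement-ecology
conventions: step length, speed, heading (counterclockwise from +x),
turning angle in (−π, π]. Turning angles across recording gaps longer than
twice the fix interval are flagged undefined; distances still accumulate
across gaps. The day boundary is civil midnight in a configurable timezone
(UTC default, which is also what the simulator emits).

GPS outliers are detected from the speed/turn signature. A fix is removed
when both its incoming and outgoing speeds exceed `speed_max` (default
2.5 m/s — faster than a grazing cow sustains over 5 minutes), or when both
exceed `spike_speed` (1.5 m/s) while the path turns back on itself by more
than 150° — the teleport-and-return spike. Requiring the excess on both
sides keeps the legitimate fix after a spike from being removed together
with the bad one. After removal, all step statistics are recomputed on the
retained sequence; on clean data the detect/remove pass is idempotent.
Thresholds are config-exposed and logged into the QC report.

## Terrain

DEMs are regular grids registered to cell centres, row 0 at the north-west
corner; the study scale is a 16 m cell. I/O supports ESRI ASCII grids
(primary, plain text) and single-band GeoTIFF via `tifffile` with
ModelPixelScale/ModelTiepoint/GDAL-nodata tags. Slope and aspect use Horn's
3×3 weighted finite differences with a replicated border; slope is carried
both in degrees, atan(|∇z|), and as rise/run percent, 100·|∇z|; aspect is
the downslope azimuth clockwise from north, NaN on flat cells. Because
field reports sometimes use a linear degrees = percent·45/100 mapping
instead of the tangent relation, both conversions are provided
(`slope_percent_to_degrees(..., convention=)`); the tangent one is the
package default and nothing downstream depends on the choice. Fixes are
annotated by nearest-cell sampling (bilinear available for elevation);
fixes outside the extent are flagged, and more than 5% outside is treated
as a fixes/DEM mismatch and raised.

## The eleven behaviours and the filters

Per cow-day: horizontal, vertical and 3-D distance, elevation range and
gain, herd-relative mean/85th-quantile/range of elevation, 85th quantile of
slope, home range as the area of the 100% minimum convex polygon (hectares,
shapely convex hull), and tortuosity = horizontal distance / home range
(m/ha). Quantiles interpolate linearly between order statistics. "Herd"
for the relative metrics is the mob (the group sharing a paddock); herd
min/max are taken over all fixes of all cows of the mob that day. Days with
zero-area polygons (fewer than three distinct non-collinear fixes) get
undefined tortuosity rather than infinity and drop out of that behaviour's
mean only.

Filters mirror the field protocol: a day is valid when at least 75% of the
expected fixes were recorded (216 of 288 at 5-minute cadence — the expected
count is 24 h × 12 fixes/h = 288); per mob, the analysis window keeps the
first up to 28 days whose herd-level median per-fix slope exceeds 8°; cows
with fewer than 7 retained valid days are excluded entirely. Per-cow
profiles are arithmetic means of daily values on the raw scale.

## Synthetic herds

The simulator's defaults describe the study conditions the package targets:
4 farms × 2 sampling years, 14 mobs of 22 cows (~306), 14 days at 5-minute
cadence, 5% i.i.d. fix dropout (a bursty Markov variant is available, off
by default), genotypes at the observed herd frequencies (AA 1%, AB 6%,
AC 10%, BB 12%, BC 36%, CC 35%), age classes 1/2/3 at 30/35/35% (not
reported for the source herds; chosen as a plausible mature-herd mix), and
rugged terrain: a 160×160 grid of 16 m cells with 300 m relief from
spectrally low-pass-filtered Gaussian noise (correlation length 8 cells),
which yields herd-median slopes well above the 8° gate.

Movement is a correlated random walk with home-point attraction:

    heading_t = heading_{t−1} + ε_t,        ε_t ~ N(0, 1/κ)
    cand_t    = pos_{t−1} + L_t·u(heading_t) + uphill drift
    pos_t     = home + (cand_t − home)/(1 + a)

with gamma step lengths (mean 12.5 m per 5-minute step ≈ 3.5 km/d), wrapped
normal turning (concentration κ), attraction a ≥ 0, and an uphill drift of
15% of the step length along the local gradient. The position process is an
OU-like walk whose stationary spread shrinks as a grows, so expected daily
home range is monotone decreasing in attraction while daily distance stays
roughly constant — mechanically producing the home-range versus tortuosity
trade-off the association analysis is designed to detect. Genotype and age
act multiplicatively: allele A lowers attraction (larger range) and raises
κ (straighter paths), allele B does the opposite, and the youngest age
class gets lower attraction; the default dial spreads expected daily home
range by roughly 20% between the extreme genotypes, the magnitude reported
for mature herds. No generative model of real cow movement was available to
fit, so the simulator is calibrated only to reproduce the qualitative
structure the analysis assumes (daily distances near 3.5 km/d, home ranges
of order 10–16 ha/d, strongly negative per-cow range/tortuosity
correlation) — passing tests demonstrate that the pipeline recovers known
effects under that structure, not that real herds behave this way. There is
no behavioural state switching (grazing/resting/travelling) and no collar
failure model beyond dropout.

Randomness: one global seed; each cow's stream derives from the CRC-32 of
its id, so adding or removing a cow never perturbs the others, and
identical configs give byte-identical fix tables. Injected teleport
outliers (off by default) displace isolated fixes by at least twice the
speed threshold so filter recall is measurable against labels.

## Mixed models

Seven behaviours are log-transformed and modelled as Gaussian LMMs; the
four 0–1 bounded behaviours (the three relative elevations and slope85 as
percent/100) get a logit-link model. All models are random-intercept
models; daily records are repeated measures, so a cow-identity intercept is
always present.

The LMM core is implemented in-package (`grazekit.lmm`): the likelihood is
profiled over fixed effects and the residual variance, leaving only the
variance ratios, and every evaluation reduces to q×q linear algebra via the
Woodbury identity (q = total random-effect levels), so likelihood
evaluations are independent of n after one pass of cross-products.
Optimisation is L-BFGS-B over the square roots of the variance ratios
(multiple starts) followed by an unconditional Nelder–Mead polish started
off the boundary, because the square-root parameterisation makes γ = 0 an
artificial stationary point. Fits with a variance ratio at the boundary are
flagged singular but reported. The implementation is verified against
statsmodels `MixedLM` (variance-components formulation) to ~5 decimals in
estimates, standard errors, variance components and REML log-likelihood.

Fixed effects are tested with Satterthwaite's approximation:
df = 2(c'Ĉc)²/Var(c'Ĉc), with the variance of the estimated contrast
variance obtained from its finite-difference gradient in the natural
variance parameters and the inverse observed information (numeric Hessian)
of the (RE)ML log-likelihood — the same recipe lmerTest uses.
Kenward–Roger is not implemented. Calibration was checked by simulation at
the study design (300 cows, 14 mobs, 10 days): the empirical sd of the
effect estimate equals the mean model SE to three decimals and 95% CI
coverage is ~94–95%.

Bounded behaviours use penalised quasi-likelihood by default: iteratively
reweighted working LMMs on z = η + (y−μ)/(μ(1−μ)) with working weights
μ(1−μ) and unit prior weights. PQL criteria are quasi-likelihood
quantities, comparable only between PQL fits of the same response; an LMM
on the logit-transformed response (clipped at 1e-4) is selectable
(`--glmm-mode logit-lmm`) for fully likelihood-based selection.

## Model selection

Step 1 (random structure): twelve candidate structures over
{farm, year, farm:year, mob, sire, genotype} — always plus cow identity —
are fitted by ML to the intercept-only model. The "best compromise" of
AIC, BIC, parameter count and factor significance is made deterministic:
rank by AIC; among candidates within ΔAIC ≤ 2 of the best prefer fewest
parameters, then lowest BIC, then enumeration order; finally a
simplification pass replaces the winner by the smallest nested candidate an
ML likelihood-ratio test cannot reject at 0.05. LRTs for variance
components use the plain χ² reference (no 50:50 boundary mixture), which is
conservative — a structure is only retained when the evidence is clear.
If the selected structure contains the genotype factor it is dropped before
step 2: a genotype random intercept would absorb the genotype fixed effect
under test.

Step 2 (fixed structure): the genetic predictor (presence/absence of one
allele, or the full genotype) is always retained as the term under test;
cow age class is kept iff the ML likelihood-ratio comparison favours it at
0.05. Final models are refitted by REML. Model suitability is checked by
the scaled-residual rule (pass iff ≤ 5% of conditional Pearson residuals
beyond ±3); on simulated herds the observed fraction is ~0.3%.

## Marginal means, post-hoc, reporting

Estimated marginal means use the full cross of the categorical fixed
factors as reference grid with equal weights over non-grouping factors
(emmeans-style), Satterthwaite df per contrast, and delta-method
back-transformation (exp for log responses, inverse logit for bounded
ones). Pairwise contrasts are tested on the link scale and adjusted with
Benjamini–Hochberg over the family of pairwise p-values; compact letters
come from the insert-and-absorb algorithm, so two groups share a letter iff
their adjusted p ≥ α (brute-force verified in tests). Pearson correlations
between per-cow behaviour means use pairwise-complete deletion, so the
home-range and tortuosity columns can have smaller n than the others.
P-values are deliberately not adjusted across the eleven behaviours
(matching the original protocol); the report states this prominently.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on small constructed herds (4 mobs × 8 cows,
8 days). The calibration studies simulate at the response level (daily log
home range drawn directly from the assumed LMM) so that 200-replicate
coverage and type-I studies complete in minutes: 300 cows, 14 mobs, 10
days, variant effect 0.2, between-mob/between-cow/residual sd
0.3/0.3/0.5 — variance magnitudes of the order herd data show. The
acceptance script runs the full GPS-level pipeline once at the default herd
scale and the calibration studies at those sizes.

## Known limitations

- Only random intercepts (no random slopes); adequate for the grouping
  factors modelled here.
- PQL is a first-order approximation; its criteria are quasi-likelihoods.
- χ² LRTs for variance components are conservative at the boundary.
- The simulator does not model behavioural states, collar failure beyond
  dropout, seasonal drift, or social interaction between cows; herd-level
  relative behaviours therefore carry less structure than real herds.
- GPX I/O treats lat/lon verbatim as planar y/x under the package's
  documented planar assumption.
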