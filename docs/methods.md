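# Methods

This note documents the models behind `ridge2reef`, the choices made where
the design was genuinely open, and what the synthetic sites do and do not
establish about real data.

## Groundwater model

The aquifer is a single confined-equivalent layer at steady state with
prescribed transmissivity `T` (m²·yr⁻¹):

    ∇·(T ∇h) = −R(x, y)

discretized on a square grid by 5-point finite differences with
harmonic-mean face transmissivities and solved by a sparse direct solve.
Boundary conditions: Dirichlet head (default 0 m, an equivalent freshwater
head standing in for density-corrected coastal boundaries) on sea cells;
no-flow on lateral and inland edges. This replaces a multilayer
variable-density code while preserving the one product the downstream
framework consumes — the distribution of coastal discharge along the shore.
On the 1-D strip with uniform recharge the solver matches the Dupuit-style
profile `h = w(2Lx − x²)/2T` to well under 1 % at 100 cells, and the face
fluxes close the mass balance to 10⁻⁶ relative.

Recharge bookkeeping is `R = P + I + OSDS − DR·P − AE − ΔSS` per cell, with
direct runoff a fixed fraction of rainfall (0.54 at the wet site, 0.10 at the
dry site where runoff is rare), ΔSS fixed at zero (long-term average),
negative cells clipped at zero with a logged count, and onsite sewage
effluent (435 m³·yr⁻¹ per residence) entering as an equivalent recharge
depth. Aquifer evapotranspiration is zero because the water table sits below
the 1.5 m maximum evapotranspiration depth. The domain budget closes with
coastal discharge as the residual `Cstl = R + Inj − ET − Str − Q`; the wet
preset's stream term scales a 0.26 m³·s⁻¹ gauged baseflow by relative domain
area. Transmissivity is a configuration value (10⁶ m²·yr⁻¹ wet,
5×10⁵ dry — a ~30 m·d⁻¹ volcanic aquifer a few tens of meters thick); no
field value is asserted.

## Nutrient loading

Background flux per cell is zone concentration × annual recharge volume
(mg·L⁻¹ ≡ g·m⁻³, so kg·yr⁻¹ = conc × m³·yr⁻¹ × 10⁻³). Anthropogenic flux
uses a class table (cesspool, septic, injection well, lawn, golf) with
per-unit loadings for wastewater classes and per-hectare loadings for
fertilized area classes; polygon loadings are apportioned by exact
polygon∩cell area so domain totals are independent of grid resolution
(closure tested to 10⁻⁹ relative). Where the published flux columns do not
reproduce from the concentration × volume arithmetic (septic P, injection P,
lawn, golf — their derivations involve unstated sorption and leaching
fractions), the flux columns are authoritative and the concentrations are
kept for reference; a per-class P delivery factor (default 1 for wastewater,
reflecting no sorption below the soil zone) is exposed for diffuse sources.
Background and anthropogenic rasters are never merged, so human-derived
fractions are exact bookkeeping, not estimates.

## Flow tubes

Pour points sit at arc-length intervals (default 200 m) along the shoreline,
the first at half an interval. Tube boundaries are traced from the tube-edge
arc positions (k·spacing) by integrating the *reversed* cell-center velocity
field (RK2, fixed half-cell step, bilinear velocity interpolation) until the
path leaves the domain, stagnates, or hits the step cap; N pour points are
bracketed by N+1 boundary paths, which is what makes "the band between
adjacent paths" a partition. Strip cells (within the inland extent of the
shoreline) are assigned to the band whose bounding paths they fall between,
via nearest-boundary geometry; cells beyond the outermost paths attach to
the nearest tube, and ties go to the lower tube index. Exchange between
tubes is exactly zero by construction. Tube budgets sum member-cell water
and nutrient fluxes; flux originating upslope of the strip is allocated
proportionally to each tube's direct water flux (equal shares if all are
zero), so tube totals equal domain totals identically. Tube water is then
rescaled so its total matches the domain budget residual (stream baseflow
removes water before the coast; injection volume is added to the tube
nearest the injection well). The inland extent is a preset scalar (1,000 m
wet; 3,500 m dry, clipped to the synthetic domain where smaller) rather than
a groundwater-elevation contour.

## Coastal plumes

The cost surface is an equal-weight composite of min-max-normalized
water-column depth, distance from shore, and wave power (weights are a
documented free parameter; a constant driver is dropped and the weights
renormalized). Accumulated cost from each pour point is the Dijkstra
shortest path over the 8-neighbour lattice with edge weight = mean endpoint
cost × center distance (×√2 diagonally). The plume kernel is

    W_i = L_p · exp(−c_i² / D_c),   W_i = 0 beyond 1 km from shore.

`D_c` is defined only as the cost equivalent of the 1 km cutoff, so a
reproducible convention is required: per site, `D_c = c̄₁ₖₘ²/9`, where
`c̄₁ₖₘ` averages over pour points the least accumulated cost among cells at
the cutoff distance — the plume decays to e⁻⁹ (≈0.01 %) of the loading at
1 km. The kernel form is the default; an optional mass-conserving mode
rescales each plume so its cell sum equals the pour-point loading, honoring
a spreading (rather than kernel) reading of the decay. There is no
advection: plumes wrap around coastal features but are not pushed by
nearshore circulation, so they are conservative spatial-pattern estimates.

## Marine terrain drivers

All metrics are computed at the 60 m reef resolution (finer bathymetry is
block-mean aggregated first): Horn 3×3 slope and downslope aspect; BPI as
center depth minus the circular-neighborhood mean (center excluded) at 60 m
and 240 m radii; plan and profile curvature from the quadratic-surface fit
(profile = negated second directional derivative along the gradient, plan =
the across-gradient term; both 0 where the gradient vanishes — note the two
have opposite signs on a sphere flank under this convention); rugosity as the
tangent-plane area ratio √(1+|∇z|²), exact for a tilted plane; and
neighborhood circular statistics of aspect (northness = cos μ, eastness =
sin μ, sd = √(−2 ln R̄)). Everything is validated against closed forms on
planes, spheres and channels to 1 %.

## Reef models

Each indicator is modeled independently with least-squares stagewise boosting
(Gaussian deviance), bagging, and shrinkage — scikit-learn's gradient
boosting is the base learner; the calibration protocol is this package's.
Responses are variance-stabilized (sqrt for % cover, fourth root for
biomass); predictions are back-transformed and clipped ([0, 100] for cover,
≥ 0 for biomass). Calibration grid-searches (learning rate, tree complexity
= max depth, bag fraction), choosing the tree count at the ten-fold
cross-validated deviance minimum and the winner by CV PDE; PDE is reported
on the transformed scale. The default grid (lr ∈ {0.05, 0.01}, tc ∈ {2, 3},
bag 0.75, ≤ 500 trees) is sized to the synthetic problems (n ≈ 100–300
surveys, 13–16 drivers) and is configuration-exposed; larger grids are a
config change, not a code change. Folds are simple random with a fixed seed.
Fish models take the observed benthic covers as extra predictors at fit time
and the *predicted* benthic maps at map time (benthic-then-fish ordering).
Moran's I on raw responses and residuals uses distance-band row-standardized
weights (3 reef cells, widened just enough that no survey point is isolated)
with a seeded 999-permutation pseudo p-value. Observed-vs-predicted maps are
compared by OLS (R², slope, p).

## Ordination

With Euclidean distances, distance-based redundancy analysis reduces to
classical RDA: z-score Y and X, regress, eigen-decompose the fitted values.
Per-axis % fitted variation = eigenvalue/Σeigenvalues; % total scales by the
constrained fraction of Y's variance. Drivers with pairwise |r| > 0.7 are
greedily pruned in column order (the later column of a pair drops); the
">70 % fitted variation" convention is reported as a flag, never enforced.

## Prioritization

Criteria are an AND of: depth shallower than 5 m (bleaching-prone), a
per-site benthic rule expressed as AND-of-OR-groups over predicted covers
(wet: (coral OR macroalgae) AND turf; dry: coral AND CCA AND turf), nutrient
plume exposure above the upper tercile (N always; P only where P was a
driver, i.e. the dry site), and wave power below the lower tercile (wet site
only). Benthic thresholds default to predicted-map site means; published
per-site values ship as optional overrides. Flagged cells are attributed to
the flow tube with the largest nutrient-plume share at that cell; tubes rank
by (anthropogenic flux, flagged-cell count) descending with tube id as a
stable tiebreak.

## Synthetic sites: what they emulate, and what they do not

The generator reproduces the *structure* of the two study conditions — wet:
rainfall ≈ 4 m·yr⁻¹ rising steeply inland, natural recharge held inside
0.11–4.97 m·yr⁻¹, uniform background concentrations (0.50 N / 0.20 P
mg·L⁻¹), 99 cesspools + 37 septic systems + 6 ha lawn in a coastal strip,
high wave power, an embayment where flow lines converge; dry: recharge
inside 0.04–0.69 m·yr⁻¹, four background zones (2.70/0.25/1.20/0.25 N;
0.20/0.10/0.15/0.10 P), 193 residences (all cesspools; the leeward-island
split is overwhelmingly cesspool and the split is immaterial downstream),
lawn/golf polygons scaled to fit the desk-scale domain, one injection well
(160,600 m³·yr⁻¹), low wave power. Rainfall/recharge fields are smooth
inland ramps plus correlated noise, inverted through the recharge equation
so the envelope holds by construction; they are not geostatistical
emulations of Hawaiian rainfall. The land domain is 40×40 cells of 50 m
(400 ha) by default — far smaller than the real model domains — so absolute
site-level totals (coastal discharge, human-derived percentages) are *not*
comparable to the published site values; only the mechanics and the
per-unit/per-hectare arithmetic are. Surveys are linear functions of 2–4
named (z-scored) drivers on the transformed scale plus Gaussian noise
(default SD = 25 % of the truth field's SD), back-transformed and clipped —
matching the models' Gaussian-deviance assumption exactly, which real reef
data will not.

Consequently, passing tests establish that every numerical engine agrees
with independent oracles and that the pipeline recovers known structure
under its own noise model; they do not establish predictive skill on real
surveys, where noise is non-Gaussian, drivers are measured with error, and
responses are not additive.

### Driver collinearity and the recovery criterion

Several driver layers are near-collinear *by construction*: the freshwater,
N and P plumes share one decay geometry (pairwise r ≈ 1), rugosity is a
monotone function of slope, and plumes decay with distance from shore.
Boosted trees split influence arbitrarily among predictors this correlated,
so the parameter-recovery check scores the top-2 influential drivers *up to
aliasing*: a driver counts as true if it is the truth driver or correlated
with one at |r| > 0.7 over reef cells — the same threshold at which the
ordination treats drivers as interchangeable. Under that scoring the
recovery experiment (n = 300, 25 % noise, 20 seeds) requires top-2 recovery
plus prediction-vs-truth R² ≥ 0.5 in ≥ 90 % of runs.

## Numerical conventions and degenerate inputs

Nodata is NaN in memory (arithmetic propagates it) and a sentinel on disk.
Grids are row-major from the lower-left corner, cell centers at
origin + (i+0.5)·cellsize, half-open cell intervals for point-in-cell
tests. Bilinear sampling renormalizes weights over valid neighbors and
returns NaN only when all four are nodata. Aspect is nodata on flat cells;
curvatures are 0 at zero gradient; a constant cost driver is dropped with a
warning; a constant response or zero-variance prediction raises. Recharge
clipping uses a 10⁻¹² tolerance so exact zero balances are not counted as
clipped. All randomness flows from one root seed through named substreams
(site, surveys, fitting, permutations); reruns are bit-identical and the
pipeline manifest records content hashes to prove it.

## Problem sizes

Default runs use a 40×40 land grid (50 m cells), a ~33×25 reef grid (60 m
cells), ten ~200 m flow tubes, 200–300 surveys, and the reduced boosting
grid above; a full pipeline completes in about a minute and a half on one
CPU, and the complete validation suite in about two minutes.

## Known limitations

Single-layer fixed-T flow (no density coupling, no transients, no
unsaturated zone); flow-tube water is reconciled to the domain budget by
uniform rescaling rather than per-stream routing; plume diffusion has no
advection or tidal modulation; nutrient transport ignores denitrification
and anammox (aquifer waters are well oxygenated, so oxidized N and P species
dominate, but this may over-estimate N and under-estimate P near injection
wells); the BRT grid is deliberately small; dbRDA supports only Euclidean
distances; and the vulnerability overlay is a threshold intersection, not a
probabilistic risk model.
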