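# Methods

## Leaf respiration schemes

Upper-canopy leaf dark respiration R_d (μmol CO₂ m⁻² s⁻¹) is modelled per
plant functional type (PFT: broadleaf tree, needleleaf tree, shrub, C3
grass, C4 grass) under four schemes that add, one component at a time, the
survey-derived revisions to the standard nitrogen-chain description.

**Standard.** Baseline R_d,25 = f_dr · V_cmax,25 with
V_cmax,25 = 10⁶ · n_e · n_l0; instantaneous response
R_d = R_d,25 · Q₁₀^{0.1(T_l−25)} divided by
(1 + e^{0.3(13−T_l)})(1 + e^{0.3(T_l−36)}), which suppresses respiration
at low and high leaf temperatures and gives the curve an interior maximum
near 32 °C. All temperatures are °C throughout; no Kelvin conversion
happens inside kernels.

**Survey baseline.** R_d,25 = r₀ + r₁ n_l,a − r₂ T_G, with area-based leaf
nitrogen n_l,a = n_l0 · σ_l · 10³ (gN m⁻²) from the trait-table medians and
per-PFT regression coefficients. The three intermediate/full schemes use
this baseline with, respectively, the plain Q₁₀ = 2 response at fixed
T_G = 25 °C, the exponential-of-quadratic (b,c) response at fixed T_G, and
the (b,c) response with T_G taken from the forcing (10-day trailing mean of
air temperature). A sensitivity mode sets T_G = T_l, which damps the
apparent temperature response because warm instantaneous temperatures then
coincide with down-regulated baselines.

The (b,c) multiplier exp[b(T_l−25) + c(T_l²−625)] (b = 0.1012 °C⁻¹,
c = −0.0005 °C⁻²) has local ratio R(T+10)/R(T) = exp[10b + c(20T+100)]
("effective Q₁₀"), which declines continuously from ≈2.3 at 10 °C to ≈1.7
at 45 °C and equals 2.04 at 25 °C; the curve itself increases monotonically
up to −b/2c ≈ 101 °C, so it never turns over at ecological temperatures.

The linear baseline can go negative for very warm T_G and low n_l,a; it is
clipped at zero (and the event logged) because negative respiration is
unphysical. Clipping can be disabled diagnostically to expose the raw
linear value, which the uncertainty and recovery code paths rely on.

C4 grasses have no survey regression; they use the full standard pathway
(baseline and suppressed Q₁₀ response) in every scheme. Whether the (b,c)
multiplier should instead be applied to the C4 standard baseline in the
(b,c) schemes is not determinable from the source material; the fallback is
the package default.

**Light inhibition.** Non-photorespiratory CO₂ release is reduced by 30 %
where downward shortwave irradiance strictly exceeds 2 W m⁻². The
threshold is approximate in nature, so both threshold and fraction are
configuration values; the comparison is strict so that exactly-threshold
light is uninhibited.

## Canopy and whole-plant aggregation

Big-leaf scaling assumes leaf respiration declines as e^{−kL} with
cumulative leaf area index, giving R_d,c = R_d·[1 − e^{−kL}]/k with
k = 0.5 by default (k = 0.2 is exposed for sensitivity runs; implemented
with `expm1` so the k → 0 limit R_d·L is stable). Maintenance respiration
adds root and stem terms linear in R_d,c with nitrogen-ratio coefficients:
R_p,m = β·R_d,c + (η_root + η_stem)·R_d,c. The soil-moisture stress factor
β ∈ [0,1] multiplies the canopy term only by default (a configuration
switch applies it to all terms). η_root = 0.5 and η_stem = 0.4 are
*placeholder defaults*: the root/stem nitrogen scalings are not constrained
here, and analyses that depend on them set them explicitly (the factorial
acceptance run uses η_root = 1.2, η_stem = 1.0, representative of forests
whose root-plus-stem nitrogen is roughly double leaf nitrogen). Growth
respiration is R_p,g = r_g·(Π_g − R_p,m) with r_g = 0.25 and is deliberately
not clamped: negative values flag maintenance exceeding supply and
propagate into unsustainable negative NPP. R_p = R_p,m + R_p,g and
NPP = Π_g − R_p hold exactly by construction and are asserted to machine
precision in tests.

## Uncertainty propagation

The regression errors ε₀, ε₁, ε₂ are treated as mutually independent (no
covariance input is supported), giving σ(R_d,25) = √(ε₀² + n_l,a²ε₁²) for
the fixed-T_G schemes and √(ε₀² + n_l,a²ε₁² + T_G²ε₂²) for the acclimated
scheme. b and c are treated as exact, so every downstream flux scales σ by
the same deterministic multiplier chain as its central value; relative
uncertainty is invariant under temperature response, light inhibition and
canopy scaling. Growth respiration treats GPP as exact, so
σ(R_p) = (1 − r_g)·σ(R_p,m); this is a modelling choice of this package. A
seeded 10⁵-draw Monte-Carlo push-through agrees with the analytic forms to
well under 2 % in the tests.

## Synthetic forcing generator

The generator replaces observational climate drivers so the whole chain is
testable offline. It emulates: a latitudinal temperature gradient
(T = −12 + 38·cos φ, ≈26 °C at the equator), a hemisphere-phased seasonal
cycle (8 °C amplitude at the poles, zero at the equator), daily Gaussian
weather noise (σ = 2 °C), an optional linear warming trend, a latitudinal
shortwave profile (≈250 W m⁻² peak daily mean), smooth latitude-dependent
PFT mixtures (broadleaf-dominated tropics, needleleaf/shrub high latitudes,
C4 bump near 12°, 15 % agriculture remainder excluded from PFT cover), a
subtropical dry belt in β, and a GPP driver increasing smoothly in
irradiance and temperature (≈9 μmol CO₂ m⁻² s⁻¹ tropical mean, matching
tropical-forest annual GPP of ~3000 gC m⁻² yr⁻¹). T_G is the exact 10-day
*trailing* mean of air temperature, back-filling the first nine days with
day 1 (the window is specified but its initialisation is not; a trailing
window is the causal choice). Leaf temperature is taken equal to air
temperature — no leaf energy balance — and the light-inhibition decision is
made on daily-mean irradiance, so the day/night inhibition cycle is not
resolved; both simplifications affect all schemes identically and cancel
from scheme ratios.

What the generator does *not* emulate: ocean/land geography (the default
mask is all land), GCM-specific warming patterns, CO₂ effects, interactive
vegetation (LAI and cover are prescribed, not responsive to NPP), and
realistic interannual variability. Consequently passing gridded tests shows
the chain's internal consistency and qualitative geography (sign structure
of scheme differences, damping of the warming response by acclimation), not
agreement with observed global totals; absolute area-integrated numbers in
GtC yr⁻¹ are reported for the synthetic world only.

## Factorial experiments and diagnostics

All schemes run on identical forcing. Gridbox means weight PFTs by
fractional cover (Σ frac_i·x_i / Σ frac_i; zero-cover cells are masked).
Global totals convert μmol CO₂ m⁻² s⁻¹ through 12.0 gC mol⁻¹ (not 12.011;
a documented constant) and a 365-day year (3.1536 × 10⁷ s); annual means
are plain arithmetic means of daily values with no calendar handling.
Scheme attribution telescopes exactly: the three sequential scheme
differences sum to the total difference, cell by cell.

A caution on acclimation established during development: the cellwise
statement "acclimation reduces ΔR_p under uniform warming" holds only where
T_G ≥ 25 °C. In colder cells the cold-acclimated baseline
(r₀ + r₁n_l,a − r₂T_G with T_G < 25) *exceeds* the fixed-25 baseline, so
the same multiplicative (b,c) response produces a larger absolute ΔR_p
despite the −r₂ΔT_G damping term. The damping test therefore runs on a
warm-climate (tropical-band) grid, where the inequality is exact cellwise;
globally the tropics dominate area-weighted totals, which is what makes the
aggregate damping statement true in a realistic geography.

Desk-scale problem sizes: gridded tests and the acceptance run use an
8 × 8-cell grid with one year of daily forcing (23 360 cell-days across
four schemes and five PFTs), which resolves every property being asserted;
the runner is vectorised and scales linearly in cells × days for larger
domains. On a productive tropical grid the survey baseline roughly
doubles-to-triples the components linear in leaf R_d (R_d,c, R_p,m ratios
≈ 2.6) while total R_p rises by a smaller factor (≈ 1.5), because the
growth term r_g·Π_g is scheme-independent; the scheme ratio of R_p grows
toward the leaf-level ratio as maintenance dominates the carbon budget.

## Parameter recovery

`recover_globresp_params` fits R_d,25 = r₀(PFT) + r₁·n_l,a − r₂·T_G by
ordinary least squares with shared slopes and per-PFT intercepts,
returning estimates and standard errors. The mixed-effects structure of a
real survey (species/site random effects) is reduced to fixed PFT
intercepts; an optional site-level random intercept in the survey generator
stress-tests this simplification. The design matrix rank is checked
explicitly so degenerate surveys (e.g. constant T_G, collinear with the
intercepts) fail loudly rather than silently via a pseudoinverse.

## Numerical and interface choices

Parameters live in a version-controlled CSV (exact decimal strings as
printed in the trait tables) so alternative PFT sets can be supplied; the
registry round-trips exactly. The trait table's V_cmax,25 row is not
reproducible from 10⁶·n_e·n_l0 with the tabulated n_l0 (e.g. 36.8 printed
vs 29.52 computed for broadleaf trees, while the R_d,25 row is consistent);
the package treats the R_d,25 chain as authoritative and does not assert
the V_cmax,25 values. Gridded outputs are netCDF (classic format via the
scipy engine) with named dimensions (scheme, lat, lon), per-variable units
strings and global provenance attributes (package version, config hash,
seed); equal config and seed reproduce byte-identical payloads. Grid cell
areas use the spherical-cap formula R²·Δλ·(sin φ₂ − sin φ₁) with
R = 6.371 × 10⁶ m.

## Known limitations

- Root/stem nitrogen ratios are free parameters, not derived from biomass
  pools; whole-plant absolute magnitudes inherit that uncertainty.
- No within-canopy re-evaluation of the leaf equation: the big-leaf profile
  assumes nitrogen and light decay identically.
- Uncertainty excludes n_l,a variability, GPP, LAI and forcing errors.
- The synthetic world's absolute global totals are not comparable to
  observation-driven estimates; only ratios, signs and orderings are
  meaningful at desk scale.
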