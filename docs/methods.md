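# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user auditing results will want to
know.

## Geometry

Fruit surface area is computed from caliper measurements (length = polar
axis, two orthogonal equatorial diameters, mm). Two models are offered:

- **sphere** on the mean diameter, `A = pi d^2`;
- **spheroid** (default): the equatorial diameters are averaged into one
  equatorial radius `b`, the polar radius is `a = length/2`, and the exact
  prolate (`a > b`), oblate (`a < b`) or sphere closed form is used. The
  three branches agree to better than 1e-9 relative at the boundary.

The spheroid is the default because it uses all three measured dimensions;
the sphere is retained for comparability with the simpler convention. The
two equatorial diameters are averaged rather than kept tri-axial: mango
cross sections are close to circular, only two diameters are measured, and
the averaged form has an exact closed-form area.

A biopsy punch of radius `r` on a fruit of local curvature radius `R`
removes a spherical cap of area `2 pi R (R - sqrt(R^2 - r^2))`, computed
in the cancellation-free conjugate form so the flat limit (`R -> inf`) is
exact. When no region-specific curvature is available, `R` defaults to
the equivalent-sphere radius `sqrt(A_fruit / 4 pi)`.

## Growth kinetics

Surface area vs time (DAFB) is fitted with a three-parameter sigmoid:
logistic `A(t) = A_max / (1 + exp(-k (t - t_mid)))` by default, Gompertz
selectable. The logistic is the minimal sigmoid whose peak growth rate has
a closed form (`A_max k / 4` at `t_mid`; Gompertz: `A_max k / e`). Growth
rate is always the analytic first derivative of the fitted model, never a
finite difference of data.

Fitting uses least squares (`scipy.optimize.curve_fit`) with a
deterministic initialization — `A_max0 = 1.05 max(A)`, `t_mid0` at the
first half-maximum crossing, `k0` from a log-linear regression of the
logit-transformed interior points — so refitting a series is
bit-reproducible. Optimizer failure sets `converged = False` instead of
raising, so batch fits over regions never abort. A fit is also flagged
non-converged when the whole data range lies in the saturated or
pre-growth regime of the fitted curve (`k |t_edge - t_mid| > 10`): such
parameters are non-identifiable (any sufficiently extreme pair fits a
constant series equally well).

The pipeline fits the *mean* series per cultivar x region; per-fruit
fitting is available through the library API. Regional dot-pattern series
are summarized by the relative rate (rate / current area), which removes
the arbitrary scale of dot-pattern units.

## Strain partitioning

Stepwise stress release — excising a skin disc, enzymatically isolating
the cuticular membrane (CM), extracting the waxes — produces the area
triplet (A_i, A_CM, A_DCM) per disc. Apparent strains are referenced to
the fully relaxed dewaxed disc at the same sampling time (units: percent);
their sum reduces algebraically to `(A_i - A_DCM)/A_DCM x 100`.

Cumulative strains are referenced to the surface area at bloom,
`A0 = 1 cm^2` by default (configurable); the carpel area at initiation is
not measurable ab initio and 1 cm^2 is the conventional choice. Disc
ratios are scaled to the whole fruit proportionally
(`A_CM_fruit = A_total * A_CM/A_i`), the unique scaling consistent with
the assumption that strain release is uniform over the fruit surface.
Because all four components are referenced to the same base, the
conservation identity `eps_total = eps_exc+iso + eps_extr + eps_resid`
holds exactly; the test suite enforces residuals below 1e-9 and treats any
violation as a bug, not a tolerance.

Records violating the expected ordering `A_i >= A_CM >= A_DCM` (possible
under measurement noise, especially early in development when the skin is
strain-free) are **kept** and produce negative strain release, with a
warning. Dropping them silently would bias time-course means upward.
Published-style tables average per-disc apparent strains rather than
pooling areas first.

## Deposition kinetics

CM, DCM and wax masses per disc are converted to mass per unit area
(ug/mm^2 == g/m^2, additive by definition). Mass-per-area vs time is
fitted with a saturating exponential
`m(t) = m_inf (1 - exp(-r (t - t0)))` by default (logistic selectable);
the regression family behind published deposition-rate figures is not
fixed by convention, and the saturating exponential is the simplest model
whose derivative is monotone declining, matching the observed
early-rapid-then-constant pattern.

Deposition rates are analytic derivatives. Whole-fruit rates (default
reporting) apply the product rule to `M(t) = m(t) A(t)` using the fitted
growth curve, since the whole-organ flux is what area expansion must be
compared against. The "area-matched onset" is the earliest time, on a
0.5-day grid over the data range, at which `|dm/dt|` falls below 1% of its
magnitude at the start of the range; wax-like series that keep rising
report a missing onset rather than an arbitrary time.

## Breakpoint regression

Two-segment continuous piecewise-linear least squares, with the breakpoint
searched exhaustively over every interior data x value and every midpoint
between consecutive x values (candidates keep at least two points strictly
on each side). For each candidate the continuity-constrained problem is
linear in the basis `{1, x, (x - c)+}` and solved exactly; the global RSS
minimizer wins, with ties going to the smallest breakpoint. Grid search
was chosen over iterative (Muggeo-type) estimation because at these data
sizes it is exact, deterministic and free of convergence pathologies.

The "biphasic" claim is quantified by an F-test of the 4-parameter
segmented model against the 2-parameter line,
`F = ((RSS_lin - RSS_seg)/2) / (RSS_seg/(n-4))`. A segmented RSS within
1e-10 of zero (relative to the linear RSS) reports an infinite F; if the
line itself is exact there is no evidence of a break (p = 1).

## Tensile analysis

From each force (N) vs uniaxial strain (% of the 10-mm clamping distance)
curve: stiffness S is the maximum over sliding windows (length = 10% of
the rising-branch samples, minimum 3; configurable) of the within-window
least-squares slope; F_max and eps_max are read at the global force
maximum, and samples beyond it are discarded for stiffness. The windowed
maximum honors the "maximum slope" definition while resisting single-point
noise; a global secant would underestimate strain-stiffening curves and
adjacent-sample differences would be noise-dominated.

Known limitation: the max-over-windows statistic is biased upward under
noise, by roughly `(sigma/L) sqrt(12/n_w)` times the extreme-value factor
of the number of window positions (L = window length in strain units, n_w
= samples per window). For weak strips whose stiffness is close to the
secant slope (early development, S of order 0.05 N/% with 1% force noise)
this bias can reach 5-13%; for mature-phase strips it is under 5%. The
recovery validation in the test suite therefore evaluates mature-phase
strips (>= 97 DAFB); results on very weak early strips should be read
with this bias in mind. Conversely, fracture-strain localization is
noise-limited to about `sigma sqrt(2)/S` strain percent regardless of
sampling density, which corresponds to about one sample step at the
generator's default 600-sample curves.

Lenticel-failure frequency is the fraction of *annotated* strips whose
fracture involved a lenticel; unannotated strips leave the denominator.

## Morphometrics

Lenticel density is count / disc area (optionally curvature-corrected).
Marginal means over a cultivar x time x region table first average
replicates into cell means, then average cell means unweighted (each
region counts equally); this reproduces published report-table margins to
the printed 2 decimals. Replicate-weighted margins are available and can
differ by ~0.01 after rounding, which accounts for occasional
inconsistencies in published margin rows. Cell shape uses the anticlinal
aspect ratio (anticlinal / periclinal diameter; > 1 "portrait") and the
periclinal area as the squared periclinal diameter (cells are isodiametric
in the tangential plane). Per-lenticel area vs time is an OLS line.

## Synthetic data generator

Two documented profiles emulate the study conditions of a
russet-susceptible (`apple_like`) and a non-susceptible (`tommy_like`)
cultivar. Parameters that the study conditions fix:

| quantity | apple_like | tommy_like |
|---|---|---|
| peak area growth rate | 3.03 cm^2/day at 94 DAFB | 3.85 at 103 DAFB |
| logistic A_max | 350 cm^2 | 450 cm^2 |
| CM mass/area plateau | 1.6 g/m^2, onset ~69 DAFB | 2.4 g/m^2, onset ~83 DAFB |
| final apparent strain sum | 28.9% (17.0 + 11.9) | 24.9% (14.5 + 10.4) |
| strain onset (breakpoint) | 55 DAFB (eps_total ~ 71) | 62 DAFB (~88) |
| lenticel failure at maturity | ~70% | ~59% |
| lenticel number per fruit | 3900 | 8700 |

Sampling follows the study design: 12 sampling times from 41 to 153 DAFB
(weekly through the early phase, biweekly later), 15 fruit per time
(midpoint of the reported 10-20 replicates), 15 tensile strips per time,
8-mm punches. Disc-area noise of CV 2% with n = 15 reproduces the
reported SE of ~1.1 percentage points on the final apparent strain sum.
Noise is multiplicative Gaussian for areas/masses/lenticel areas
(positive-valued measurements), additive sigma = 1% of F_max for forces,
and Poisson for lenticel counts. All randomness flows from the profile
seed through independent per-table child streams, so one table can be
regenerated without perturbing the rest, and equal seeds give
byte-identical CSVs.

Disc-ratio trajectories are area-driven hinges,
`ratio(t) = 1 - c (1 - A(t_lag)/A(t))` for `t > t_lag`: deposition keeps
the skin strain-free until `t_lag`; afterwards un-fixed strain accumulates
in proportion to further area growth. This makes the elastic and
wax-fixed components exactly biphasic against total strain (hinge at
`eps_total = A(t_lag)/A0 - 1`) and the residual component exactly linear —
the qualitative structure the analysis is designed to detect. An
exponential-in-time ratio decay was tried first and rejected: composed
with logistic area growth it yields no well-defined breakpoint (the
elastic-vs-total curve has a second, spurious bend near maturity that the
segmented estimator locks onto under noise).

Tensile curves are C^1: a power-law toe joined to a final linear segment
whose slope equals the target stiffness, fracturing exactly at
(eps_max, F_max), with two post-peak samples marking the force drop. The
construction requires `S eps_max > F_max` (maximum slope above the secant
slope), true of strain-stiffening membranes.

What the generator does **not** emulate: spatial heterogeneity of strain
release over the fruit surface (the uniform-release assumption is built
in, so tests cannot detect its violation); fruit-to-fruit correlation
across sampling times (each time draws fresh fruit, as in destructive
sampling); wax mass per area that keeps rising late in development (wax
is generated as a fixed fraction of CM); weather- or handling-induced
outliers; and any mechanistic link between lenticel geometry and
measured failure (failure flags are Bernoulli draws from the profile's
frequency curve). Passing tests therefore validate the estimators and
the pipeline plumbing under the stated statistical structure, not the
biological assumptions themselves.

## Directional contrasts

The eight susceptible-vs-non-susceptible contrasts (lower peak growth
rate; earlier deposition plateau; higher elastic and higher wax-fixed
strain at matched total strain; earlier breakpoint; lower stiffness and
fracture force; larger lenticel areas; higher lenticel-failure frequency)
are evaluated by generating five replicate dataset pairs, running the
full analysis on each, and taking a per-contrast majority vote. A single
noisy replicate can misplace the breakpoint (the RSS profile across
candidate breakpoints is shallow with 12 mean points); replication is the
standard guard, and all contrasts are strict inequalities so swapping the
two profiles reverses every verdict exactly.

## Reporting conventions

Report tables round densities to 2 decimals, percent strains to 1, and
cumulative strains to 2 (matching the precision of published tables).
Derived CSVs carry the config hash and source-file provenance columns;
the run timestamp lives only in `report.json` so numeric outputs are
byte-reproducible for a given config and inputs.
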