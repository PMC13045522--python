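# Methods

## Scope and model

The toolbox treats one *condition* — a bioink formulation jetted through
a microvalve nozzle at fixed dwell time and frequency — as the unit of
analysis. Measurements come in three streams: a steady-shear flow curve
(γ̇, µ) from a cone-plate rheometer, a leading-edge displacement sweep
from strobe imaging, and gravimetric burst masses from dispensing a
known droplet count into a pre-weighed tube. From these the pipeline
derives a power-law viscosity model, a ligament velocity and volume, the
dimensionless jetting set, a nozzle-flow profile, and a regime label.

All internal arithmetic is SI; unit tags (µm, nl, µs, mPa·s, …) are
converted exactly at the boundary (`units.convert_to_si`) and
concentration units are opaque labels, never interconverted between
mg/mL and percent conventions.

## Rheology

The power-law (Ostwald–de Waele) model µ = K γ̇ⁿ⁻¹ is fitted by
minimising Σ wᵢ (µᵢ − K γ̇ᵢⁿ⁻¹)² with inverse-square weights wᵢ = 1/µᵢ²
(equivalently, unweighted least squares on relative residuals). The
weighting keeps a curve spanning several viscosity decades from being
fitted only at its low-shear end. The optimiser is bounded damped least
squares (`scipy.optimize.least_squares`, trust-region reflective — a
Levenberg–Marquardt-type method that honours bounds), seeded from an
ordinary log–log regression, which is already the global optimum for
noiseless power-law data; the refinement then accounts for the weights
in linear space.

Parameter bounds are K ∈ (10⁻⁸, 10⁴) Pa·sⁿ and n ∈ (0.05, 1.5); a fit
pinned at a bound is flagged (`at_bounds`) rather than rejected, and
non-convergence within 200 iterations returns the best point with
`converged=False`. Up- and down-sweeps are fitted separately; no
thixotropy model is attempted. No automatic outlier rejection is
applied — replicate scatter is reported through the residual diagnostics
instead.

Two shear-rate floors exist: a *cleaning* floor (default 10⁻³ 1/s) below
which flow-curve rows are considered unmeasurable and dropped, and a
*regularisation* floor (default 10⁻² 1/s, configurable) used wherever
µ(γ̇) is evaluated, which keeps the n < 1 viscosity finite at γ̇ = 0.
The regularisation floor only matters near the nozzle centerline and in
the γ̇ → 0 limit; at jetting shear rates (10³–10⁵ 1/s) it is inert.

## Dimensionless set

Definitions: We = ρv²D/σ, Re = ρvD/µ, Oh = µ/√(ρσD), Fr = v/√(gD),
Z = 1/Oh, Bo = We/Fr², K_splash = Oh·Re^1.25. Three conventions are
fixed deliberately:

* **Characteristic length** is the nozzle orifice diameter D (not the
  ligament or droplet diameter).
* **Characteristic velocity** is the measured ligament velocity from the
  displacement sweep — the only velocity the imaging protocol yields.
* **Characteristic viscosity** is either a directly measured high-shear
  viscosity or, from a power-law fit, µ = K γ̇_c^{n−1} at γ̇_c = v/D
  (configurable). For shear-thinning inks the high-shear choice is the
  physically relevant one during jetting; the selected path is recorded
  in each report (`viscosity_source`).

`invert_dimensionless` closes the definition set: given printed
(We, Re, Fr) plus ρ and D it returns (v, σ, µ), which lets published
dimensionless tables be turned back into physical properties and
re-verified by the forward computation (round trip tested to 1e-9).

The splash parameter uses the classical Mundo-type composite Oh·Re^1.25;
the deposition/splash threshold K_c defaults to 57.7, the literature
value for that correlation. K_c is an external default, not a quantity
estimated from the data this package analyses, and is configurable.

## Ligament metrology

Per-drop (= ligament) volume is mass/(count·ρ) per burst. The session
acceptance rule is the exact conjunction CV ≤ 5 % **and** R² ≥ 0.99,
both boundaries inclusive: CV is the sample SD/mean over the ≥3 bursts
at the operating dwell (the most frequent dwell, unless given), and R²
is an ordinary least-squares line of burst-mean volume against the ≥3
bracketing dwell times. With fewer than three distinct dwells R² is
undefined (NaN) and acceptance fails. A constant volume across dwells is
given R² = 1 (a flat line fits exactly; the zero-variance case would
otherwise be 0/0).

Velocity is the OLS slope of position vs time over the full sweep, with
a Theil–Sen variant behind `robust=True` for sweeps with dropped or
mis-tracked frames. The estimator is invariant under time- and
position-origin shifts.

Geometric descriptors: L_ar = L_l/D and d_eq = (6V/π)^{1/3}. In the
pipeline, where no measured ligament length is supplied, L_l is taken
kinematically as v·t_dwell (distance travelled while the valve is open);
directly measured lengths take precedence when present, and the
measurement time is required metadata because imaging at a fixed delay
after actuation is not the same as imaging at pinch-off.

Cell density is carried as a covariate only; no viscosity correction for
cell volume fraction is applied at the densities involved (≤3×10⁶
cells/mL, volume fractions ≲1 %).

## Nozzle flow

The millisecond valve-open flow in the short nozzle (R = 125 µm,
L = 0.84 mm defaults) is modelled as steady, laminar, fully developed
power-law pipe flow, for which the exact solution is

    u(r) = (Q/πR²)·(3n+1)/(n+1)·[1 − (r/R)^((n+1)/n)]
    γ̇_w  = (3n+1)/(4n)·4Q/(πR³),   γ̇(r) = γ̇_w (r/R)^(1/n)

with Q = V_lig/t_dwell. For fully developed laminar pipe flow this
closed form is exactly what a converged finite-element solve of the same
governing equations returns, so the analytic route replaces any
mesh-based solver without loss; mesh, stabilisation and entrance effects
(development length ≪ L at these Reynolds numbers through a short
nozzle) are consciously out of scope. The apparent-viscosity profile
µ(r) = K·max(γ̇(r), floor)^{n−1} uses the shared regularisation floor so
the centerline value is large but finite.

The radial grid is uniform with both endpoints, 256 points by default —
enough that Simpson quadrature of 2π∫u r dr returns Q to ~1e-6 even for
the most plug-like profiles (n = 0.15).

## Regimes and frequency bands

Z-bands follow the canonical drop-on-demand windows with closed
printable boundaries: viscous/energy-limited for Z < 1, printable for
1 ≤ Z ≤ 10, satellite-prone for Z > 10. Splash classification is a
strict exceedance of K_c (K = K_c is deposition).

The actuation-frequency recommendation is a data table (overridable in
config), not code: [0,1] → 20–50 Hz, [1,5] → 50–150 Hz,
[5,30] → 100–200 Hz, (30,∞) → 20–100 Hz, all clipped to the 20–200 Hz
solenoid operating window. Where Z falls exactly on a shared edge the
band with the higher upper frequency wins, which places Z = 1 and Z = 5
in the faster band and keeps Z = 30 at 100–200 Hz. The non-monotonic
final row encodes practice: moderately high-Z inks (dilute collagen)
tolerate fast jetting, while extreme-Z inks (fibrinogen) need the
impulse damped to suppress satellites. Published figure-caption zone
names for the high-Z region conflict with the running-text guidance
(caption: "printable fluid with a low frequency (f > 200 Hz)"); the
table follows the running text, which recommends *low* frequencies
there.

The physical ceiling on frequency is exposed separately:
τ_c = √(ρR³/σ) and t_p = τ_c(1 + α·Oh) with α = 2.0 by default — the
linear-in-Oh retardation is a standard interpolation between the
inviscid capillary limit and viscous-dominated breakup; only the scaling
is physically fixed, so α is configurable.

Maps place each condition in six planes; boundaries are the Z = 1 and
Z = 10 loci expressed per plane (Re = Z√We in We–Re; Oh = 1/Z lines
elsewhere; the 20/200 Hz lines on Oh–f). Points always carry a label
recomputed from their own coordinates — maps never relabel. Zone shading
is advisory: the framework is semi-quantitative.

## Synthetic data

The generators emulate the measurement protocols' statistical structure:
log-spaced flow curves over 0.1–1000 1/s with multiplicative lognormal
noise (instrument noise on viscosity is proportional, not additive),
displacement series on the 50 µs imaging grid with Gaussian position
jitter of order the pixel scale (10 µm), and burst masses with a stated
CV plus a linear volume-vs-dwell response for the calibration bracket.
Defaults mirror the bench protocol: 1000 drops per burst, three bursts,
1 ms operating dwell, ~60 nl drops, 30-point flow curves, 37-frame
sweeps. Each artifact is a pure function of (parameters, seed) via
`numpy.random.default_rng`; byte-identical reproduction is guaranteed
within this implementation only — cross-implementation checks should
assert statistical properties.

What the fixtures do *not* emulate: rheometer inertial and edge
artifacts, thixotropic hysteresis between up- and down-sweeps,
evaporation drift during gravimetric collection, segmentation error
structure in the imaging. Passing tests on synthetic data therefore
demonstrate the estimators' correctness under the assumed noise models,
not robustness to every instrument pathology.

## Numerical choices and degenerate inputs

* Fit initialisation: log–log OLS; bounds as above; `x_scale` set from
  the initial K so the two parameters are comparably scaled.
* Duplicate shear rates in a loaded curve are averaged so sweeps are
  strictly increasing; rows with γ̇ ≤ floor or non-finite µ are dropped
  and counted.
* `u(R)` is set to exactly zero (the closed form already vanishes there
  up to rounding).
* Oh is computed from µ/√(ρσD) and asserted against √We/Re at 1e-12 as
  an internal consistency guard.
* Problem sizes in the test-suite simulations — 200 seeds for fit
  recovery, 500 for velocity recovery, 1000 draws for the inversion
  round trip — give medians and means stable to well inside the asserted
  tolerances while keeping the whole suite interactive (~10 s).

## Known limitations

* Power-law only: no yield stress (Herschel–Bulkley), no Newtonian
  plateaus (Carreau/Cross), no viscoelastic breakup model — inks with
  strong elasticity (high G′) can pinch off later than the Oh-based
  t_p predicts.
* No in-flight drag/deceleration, no satellite-count prediction, no
  substrate interaction (coalescence, splash crown dynamics) beyond the
  scalar K classification.
* Contact angles are stored measurements only, never computed.
* The regime boundaries are literature bands, not probabilistic
  decision surfaces fitted to outcomes.
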