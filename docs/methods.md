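# Methods

## Measurement model and conventions

A QCM-D adhesion run is a time series (hours) of frequency shifts Δf (Hz)
and dissipation shifts ΔD (ppm) at the odd overtones n = 3, 5, 7, 9, 11, 13
of a 5 MHz AT-cut shear resonator, with three operator-annotated events:
baseline start (buffer only), injection of the bacterial suspension, and
the final buffer rinse.  All shifts are differential against the buffer
baseline, so the Newtonian liquid loading of the bare sensor cancels and
does not appear anywhere in the package.

The canonical internal frequency unit is **raw Hz at the overtone** (not
Δf/n).  Exports that store overtone-normalized shifts are converted on
read by multiplying by n (`TraceFileDialect`).  Raw-dialect file
round-trips are bit-identical (floats are written with shortest
round-trip precision and parsed with pandas' round-trip parser).

## Acoustic models

* Penetration depth: δ(n) = sqrt(2η / (ρ·2π·n·f₀)), returned in nm.
  Defaults η = 0.98 mPa·s, ρ = 1000 kg/m³ describe phosphate-buffered
  saline near room temperature; with f₀ = 5 MHz they give δ = 144.2,
  111.7 and 75.3 nm at n = 3, 5, 11.  The viscosity default is a
  documented package choice (buffer temperature is rarely reported with
  the data); both fluid properties are configurable.
* Sauerbrey areal mass: m_a = −Zq·Δfₙ/(2·n·f₀²), reported in ng/cm²
  (17.6 ng·cm⁻²·Hz⁻¹ of normalized shift for a 5 MHz crystal with
  Zq = 8.8·10⁶ kg·m⁻²·s⁻¹).
* Coupled resonator: a cell of mass m_p tethered by a bond of stiffness k
  and loss tangent γ contributes an areal load impedance
  Z_L(ω) = i·(N_s·m_p)·ω·ω_p*²/(ω_p*² − ω²), ω_p*² = k(1+iγ)/m_p,
  for N_s cells per unit area.  Shifts follow the small-load
  approximation Δfₙ = (f₀/πZq)·Re(i·Z_L), ΔΓₙ = (f₀/πZq)·Im(i·Z_L),
  ΔDₙ = 2ΔΓₙ/(n·f₀) (ppm).  The sign convention is anchored by the
  Sauerbrey limit: a purely inertial load Z_L = iωm_a must give
  Δfₙ = −2nf₀²m_a/Zq exactly, with ΔD = 0.  Damping as a complex
  stiffness is the simplest passive model: it guarantees ΔD ≥ 0 at all
  frequencies and removes the lossless pole at ω = ω_p.  The lossless
  frequency shift changes sign exactly once, at the bond resonance.

## Equilibrium shift extraction

Δf_eq(n) and ΔD_eq(n) are window means: (post-rinse plateau) − (pre-injection
baseline).  A window is the longest trailing window (at a resolution of
half the minimum duration, default 30 min) whose fitted drift passes a
stationarity test; the fitted drift is the larger magnitude of the OLS and
Theil–Sen slopes, which keeps the test sensitive both to noise-robust
trends and to localized settling transients a median-based slope alone
would ignore.  A window passes when the drift is below the tolerance
(defaults 0.5 Hz/h and 0.1 ppm/h) **or** within `slope_z` (default 4)
standard errors of zero.  The second clause matters in batch work: the
slope of a pure-noise 30–60 min window has a standard error comparable to
the dissipation tolerance, so a fixed threshold alone would intermittently
reject perfectly stationary baselines when thousands of windows are
fitted; a 4σ gate makes such false failures negligible without masking
any drift larger than the noise floor.  When no window passes, a
stabilization error carrying the best achieved slope is raised, naming
the overtone and channel.

Window standard deviations are propagated in quadrature into the shift
uncertainties.  All derived quantities are invariant under constant
offsets of the raw series.

## Rigidity ratio

|ΔD/Δf| (ppm/Hz) removes the dependence of dissipation on the amount of
adhered material; it is reported as a magnitude (low = rigid, well-coupled
adlayer; high = soft/hydrated).  The signed ratio is kept internally by
the segmentation logic.

## Phase segmentation

The (Δf(t), ΔD(t)) trajectory between injection and rinse is classified
pointwise from sliding-window linear-fit derivatives (window default
0.5 h, which is also the tolerance within which detected boundaries
should be trusted):

* hook — df/dt > f-tolerance and dD/dt < −D-tolerance (must be sustained
  ≥ 1 h, otherwise demoted to reversal drift);
* buildup — dD/dt > D-tolerance; sub-split into contact initiation vs
  soft buildup by comparing |dD/df| against `steepening` (default 2×) the
  reference slope taken at the fastest frequency drop within the first
  window, where initial attachment dominates;
* reversal drift — df/dt > f-tolerance at flat D;
* rigid plateau — everything else (flat D, frequency flat or still
  falling).

Consecutive equal states are merged and runs shorter than `min_segment`
(default 0.5 h) are absorbed into their predecessor (the first run is
exempt so that a brief initial-contact phase survives).  Slope tolerances
default to 0.5 Hz/h and 0.1 ppm/h.  Labels are stable (≥95% identical
sequences over seeds) for added Gaussian dissipation noise up to the
`noise_margin` (0.05 ppm).

## Sign patterns and distance bounds

Sign calls use a dead-band |Δf_eq| ≤ max(z·sd, 0.5 Hz) (z default 1);
overtones inside the dead-band are indeterminate and skipped.  The
determinate pattern must be single-crossing (all negatives below all
positives in n); anything else raises an ambiguity error rather than a
guess.  Bounds: mixed patterns report d < δ(last negative n) — the depth
at the bracket's lower overtone, not an interpolated crossing — and
all-positive patterns report d > δ(smallest measured n).  All-negative
patterns report direct contact with no numeric bound; an all-indeterminate
set is an explicit no-call.  The reported bound is bit-identical to the
corresponding entry of the estimate's depth table (no recomputation
drift), and flipping positive shifts to negative can never increase a
reported bound.

## Mass reconciliation

Microscopy densities (cells/mm²) convert to areal mass with a per-cell
wet mass (default 1 pg, typical for hydrated E. coli; a configuration
value users should confirm for their strain).  The Sauerbrey prediction is
evaluated at n = 3.  Rows with Δf_eq(3) > 0 carry an undefined prediction
flagged "elastic loading - Sauerbrey inapplicable"; negative masses are
never emitted.

## Synthetic experiments

The generator drives the coupled-resonator forward model with attachment
kinetics and adds a phenomenological dissipation channel and seeded
Gaussian noise:

* Kinetics are sums of saturating terms anchored in Hz at n = 3: a fast
  initial-contact term, a slow accumulation term, an optional
  overshoot-recovery (a fraction of the initially attached material
  detaches again), an optional late hook detachment, and a rinse-removal
  step.  The anchor curve converts to areal density N_s(t) through the
  per-particle response at n = 3, so the same kinetics serve inertial and
  elastic archetypes.
* Each saturating term is a *clamped* exponential: exponential in shape
  but rescaled to reach its target exactly after four time constants and
  exactly constant afterwards.  A pure exponential never settles, which
  would make "the plateau value" ill-defined at the 1e-9 Hz level and
  smear the kinetic knots the segmentation tests recover; the clamp keeps
  the familiar shape while making plateaus and change-point times exact.
  The generator reports these exact equilibria and knot times as ground
  truth alongside the trace.
* Dissipation is the sum of the (small) physical bond loss and a
  trapped-water term with its own kinetics, scaled by sqrt(3/n) across
  overtones to mimic the shrinking sampled volume.  A point-bond loss
  tangent alone produces ΔD/|Δf| of order 10⁻³ ppm/Hz, two to three
  orders below what hydrated bacterial adlayers show — the viscous losses
  live in the interfacial water, not in the tether — so the water channel
  carries the realistic D magnitudes and the phase structure of the
  D-versus-f trajectory.
* Noise is i.i.d. Gaussian per sample (defaults 0.2 Hz, 0.1 ppm — well
  below typical between-replicate spreads, so batch statistics are
  stable).

Six presets cover the archetypes: `c8_like` (inertial-rigid, hook at 45 h
after injection), `nh2_like` and `cooh_like` (inertial-dissipative with
overshoot recovery), `oh_like` (mixed, bond resonance 60 MHz, crossing
between n = 11 and 13), `oeg_like` (mixed, 20 MHz, crossing between n = 3
and 5) and `sb_like` (fully elastic, 10 MHz).  The archetype category is
validated against the sensor at simulation time: inertial presets must
have ω_p above the highest measured overtone frequency, fully elastic
presets below the lowest, mixed presets strictly between two adjacent
ones.  Default runs last 50 h (injection at 1 h, rinse at 47.5 h) at a
0.01 h sampling step (5001 samples), which keeps a hundred-run batch under
a minute on one CPU.

Cell-density tables are Poisson field counts (default six fields of
0.01 mm², the scale of a 100 µm × 100 µm micrograph) converted to
cells/mm².

### What the generator does and does not emulate

It reproduces the qualitative structure the analysis depends on: the sign
pattern across overtones as a function of bond resonance placement, the
kinetic phases (initial drop, buildup, plateau, reversal, hook, rinse),
rigidity-ratio ordering between archetypes, and realistic noise.  It does
**not** model the finite sampling depth of the shear wave with respect to
the cell body, so inertial presets show |Δf| increasing with n whereas
real bacterial layers (thick compared with δ) show the opposite ordering;
inter-overtone magnitude ratios are therefore not meaningful test
targets — only signs, time structure and n = 3 anchors are.  Passing
tests demonstrate correct recovery of the model's structure, not
instrument-level realism of every curve.

## Numerical choices and degenerate inputs

* Stationarity fits subsample Theil–Sen to ≤ 201 points per window;
  candidate window starts step at half the minimum duration ("longest
  passing window" therefore holds at that resolution).
* Rolling derivatives in the segmentation assume a near-uniform time
  grid (uniform-filter moments; edges use nearest-sample padding).
* The lossless coupled resonator raises a singularity error within a
  10⁻¹² relative band of its pole instead of returning a huge number.
* Zero measured particles (N_s = 0) produce exactly zero shifts; a zero
  frequency shift makes ΔD/Δf an explicit error, not infinity.
* A normalized-dialect file round-trip is exact only to ~1e-14
  relative (division/multiplication by n is not always lossless in
  binary64); the raw dialect round-trips bit-identically.

## Known limitations

* No continuum viscoelastic (Voigt-type) film fitting; the package
  interprets shifts through the tethered-particle picture only.
* The distance bounds are bracket statements tied to the measured
  overtone set; no interpolated f_ZC or continuous distance inversion is
  attempted, and no bound is invented for the direct-contact case.
* Event times must be supplied (file header or config); there is no
  automatic injection/rinse detection.
* The per-cell mass in the mass reconciliation is a stated assumption;
  water and extracellular polymer corrections are not modelled.
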