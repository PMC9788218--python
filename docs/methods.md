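# Methods

## Scope and structure

`trtsim` models one experimental paradigm: a subcutaneous xenograft
treated once (or repeatedly) with an intravenous alpha-emitter, followed
by caliper volume measurements. The pipeline is
delivery → dosimetry → response → estimation, with a synthetic-cohort
generator closing the loop for testing.

## Delivery model

A linear four-compartment system (blood, tumor, body organs, excretion)
with first-order transfer and a uniform physical decay rate
y = ln2 / half-life. Activities are carried in MBq; the absolute number
of nuclides differs by a constant that cancels in every downstream use.
Time is hours in the delivery and dosimetry layers and days in the
response layer; the dose rate is converted (×24) exactly once, at the
`DoseInput` boundary.

Default transfer coefficients (per hour): blood→tumor 0.33, blood→body
1.0, blood→excretion 0.5, tumor→blood 0.1, body→blood 0.5. These are
fixed values reproducing observed biodistribution behavior, not fitted
by this package (fitting them is out of scope).

**Numerics.** The full system is integrated with LSODA after factoring
out physical decay: the solver works on S_i = R_i·e^{+yt}, whose
transfer matrix conserves ΣS exactly, and the decay factor is reapplied
afterwards. This makes the relative error of the mass balance
R_T = Q·e^{−yt} independent of how far the total has decayed — in raw
coordinates an absolute solver tolerance would dominate once R_T
underflows toward zero at late times for short half-lives. Tolerances
are rtol 1e-10 / atol 1e-12, leaving two orders of margin under the
1e-8 conservation contract. Solver undershoot below −atol raises rather
than being clipped; values in [−atol, 0) are clamped to zero.

The no-return closed form (used for all dosimetry) ignores the stored
return coefficients by construction; with the defaults the difference is
small because the tumor→blood return (0.1/h) is slow compared with decay.

## Dosimetry

Dose rate is proportional to resident tumor activity:
d(t) = k·R₂(t) with k = 5.45 Gy·h⁻¹·MBq⁻¹ for a 1.5 g tumor. The
constant is taken as a configured value; note that averaging the two
alpha energies of the decay chain (5.9 and 7.5 MeV) over a 1.5 g mass
would give ≈2.6 Gy/h, so k as used here corresponds to a larger energy
deposition per decay. The package treats it as an input, not a derived
quantity.

Cumulative dose uses the closed-form partial integral of the analytic
tumor activity whenever the analytic model is in use; trapezoid
accumulation is used only for the numeric (return-path) variant. "Total
dose" always means the closed form Q·k·α₁₂/(yA), never a truncated
numeric integral. Repeated injections superpose linearly, which is exact
for a linear time-invariant ODE.

## Tumor response

Three nested models:

1. **Basic kill**: dN/dt = (λ − b·d)·N·(1 − N/Nm). The saturation
   bracket multiplies the whole (λ − b·d) term, kill included — the
   model is implemented exactly as written even though bracketing only
   the growth term would be more conventional.
2. **Volume delay**: damaged cells accumulate as dN_D/dt = b·d·N and
   contribute volume V_D(t) = v·N_D(t)·e^{−c(t−t₀)} with t₀ = 0. This
   literal form is justified by time-scale separation: irradiation is
   over within a day while clearance takes 1/c ≈ 10 days. An
   alternative continuous balance dV_D/dt = v·b·d·N − c·V_D is available
   behind `continuous_clearance=True` for sensitivity checks; the two
   agree within a few percent after the dose is complete.
3. **Impaired regrowth**: λ_mod(t) = λ / (1 + D(t)^{1/4}). The quartic
   root encodes that even large doses reduce, but do not abolish,
   regrowth (9.7 Gy gives λ_mod ≈ 0.051/day from λ = 0.14/day). The
   exponent placement follows the 1/(1 + D^{1/4}) reading; this is a
   design choice where the algebra could be read otherwise.

Parameters and units: λ = 0.14/day (control-cohort mean), b = 0.3/Gy,
c = 0.1/day, N₀ = 2×10⁹ cells, Nm = 4×10¹⁰, V₀ = 577 mm³ (cohort mean
initial volume). The apparent cell volume defaults to v = V₀/N₀ so that
V = vN holds at t = 0, and Vm = v·Nm (= 20·V₀ at the default N₀/Nm).
`Nm = inf` disables saturation and recovers the exponential limit
V = V₀e^{λt}.

**Numerics.** LSODA with rtol 1e-9; the dose input is a linear
interpolant that is zero after the profile's end, and integration is
restarted at the interpolant's breakpoints so that arbitrarily narrow
dose pulses are resolved (an adaptive solver stepping across a 1e-3-day
pulse would otherwise miss it entirely). In the impulse limit the
surviving fraction converges to e^{−bD}; the residual relative error at
pulse width w is λw (the growth accrued during the pulse), ≈1.4e-4 at
w = 1e-3 day.

The caliper-volume helper assumes an oblate ellipsoid with the long
caliper axis duplicated, V = (π/6)·L²·W; the sphere limit of a 10 mm
tumor (≈524 mm³) matches the volume scale at which treatment starts in
this paradigm. The formula choice (which axis is duplicated) is a
convention; the alternative prolate reading would give (π/6)·L·W².

## Estimation

Per-animal ordinary least squares of ln V on t over [0, 10] days, day 0
being the animal's first measurement; λ̂ is the slope and V̂₀ = e^intercept.
This is the standard reading of "fitting V = V₀e^{λt}" and inverts clean
exponential data exactly. Cohorts are summarized by arithmetic mean and
sample SD (n−1); a single-animal cohort reports SD = 0 with a
`degenerate` flag rather than raising. Fitting the treatment parameters
(b, c, the λ_mod exponent) to treated trajectories is deliberately not a
headline feature — in this modeling paradigm they are hand-tuned — though
nothing prevents a user from wrapping `simulate_full` in a least-squares
loop.

A caveat the tests document explicitly: when data are generated by the
full logistic model with the default Nm = 20·N₀, the exponential-window
fit is biased low by roughly 10–15%, because the logistic bracket
already bends the curve inside the 10-day window (the bracket is 0.95 at
t = 0). The estimator is therefore validated for bias and spread in the
exponential regime (Nm = ∞), which is the regime its defining equation
assumes; against the saturated generator only the direction of the
misspecification bias is asserted.

## Synthetic cohorts

The generator emulates a four-group treatment experiment (control, 0.1,
0.4, 1 MBq by default) aligned on treatment day: each animal draws
λ_i from a normal with mean 0.14/day and SD 0.08/day truncated at
0.01/day (no spontaneously shrinking controls), and V₀_i from a
lognormal moment-matched to mean 577 mm³ / SD 372 mm³ (positivity
guaranteed); it is then simulated with the full model under its group's
dose profile and observed every 2 days to day 30 with i.i.d.
multiplicative lognormal noise of log-SD 0.15. The noise magnitude and
schedule are fixture conventions chosen to look like real caliper data,
not measured values. Tables are byte-identical for a fixed seed.

What the fixtures do **not** emulate: welfare-endpoint censoring of
large tumors, the occasional complete responder that never regrows,
correlated measurement error within an animal, and any deviation of the
true biology from the model's own dynamics. Passing round-trip tests
therefore demonstrates internal consistency of the pipeline, not
external validity.

The comparison target for recovery tests is the mean of the truncated λ
law (computed via `scipy.stats.truncnorm`), since that — not the
untruncated 0.14 — is the mean of the distribution actually sampled.
Group-level dose–response ordering is asserted on geometric means of
day-30 volumes: with per-animal rates spread by SD 0.08/day, day-30
volumes vary as e^{30λ}, so arithmetic group means are dominated by the
fastest grower and are not a stable finite-n statistic, while the log
scale is where the growth model is linear.

## Problem sizes

Reporting grids default to 0–48 h at 0.01 h for delivery, 0–96 h for
dose profiles (≥99.99% of the total dose is delivered by 96 h), and
0–40 days at 0.1 day for response scenarios. Monte-Carlo checks use
100–1000 replicates; the synthetic-cohort recovery check uses 100
control animals. All are comfortably converged for the tolerances
asserted alongside them.

## Known limitations

- The delivery topology is fixed to the four-box structure; only the
  rates are configurable.
- Dosimetry is tumor-only and macroscopic: no organ doses, S-values,
  microdosimetry or RBE weighting.
- The response model is deterministic; no birth–death stochasticity,
  cell-cycle, hypoxia, immune or stem-cell compartments.
- The 5.45 Gy·h⁻¹·MBq⁻¹ constant and the transfer coefficients are
  inputs inherited from the modeled experimental system; transferring
  them to another compound, tumor line or nuclide requires re-derivation.
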