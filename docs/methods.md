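# Methods

This note records the models implemented in `epferm`, the assumptions
behind them, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Uniform design construction

A U-type design U_n(n^s) places n runs over s factors at n levels each so
that every factor column is a permutation of the level set. Candidate
columns come from the good-lattice-point method: with modulus m and
generator h coprime to m, column h holds (i·h mod m) for runs i = 1..n.
When Euler's totient of n supplies enough coprime generators the lattice
is built modulo n directly; otherwise (e.g. n = 10, where only 4
generators exist but 6 factors are needed) the standard plus-one variant
builds the lattice modulo n+1 and drops the all-equal last row, which
preserves column balance.

Among the candidate columns the constructor selects the s-subset with the
smallest centered L2-discrepancy of the run points mapped to the unit
cube (levels u → (u−0.5)/n), by exhaustive enumeration; at n = 10 this is
C(10,6) = 210 subsets and takes milliseconds. Exhaustive search makes the
choice verifiable against an independent brute-force oracle, which the
test suite does. Explicitly supplied generators are validated for
coprimality and used as-is.

The packaged 10-run fixture carries its measured yield responses and is
checksum-validated on load; factor levels are stored in the table's native
g/100 mL, and conversion to g/L is an explicit ×10 helper (`to_g_per_L`),
never implicit.

## Mono-factor screening statistics

Screening results arrive as group mean ± SE of n = 3 replicates (the
"±" of such screens is treated as a standard error; that and n = 3 are
assumptions, recorded here). The one-way ANOVA is reconstructed exactly
from the summaries: per-group SD = SE·√n, within-group mean square =
mean of the SD², between-group mean square from the means. Dunnett
many-to-one comparisons use the pooled t statistics; the familywise
adjustment samples the joint null of the max-|t| statistic by seeded
Monte Carlo (default 100,000 draws) instead of critical-value tables —
there is no closed form, and the sample is reproducible by seed. Adjusted
p-values are floored at the unadjusted ones, so Monte-Carlo noise can
never make the adjustment anti-conservative. Zero pooled variance with
unequal means is refused as degenerate.

## Response-surface model

The yield model is fixed — quadratic in sampling time and glycerol,
linear in the other five factors, no interactions, no term selection —
and fit by OLS with the classical variance estimate for per-term SE/t/p
and the overall regression F (df 9, 30 on the packaged table). Factor
units inside the model are g/100 mL.

Optimum recommendation: a concave quadratic factor takes its vertex
−α/(2β), clamped into the tested range if outside; a convex one falls
back to the better range endpoint with a warning; linear factors take the
upper bound when the coefficient is positive, else the lower. Predictions
are straight polynomial evaluation, deliberately not clipped at zero —
negative predictions warn instead, preserving linear-model semantics.

On the packaged table the refit reproduces the reference coefficient
table to printed precision (time coefficient 8.617, model F 7.454). The
predicted yield at the recommended medium and an 80-h harvest is
~218 μg/L by direct evaluation of the fitted polynomial; this is the
value the package reports.

## Structured growth models

All four rate laws treat glycerol as the single limiting substrate; the
mycelium pellet is an idealized reactor with no internal mass-transfer
resistance, enzyme capacity proportional to biomass, and product
formation proportional to substrate consumption. Oxygen, death phase,
and temperature/pH dependence are out of scope. The product-inhibition
rate is implemented in the multiplicative form
μ = μmax·[Cs/(ks+Cs)]·[kp/(kp+Cp)], the only form consistent with its own
integrated equation.

Yield coupling closes the system: X = X0 + Yb(C0−Cs), Cp = Yp(C0−Cs).
Product units follow Yp: when modelling EP, Yp carries μg product per g
substrate and Cp is in μg/L — no hidden conversion.

### Simulation

Only the substrate ODE dCs/dt = −μX/Yb is integrated (adaptive explicit
Runge-Kutta, rtol 1e-8, atol 1e-10, dense output sampled on the user
grid); biomass and product follow the coupling identities exactly, so
conservation holds to solver precision. Substrate is floored at
1e-9 g/L. With optional first-order product decay kd the product channel
is integrated alongside (dCp/dt = −Yp·dCs/dt − kd·Cp) and, for the
product-inhibited law, feeds back into μ.

Fed-batch runs integrate (Cs, X, Cp) between discrete feed events; each
event applies an instantaneous mass balance (V′ = V+ΔV,
Cs′ = (CsV+m)/V′, X′ = XV/V′, Cp′ = CpV/V′) that conserves total
biomass and product mass exactly; the output repeats each event time with
the pre- and post-event state.

### Integrated (linearized) forms and fitting

With yield coupling each rate law integrates in closed form to
t = Σ bⱼ·φⱼ(Cs) + C with transforms φ among {ln[Cs/(C0−Cs)], ln(C0−Cs),
ln Cs, Cs}. Three derivation details matter:

* **Effective initial substrate.** The coupling forces X = 0 at Cs = C0
  unless an inoculum is carried explicitly; the closed forms stay exact
  with C0 replaced by C0_eff = C0 + X0/Yb. Fits default to C0_eff = C0
  when the inoculum is unknown.
* **Substrate-inhibition sign.** Re-derivation of the Andrews integral
  gives +Cs/(ki·μmax) for the linear-in-Cs term; the re-derived sign is
  implemented and validated against the ODE oracle.
* **Product-inhibition with an inoculum.** Biomass couples to C0_eff but
  product to C0, so the inhibition denominator becomes
  kp_eff + Yp(C0_eff−Cs) with kp_eff = kp − Yp·X0/Yb; the two log terms
  of the closed form scale by kp_eff/kp. The oracle test covers this.

The four-transform set of the product-inhibition form is exactly
collinear (ln[Cs/(C0−Cs)] = ln Cs − ln(C0−Cs)), so its regression runs on
the reduced basis {ln(C0−Cs), ln Cs, Cs} — the same reduction statistical
packages apply silently — and (μmax, ks, Yp/kp) are recovered by solving
the reparameterized coefficient equations, a quadratic in μmax whose
admissible (all-positive, with kp_eff/kp ∈ (0,1]) root is unique away
from degeneracies. Only the ratio Yp/kp is identifiable from substrate
data; a known Yp splits out kp.

Fitting regresses t on the transforms (the direction in which the closed
form is linear), always with intercept. The t = 0 point sits on the log
singularity and is dropped with a logged count. For noisy data an
explicit `min_consumed` option extends this rule: ln(C0_eff−Cs) amplifies
relative measurement noise by Cs/(C0_eff−Cs), so samples whose consumed
substrate is within a few noise SDs of zero are excluded (and counted)
rather than allowed to dominate the fit. The regressor condition number
is reported; above 1e6 the result carries a warning, above 1e10 the fit
is refused as collinear. Model comparison fits all four laws and ranks by
adjusted R², then F, then parsimony; individual failures are flagged, not
raised.

**Identifiability caveat.** Saturation parameters are only well
determined when the trajectory spans both the saturated and the
substrate-limited regime. Under the calibrated reference conditions only
~39% of substrate is consumed by 80 h; there the two log transforms are
nearly affine and 2% measurement noise produces parameter errors well
above 100%. The parameter-recovery studies therefore sample 20 points to
160 h (near-complete consumption), where median recovery errors at 2%
noise are 6–9% for μmax and ks over 100 seeds. Fit quality (R²) is
insensitive to this: the linearized fits exceed R² = 0.98 on the 112-h
calibrated noisy trajectory.

## Synthetic-data generator

Design responses are the response polynomial evaluated on the design grid
plus additive Gaussian noise (the OLS error model); they are deliberately
not clipped at zero. Trajectories are noiseless simulations with
independent mean-one multiplicative log-normal noise per measured channel
(concentrations are positive; σ is chosen so the coefficient of variation
equals the requested CV). Both are bitwise-reproducible by seed.

Defaults (versioned in `data/default_batch.yaml`, derivation in
`scripts/calibrate_defaults.py`): Monod, ks = 15 g/L, μmax calibrated by
forward simulation to carry substrate from 34.34 to 21.02 g/L in 80 h
(≈ 0.05 1/h), Yb = 0.5 g/g, X0 = 0.5 g/L (a 10% v/v inoculum), Yp =
19.6 μg/g so that the consumed substrate maps to a product scale of
~260 μg/L, channel CVs 2%. The design-noise SD default (10 μg/L) is a
free choice — the screening table carries no replicate variance.

What the generator does *not* emulate: absolute product yields of real
fed-batch runs (the group fixtures target only the qualitative ordering
glycerol feed ≥ water ≥ none, which product-inhibited kinetics with
μmax = 0.1, ks = 5 g/L, kp = 150 μg/L reproduce deterministically), and
the post-peak product decline of real runs. The optional first-order
decay kd is an explicit extension for the latter — but note that under
yield-coupled production the product can only peak after the production
rate μX does, which for the calibrated substrate profile happens near
100–105 h; a mid-run peak (as real fermentations show near 76 h) is not
reachable by decay alone while only ~40% of the substrate is consumed.
Default kd = 0 keeps the generator exactly on the coupled model.

## Degenerate inputs and tie-breaks

Zero quadratic coefficient → no stationary point (error); convex
quadratic → endpoint comparison with warning, ties to the upper end;
linear coefficient exactly zero → lower bound. Constant-substrate series
→ collinearity/insufficient-data errors. Discrepancy ties in column
selection break to the lexicographically first subset, making
construction deterministic. Dunnett Monte-Carlo p-values are floored at
the unadjusted p. Exit codes in the CLI separate usage (2), data (3) and
numeric (4) failures.

## Known limitations

* The linearized fits inherit errors-in-variables bias from transforming
  noisy substrate measurements; they are the method implemented here by
  design, not a general recommendation over nonlinear least squares.
* Contois ks is recoverable only as ks·Yb without a known biomass yield;
  product-inhibition kp only via a known Yp.
* The fed-batch group ordering is a property of the chosen
  product-inhibition defaults; under pure Monod kinetics water addition
  slightly *lowers* final product mass.
* No oxygen transfer, death phase, logistic/unstructured growth, pH or
  temperature effects.
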