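# Methods

## Kinetic models of the MOMP switch

Both network variants share one backbone, in nM and seconds:

- Mcl-1 turnover: dM/dt = σ_M − δ_M·M − α_M·M·B₁ + β_M·MB, with synthesis
  σ_M = 5×10⁻⁶ nM/s and degradation δ_M = 1.3×10⁻⁴ /s (a mitotic Mcl-1
  half-life of ~1.5 h).
- Sequestration: M + B₁ ⇌ MB, α_M = 0.05 /nM/s, β_M = 0.5 /s
  (K_M = 10 nM). Mcl-1 binds only the Bak monomer.
- Oligomerization ladder: B_n + B_n ⇌ B_2n for n = 1, 2, …, A/2. The
  monomer→dimer step uses α₁₂ = 0.05 /nM/s, β₁₂ = 500 /s, the dimer→tetramer
  step α₂₄ = 0.05 /nM/s, β₂₄ = 0.05 /s, and all higher steps 1 /nM/s and
  1 /s. Pore sizes are powers of two; anything else is rejected.
- CytC exchange, driven only by the size-A pore:
  dC_c/dt = γ_m·[B_A]·[C_m] − γ_c·[C_c], with γ_c = 0.5 /s and a
  model-specific γ_m (5000 /nM/s for the tetramer model, 0.5 /nM/s for the
  256-mer model, as bundled in `data/reference_params.yaml`).

Total Bak (in subunits, including MB) and total CytC are conserved;
every simulation asserts both to a relative 10⁻⁶ (achieved: ~10⁻¹⁵).
Initial conditions: M = 3000, MB = 1000 (hence B_T = 1000), C_m = 1000 nM,
all oligomers empty.

Integration uses `scipy.integrate.solve_ivp` with the BDF stiff solver,
rtol 10⁻⁸ / atol 10⁻¹⁰ nM. The output grid (default 10 s) only affects the
linear interpolation used for crossing times; 10 s keeps the interpolation
error far below 1% of any reported duration. Nonnegativity is enforced by
solver tolerance, not clipping: values in (−10⁻⁹, 0) nM raise a warning,
anything lower an error carrying the last valid state. A threshold crossed
more than once raises an ambiguity error rather than returning the first
crossing.

Switch metrics: the MOMP delay T_c is the first time the cytoplasmic CytC
fraction C_c/(C_c+C_m) reaches 1/2; the switch duration ΔT is its 0.1 → 0.5
rise time.

## Quasi-static closed forms

When Mcl-1 decay is slow compared with binding, oligomerization and CytC
exchange, free Mcl-1 obeys M(t) = M_s + (M₀−M_s)e^(−δ_M t) with
M_s = σ_M/δ_M, Bak monomer follows the isotherm B₁ = B_T/(1+M/K_M), and
the CytC fraction is the Hill function B₁^A/(B₁^A+K_C^A), evaluated in log
space so A = 256 cannot overflow. K_C — the monomer level at half-maximal
steady release — is calibrated per model by clamping B₁, propagating the
ladder equilibrium in log space, and root-finding where the steady pore
concentration equals γ_c/γ_m (for the bundled constants: K_C = 10 nM at
A = 4, 100 nM at A = 256, both matching the closed-form
(γ_c/γ_m · ∏K)^(1/A)).

Inverting the Hill function gives M_x = K_M(B_T/B₁(x) − 1) with
B₁(1/2) = K_C and B₁(1/10) = K_C·9^(−1/A), hence
T_c = (1/δ_M)·ln[(M₀−M_s)/(M_½−M_s)] and the sharpness bound
ΔT ≥ ln 9/(A·δ_M), with equality exactly in the fully sequestered regime
M ≫ K_M. All closed forms retain the synthesis floor M_s; σ_M = 0 recovers
the floorless expressions.

**Validity regime.** The reduction assumes (i) fast ladder equilibration,
(ii) a small oligomerized Bak fraction, and (iii) negligible Mcl-1:Bak
buffering at the threshold, i.e. M_½ ≫ √(B_T·K_M). With the bundled
constants the tetramer model satisfies all three (numeric vs closed-form
delay agree to <1%), but the 256-mer threshold sits at B₁ ≈ 100 nM where
buffering (dMB/dM ≈ 1) and bulk redistribution of Bak into the oligomer
pool (~0.5·B_T at threshold) dominate — there the closed forms
underestimate both T_c and ΔT severalfold, which is why the bundled 256-mer
simulation is *less* sharp than the tetramer one. The property tests
therefore probe the reduction where its assumptions hold (K_M raised to
100–1000 nM and M₀ to 30 µM, thresholds well above the buffering zone):
across δ_M ∈ [10⁻⁵, 10⁻³]/s and A ∈ {4, 256} the closed-form delay then
agrees with the full network to 10%, and the switch sharpens strictly with
pore size while always respecting the ln 9/(A·δ_M) bound. The bound itself
holds in *every* simulated configuration, buffered or not.

## Threshold death-time model and population curves

For A → ∞ the Hill function becomes a step, and with Bcl-xL added at
steady state a cell dies when its total inhibition
I(t) = m₀e^(−t/τ_M) + x₀e^(−t/τ_X) decays through θ ≈ B_T/K_c. The
biochemical constants (K_M, K_X, K_c) are absorbed into the dimensionless
m₀, x₀, θ, so only measurable ratios enter. Death times use the
single-exponential closed form when x₀ = 0 and otherwise vectorized
bisection on [0, 10·max(τ_M, τ_X)] (bracket doubled as needed, ~105
halvings → resolution far below a second in hour units; I(t) is monotone,
so bisection is guaranteed). Cells at or below threshold at arrest onset
die at t = 0; optional decay floors (m_s, x_s, default 0) can keep I above
θ forever, returned as +inf.

Populations draw ln M ~ N(μ_m, σ_m²), ln X ~ N(μ_x, σ_x²),
ln B ~ N(μ_b, σ_b²) independently (a covariance hook is deliberately
absent); ratios are m₀ = M/B, x₀ = X/B, and the threshold scales with Bak:
θ = θ_ref·B/B_ref, B_ref = e^(μ_b). RNAi knockdown multiplies the targeted
protein's median by a factor in (0, 1], leaving spreads unchanged. "Fold
variation" is reported as e^(2σ), the 84th/16th-percentile ratio.

Survival curves S(T) = P(t_c > T) come from two independent routes:
Monte Carlo over sampled cells, and deterministic quadrature. The
quadrature exploits that survival at T is the event
M·e^(−T/τ_M) + X·e^(−T/τ_X) > (θ_ref/B_ref)·B²: for σ_b > 0 the
probability over B has the log-normal closed form
Φ[(ln I_T − ln θ_ref − μ_b)/(2σ_b)], an analytic integrand that
Gauss–Hermite quadrature (default 40 nodes/dimension) integrates to ~10⁻⁶;
for σ_b = 0 the probability over M is taken in closed form and the
remaining Bcl-xL dimension handled by a dense Gauss–Legendre rule, which
tolerates the hard-threshold kink. The two routes agree to a maximum gap
of ~10⁻³ at n = 2×10⁵ cells (Monte-Carlo noise). Integrating over Bak
analytically rather than over Mcl-1 matters: the Mcl-1-integrated form has
a non-analytic flat transition where Bcl-xL alone exceeds threshold, and
Gauss–Hermite converges pathologically slowly on it.

## Exit-corrected survival from fate tables

Fate tables are tab-separated text (`cell_id, entry_h, fate, fate_h`;
fates death/exit/censored; each cell's clock starts at its own arrest
entry). Death and exit are treated as independent competing risks with
cause-specific hazards; each is estimated per time bin as events divided by
(cells at risk at bin start × bin width), cells leaving the risk set at
their fate time. The corrected (death-only) survival is
S(T) = exp(−Σ_{bins≤T} δ·Δt), the exit curve E(T) = 1 − exp(−Σ ε·Δt); bins
with an empty risk set yield undefined hazards and the gap is propagated,
never interpolated. No smoothing is applied.

The default bin width is 1 h (configurable); validation tests use 0.25 h,
matching 10-minute imaging frames. The at-risk-at-start convention biases
each hazard low by a factor ≈ 1 − (δ+ε)·Δt/2, so fine bins matter when
total event rates approach 0.3/h; at 0.25 h bins the residual bias in
S(10 h) is well inside Monte-Carlo error at n = 2000 cells. A
Nelson–Aalen estimate (lifelines) of the same cause-specific cumulative
hazard serves as an independent cross-check in the tests.

## Constrained fitting

`fit_decay` estimates (A₀, τ) of f(t) = A₀e^(−t/τ) by nonlinear least
squares seeded from the log-linear regression; non-decaying series pin τ at
an upper limit with a warning.

The survival-curve calibration is a two-stage search over
(μ_m, σ_m, μ_x, σ_x, σ_b, τ_M, τ_X, knockdown_m, knockdown_x), coordinates
log-transformed except the already-log μ's. Stage 1 samples n_random
vectors uniformly in the transformed box; stage 2 runs compass (pattern)
search from the n_starts best: poll ±step along each coordinate, accept
the best strict improvement, halve the step otherwise; initial step 0.25,
termination at step < 10⁻³ or 500 iterations. Descent is monotone by
construction, and the objective — summed squared residuals against the
data curves, with model curves from the deterministic quadrature — is
noise-free, so the search is reproducible given its seed.

Constraints enter as hard box bounds: τ_M within the interval implied by
the measured half-life (the harness uses ±7% around a triplicate decay-fit
mean, reflecting that estimator's ~2–3% spread), protein-ratio medians
within blot mean ± 2 SD, knockdown factors within [0.05, 0.5] (plausible
residual after RNAi). The threshold θ_ref is fixed at 1 rather than
fitted: scaling both protein medians and θ_ref together leaves every death
time unchanged, so θ_ref only chooses the unit in which ratios are
expressed and is structurally unidentifiable from survival data. With
knockdown conditions absent, μ_m and μ_x are confounded with the spread
and decay nuisances; the tests demonstrate that adding the two knockdown
curves shrinks the median recovery error of the pair by well over 2×.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs: death
times from the log-normal threshold population; mitotic exit as an
independent piecewise-constant hazard (default: zero for the first 5 h of
arrest, then 0.1/h — a delayed-slippage profile); censoring at the imaging
horizon (default 72 h); blot replicates and decay time courses as
population medians with multiplicative log-normal noise (default log-SD
0.2 for blots, 0.05 for decay series). All randomness flows through one
seeded generator per ground truth, split into independent child streams
per artifact, so regenerating with a modified death process leaves the
exit draws bit-identical — the property exploited by the independence
diagnostics. A hazard-override mode draws death times from a specified
hazard instead of the threshold model, used to validate the
competing-risks correction against exact constant-hazard truth.

The reference synthetic cell line
(μ_m = ln 50, μ_x = ln 0.6, σ_m = σ_x = 0.5, σ_b = 0.25, τ_M = 2 h,
τ_X = 24 h, θ_ref = 1) was chosen once as a line where both inhibitors
matter: control deaths center near 9 h of arrest and knocking down either
protein visibly accelerates death; spreads of 0.5 give ~e-fold (2.7×)
cell-to-cell variation. What the generator does *not* emulate: correlated
protein levels, time-varying death hazards beyond those induced by the
threshold model, post-slippage death, measurement error in fate timing, or
imaging-frame discretization. Passing tests therefore validate the
estimators and the fitting machinery under the model's own assumptions,
not the biological adequacy of those assumptions for any particular cell
line.

## Problem sizes

Defaults used by the test suite and analysis scripts: ODE horizons 30–50 h
on a 10 s output grid; survival grids of 33–97 points over 48 h;
Monte-Carlo cohorts of 2×10⁵ (curve validation) and 2–4×10³ (fate tables);
recovery fits with n_random = 1600, n_starts = 8, ≤150 compass iterations,
3 seeded replicates. These sizes give estimator noise comfortably below
every asserted tolerance while keeping a full run in minutes on one CPU.

## Known limitations

- The bundled 256-mer translocation constant places that model deep in the
  buffered regime, where its simulated switch is broader than the
  tetramer's; sharpening with pore size — the central cooperativity effect —
  appears once thresholds sit in the quasi-static regime (see the sweep
  script). The closed forms are quantitative only in that regime.
- The finite-A network deliberately omits explicit Bcl-xL:Bak kinetics
  (Bcl-xL enters only through the A → ∞ threshold model), so
  finite-A-vs-threshold consistency is checked at x₀ = 0.
- Exit hazards are estimated without smoothing; with < ~500 cells the exit
  curve is noticeably step-like.
- The pattern search is a local method; with the prescribed random-start
  stage it reliably finds the basin on the tested problems, but SSE
  near-ties along weakly identified directions (e.g. knockdown factor vs
  spread) are reported in the restart table rather than resolved.
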