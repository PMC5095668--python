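# mitoswitch

Kinetic and statistical models of the apoptotic switch that kills cancer
cells during drug-induced mitotic arrest.

Cells arrested in mitosis by anti-mitotic drugs survive for many hours and
then die abruptly: mitochondrial outer membrane permeabilization (MOMP)
releases cytochrome C within minutes, after a delay of ten hours or more.
This package implements, end to end, an analysis of how that delayed,
switch-like decision arises from a small Bcl-2 protein network — Mcl-1 and
Bcl-xL sequestering the pore-former Bak while Mcl-1 is steadily degraded —
and of what makes individual cells and cell lines differ in their
sensitivity. It is written for computational/systems biologists who want a
tested reference implementation of the models and estimators, and for
experimentalists who want to run the same analysis on their own single-cell
fate data.

## The models

**Switch kinetics** (`mitoswitch.kinetics`, `mitoswitch.analytics`). Bak
monomers are sequestered by Mcl-1 (M + B₁ ⇌ MB) and oligomerize by
successive dimerizations B_n + B_n ⇌ B_2n up to a pore of A subunits; the
pore drives CytC exchange, dC_c/dt = γ_m[B_A][C_m] − γ_c[C_c]; free Mcl-1
follows dM/dt = σ_M − δ_M·M. Two variants differ in pore size: a tetramer
(A = 4) and a massively oligomeric pore (A = 256). In the quasi-static
limit the cytoplasmic CytC fraction is a Hill function of free Bak monomer
with exponent A, giving the MOMP delay T_c = (1/δ_M)·ln[(M₀−M_s)/(M_½−M_s)]
and the sharpness bound **ΔT ≥ ln 9/(A·δ_M)**: only high-order cooperativity
(hundreds of subunits) can reconcile a many-hour delay with a sub-hour
switch.

**Single-cell death times** (`mitoswitch.death_model`,
`mitoswitch.population`). For A → ∞ the switch becomes a hard threshold: a
cell dies when m₀e^(−t/τ_M) + x₀e^(−t/τ_X) decays through θ ≈ B_T/K_c,
where m₀ and x₀ are its Mcl-1/Bak and Bcl-xL/Bak ratios. Log-normal
cell-to-cell variability in M, X and B then yields the mitotic survival
curve S(T) = P(t_c > T), computed both by Monte Carlo and by deterministic
quadrature.

**Competing risks** (`mitoswitch.empirical`). Arrested cells either die or
exit mitosis; the two hazards are independent. Binned cause-specific
hazard estimation turns per-cell fate tables into exit-corrected survival
curves S(T) = exp(−Σ δ·Δt) and exit curves E(T) = 1 − exp(−Σ ε·Δt).

**Calibration** (`mitoswitch.fitting`). A two-stage constrained least
squares (large random search, then compass/pattern search) fits population
parameters to corrected survival curves for control + Mcl-1-knockdown +
Bcl-xL-knockdown conditions, with hard box bounds from western-blot
summaries and the measured Mcl-1 half-life (single-exponential fit,
f(t) = A₀e^(−t/τ)).

**Synthetic data** (`mitoswitch.synthetic`). Generates every input the
pipeline consumes — fate tables, blot summaries, decay time courses — from
known ground truth, so the whole chain is testable without downloads.

## Worked example

```
$ python analysis/01_switch_kinetics.py
Model I (A=4): MOMP delay 2.39 h, switch duration 1.19 h (pore-size bound 1.174 h)
Model II (A=256): MOMP delay 28.33 h, switch duration 15.19 h (pore-size bound 0.018 h)
```

The delay is the time for the cytoplasmic CytC fraction to reach 1/2 from
the onset of arrest; the switch duration is its 0.1 → 0.5 rise time. With
the bundled translocation constants the tetramer model sits essentially at
its quasi-static solution (1.19 h vs the 1.17 h bound), while the 256-mer
pore's threshold falls where Mcl-1:Bak buffering and bulk Bak
redistribution dominate, stretching both timings (see
`docs/methods.md` for why, and `analysis/02_pore_size_sweep.py` for a
regime where the switch sharpens strictly with pore size, down to 0.07 h at
A = 256).

```
$ python analysis/03_survival_curves.py
control: median death 9.09 h; Monte-Carlo vs quadrature max gap 0.0012
mcl1kd: median death 6.09 h; Monte-Carlo vs quadrature max gap 0.0011
bclxlkd: median death 8.04 h; Monte-Carlo vs quadrature max gap 0.0011
```

For the reference synthetic cell line, knocking either inhibitor down to
20% advances the median death time, and the two independent survival-curve
routes agree to ~10⁻³.

```
$ python analysis/05_fit_recovery.py
...
best SSE 0.003622; median-ratio errors: Mcl-1/Bak 6.9%, Bcl-xL/Bak 1.2%;
ratio ordering preserved: True
```

A full synthetic experiment (three conditions × 3000 imaged cells, blot and
half-life constraints) recovers the ground-truth protein-ratio medians to
within a few percent.

A CLI mirrors the analysis stages
(`mitoswitch simulate|analytics|survival|synth|correct|fit`); run
`mitoswitch --help`.

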