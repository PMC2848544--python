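# Methods

## Model

Each cell carries four state variables: total clock protein `P`, clock mRNA
`M`, coupling-signal protein `D`, and signal mRNA `MD` (copies per nuclear or
cytosolic compartment). With `eq(P, G)` the fast-dimerization decomposition
of the totals into monomers and dimers, cell *i* obeys

```
dP_i/dt  = α_p · M_i(t−τ_p) − [δ_p·p + 2δ_hh·hh + δ_pg·pg](P_i(t), G_i(t))
dM_i/dt  = κ_m · f(hh(P_i(t−τ_m), G_i(t−τ_m)), S̄_i(t−τ_m)) − δ_M · M_i
dD_i/dt  = α_d · MD_i(t−τ_dp) − δ_d · D_i
dMD_i/dt = κ_d · f_d(hh(P_i(t−τ_dm), G_i(t−τ_dm))) − δ_MD · MD_i
```

`S̄_i = Σ_{j∈N(i)} D_j / n_max` is the normalised Notch signal (`n_max` = 2 on
a line, 8 on the Moore grid), so a boundary cell with one neighbour receives
half an interior cell's signal. Both the repressor and the activator in the
clock promoter are evaluated at `t − τ_m`: the production delay applies to
the whole transcription event. The homodimer decay term carries a factor 2
(one decay event removes two clock subunits); heterodimer decay removes one
— the control protein is prescribed, so its half is not tracked.

The dimer equilibrium `P = p + 2p²/K_hh + pg/… , G = g + 2g²/K_gg + …` has a
unique non-negative root (both conservation functions are increasing in the
monomers). The solver runs eight damped fixed-point sweeps to enter the
Newton basin and then a safeguarded two-dimensional Newton iteration to
relative residual 1e−12; the Jacobian determinant is provably positive on
the non-negative quadrant, so the iteration cannot break down. It is
JIT-compiled because it runs six times per right-hand-side evaluation (two
cells × three evaluation times in the two-cell configuration).

### Promoter functions

The transcription probability treats the promoter as an equilibrium ensemble
of states: RNAP-II alone (weight `q`), RNAP-II plus activator (weight
`q·c_a·k_a·A`), and — mutually exclusive with RNAP — every combination of
activator and repressor-site occupancy, `(1 + k_a A)·F_R(R)` with
`F_R = 1 + k_r R` (one site) or `1 + 2k_r R + c_r (k_r R)²` (two equivalent
sites, cooperativity `c_r`). Transcription is proportional to the RNAP-bound
fraction. The signal gene's promoter has one repressor site and no
activator: `f_d = q/(q + 1 + k_r R)`, sharing the repressor affinity `k_r`
and, by default, the RNAP weight `q` with the clock promoter (`q_signal` is
an overridable argument of the tissue assembly). A state-enumeration oracle
in the tests verifies both forms against explicit Boltzmann sums.

### Parameters

Fixed (experimentally constrained) defaults: `σ = 5` cells/somite,
`ω = 1/30` somites/min (the tailbud period is 30 min and somites form at the
same rate — so consecutive cells exit 6 min apart), `t_half = 60` min,
`τ_p = 1.7`, `τ_dp = 20`, `τ_dm = 12.4` min, `α_p = α_d = 4.5`,
`κ_m = κ_d = 33`, `δ_M = 0.206`, `δ_d = 0.23`, `δ_MD = 0.273` /min,
`c_a = 25`.

Estimated parameters and their screening prior: `τ_m ~ U[2.3, 8.1]` min,
`δ_p ~ U[0.2, 0.5]` /min, `c_r ~ U[1, 100]` (linear); `K_hh, K_gg, K_pg`
log-uniform on [10, 1000] copies, `k_r` log-uniform on [0.01, 1],
`q` log-uniform on [0.03, 3]. The lower bound of the `q` range is not
experimentally constrained; it is set two decades below the upper bound,
matching the span of every other log-sampled range, and above the level
(~0.033) at which the maximal clock mRNA production `κ_m·q/(q+1)` could
never reach the 5-copy amplitude threshold — a region that would
mechanically exclude large parts of the prior in every scenario.

`k_a = 2e−6` 1/copies. The activator affinity is the least-constrained
constant in the model. Two qualitative facts pin its scale: coupling must
synchronize phases yet leave oscillation *rates* essentially unchanged
(single cells and coupled pairs differ by well under 2% in period), and a
tissue of identical cells must count as synchronized (< 1% period spread)
even though boundary cells receive half the interior signal. In this
implementation the period responds measurably to the mean signal level, so
both facts bound `k_a` from above; 2e−6 gives a ~0.2% boundary-cell period
shift and a ~1–3% transcription modulation at typical signal levels
(`S̄ ≈ 200–350` copies). Larger values (≥ 5e−6) make the deterministic
boundary effect alone exceed the 1% synchrony band.

### Reference parameter sets

`REFERENCE_SET_III/IV` (in `clockwave.params`) are reconstructions of the
screen optima with the largest period change; the assignment of the three
dissociation constants to columns of the printed table is ambiguous, and the
adopted permutation (`K_pg = 47.6, K_hh = 94.4, K_gg = 133` for III) is the
one whose sweep loses its oscillation just above `G = G_max = 330`,
matching the reported period-vs-G curve. In this implementation the
scenario-III reconstruction reaches `ΔT ≈ 9.8` min with a 33.7-min tailbud
period — close to, but slower than, the reported optimum. The frozen
demonstration set `WAVE_DEMO_III` (in `clockwave.fixtures`) was produced by
the package's seeded local refinement helper (`screening.refine_delta_T`)
started from the reference set: period range 32.5→45.5 min, `ΔT ≈ 12.9`,
a collection-D member that generates the narrowing anterior wave used in
the stage-2 demonstrations, experiments, and robustness runs.

## Numerics

**Integrator.** Adaptive Dormand–Prince 5(4) with the standard quartic
continuous extension, written in numba. Every accepted step stores its
interpolation polynomial; delayed state lookups are binary searches into
this piecewise polynomial (or into the constant/warm-start history before
`t0`). The step size is capped at the smallest delay so lookups normally
stay behind the integration front; when delays are shorter than 0.5 min the
cap is relaxed and each step is iterated against its own developing
interpolant (up to 5 corrector passes, converged when the endpoint moves by
< 5% of the local error tolerance) — the standard short-delay treatment,
verified against a stiff delay-free reference integration to ~10·rtol.
Defaults `rtol = 1e−6`, `atol = 1e−9`, recorded in every result file.
Propagated discontinuities from the zero-history start are resolved by the
error controller rather than by explicit breaking-point meshes; the
closed-form linear-DDE test bounds the resulting error. Warm starts copy
the predecessor trajectory's trailing `max-delay` window of steps, making a
chained integration agree with a single call to ~10·rtol.

**Classification.** A control level is classified on the trailing 200 min of
its (≥ 250 min, warm-started) window: successive maxima of cell 1's total
clock protein are refined by local quadratic fits; the solution is settled
periodic when the last three inter-peak intervals and peak heights agree to
relative 1e−3 (the settledness tolerance is an artifact choice — the study
only requires "settled"). The period is the mean of those three intervals.
Every state variable's peak-to-peak amplitude must reach 5 copies/nucleus,
otherwise the settled oscillation is *subthreshold* — small-copy-number
oscillations the deterministic model cannot trust. Peak-to-peak below 1e−3
is *steady*; anything else is extended in 250-min chunks up to a 2000-min
cap. `ΔT` is computed over the accepted periodic levels only, mirroring the
truncated scenario-III period curve. The standalone period estimator used
for per-cell synchrony measurements adds Savitzky–Golay smoothing and
regresses refined peak times on cycle index; on synthetic oscillations with
1% additive noise its absolute error is below 0.01 min.

**Stage-1 screen.** Two mutually coupled identical cells (`n_max = 2`, so
each receives half its neighbour's signal — the weak-coupling regime where
the paper reports negligible rate effects makes this choice immaterial).
The control level steps 0 → 2500; each level settles ≥ 250 min using the
previous level's solution as history. The reduced configuration (n = 500
sets, step 100) reproduces the screen's proportions to binomial accuracy in
a few minutes; the full configuration (n = 40,000, step 10) is the CLI
default `screen --n 40000 --g-step 10`. Sensitivity is the per-parameter
coefficient of variation over each nested collection, computed on raw (not
log) parameter values.

**Stage-2 tissue runs.** Zero history, 500 min settling with every cell at
`G_max` (all cells in the tailbud), then scheduled exits; laterally adjacent
cells exit together. Heterogeneity perturbs 22 strictly positive per-cell
constants (`α_p, α_d, κ_m, κ_d, τ_p, τ_m, τ_dp, τ_dm, δ_p, δ_M, δ_d, δ_MD,
K_hh, K_gg, K_pg, q, k_r, c_r, k_a, c_a, t_half, G_max`) independently per
cell, Normal with σ = level/3 of the nominal (so 99.7% of draws fall within
the stated level), resampling negative draws rather than clamping to keep
the mean unbiased; exact zeros (scenario dimer decays, `G_min = 0`) are
never perturbed. Band spacing smooths a snapshot with a 3-cell moving
average and takes peaks at ≥ 20% prominence of the snapshot range by
default (the low-amplitude posterior bands of the scenario-III wave need
5%); spacings are reported posterior-most first and carry ±1-cell
discretisation ambiguity.

## What the synthetic data does and does not show

The synthetic fixtures (seeded parameter draws, analytic period curves, the
mini-lattice) exercise classification logic and the pipeline plumbing; they
emulate the *statistical* shape of screen outputs, not the biology. Passing
tests on them shows the bookkeeping (collection nesting, ΔT arithmetic,
estimator accuracy under noise) is correct — it says nothing about real PSM
tissue, where cell movement, gradient dynamics, anterior wave arrest and
stochastic gene expression are all outside this model's scope (the gradient
is prescribed, cells never rearrange, and chemistry is deterministic).

## Known limitations

- The promoter functions are reconstructions anchored to the thermodynamic
  ensemble structure (transcribing states: RNAP alone and RNAP+activator;
  repressor occupancy excludes RNAP); they are normative for this package.
  With them, oscillation periods run ~5–10% longer than the published
  optimum curves, and the screen's scenario-III periodic and period-criterion
  fractions land a few points above the published 48.4% / 8.1%; the
  conditional ΔT ≥ 5 fraction lands below the published 10.6%.
- The sigmoidal gradient shape `s(x) = 1/(1+x³)` is an artifact choice
  (normalised, half-value at one half-life); the exponent is configurable.
- Periods are measured on cell 1's total clock protein; for identical cells
  any synchronized variable is equivalent.
- Quasi-periodic or very slowly settling solutions that still drift at the
  2000-min cap are classified subthreshold/steady, not periodic; spectral
  period estimation is out of scope.
- 2-D simulations treat corner-touching cells as neighbours (Moore
  coupling) with an 8-fold normalizer; no other coupling topologies are
  implemented.
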