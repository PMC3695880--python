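# Methods

`uprkit` implements a deterministic kinetic model of the mammalian
unfolded protein response (UPR) — the signalling network by which the
endoplasmic reticulum (ER) reacts to an accumulating load of unfolded
protein — together with the analysis machinery needed to characterise its
behaviour: stiff time integration, steady-state continuation with Hopf and
fold detection, quasi-static bistability sweeps, a delay-differential
reduction of the oscillator core, and an approximate-Bayesian-computation
scan of the oscillatory parameter region.

All quantities are in arbitrary concentration and time units (acu, atu).

## The model

The network couples five modules in four compartments (ER, Golgi, nucleus,
cytoplasm); the reference assembly has 27 species, 62 reaction channels
and 82 parameters.

**Receptor activation.** The chaperone BiP partitions competitively
between the three stress receptors (IRE1α, PERK, ATF6) and unfolded
protein (UFP). Unbound receptor monomers oligomerise cooperatively into
active complexes (`kf·R^n` with n = 4 for IRE1α, n = 2 for PERK) and
revert spontaneously; no external phosphatase is required. Stress enters
as a constant UFP accumulation rate `mUFPT`. Free UFP is cleared at
`kdUFP`; chaperone-bound UFP is cleared together with its chaperone at
`kdbUFP`, so sustained stress *consumes* folding capacity at roughly
`mUFPT` acu/atu. This co-clearance is the load-versus-capacity balance at
the heart of the model: a stress level is manageable exactly when BiP
production can match it.

**IRE1α branch.** Active IRE1α quadromers carry two catalytic domains
each; they splice XBP1 mRNA through the extended Michaelis–Menten law
(below) with enzyme pool `2·[IRE1α complexes]`. Spliced XBP1 protein
activates BiP expression. Because splicing is capped by XBP1 transcription,
which in turn is driven largely by cleaved ATF6, the XBP1 arm's *capacity*
is gated by the slow ATF6 arm while its *response* (protein-level splicing)
is fast — the separation that makes preconditioning protective.

**ATF6 branch.** BiP-free ATF6 translocates to the Golgi (slow,
`ktransfer`), is cleaved rapidly (`kcleave >> ktransfer`) to the
transcription factor ATF6p50, which activates XBP1, BiP and CHOP and
induces WFS1, its own negative regulator. ATF6p50 turnover is slow, so the
branch integrates stress history — it is the "preconditionable" arm.

**PERK branch / translation attenuation.** A phosphorylation cycle of
eIF2α between the PERK kinase (activity `2·[PERK complexes]`) and the
phosphatases CReP (constitutive) and GADD34 (induced), both saturated
(shared Michaelis constant `KmEif2a` far below the eIF2α total), gives a
zero-order ultrasensitive switch. ATF4 is translated through a repressing
Hill response of active eIF2α with midpoint `kATF4 = 0.1·eIF2aT` — a 90%
drop of active eIF2α attenuates translation — and drives CHOP, which
drives GADD34, closing a delayed negative feedback. CHOP also weakens the
effective phosphorylation capacity (`kmChop`). The cascade's turnover
rates are ~3–6× faster than BiP accumulation, so the oscillation period
(~25–70 atu) is short relative to adaptation (~100–300 atu).

**Apoptosis switch.** A condensed three-variable BAX/BAK/BH3 switch:
CHOP induces BH3 and represses Bcl-2 (Hill, midpoint `KrCHOP`), BH3
catalyses BAX activation from a fixed pool, active BAX auto-activates
cooperatively (the bistability source), Bcl-2 deactivates it. With CHOP
as input the switch is bistable over CHOP ≈ 2–7, with the activation
threshold above the deactivation threshold (hysteresis). BH3-driven
activation is slow (`kaBAX`), so brief CHOP oscillation peaks do not
ratchet the switch; only a sustained high-CHOP phase flips it.

## Rate laws

*Extended Michaelis–Menten (total quasi-steady-state).* For substrate and
enzyme totals of comparable size,

    v = (kc/2) · [St + Et + Km − sqrt((St + Et + Km)² − 4·St·Et)].

The law is symmetric in `St`/`Et`, bounded by `kc·min(St, Et)`, reduces to
the classical form when enzyme is scarce, and matches brute-force
integration of the explicit binding scheme E+S ⇌ C → E+P within 5% in the
fast-binding regime (tested over random parameter sets). Floating-point
negative discriminants are clamped at zero.

*Competitive transcription.* A single (low-copy) gene shared by several
regulators transcribes at

    v = Σ_i kc_i·[TF]_i/Km_i / (1 + Σ_j [TF]_j/Km_j),

activators in the numerator, every regulator in the denominator. This is
the single-promoter occupancy average; a pure repressor has `kc = 0`.
Genes with constitutive expression carry an explicit constant activator
term (XBP1) or a separate constant synthesis channel (BiP) rather than a
hidden basal rate. Consequence worth remembering: the law's ceiling is a
*weighted average* of the `kc_i`, so adding a weaker activator can lower
the rate — the rising arm of BiP production (XBP1s) therefore carries the
largest `kc`.

*Hill responses* are normalised to [0, 1] and scaled by explicit rate
constants at call sites; exponents are ≥ 1 everywhere.

## Reference parameterisation

The bundled parameter file
(`src/uprkit/data/reference_parameters_synthetic.yaml`) is a synthetic
reconstruction calibrated by the package authors against the model's
qualitative design targets, in this order:

1. fast protein-level kinetics (binding, oligomerisation: rate constants
   0.1–10/atu) versus slow genetic regulation (0.002–0.3/atu);
2. a 3–4× rise of total BiP across the isolated IRE1α branch's response,
   with the majority of XBP1 mRNA spliced under stress;
3. a pair of Hopf bifurcations over activated PERK (reference window
   PERKA ≈ 2.8–5.5) separating low/oscillatory/high regimes of CHOP and
   translation;
4. a bistable BAX window aligned with the intermediate CHOP range, wide
   enough that oscillation troughs do not release an activated switch and
   oscillation peaks do not flip an inactive one;
5. low/intermediate/high activity at stress rates mUFPT = 12/15/18, which
   requires the total BiP production capacity (~16 acu/atu) to straddle
   the moderate demand inside the oscillatory window;
6. preconditioning protection: the mild-adapted state (elevated ATF6p50
   and warm XBP1 arm) absorbs the step to moderate stress without the
   sustained high-CHOP excursion that the direct moderate scenario shows.

These targets fix the architecture-level ratios; individual values are
otherwise round numbers. The calibration is a working point, not a fit to
data.

## Numerical choices

- **Integration**: LSODA with the model's exact symbolic Jacobian;
  defaults rtol 1e-8, atol 1e-10, ≥ 2000 output points per scenario.
  Piecewise-constant stress protocols restart the integrator at segment
  boundaries (no smoothing). Trajectories are clamped at zero after
  checking that no excursion exceeds −1e-9.
- **Steady states**: Newton (Powell hybrid) with the residual augmented by
  `Cᵀ(Cy − c₀)`, where `C` spans the conserved combinations (left null
  space of the stoichiometric matrix) — conservation (e.g. total eIF2α)
  makes the raw Jacobian singular and lets an unpinned Newton drift to
  spurious roots. Fallback: long relaxation then re-polish. Stability =
  all eigenvalue real parts < 1e-8.
- **Continuation**: pseudo-arclength (secant predictor, bordered Newton
  corrector with the same conservation pinning; ∂F/∂λ by central
  difference), state axis scaled by the branch's norm. Folds are
  traversed; the step halves on corrector failure down to 1/256 of the
  nominal step, after which a partial branch is returned with a warning.
  Hopf points: sign change of the leading complex-pair real part between
  adjacent points, refined by bisection to |Re| < 1e-8. Verified against
  the supercritical normal form (Hopf at 0, onset frequency 1, cycle
  radius √μ) and the cubic fold pair at ±2/(3√3).
- **Oscillation metrics**: discard the first 50% of the window; frequency
  = (maxima − 1)/(time between first and last maximum); *sustained*
  requires relative peak-to-trough amplitude > 1% of the series mean and a
  last/first peak-height ratio > 0.95. Constant or decaying series score
  frequency 0. A series that looks sustained but shows fewer than 5 peaks
  raises an error asking for a longer window.
- **Renormalisation** maps each series to 0–100% of its own range;
  constant series map to 0 (declared convention).
- **Delay model**: method of steps on the two-variable ATF4/GADD34
  skeleton, with the eIF2α cycle treated as instantaneous (its quasi-steady
  balance solved by bisection per evaluation) and the transcriptional lag
  condensed into a single delay τ. τ = 0 runs the identical solver path as
  a plain ODE. The linear test equation x′(t) = −x(t−τ) destabilises at
  τ = π/2, which the integrator reproduces to 2%.
- **Bistability**: quasi-static two-sweep protocol, 1% parameter
  increments with 500 atu re-equilibration; an interval is bistable where
  the sweeps disagree by more than 10% of the observable range.
- **Activity classification**: *intermediate* = sustained CHOP
  oscillation; otherwise *low*/*high* by the late CHOP level against the
  midpoint of the model's own low/high CHOP asymptotes and the late
  translation level against recovery (50% of total eIF2α) or attenuation
  (10%) thresholds. Anything else is labelled *ambiguous* with full
  diagnostics rather than coerced. Scenario runs last 1000 atu so the
  post-transient behaviour that defines each state has established itself;
  the preconditioning protocol keeps 500 atu per step.
- **BAX verdict**: active if above the midpoint of the switch's off/on
  branches at the prevailing CHOP level (relaxation from both ends of the
  pool); 50% of the pool where monostable.

## The oscillation scan

The ABC-SMC scan asks which PERK-branch parameters sustain high-frequency
CHOP oscillations. The distance is the Heaviside step on the measured
frequency — accept iff `f ≥ ε` — with ε raised each generation to the 60%
weighted quantile of the previous generation's frequencies. Priors are
log-uniform over ×1/10…×10 around each scanned parameter's reference
value; the scan's own reference point sets PERKA = 4 (mid-window) and an
external CHOP drive of 1.0 acu, chosen so the prior brackets the
drive level at which oscillations die. Perturbation kernel: Gaussian in
log-space with twice the weighted covariance of the previous generation;
importance weights carry the standard kernel correction (the log-uniform
prior is flat in the sampling space). Defaults N = 500 particles,
5 generations; each particle is a 2000 atu simulation (transient fraction
0.5), run through a numba-specialised transcription of the module's
right-hand side that the test suite asserts equal to the generic compiled
network to machine precision.

Population summaries use weighted quantiles and weighted Spearman
(rank) correlations. The sensitivity score of the frequency against each
parameter is a weighted rank-regression: ranks of f regressed jointly on
ranks of all log-parameters, standardised, absolute coefficients
normalised to sum 1. Parameters with zero spread are flagged degenerate
and scored 0.

Two caveats the scan exposes about this reconstruction (both verified
across seeds): the eIF2α-total marginal stays essentially flat, because
the ATF4 threshold is an absolute level and oscillation only requires it
to sit inside the active-eIF2α swing; and activated PERK ranks among the
*more* sensitive frequency determinants (rank ~9 of 10), because the
relaxation oscillator's attenuation-phase dwell time varies ~1.4× across
the inter-Hopf window.

## What the synthetic conditions do and do not show

Every input to the analyses is generated by the model itself; there is no
experimental data path. Passing tests therefore demonstrate internal
consistency of the mechanism — that the published qualitative phenomena
(three states, Hopf pair, hysteresis, preconditioning protection) are
reproducible consequences of this network topology under a plausible
parameterisation — not that the parameterisation describes any particular
cell type. Known limitations: deterministic dynamics only (no intrinsic
noise); no ER folding/ERAD feedback (unmitigated-stress framing, by
design); the ATF6 membrane reservoir is small relative to the BiP pool, so
the transfer-knockout variant strands ATF6 without diverting enough BiP to
activate the other receptors; and limit cycles are characterised by
simulation, not continued as periodic orbits.

## Problem sizes

Default analysis sizes, chosen as the smallest that make the qualitative
verdicts stable: continuation 100 nominal steps per sweep; oscillatory-
window grid 19 points × 2500 atu; bistability sweeps 100 steps × 500 atu
each way; scenarios 1000 atu (2000 output points); preconditioning 3 × 500
atu; scan N = 500 × 5 generations × 2000 atu per particle; rate-law oracle
120 random parameter sets.
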