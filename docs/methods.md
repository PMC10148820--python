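# Methods

`hogpath` models osmostress-induced activation of the MAP kinase Hog1 in
*Saccharomyces cerevisiae* with deterministic mass-action/Michaelis–Menten
ODE networks, fits competing network topologies to multimodal data by
multistart maximum likelihood, ranks them by AIC, and interrogates fitted
models with processivity, ultrasensitivity, robustness and quantile-shift
analyses.  This note documents the model, its assumptions, the numerical
choices, and what the synthetic-data experiments do and do not show.

## The overcomplete HOG network

One "overcomplete" reaction inventory covers every submodel; a topology
configuration selects which reactions exist.

**Signalling backbone.**  Osmotic shock is sensed through turgor loss (see
the volume module below).  The Sln1 branch is a collapsed two-state relay:
active Sln1 represses Ssk1 (second order in Sln1, reflecting the dimeric
sensor), stress inactivates Sln1, de-repressed Ssk1 activates the MAPKKK
Ssk2.  The Sho1 branch activates Ste20 (second order in active Sho1,
standing in for the scaffolded membrane complex) and then Ste11; Ste50 and
the scaffold partners are lumped into these steps.  Both MAPKKKs activate
the MAPKK Pbs2 through a step that is saturable in Pbs2 (Michaelis–Menten
with the MAPKKK as enzyme).  Dephosphorylation of every upstream species is
first order.

**Hog1 phosphorylation mechanisms.**  Hog1 carries two activating sites,
collapsed here to an ordered pair whose mono-phosphorylated form is
interpreted as phospho-Y176 (the form the mass-spectrometry observable
reports).  Activated Pbs2 binds free Hog1 and performs the first
phosphorylation without release, producing the nascent complex
`Pbs2PPHog1P`.  The mechanisms differ in that complex's fate:

* *processive*: only the immediate second phosphorylation (`k_phospho`)
  exists; bound mono-phospho Hog1 is never released, and free mono-phospho
  Hog1 cannot rebind.
* *distributive*: only dissociation (`k_off`) exists for the nascent
  complex; free mono-phospho Hog1 rebinds activated Pbs2 (a *rebound*
  complex) from which the second phosphorylation proceeds (`k_phospho2`).
* *mixed*: both routes coexist and compete.

Splitting nascent and rebound complexes makes the limits exact: the mixed
network with `k_phospho -> 0` is reaction-for-reaction the distributive
network, and with dissociation and rebinding removed it is the processive
network.  These identities are tested to trajectory max-difference < 1e-6.

**Feedbacks.**  Negative feedback is a Hog1-PP–catalysed deactivation of
active Ssk2.  Positive feedback converts activated Pbs2 to a
feedback-modified form (`Pbs2PP_fb`, reversible, Hog1-PP–catalysed) whose
Hog1-association rates carry the *affinity* multiplier `fb_affinity` and
whose catalytic rates the *catalytic* multiplier `fb_catalytic`; the
dissociation rate is never modified.  Alternative feedback targets
(Sln1+Ste20, Ssk1+Ste20) are supported by analogous modified-species
constructions; because those targets couple to their substrates without an
explicit binding step, both multipliers act on the activation rate there.

**Scaffold binding.**  Unphosphorylated Pbs2 binds free unphosphorylated
Hog1 in a non-productive scaffold complex.  This is part of the network
reconstruction (Pbs2 is a scaffold protein) and is what makes Pbs2 dosage
mechanism-dependent: under 10x Pbs2 overexpression the excess inactive Pbs2
sequesters free Hog1.  The distributive/mixed calibrations escape through
the mono-phospho recycling loop (free Hog1-P does not bind the scaffold) and
hyperactivate, while the processive calibration — whose Pbs2 activation is
saturated, so active Pbs2 does not scale with total Pbs2 — is suppressed.

**Phosphatases.**  Ptp2 acts only on nuclear Hog1 phospho-forms and Ptp3
only on cytosolic ones, both Michaelis–Menten and stepwise
(PP -> P -> unphosphorylated); the Ser/Thr phosphatases (Ptc1, Ptc2/3) are a
lumped constitutive first-order background in both compartments.

**Compartments and shuttling.**  Hog1 species shuttle between cytosol and
nucleus with first-order rates; doubly phosphorylated Hog1 imports faster
and exports slower.  The nucleus occupies a fixed 10 % of cell volume when
amounts are converted to concentrations for the nuclear:cytosolic ratio (the
volume factor cancels in the ratio).  Species are expressed in normalized
copy-number units with wild-type totals of 1; all packaged observables are
ratios or percentages, so the absolute scale never enters.

**Cell-volume module.**  Two additional states, intracellular glycerol `G`
(osmolar units) and relative volume `V`:

    dV/dt = kv * ( (n_fix + G)/V − e(t) − Pi(V) )
    dG/dt = kg0 + kg_hog * [Hog1-PP] + kg_basal * s − kleak * G * gate(Pi)

with turgor `Pi(V)` linear in volume above a collapse point `Vb` and the
turgor-loss signal `s = clip(1 − Pi/Pi0, 0, 1)` driving the osmosensors.
The glycerol export gate closes under stress and reopens steeply as turgor
approaches its resting value (`gate = clip(0.5 + 25 (Pi/Pi0 − 1), 0, 2)`),
which makes glycerol accumulation an approximate integral controller: volume
and signal adapt essentially completely after a step.  The Hog1-independent
production term (`kg_basal`) is what lets a *pbs2Δ* cell recover volume
partially.  Hog1-PP–dependent production is the Gpd1 transcriptional proxy;
no explicit transcription or Fps1 channel chemistry is modelled.

## Reference calibration

`hogpath.calibration` ships a curated, versioned parameter point (log10
scale) reproducing the qualitative physiology: ~2 % basal Hog1-PP rising to
~45 % within a minute of 0.4 M NaCl and adapting within ~10 min; a sigmoidal
dose-response (Hill coefficient ~2.7, EC50 ~0.06 M); strongly elevated and
sustained phosphorylation in *ptp2Δ ptp3Δ*; no response in *pbs2Δ*; a
processivity score that is low at rest and rises several-fold during the
response; damped/constitutive affinity feedback in the Pbs2-S248A/S248E
mutants; and the mechanism-dependent Pbs2-dosage behaviour described above.
The per-mechanism calibrations share a base and differ in a handful of
values (`MECHANISM_OVERRIDES`), as expected when each topology is fitted
separately: the purely processive variant needs a fast immediate second step
and operates in the saturated, scaffold-dominated Pbs2 regime.

The calibration is hand-curated rather than the output of one specific
optimization run: it is the self-consistent ground truth from which the
synthetic corpus is generated and against which the recovery experiments
refit.  Timescales are modestly compressed relative to live-cell kinetics
(full adaptation in ~10 simulated minutes) so that every packaged experiment
integrates quickly; all packaged analyses are invariant to this uniform
compression.

## Observables and objective

Modalities: mass-spectrometry fold change (species amount over its
pre-stimulus amount), western-blot percent phosphorylation (mono + doubly
phosphorylated Hog1, complexes included, over total Hog1; the
tyrosine-specific variant coincides with it because the model's single mono
form is pY176, but it is kept as a separate modality with an independent
error model), single-cell nuclear:cytosolic Hog1 concentration ratio, and
projected cell area (`V^(2/3)`, normalized).  Errors are additive Gaussian
on each observable's own scale.  The objective is

    −2 log L = Σ_i [ (y_i − ŷ_i)² / σ_i² + log(2π σ_i²) ],

with per-class error scales either fixed from the data table or profiled
analytically at their conditional maximum (variance = mean squared residual,
floored); the *ptp2Δ ptp3Δ* western-blot class is profiled, mirroring the
policy of keeping that dataset's error model generous and independent.
Simulation failures contribute a large finite penalty (1e8 per condition),
never an exception, so multistart optimization survives pathological
parameter draws.

## Fitting

Parameters are optimized on log10 scale within bounds (default −3..3; the
physiological mode applies per-class boxes such as 0.1–100 /s for catalytic
rates).  A round samples starting vectors uniformly (round 1) or from a
multivariate normal matched to the previous round's top set (covariance
floored on degeneracy), polishes each start with bound-constrained L-BFGS-B
(iteration cap, 1e-6 objective-change stop, finite-difference gradients with
a step of 1e-3 log10 units — large enough to dominate ODE-solver noise at
the fitting tolerances), and keeps the best `top_set` vectors; rounds stop
when the best goodness of fit no longer improves.  Production-scale defaults
(10,000 starts, top-100) are kept in `FitSettings`; every packaged
experiment states its own scaled-down budget.  Two optional accelerators for
small budgets are `n_screen` (sample many vectors, score each once —
optionally on a single informative condition — and locally optimize only the
best few) and deterministic anchor starts (nominal parameter values joining
the random starts); both preserve the protocol's exploration breadth at a
fraction of the cost and are disabled by default.  AIC = 2k − 2 ln L_max
with k counting fitted kinetic parameters plus profiled error scales;
differences above ten are flagged highly significant.

## Synthetic corpus

The packaged catalogue emulates the structure of the multimodal fitting
corpus: MS fold-change series for Hog1-PP and Hog1-P176 (every 5 s over the
first minute, then every 5 min to 30 min; the mono series carries a flag so
experiments can exclude it), western-blot percent series (wild type,
*ptp2Δ ptp3Δ*, Hog1-inhibited with and without salt, 0–40 min), single-cell
nuclear:cytosolic ratios (steps at 0.05–0.6 M, 90-s cadence over 39 min; a
0.2 M ramp held out as test data; pulse trains of 2/4/8/16 min period;
*sln1Δ*, *sho1Δ*, S248A, S248E, Ssk2-feedback-dead and *pbs2Δ* mutants), and
cell-area series for wild type and *pbs2Δ* — 533 fit-use rows in total.
MS sigmas are relative (10 % with a floor of 0.1 fold-change units);
western-blot, microscopy and area sigmas are 5–8 %, 0.3 ratio units and 0.02
area units respectively.  At the 60-s MS point the generator averages two
independent noisy draws, emulating two overlapping source studies.

The generator reproduces measurement *noise* but not several features of
real data: no cell-to-cell variability beyond the perturbation ensembles, no
systematic antibody or normalization biases, no autocorrelated errors within
a time series.  Passing recovery and model-selection tests on this corpus
therefore demonstrates correctness of the pipeline under its own error
model, not identifiability on any particular experimental dataset.

## Scaled-down experiments

*Identifiability*: data are generated from the reference ground truth on the
full catalogue and refit with three parameters free (cytosolic phosphatase
rate, Hog1-PP nuclear import, Pbs2 dephosphorylation — rates that are
individually well constrained by the corpus); 300 candidate starts are
screened on the wild-type step condition and the best is optimized against
the full objective (25 iterations).  Reported: per-parameter |Δlog10|, the
median, and the within-one-order count.  Freeing strongly correlated pairs
(e.g. the immediate-second-step rate together with the dissociation rate,
whose ratio is the processivity) instead reveals genuine sloppy directions —
an expected property of the model family, not an optimizer artifact.

*Model recovery*: five replicate datasets are generated from the mixed
ground truth on the two MS series; mixed, distributive and processive
topologies (each with both feedbacks) are refit with their
mechanism-defining rates free and ranked by AIC.  The mixed topology should
rank first in at least half the replicates; in practice the margins are
large because the mono-phospho time course separates the mechanisms.

*Basic cascade*: a three-tier MAPK cascade (saturable kinase and phosphatase
steps at the lower tiers — the classic source of zero-order
ultrasensitivity — and an explicit-complex MAPK tier encoding the mechanism
structurally) is fitted to a synthetic mildly ultrasensitive dose-response
(Hill ≈ 3, EC50 0.3, basal 2 %, max 87 %).  Both mechanisms fit such data
comparably (|ΔAIC| ≤ 10): dose-response data alone cannot discriminate
them, which is precisely why the multimodal corpus is needed.  The two
dephosphorylation steps of the MAPK tier have independent rates; with a
single shared rate the processive variant is artificially capped near 50 %
activation because saturated phosphatase steps equalize the mono- and
doubly-phosphorylated pools.

## Numerics

LSODA with rtol 1e-8 / atol 1e-10 by default (fitting loops use 1e-5..1e-6);
the right-hand side is JIT-compiled (numba) with a pure-numpy fallback.
Protocol discontinuities restart the solver at each breakpoint, and the
external-osmolarity function is clamped inside each segment so the solver
never samples a post-discontinuity value.  Pre-equilibration integrates in
growing windows and accepts an early Newton polish only when it preserves
every conserved total to 1e-8 relative (fixed points form a manifold
parameterized by the totals, so an unchecked polish could drift off the
stoichiometric compatibility class).  Amounts are clipped at a small
negative floor tied to the absolute tolerance (max(1e-12, 100·atol)), with
failure below it.  Inside fitting loops each simulation carries a hard
budget of right-hand-side evaluations; exhaustion is a failure (penalty),
which bounds the cost of pathological parameter draws.  Conservation holds
along trajectories to ~1e-14 relative and across protocol discontinuities to
better than 1e-6.

## Known limitations

* The reaction inventory is a documented reconstruction of the described
  topology, not a transcription of any specific published equation set;
  lumping choices (Ste50/Ste20, the phospho-relay, Ptc background) are
  recorded above.
* Whether free mono-phosphorylated Hog1 may rebind Pbs2 under the purely
  processive variant is an open choice; the default (not permitted) is what
  makes the processive limit exact.
* The mono-phospho pool is a single species (pY176); T174/Y176 ordering is
  collapsed, so the two western-blot modalities coincide numerically.
* Absolute protein abundances and absolute time calibration are not
  constrained by the packaged observables.
* No stochastic (SSA) simulation, no profile likelihoods, no MCMC.
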