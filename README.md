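# hogpath

ODE modelling of Hog1 activation in the budding-yeast HOG (High Osmolarity
Glycerol) pathway: distributive, processive and mixed MAP-kinase
phosphorylation mechanisms, positive and negative feedback, multistart
likelihood fitting, AIC model selection, and post-fit analyses of
processivity, ultrasensitivity and robustness.

## The scientific problem

When yeast cells are exposed to osmotic shock, the MAP kinase Hog1 is
activated by dual phosphorylation downstream of the osmosensors Sln1 and
Sho1, which converge on the MAP kinase kinase Pbs2.  The pathway responds
ultrasensitively — almost switch-like — to NaCl concentration.  Whether the
two Hog1 phospho-sites are installed *distributively* (Hog1 dissociates from
Pbs2 after each phosphorylation and must rebind) or *processively* (both
sites in one binding event) shapes the response: theory associates
distributive phosphorylation with ultrasensitivity and processive with a
graded response.  A *mixed* mechanism, in which the Pbs2-bound
mono-phosphorylated Hog1 either proceeds immediately to the second
phosphorylation or dissociates, can interpolate — and a positive feedback of
active Hog1 on Pbs2 (an *affinity* component raising Hog1–Pbs2 association
and a *catalytic* component raising the phosphorylation rate) can switch the
reaction from distributive-like to processive-like during the response.

`hogpath` is for modellers who want to build, fit and interrogate this model
family: it constructs an overcomplete reaction network whose submodels
("topologies") differ in mechanism and feedback wiring, simulates them under
step/ramp/pulse-train NaCl protocols with a turgor–glycerol–volume module,
scores them against multimodal data (mass-spectrometry fold changes,
western-blot percent phosphorylation, single-cell nuclear:cytosolic Hog1
ratios, cell area) with a Gaussian −2 log L objective, fits by multistart
optimization with multivariate-normal refinement rounds, ranks by

    AIC = 2k − 2 ln(L_max)          (ΔAIC > 10: highly significant),

and quantifies the distributive↔processive switch with the processivity
score

    S(t) = ([C](t)·k_phospho + [C_fb](t)·k_phospho_feed)
           / (([C](t) + [C_fb](t))·k_off),

the ratio of immediate-second-phosphorylation flux to dissociation flux of
the Pbs2-bound mono-phospho complex `C` and its feedback-modified
counterpart `C_fb`.  A synthetic-data module generates multimodal datasets
with the structure of the 533-point fitting corpus from any ground-truth
parameter set, enabling parameter-recovery and model-recovery experiments
without any downloads.

## Worked example

Simulate the reference calibration of the mixed-mechanism model, quantify
its ultrasensitivity, and watch the processivity switch:

```
$ hogpath hill --mechanism mixed
Hill n=2.70 EC50=0.056 M basal=-0.7% max=57.4%

$ hogpath processivity --mechanism mixed --out processivity.tsv
basal score 0.1497, peak 1.0619
```

The Hill fit summarizes the simulated dose-response of maximal Hog1-PP
(percent of total Hog1) against NaCl steps from 0.0125 to 0.6 M: a Hill
coefficient near 3 means mildly ultrasensitive, with half-maximal activation
around 0.06 M (the basal level is a free intercept of the fit, hence the
slightly negative value).  The processivity score starts well below 1 (dissociation
dominates: distributive-like behaviour) and rises roughly seven-fold after
salt addition as positive feedback converts Pbs2 to its high-affinity,
high-activity form — the reaction transiently becomes processive-like, then
relaxes as the cell adapts.

The same machinery is available as a library:

```python
import numpy as np
from hogpath import (GroundTruth, FitSettings, generate, fit_network,
                     reference_network)

gt = GroundTruth.reference("mixed", seed=1)        # shipped calibration
data = generate(gt, noise_on=True, seed=1)         # 533-point synthetic corpus
net = reference_network("mixed")
fit = fit_network(net, data, free_names=["k_phospho", "k_off"],
                  settings=FitSettings(n_starts=6, top_set=3, max_iter=30,
                                       max_rounds=2, seed=0))
print(fit.aic, fit.parameters)
```

Other CLI stages: `topologies` (enumerate the 8 canonical submodels, 12 with
`--mixed`), `simulate`, `synth`, `fit`, `select`, `recover`, `robustness`,
`qshift`.  See `docs/methods.md` for the model definition, the error-model
policy, the scaled-down experiment designs and known limitations.

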