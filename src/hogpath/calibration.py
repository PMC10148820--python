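"""Reference calibration of the HOG model.

A curated, versioned parameter point for the overcomplete network that
reproduces the qualitative physiology of osmoadaptation in budding yeast:

* low basal Hog1 double phosphorylation (~2 % of total Hog1) that rises to
  ~45 % within a minute of a 0.4 M NaCl step and adapts back within ~10 min
  as glycerol accumulation restores turgor;
* a sigmoidal dose-response with half-maximal activation near 0.1 M NaCl;
* elevated, sustained phosphorylation when the tyrosine phosphatases Ptp2 and
  Ptp3 are deleted;
* a processivity score that is low before stimulation and rises sharply as
  positive feedback converts Pbs2 to its feedback-modified form;
* damped/constitutive affinity feedback in the Pbs2-S248A / S248E mutants;
* suppression of signalling by 10x Pbs2 overexpression under the processive
  mechanism but hyperactivation under the distributive/mixed mechanisms.

``MECHANISM_OVERRIDES`` hold the parameters in which the per-mechanism
best-fitting calibrations differ from the shared base: the purely processive
variant requires a fast immediate second phosphorylation step and operates
with saturated, scaffold-dominated Pbs2 handling.

Values are stored as log10 of the linear rate constants, the scale on which
all fitting operates.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .network import (ReactionNetwork, StrainSpec, TopologyConfig, WILD_TYPE,
                      apply_strain, build_network)

__all__ = [
    "REFERENCE_PARAMS_LINEAR",
    "REFERENCE_PARAMS",
    "MECHANISM_OVERRIDES",
    "REFERENCE_VOLUME_PARAMS",
    "reference_params",
    "reference_network",
]

#: Shared base calibration (linear scale).
REFERENCE_PARAMS_LINEAR: dict[str, float] = {
    # Sln1 phospho-relay
    "k_sln1_off": 1.0,
    "k_sln1_on": 0.03,
    "k_ssk1_act": 0.03,
    "k_ssk1_deact": 10.0,
    "k_ssk1_deact0": 0.01,
    "k_ssk2_act": 1.0,
    "k_ssk2_deact": 0.2,
    "k_nfb": 0.5,
    # Sho1 branch
    "k_sho1_act": 0.1,
    "k_sho1_deact": 0.1,
    "k_ste20_act": 1.0,
    "k_ste20_deact": 0.2,
    "k_ste11_act": 0.5,
    "k_ste11_deact": 0.2,
    # Pbs2
    "k_pbs2_ssk2": 6.0,
    "k_pbs2_ste11": 3.0,
    "km_pbs2": 3.0,
    "k_pbs2_deph": 0.5,
    "kon_scaffold": 0.5,
    "koff_scaffold": 0.2,
    # Hog1-Pbs2 module
    "kon_hog1": 5.0,
    "koff_hog1": 1.0,
    "k_phospho1": 5.0,
    "k_phospho": 0.05,
    "k_off": 1.0,
    "kon_hog1p": 3.0,
    "k_phospho2": 2.0,
    # positive feedback
    "fb_affinity": 3.0,
    "fb_catalytic": 30.0,
    "k_fb_conv": 2.0,
    "k_fb_rev": 0.1,
    # phosphatases
    "kcat_ptp2": 0.3,
    "km_ptp2": 1.0,
    "kcat_ptp3": 0.5,
    "km_ptp3": 1.0,
    "k_ptc": 0.04,
    # shuttling
    "k_imp": 0.02,
    "k_exp": 0.04,
    "k_imp_pp": 0.05,
    "k_exp_pp": 0.005,
}

REFERENCE_PARAMS: dict[str, float] = {
    k: float(np.log10(v)) for k, v in REFERENCE_PARAMS_LINEAR.items()}

#: Parameters in which each mechanism's best-fitting calibration departs from
#: the shared base (linear scale).
MECHANISM_OVERRIDES: dict[str, dict[str, float]] = {
    "mixed": {},
    "distributive": {},
    "processive": {
        "k_phospho": 2.0,      # sole second-step route must be fast
        "km_pbs2": 0.05,       # Pbs2 activation saturated in Pbs2
        "k_pbs2_ssk2": 2.0,
        "k_pbs2_ste11": 1.0,
        "kon_scaffold": 4.0,   # scaffold-dominated Hog1 handling
    },
}

#: Cell-volume module constants of the reference calibration.
REFERENCE_VOLUME_PARAMS: dict[str, float] = {
    "kv": 0.2,
    "Pi0": 0.6,
    "Vb": 0.7,
    "n_fix": 0.55,
    "kg0": 1.0e-4,
    "kg_hog": 2.5e-3,
    "kg_basal": 2.5e-4,
    "kleak": 2.0e-3,
}


def reference_params(mechanism: str = "mixed") -> dict[str, float]:
    """Log10 reference parameter values for one mechanism's calibration."""
    lin = dict(REFERENCE_PARAMS_LINEAR)
    lin.update(MECHANISM_OVERRIDES.get(mechanism, {}))
    return {k: float(np.log10(v)) for k, v in lin.items()}


def reference_network(mechanism: str = "mixed",
                      topology: TopologyConfig | None = None,
                      strain: StrainSpec = WILD_TYPE,
                      params: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Build a network at the reference calibration.

    ``topology`` defaults to the canonical full topology for *mechanism*
    (two-component positive feedback on Pbs2, negative feedback on Ssk2).
    ``params`` may override individual log10 values on top of the calibration.
    """
    top = topology or TopologyConfig(mechanism=mechanism)
    p = reference_params(top.mechanism)
    if params:
        p.update(params)
    net = build_network(top, params=p, volume_params=REFERENCE_VOLUME_PARAMS)
    if not strain.is_wildtype:
        net = apply_strain(net, strain)
    return net
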