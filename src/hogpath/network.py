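"""Reaction-network construction for the yeast HOG (High Osmolarity Glycerol)
MAP-kinase pathway.

The module builds an *overcomplete* ODE reaction network for osmostress-induced
Hog1 activation and carves out submodels ("topologies") that differ in

* the Hog1 phosphorylation mechanism (distributive, processive, or mixed),
* the target and composition of a Hog1-dependent positive feedback
  (catalytic and/or affinity component, on Pbs2 or on upstream sensors), and
* the presence of a Hog1-dependent negative feedback on the MAPKKK Ssk2.

Mechanism semantics
-------------------
Hog1 carries two activating phospho-sites.  Activated Pbs2 (``Pbs2PP``) binds
free Hog1 and performs the first phosphorylation while Hog1 stays bound,
producing a *nascent* mono-phospho complex ``Pbs2PPHog1P``.  The three
mechanisms differ in what this complex may do next:

* ``processive``  -- the complex proceeds directly to doubly phosphorylated
  Hog1 (rate ``k_phospho``); it never releases mono-phosphorylated Hog1.
* ``distributive`` -- the complex must dissociate (rate ``k_off``); free
  mono-phospho Hog1 then rebinds Pbs2PP, forming a *rebound* complex from
  which the second phosphorylation occurs (rate ``k_phospho2``).
* ``mixed``       -- both routes coexist: the immediate second step
  (``k_phospho``) competes with dissociation (``k_off``) and rebinding.

Consequently the mixed network reduces *exactly* to the distributive network
when ``k_phospho`` is zero, and to the processive network when dissociation
and rebinding are removed.

Positive feedback converts activated Pbs2 into a feedback-modified form
(``Pbs2PP_fb``) whose Hog1-association rates are multiplied by
``fb_affinity`` (affinity component) and whose catalytic rates by
``fb_catalytic`` (catalytic component).  The mono-phospho complex on
feedback-modified Pbs2 is the species ``Pbs2PPHog1P_feedback`` entering the
processivity score.

A cell-volume module (turgor pressure, intracellular glycerol, volume) drives
the osmosensors; it is integrated alongside the chemical species but kept out
of the stoichiometry so that protein conservation is exact.
"""

from __future__ import annotations

import copy as _copy
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MECHANISMS",
    "FEEDBACK_TARGETS",
    "PHYSIOLOGICAL_BOUNDS",
    "TopologyConfig",
    "Parameter",
    "Reaction",
    "ReactionNetwork",
    "VolumeState",
    "StrainSpec",
    "NetworkError",
    "StrainError",
    "enumerate_topologies",
    "build_network",
    "apply_strain",
    "build_basic_cascade",
]

MECHANISMS = ("distributive", "processive", "mixed")
FEEDBACK_TARGETS = ("none", "pbs2", "sln1_and_ste20", "ssk1_and_ste20")
FEEDBACK_COMPONENTS = ("catalytic", "affinity")
BOUNDS_MODES = ("unconstrained", "physiological")
COMPARTMENTS = ("cytosol", "nucleus", "membrane")

#: Fraction of total cell volume occupied by the nucleus; used when converting
#: nuclear and cytosolic amounts to concentrations for the nuc:cyt observable.
NUCLEAR_VOLUME_FRACTION = 0.1

#: Log10 bound table used in ``bounds_mode='physiological'``.  Classes follow
#: typical yeast kinase/phosphatase kinetics: catalytic rates of order
#: 0.1-100 /s, association rates bounded by a diffusion-limited ceiling
#: (here 100 in normalized copy-number units), Michaelis constants around the
#: protein abundance scale.  Parameters of unknown class keep the
#: unconstrained range.
PHYSIOLOGICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "kinase_kcat": (-1.0, 2.0),
    "phosphatase_kcat": (-1.0, 2.0),
    "association": (-3.0, 2.0),
    "dissociation": (-3.0, 2.0),
    "km": (-2.0, 1.0),
    "transport": (-3.0, 1.0),
    "multiplier": (0.0, 3.0),
    "other": (-3.0, 3.0),
}

UNCONSTRAINED_BOUNDS = (-3.0, 3.0)


class NetworkError(ValueError):
    """Raised for invalid topology or network specifications."""


class StrainError(ValueError):
    """Raised when a strain specification cannot be applied to a network."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyConfig:
    """Switchboard selecting one submodel of the overcomplete HOG model."""

    mechanism: str = "mixed"
    positive_feedback_target: str = "pbs2"
    feedback_components: frozenset = frozenset({"catalytic", "affinity"})
    negative_feedback_ssk2: bool = True
    bounds_mode: str = "unconstrained"

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise NetworkError(f"unknown mechanism {self.mechanism!r}")
        if self.positive_feedback_target not in FEEDBACK_TARGETS:
            raise NetworkError(
                f"unknown positive_feedback_target {self.positive_feedback_target!r}")
        comps = frozenset(self.feedback_components)
        object.__setattr__(self, "feedback_components", comps)
        if not comps <= set(FEEDBACK_COMPONENTS):
            raise NetworkError(f"unknown feedback components {comps - set(FEEDBACK_COMPONENTS)}")
        if self.positive_feedback_target == "none" and comps:
            raise NetworkError("feedback components given but positive_feedback_target is 'none'")
        if self.positive_feedback_target != "none" and not comps:
            raise NetworkError("positive feedback target set but no feedback components named")
        if self.bounds_mode not in BOUNDS_MODES:
            raise NetworkError(f"unknown bounds_mode {self.bounds_mode!r}")

    @property
    def label(self) -> str:
        fb = self.positive_feedback_target
        if fb != "none":
            fb += "(" + "+".join(sorted(self.feedback_components)) + ")"
        nfb = "nfb" if self.negative_feedback_ssk2 else "no-nfb"
        return f"{self.mechanism}/{fb}/{nfb}"

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "positive_feedback_target": self.positive_feedback_target,
            "feedback_components": sorted(self.feedback_components),
            "negative_feedback_ssk2": self.negative_feedback_ssk2,
            "bounds_mode": self.bounds_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TopologyConfig":
        target = d.get("positive_feedback_target", "pbs2")
        if "feedback_components" in d:
            comps = frozenset(d["feedback_components"])
        else:
            comps = frozenset(FEEDBACK_COMPONENTS) if target != "none" else frozenset()
        return cls(
            mechanism=d.get("mechanism", "mixed"),
            positive_feedback_target=target,
            feedback_components=comps,
            negative_feedback_ssk2=bool(d.get("negative_feedback_ssk2", True)),
            bounds_mode=d.get("bounds_mode", "unconstrained"),
        )


@dataclass(frozen=True)
class Parameter:
    """One kinetic parameter, handled on a log10 scale during fitting."""

    name: str
    log10_value: float
    lower: float = UNCONSTRAINED_BOUNDS[0]
    upper: float = UNCONSTRAINED_BOUNDS[1]
    fixed: bool = False
    cls: str = "other"

    @property
    def value(self) -> float:
        return 10.0 ** self.log10_value


@dataclass(frozen=True)
class Reaction:
    """A single reaction with mass-action or Michaelis-Menten kinetics.

    ``params`` is a tuple of parameter names whose *linear* values multiply to
    give the rate constant (so feedback multipliers compose transparently).
    For Michaelis-Menten kinetics ``params`` is ``(kcat, Km)`` and ``enzyme``
    names the catalysing species; the rate is ``kcat*E*S/(Km + S)``.
    Catalysts of mass-action reactions appear on both sides with equal
    stoichiometry.  ``signal_modulated`` reactions have their rate multiplied
    by the turgor-loss signal s(t) in [0, 1].
    """

    name: str
    reactants: tuple  # ((species, stoich), ...)
    products: tuple
    kind: str = "mass_action"
    params: tuple = ()
    enzyme: str | None = None
    signal_modulated: bool = False

    def __post_init__(self):
        if self.kind not in ("mass_action", "michaelis_menten"):
            raise NetworkError(f"unknown rate-law kind {self.kind!r}")
        if self.kind == "michaelis_menten":
            if self.enzyme is None or len(self.params) != 2:
                raise NetworkError(
                    f"reaction {self.name}: Michaelis-Menten needs (kcat, Km) and an enzyme")


@dataclass
class VolumeState:
    """Osmotic state of the cell at one instant.

    All osmotic quantities share the same (osmolar) units; volume is a
    fraction of the pre-stress volume.
    """

    external_osmolarity: float
    turgor: float
    glycerol: float
    volume: float

    def __post_init__(self):
        if self.volume <= 0:
            raise NetworkError("cell volume must be strictly positive")
        if self.turgor < 0:
            raise NetworkError("turgor pressure cannot be negative")


@dataclass(frozen=True)
class StrainSpec:
    """Genetic background applied to a network before simulation."""

    deletions: frozenset = frozenset()
    pbs2_s248: str = "wt"  # 'wt' | 'S248A' | 'S248E'
    ssk2_feedback_dead: bool = False
    hog1_inhibited: bool = False
    overexpression: tuple = ()  # ((protein, factor), ...)

    def __post_init__(self):
        object.__setattr__(self, "deletions", frozenset(self.deletions))
        if self.pbs2_s248 not in ("wt", "S248A", "S248E"):
            raise StrainError(f"invalid pbs2_s248 {self.pbs2_s248!r}")
        over = tuple(sorted(dict(self.overexpression).items()))
        object.__setattr__(self, "overexpression", over)
        for prot, fac in over:
            if fac <= 0:
                raise StrainError(f"overexpression factor for {prot} must be > 0")

    @property
    def is_wildtype(self) -> bool:
        return (not self.deletions and self.pbs2_s248 == "wt"
                and not self.ssk2_feedback_dead and not self.hog1_inhibited
                and not self.overexpression)

    def to_dict(self) -> dict:
        return {
            "deletions": sorted(self.deletions),
            "pbs2_s248": self.pbs2_s248,
            "ssk2_feedback_dead": self.ssk2_feedback_dead,
            "hog1_inhibited": self.hog1_inhibited,
            "overexpression": dict(self.overexpression),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StrainSpec":
        return cls(
            deletions=frozenset(d.get("deletions", ())),
            pbs2_s248=d.get("pbs2_s248", "wt"),
            ssk2_feedback_dead=bool(d.get("ssk2_feedback_dead", False)),
            hog1_inhibited=bool(d.get("hog1_inhibited", False)),
            overexpression=tuple(dict(d.get("overexpression", {})).items()),
        )


WILD_TYPE = StrainSpec()


class ReactionNetwork:
    """Species, reactions and parameters of one HOG submodel.

    The network is an immutable-by-convention value object: operations that
    modify it (``apply_strain``, parameter updates) return copies.
    """

    def __init__(self, name, species, reactions, parameters, conserved_totals,
                 topology=None, volume_params=None, kind="hog",
                 strain=WILD_TYPE):
        self.name = name
        # species: list of (name, compartment, initial amount)
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = {p.name: p for p in parameters}
        if len(self.parameters) != len(parameters):
            raise NetworkError("duplicate parameter names")
        self.conserved_totals = {k: tuple(v) for k, v in conserved_totals.items()}
        self.topology = topology
        self.volume_params = dict(volume_params) if volume_params else None
        self.kind = kind
        self.strain = strain
        self._index = {s[0]: i for i, s in enumerate(self.species)}
        self._validate()

    # -- basic introspection ------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s[0] for s in self.species]

    @property
    def has_volume(self) -> bool:
        return self.volume_params is not None

    def species_index(self, name: str) -> int:
        return self._index[name]

    def compartment(self, name: str) -> str:
        return self.species[self._index[name]][1]

    def initial_amounts(self) -> np.ndarray:
        return np.array([s[2] for s in self.species], dtype=float)

    def species_in_compartment(self, compartment: str) -> list[str]:
        return [s[0] for s in self.species if s[1] == compartment]

    def _validate(self):
        names = set(self._index)
        for rxn in self.reactions:
            for sp, _ in rxn.reactants + rxn.products:
                if sp not in names:
                    raise NetworkError(f"reaction {rxn.name}: unknown species {sp}")
            if rxn.enzyme is not None and rxn.enzyme not in names:
                raise NetworkError(f"reaction {rxn.name}: unknown enzyme {rxn.enzyme}")
            for p in rxn.params:
                if p not in self.parameters:
                    raise NetworkError(f"reaction {rxn.name}: unknown parameter {p}")
        for sname, _, init in self.species:
            if init < 0:
                raise NetworkError(f"negative initial amount for {sname}")
        for prot, members in self.conserved_totals.items():
            for m in members:
                if m not in names:
                    raise NetworkError(f"conserved total {prot}: unknown species {m}")

    # -- stoichiometry ------------------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        """Dense stoichiometry matrix N (species x reactions)."""
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sp, st in rxn.reactants:
                N[self._index[sp], j] -= st
            for sp, st in rxn.products:
                N[self._index[sp], j] += st
        return N

    def conservation_vector(self, protein: str) -> np.ndarray:
        v = np.zeros(len(self.species))
        for m in self.conserved_totals[protein]:
            v[self._index[m]] = 1.0
        return v

    # -- parameters ---------------------------------------------------------

    def param_value(self, name: str) -> float:
        return self.parameters[name].value

    def rate_constant(self, names: Iterable[str]) -> float:
        out = 1.0
        for n in names:
            out *= self.parameters[n].value
        return out

    def free_parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters.values() if not p.fixed]

    def log10_values(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.free_parameter_names()
        return np.array([self.parameters[n].log10_value for n in names])

    def bounds(self, names: Sequence[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.free_parameter_names()
        return np.array([(self.parameters[n].lower, self.parameters[n].upper)
                         for n in names])

    def with_params(self, updates: Mapping[str, float]) -> "ReactionNetwork":
        """Return a copy with parameter log10 values replaced."""
        net = self.copy()
        for name, lv in updates.items():
            if name not in net.parameters:
                raise NetworkError(f"unknown parameter {name}")
            net.parameters[name] = replace(net.parameters[name], log10_value=float(lv))
        return net

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            self.name, [tuple(s) for s in self.species], list(self.reactions),
            list(self.parameters.values()), dict(self.conserved_totals),
            topology=self.topology,
            volume_params=dict(self.volume_params) if self.volume_params else None,
            kind=self.kind, strain=self.strain)

    # -- export -------------------------------------------------------------

    def to_table(self) -> str:
        """Plain-text reaction table (one reaction per line)."""
        buf = io.StringIO()
        buf.write("# reaction\treactants\tproducts\tkind\tparameters\n")
        for rxn in self.reactions:
            lhs = " + ".join(f"{st}*{sp}" if st != 1 else sp for sp, st in rxn.reactants) or "0"
            rhs = " + ".join(f"{st}*{sp}" if st != 1 else sp for sp, st in rxn.products) or "0"
            pars = ",".join(rxn.params)
            if rxn.enzyme:
                pars += f";enzyme={rxn.enzyme}"
            if rxn.signal_modulated:
                pars += ";signal"
            buf.write(f"{rxn.name}\t{lhs}\t{rhs}\t{rxn.kind}\t{pars}\n")
        return buf.getvalue()

    def to_sbml(self) -> str:
        """Minimal SBML level-3 document for interchange (kinetics omitted)."""
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">',
            f'  <model id="{self.name}">',
            "    <listOfCompartments>",
        ]
        for c in COMPARTMENTS:
            lines.append(f'      <compartment id="{c}" constant="true"/>')
        lines.append("    </listOfCompartments>")
        lines.append("    <listOfSpecies>")
        for sp, comp, init in self.species:
            lines.append(
                f'      <species id="{sp}" compartment="{comp}" '
                f'initialAmount="{init}" hasOnlySubstanceUnits="true" '
                'boundaryCondition="false" constant="false"/>')
        lines.append("    </listOfSpecies>")
        lines.append("    <listOfParameters>")
        for p in self.parameters.values():
            lines.append(f'      <parameter id="{p.name}" value="{p.value}" constant="true"/>')
        lines.append("    </listOfParameters>")
        lines.append("    <listOfReactions>")
        for rxn in self.reactions:
            lines.append(f'      <reaction id="{rxn.name}" reversible="false">')
            if rxn.reactants:
                lines.append("        <listOfReactants>")
                for sp, st in rxn.reactants:
                    lines.append(f'          <speciesReference species="{sp}" stoichiometry="{st}" constant="true"/>')
                lines.append("        </listOfReactants>")
            if rxn.products:
                lines.append("        <listOfProducts>")
                for sp, st in rxn.products:
                    lines.append(f'          <speciesReference species="{sp}" stoichiometry="{st}" constant="true"/>')
                lines.append("        </listOfProducts>")
            lines.append("      </reaction>")
        lines.append("    </listOfReactions>")
        lines.append("  </model>")
        lines.append("</sbml>")
        return "\n".join(lines) + "\n"

    def __repr__(self):
        return (f"<ReactionNetwork {self.name!r}: {len(self.species)} species, "
                f"{len(self.reactions)} reactions, {len(self.parameters)} parameters>")


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def enumerate_topologies(include_mixed: bool = False,
                         bounds_mode: str = "unconstrained") -> list[TopologyConfig]:
    """Enumerate the canonical submodel topologies.

    The canonical set crosses {distributive, processive} phosphorylation with
    presence/absence of the two-component positive feedback on Pbs2 and of the
    negative feedback on Ssk2 (8 configurations).  With ``include_mixed`` the
    four mixed-mechanism combinations are appended (12 total).
    """
    out = []
    mechs = ["distributive", "processive"] + (["mixed"] if include_mixed else [])
    for mech in mechs:
        for pfb in (True, False):
            for nfb in (True, False):
                out.append(TopologyConfig(
                    mechanism=mech,
                    positive_feedback_target="pbs2" if pfb else "none",
                    feedback_components=frozenset(FEEDBACK_COMPONENTS) if pfb else frozenset(),
                    negative_feedback_ssk2=nfb,
                    bounds_mode=bounds_mode,
                ))
    return out


# ---------------------------------------------------------------------------
# Default kinetic parameters (linear scale) for the overcomplete model.
# The reference calibration in ``calibration.py`` overrides these.
# ---------------------------------------------------------------------------

_DEFAULT_PARAMS: dict[str, tuple[float, str]] = {
    # (linear default, parameter class)
    # Sln1 phospho-relay (collapsed to a stress-responsive two-state switch)
    "k_sln1_off": (0.2, "kinase_kcat"),
    "k_sln1_on": (0.05, "kinase_kcat"),
    "k_ssk1_act": (0.02, "kinase_kcat"),
    "k_ssk1_deact": (2.0, "kinase_kcat"),
    "k_ssk1_deact0": (0.01, "kinase_kcat"),
    "k_ssk2_act": (1.0, "kinase_kcat"),
    "k_ssk2_deact": (0.1, "phosphatase_kcat"),
    "k_nfb": (1.0, "kinase_kcat"),
    # Sho1 branch (scaffolded Ste20/Ste50/Ste11 activation, sequential)
    "k_sho1_act": (0.1, "kinase_kcat"),
    "k_sho1_deact": (0.1, "phosphatase_kcat"),
    "k_ste20_act": (1.0, "kinase_kcat"),
    "k_ste20_deact": (0.2, "phosphatase_kcat"),
    "k_ste11_act": (1.0, "kinase_kcat"),
    "k_ste11_deact": (0.2, "phosphatase_kcat"),
    # Pbs2 activation / deactivation (activation saturable in Pbs2)
    "k_pbs2_ssk2": (2.0, "kinase_kcat"),
    "k_pbs2_ste11": (1.0, "kinase_kcat"),
    "km_pbs2": (0.2, "km"),
    "k_pbs2_deph": (0.5, "phosphatase_kcat"),
    # Pbs2 scaffold binding of unphosphorylated Hog1 (nonproductive)
    "kon_scaffold": (0.2, "association"),
    "koff_scaffold": (1.0, "dissociation"),
    # Hog1-Pbs2 phosphorylation module
    "kon_hog1": (5.0, "association"),
    "koff_hog1": (1.0, "dissociation"),
    "k_phospho1": (5.0, "kinase_kcat"),
    "k_phospho": (0.05, "kinase_kcat"),    # immediate second step (processive route)
    "k_off": (1.0, "dissociation"),        # mono-phospho complex dissociation
    "kon_hog1p": (5.0, "association"),     # rebinding of mono-phospho Hog1
    "k_phospho2": (2.0, "kinase_kcat"),    # second step after rebinding
    # Positive feedback
    "fb_affinity": (10.0, "multiplier"),
    "fb_catalytic": (50.0, "multiplier"),
    "k_fb_conv": (5.0, "kinase_kcat"),
    "k_fb_rev": (0.05, "phosphatase_kcat"),
    # Phosphatases
    "kcat_ptp2": (2.0, "phosphatase_kcat"),
    "km_ptp2": (0.3, "km"),
    "kcat_ptp3": (1.0, "phosphatase_kcat"),
    "km_ptp3": (0.3, "km"),
    "k_ptc": (0.01, "phosphatase_kcat"),
    # Nucleocytoplasmic shuttling
    "k_imp": (0.01, "transport"),
    "k_exp": (0.05, "transport"),
    "k_imp_pp": (0.2, "transport"),
    "k_exp_pp": (0.02, "transport"),
}

#: Cell-volume module constants (linear scale, not part of the kinetic
#: parameter vector by default).  Units: osmotic quantities in osM, volume as
#: a fraction of the pre-stress volume, rates in /s.
DEFAULT_VOLUME_PARAMS: dict[str, float] = {
    "kv": 0.01,         # volume relaxation rate
    "Pi0": 0.6,         # resting turgor pressure (osM equivalent)
    "Vb": 0.8,          # volume at which turgor vanishes
    "n_fix": 0.55,      # fixed internal osmolyte amount
    "kg0": 2.5e-4,      # constitutive glycerol production
    "kg_hog": 1.0e-3,   # Hog1-PP dependent glycerol production (Gpd1 proxy)
    "kg_basal": 3.0e-4,  # Hog1-independent stress-induced production
    "kleak": 5.0e-3,    # glycerol leak through turgor-gated channels
}


def _mk_params(overrides: Mapping[str, float] | None,
               names: Iterable[str],
               bounds_mode: str,
               fixed: Iterable[str] = ()) -> list[Parameter]:
    fixed = set(fixed)
    out = []
    for n in names:
        default, cls = _DEFAULT_PARAMS[n]
        lv = float(overrides[n]) if overrides and n in overrides else float(np.log10(default))
        if bounds_mode == "physiological":
            lo, hi = PHYSIOLOGICAL_BOUNDS.get(cls, UNCONSTRAINED_BOUNDS)
        else:
            lo, hi = UNCONSTRAINED_BOUNDS
        # defaults outside the box are clipped into it so that every shipped
        # network is admissible under its own bounds
        lv_b = float(np.clip(lv, lo, hi))
        out.append(Parameter(n, lv_b, lo, hi, fixed=n in fixed, cls=cls))
    return out


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------

def build_network(topology: TopologyConfig,
                  params: Mapping[str, float] | None = None,
                  totals: Mapping[str, float] | None = None,
                  volume_params: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Construct the HOG reaction network for one topology.

    Parameters
    ----------
    topology
        The submodel selector.
    params
        Optional overrides of parameter *log10* values by name.
    totals
        Optional overrides of protein totals (linear), default 1.0 each.
    volume_params
        Optional overrides of the cell-volume module constants (linear).
    """
    if not isinstance(topology, TopologyConfig):
        raise NetworkError("topology must be a TopologyConfig")
    mech = topology.mechanism
    fb_target = topology.positive_feedback_target
    comps = topology.feedback_components

    tot = {p: 1.0 for p in ("Hog1", "Pbs2", "Ssk2", "Sln1", "Ssk1", "Sho1",
                            "Ste11", "Ste20", "Ptp2", "Ptp3")}
    if totals:
        tot.update(totals)

    species: list[tuple[str, str, float]] = [
        ("Sln1", "membrane", tot["Sln1"]),
        ("Sln1_off", "membrane", 0.0),
        ("Ssk1", "cytosol", tot["Ssk1"]),
        ("Ssk1_act", "cytosol", 0.0),
        ("Ssk2", "cytosol", tot["Ssk2"]),
        ("Ssk2_act", "cytosol", 0.0),
        ("Sho1", "membrane", tot["Sho1"]),
        ("Sho1_act", "membrane", 0.0),
        ("Ste20", "cytosol", tot["Ste20"]),
        ("Ste20_act", "cytosol", 0.0),
        ("Ste11", "cytosol", tot["Ste11"]),
        ("Ste11_act", "cytosol", 0.0),
        ("Pbs2", "cytosol", tot["Pbs2"]),
        ("Pbs2PP", "cytosol", 0.0),
        ("Pbs2_Hog1", "cytosol", 0.0),
        ("Hog1_c", "cytosol", tot["Hog1"]),
        ("Hog1P_c", "cytosol", 0.0),
        ("Hog1PP_c", "cytosol", 0.0),
        ("Hog1_n", "nucleus", 0.0),
        ("Hog1P_n", "nucleus", 0.0),
        ("Hog1PP_n", "nucleus", 0.0),
        ("Pbs2PP_Hog1", "cytosol", 0.0),
        ("Pbs2PPHog1P", "cytosol", 0.0),
        ("Pbs2PPHog1P_rebound", "cytosol", 0.0),
        ("Ptp2", "nucleus", tot["Ptp2"]),
        ("Ptp3", "cytosol", tot["Ptp3"]),
    ]

    rxns: list[Reaction] = []
    pnames: set[str] = set()

    def R(name, reactants, products, params_=(), kind="mass_action",
          enzyme=None, signal=False):
        rxns.append(Reaction(name, tuple(reactants), tuple(products), kind,
                             tuple(params_), enzyme, signal))
        pnames.update(params_)

    one = lambda *sp: tuple((s, 1) for s in sp)

    # --- Sln1 branch: stress inactivates Sln1, relieving Ssk1 repression ---
    R("sln1_inactivation", one("Sln1"), one("Sln1_off"), ("k_sln1_off",), signal=True)
    R("sln1_reactivation", one("Sln1_off"), one("Sln1"), ("k_sln1_on",))
    R("ssk1_activation", one("Ssk1"), one("Ssk1_act"), ("k_ssk1_act",))
    # Sln1 represses Ssk1 as a dimeric sensor: second order in active Sln1,
    # which steepens the relay's response to partial Sln1 inactivation
    R("ssk1_repression", (("Ssk1_act", 1), ("Sln1", 2)),
      (("Ssk1", 1), ("Sln1", 2)), ("k_ssk1_deact",))
    R("ssk1_decay", one("Ssk1_act"), one("Ssk1"), ("k_ssk1_deact0",))
    R("ssk2_activation", one("Ssk2", "Ssk1_act"), one("Ssk2_act", "Ssk1_act"), ("k_ssk2_act",))
    R("ssk2_deactivation", one("Ssk2_act"), one("Ssk2"), ("k_ssk2_deact",))
    if topology.negative_feedback_ssk2:
        R("ssk2_negative_feedback", one("Ssk2_act", "Hog1PP_c"),
          one("Ssk2", "Hog1PP_c"), ("k_nfb",))

    # --- Sho1 branch ---
    R("sho1_activation", one("Sho1"), one("Sho1_act"), ("k_sho1_act",), signal=True)
    R("sho1_deactivation", one("Sho1_act"), one("Sho1"), ("k_sho1_deact",))
    # Sho1 signals through a scaffolded (oligomeric) membrane complex:
    # Ste20 activation is second order in active Sho1
    R("ste20_activation", (("Ste20", 1), ("Sho1_act", 2)),
      (("Ste20_act", 1), ("Sho1_act", 2)), ("k_ste20_act",))
    R("ste20_deactivation", one("Ste20_act"), one("Ste20"), ("k_ste20_deact",))
    R("ste11_activation", one("Ste11", "Ste20_act"), one("Ste11_act", "Ste20_act"), ("k_ste11_act",))
    R("ste11_deactivation", one("Ste11_act"), one("Ste11"), ("k_ste11_deact",))

    # --- Pbs2 activation by either MAPKKK (saturable in Pbs2) ---
    R("pbs2_activation_ssk2", one("Pbs2"), one("Pbs2PP"), ("k_pbs2_ssk2", "km_pbs2"),
      kind="michaelis_menten", enzyme="Ssk2_act")
    R("pbs2_activation_ste11", one("Pbs2"), one("Pbs2PP"), ("k_pbs2_ste11", "km_pbs2"),
      kind="michaelis_menten", enzyme="Ste11_act")
    R("pbs2_deactivation", one("Pbs2PP"), one("Pbs2"), ("k_pbs2_deph",))

    # --- Scaffold binding of Hog1 to inactive Pbs2 (nonproductive) ---
    R("scaffold_binding", one("Pbs2", "Hog1_c"), one("Pbs2_Hog1"), ("kon_scaffold",))
    R("scaffold_release", one("Pbs2_Hog1"), one("Pbs2", "Hog1_c"), ("koff_scaffold",))

    # --- Hog1-Pbs2 phosphorylation module -----------------------------------
    def hog1_module(pbs2pp, c1, c2a, c2b, suffix, extra=()):
        """Attach one copy of the Hog1 phosphorylation module to *pbs2pp*.

        ``extra`` holds multiplier parameter names (feedback components).
        Association reactions get affinity multipliers, catalytic steps get
        catalytic multipliers; dissociation rates are never modified.
        """
        aff = tuple(p for p in extra if p == "fb_affinity")
        cat = tuple(p for p in extra if p == "fb_catalytic")
        R(f"hog1_binding{suffix}", one(pbs2pp, "Hog1_c"), ((c1, 1),), ("kon_hog1",) + aff)
        R(f"hog1_unbinding{suffix}", ((c1, 1),), one(pbs2pp, "Hog1_c"), ("koff_hog1",))
        R(f"hog1_first_phospho{suffix}", ((c1, 1),), ((c2a, 1),), ("k_phospho1",) + cat)
        if mech in ("processive", "mixed"):
            R(f"hog1_second_phospho_immediate{suffix}", ((c2a, 1),),
              one(pbs2pp, "Hog1PP_c"), ("k_phospho",) + cat)
        if mech in ("distributive", "mixed"):
            R(f"hog1p_dissociation{suffix}", ((c2a, 1),), one(pbs2pp, "Hog1P_c"), ("k_off",))
            R(f"hog1p_rebinding{suffix}", one(pbs2pp, "Hog1P_c"), ((c2b, 1),),
              ("kon_hog1p",) + aff)
            R(f"hog1_second_phospho_rebound{suffix}", ((c2b, 1),),
              one(pbs2pp, "Hog1PP_c"), ("k_phospho2",) + cat)
            R(f"hog1p_rebound_dissociation{suffix}", ((c2b, 1),),
              one(pbs2pp, "Hog1P_c"), ("k_off",))

    hog1_module("Pbs2PP", "Pbs2PP_Hog1", "Pbs2PPHog1P", "Pbs2PPHog1P_rebound", "")

    # --- Positive feedback ---------------------------------------------------
    if fb_target == "pbs2":
        species += [
            ("Pbs2PP_fb", "cytosol", 0.0),
            ("Pbs2PP_fb_Hog1", "cytosol", 0.0),
            ("Pbs2PPHog1P_feedback", "cytosol", 0.0),
            ("Pbs2PPHog1P_feedback_rebound", "cytosol", 0.0),
        ]
        mult = tuple(sorted(f"fb_{c}" for c in comps))
        R("pbs2_feedback_conversion", one("Pbs2PP", "Hog1PP_c"),
          one("Pbs2PP_fb", "Hog1PP_c"), ("k_fb_conv",))
        R("pbs2_feedback_reversal", one("Pbs2PP_fb"), one("Pbs2PP"), ("k_fb_rev",))
        R("pbs2_fb_deactivation", one("Pbs2PP_fb"), one("Pbs2"), ("k_pbs2_deph",))
        hog1_module("Pbs2PP_fb", "Pbs2PP_fb_Hog1", "Pbs2PPHog1P_feedback",
                    "Pbs2PPHog1P_feedback_rebound", "_fb", extra=mult)
    elif fb_target in ("sln1_and_ste20", "ssk1_and_ste20"):
        mult = tuple(sorted(f"fb_{c}" for c in comps))
        # Ste20 component: feedback-modified active Ste20 with boosted Ste11
        # activation (both multipliers act on the activation rate since the
        # target couples to its substrate without an explicit binding step).
        species.append(("Ste20_act_fb", "cytosol", 0.0))
        R("ste20_feedback_conversion", one("Ste20_act", "Hog1PP_c"),
          one("Ste20_act_fb", "Hog1PP_c"), ("k_fb_conv",))
        R("ste20_feedback_reversal", one("Ste20_act_fb"), one("Ste20_act"), ("k_fb_rev",))
        R("ste20_fb_deactivation", one("Ste20_act_fb"), one("Ste20"), ("k_ste20_deact",))
        R("ste11_activation_fb", one("Ste11", "Ste20_act_fb"),
          one("Ste11_act", "Ste20_act_fb"), ("k_ste11_act",) + mult)
        if fb_target == "sln1_and_ste20":
            # Hog1-PP promotes Sln1 inactivation, de-repressing Ssk1.
            R("sln1_feedback_inactivation", one("Sln1", "Hog1PP_c"),
              one("Sln1_off", "Hog1PP_c"), ("k_fb_conv",) + mult)
        else:
            species.append(("Ssk1_act_fb", "cytosol", 0.0))
            R("ssk1_feedback_conversion", one("Ssk1_act", "Hog1PP_c"),
              one("Ssk1_act_fb", "Hog1PP_c"), ("k_fb_conv",))
            R("ssk1_feedback_reversal", one("Ssk1_act_fb"), one("Ssk1_act"), ("k_fb_rev",))
            R("ssk1_fb_repression", (("Ssk1_act_fb", 1), ("Sln1", 2)),
              (("Ssk1", 1), ("Sln1", 2)), ("k_ssk1_deact",))
            R("ssk2_activation_fb", one("Ssk2", "Ssk1_act_fb"),
              one("Ssk2_act", "Ssk1_act_fb"), ("k_ssk2_act",) + mult)

    # --- Phosphatases --------------------------------------------------------
    # Ptp2 (nuclear) and Ptp3 (cytosolic) remove phosphates stepwise with
    # Michaelis-Menten kinetics; Ptc1/Ptc2-3 are a lumped constitutive
    # background acting in both compartments.
    R("ptp3_pp", one("Hog1PP_c"), one("Hog1P_c"), ("kcat_ptp3", "km_ptp3"),
      kind="michaelis_menten", enzyme="Ptp3")
    R("ptp3_p", one("Hog1P_c"), one("Hog1_c"), ("kcat_ptp3", "km_ptp3"),
      kind="michaelis_menten", enzyme="Ptp3")
    R("ptp2_pp", one("Hog1PP_n"), one("Hog1P_n"), ("kcat_ptp2", "km_ptp2"),
      kind="michaelis_menten", enzyme="Ptp2")
    R("ptp2_p", one("Hog1P_n"), one("Hog1_n"), ("kcat_ptp2", "km_ptp2"),
      kind="michaelis_menten", enzyme="Ptp2")
    R("ptc_pp_c", one("Hog1PP_c"), one("Hog1P_c"), ("k_ptc",))
    R("ptc_p_c", one("Hog1P_c"), one("Hog1_c"), ("k_ptc",))
    R("ptc_pp_n", one("Hog1PP_n"), one("Hog1P_n"), ("k_ptc",))
    R("ptc_p_n", one("Hog1P_n"), one("Hog1_n"), ("k_ptc",))

    # --- Hog1 nucleocytoplasmic shuttling ------------------------------------
    R("import_hog1", one("Hog1_c"), one("Hog1_n"), ("k_imp",))
    R("export_hog1", one("Hog1_n"), one("Hog1_c"), ("k_exp",))
    R("import_hog1p", one("Hog1P_c"), one("Hog1P_n"), ("k_imp",))
    R("export_hog1p", one("Hog1P_n"), one("Hog1P_c"), ("k_exp",))
    R("import_hog1pp", one("Hog1PP_c"), one("Hog1PP_n"), ("k_imp_pp",))
    R("export_hog1pp", one("Hog1PP_n"), one("Hog1PP_c"), ("k_exp_pp",))

    # --- Conserved totals ----------------------------------------------------
    sp_names = [s[0] for s in species]
    hog1_members = [s for s in sp_names if "Hog1" in s]
    pbs2_members = [s for s in sp_names if "Pbs2" in s]
    conserved = {
        "Hog1": hog1_members,
        "Pbs2": pbs2_members,
        "Ssk2": ["Ssk2", "Ssk2_act"],
        "Sln1": ["Sln1", "Sln1_off"],
        "Ssk1": [s for s in sp_names if s.startswith("Ssk1")],
        "Sho1": ["Sho1", "Sho1_act"],
        "Ste11": ["Ste11", "Ste11_act"],
        "Ste20": [s for s in sp_names if s.startswith("Ste20")],
        "Ptp2": ["Ptp2"],
        "Ptp3": ["Ptp3"],
    }

    vol = dict(DEFAULT_VOLUME_PARAMS)
    if volume_params:
        vol.update(volume_params)

    parameters = _mk_params(params, sorted(pnames), topology.bounds_mode)
    return ReactionNetwork(
        name=f"hog_{topology.label}",
        species=species,
        reactions=rxns,
        parameters=parameters,
        conserved_totals=conserved,
        topology=topology,
        volume_params=vol,
        kind="hog",
    )


# ---------------------------------------------------------------------------
# apply_strain
# ---------------------------------------------------------------------------

def apply_strain(network: ReactionNetwork, strain: StrainSpec) -> ReactionNetwork:
    """Return a copy of *network* with a genetic background applied.

    Deletions zero the protein's total; overexpression scales initial totals;
    S248A removes the affinity component from the feedback-modified Hog1
    association reactions (catalytic component untouched); S248E applies the
    affinity multiplier to the base association reactions, i.e. fixes the
    Hog1-association parameters at their feedback-modified values from the
    unstressed steady state on; ``hog1_inhibited`` silences every reaction
    catalysed by active Hog1 (feedback conversions, negative feedback, the
    Hog1-dependent glycerol production) while Hog1's own phosphorylation and
    binding remain intact; ``ssk2_feedback_dead`` removes the negative
    feedback reaction.
    """
    if not isinstance(strain, StrainSpec):
        raise StrainError("strain must be a StrainSpec")
    net = network.copy()
    gene_to_protein = {"PBS2": "Pbs2", "SLN1": "Sln1", "SHO1": "Sho1",
                       "SSK2": "Ssk2", "PTP2": "Ptp2", "PTP3": "Ptp3"}

    species = [list(s) for s in net.species]
    index = {s[0]: i for i, s in enumerate(species)}

    for gene in sorted(strain.deletions):
        prot = gene_to_protein.get(gene, gene)
        if prot not in net.conserved_totals:
            raise StrainError(f"cannot delete {gene}: protein {prot} not in network")
        for m in net.conserved_totals[prot]:
            species[index[m]][2] = 0.0

    for prot, fac in strain.overexpression:
        if prot not in net.conserved_totals:
            raise StrainError(f"cannot overexpress {prot}: not in network")
        for m in net.conserved_totals[prot]:
            species[index[m]][2] *= fac

    reactions = list(net.reactions)

    if strain.pbs2_s248 == "S248A":
        reactions = [
            replace(r, params=tuple(p for p in r.params if p != "fb_affinity"))
            if r.name.endswith("_fb") and ("binding" in r.name or "rebinding" in r.name)
            else r
            for r in reactions
        ]
    elif strain.pbs2_s248 == "S248E":
        if "fb_affinity" in net.parameters:
            def _boost(r):
                base = ("hog1_binding", "hog1p_rebinding")
                if r.name in base and "fb_affinity" not in r.params:
                    return replace(r, params=r.params + ("fb_affinity",))
                return r
            reactions = [_boost(r) for r in reactions]

    drop = set()
    if strain.ssk2_feedback_dead or strain.hog1_inhibited:
        drop.add("ssk2_negative_feedback")
    if strain.hog1_inhibited:
        for r in reactions:
            if "feedback_conversion" in r.name or r.name == "sln1_feedback_inactivation":
                drop.add(r.name)
    reactions = [r for r in reactions if r.name not in drop]

    vol = dict(net.volume_params) if net.volume_params else None
    if strain.hog1_inhibited and vol is not None:
        vol["kg_hog"] = 0.0

    return ReactionNetwork(
        name=net.name, species=[tuple(s) for s in species], reactions=reactions,
        parameters=list(net.parameters.values()),
        conserved_totals=net.conserved_totals, topology=net.topology,
        volume_params=vol, kind=net.kind, strain=strain)


# ---------------------------------------------------------------------------
# Basic three-tier MAPK cascade (no feedback)
# ---------------------------------------------------------------------------

_CASCADE_PARAMS: dict[str, tuple[float, str]] = {
    "input": (0.1, "other"),
    "k1": (1.0, "kinase_kcat"),
    "d1": (0.25, "phosphatase_kcat"),
    "k2": (1.0, "kinase_kcat"),
    "km_kk": (0.05, "km"),
    "d2": (0.25, "phosphatase_kcat"),
    "km_kk_p": (0.05, "km"),
    "kon_mapk": (5.0, "association"),
    "koff_mapk": (1.0, "dissociation"),
    "kcat_mapk1": (5.0, "kinase_kcat"),
    "k_phospho": (2.0, "kinase_kcat"),
    "k_off": (1.0, "dissociation"),
    "kon_mapkp": (5.0, "association"),
    "k_phospho2": (2.0, "kinase_kcat"),
    "d3": (0.25, "phosphatase_kcat"),
    "d3_mono": (0.25, "phosphatase_kcat"),
    "km_k": (0.05, "km"),
}


def build_basic_cascade(mechanism: str = "distributive",
                        params: Mapping[str, float] | None = None) -> ReactionNetwork:
    """Three-tier MAPK cascade (MAPKKK -> MAPKK -> MAPK), no feedback.

    Dual phosphorylation at the lower two tiers; first-order phosphatase
    steps at every tier; the MAPK tier uses explicit kinase-substrate
    complexes so that the distributive/processive mechanism choice is encoded
    structurally, exactly as in the full HOG model.  The stimulus enters as
    the ``input`` parameter driving MAPKKK activation.
    """
    if mechanism not in ("distributive", "processive"):
        raise NetworkError("basic cascade mechanism must be distributive or processive")

    species = [
        ("KKK", "cytosol", 1.0),
        ("KKK_act", "cytosol", 0.0),
        ("KK", "cytosol", 1.0),
        ("KK_P", "cytosol", 0.0),
        ("KK_PP", "cytosol", 0.0),
        ("K", "cytosol", 1.0),
        ("K_P", "cytosol", 0.0),
        ("K_PP", "cytosol", 0.0),
        ("KKPP_K", "cytosol", 0.0),
        ("KKPP_KP", "cytosol", 0.0),
        ("KKPP_KP_rebound", "cytosol", 0.0),
        # tier phosphatases: constant pools acting through saturable
        # (Michaelis-Menten) steps, the classic source of zero-order
        # ultrasensitivity in three-tier cascade models
        ("P2", "cytosol", 1.0),
        ("P3", "cytosol", 1.0),
    ]
    rxns: list[Reaction] = []
    pnames: set[str] = set()

    def R(name, reactants, products, params_=(), kind="mass_action", enzyme=None):
        rxns.append(Reaction(name, tuple(reactants), tuple(products), kind,
                             tuple(params_), enzyme))
        pnames.update(params_)

    one = lambda *sp: tuple((s, 1) for s in sp)

    R("kkk_activation", one("KKK"), one("KKK_act"), ("k1", "input"))
    R("kkk_deactivation", one("KKK_act"), one("KKK"), ("d1",))
    R("kk_phospho1", one("KK"), one("KK_P"), ("k2", "km_kk"),
      kind="michaelis_menten", enzyme="KKK_act")
    R("kk_phospho2", one("KK_P"), one("KK_PP"), ("k2", "km_kk"),
      kind="michaelis_menten", enzyme="KKK_act")
    R("kk_dephospho2", one("KK_PP"), one("KK_P"), ("d2", "km_kk_p"),
      kind="michaelis_menten", enzyme="P2")
    R("kk_dephospho1", one("KK_P"), one("KK"), ("d2", "km_kk_p"),
      kind="michaelis_menten", enzyme="P2")

    R("mapk_binding", one("KK_PP", "K"), one("KKPP_K"), ("kon_mapk",))
    R("mapk_unbinding", one("KKPP_K"), one("KK_PP", "K"), ("koff_mapk",))
    R("mapk_first_phospho", one("KKPP_K"), one("KKPP_KP"), ("kcat_mapk1",))
    if mechanism == "processive":
        R("mapk_second_phospho_immediate", one("KKPP_KP"), one("KK_PP", "K_PP"), ("k_phospho",))
    else:
        R("mapkp_dissociation", one("KKPP_KP"), one("KK_PP", "K_P"), ("k_off",))
        R("mapkp_rebinding", one("KK_PP", "K_P"), one("KKPP_KP_rebound"), ("kon_mapkp",))
        R("mapk_second_phospho_rebound", one("KKPP_KP_rebound"), one("KK_PP", "K_PP"), ("k_phospho2",))
        R("mapkp_rebound_dissociation", one("KKPP_KP_rebound"), one("KK_PP", "K_P"), ("k_off",))
    R("mapk_dephospho2", one("K_PP"), one("K_P"), ("d3", "km_k"),
      kind="michaelis_menten", enzyme="P3")
    R("mapk_dephospho1", one("K_P"), one("K"), ("d3_mono", "km_k"),
      kind="michaelis_menten", enzyme="P3")

    parameters = []
    for n in sorted(pnames):
        default, cls = _CASCADE_PARAMS[n]
        lv = float(params[n]) if params and n in params else float(np.log10(default))
        lo, hi = UNCONSTRAINED_BOUNDS
        parameters.append(Parameter(n, lv, lo, hi, fixed=(n == "input"), cls=cls))

    conserved = {
        "MAPKKK": ["KKK", "KKK_act"],
        "MAPKK": ["KK", "KK_P", "KK_PP", "KKPP_K", "KKPP_KP", "KKPP_KP_rebound"],
        "MAPK": ["K", "K_P", "K_PP", "KKPP_K", "KKPP_KP", "KKPP_KP_rebound"],
        "P2": ["P2"],
        "P3": ["P3"],
    }
    return ReactionNetwork(
        name=f"cascade_{mechanism}", species=species, reactions=rxns,
        parameters=parameters, conserved_totals=conserved,
        topology=None, volume_params=None, kind="cascade")
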