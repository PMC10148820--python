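"""Observables, datasets and the likelihood objective.

Maps simulated trajectories onto the measured quantities of the multimodal
Hog1-activation corpus and scores parameter points against datasets with a
Gaussian -2*log(likelihood) objective.

Modalities
----------
``ms_fold_change``
    Relative phospho-peptide abundance: amount of the mapped species set at
    time t divided by its pre-stimulus amount (mass spectrometry).
``wb_percent_total_phospho``
    100 x (mono- + doubly phosphorylated Hog1, all compartments and
    complexes) / total Hog1 (western blot, phospho-Hog1 antibodies).
``wb_percent_pY``
    100 x (doubly phosphorylated + tyrosine-mono-phosphorylated Hog1) /
    total Hog1.  The model collapses the mono-phospho pool to the pY176
    form, so the species set coincides with the total-phospho one; the
    modality is kept separate because its error model is independent.
``nuc_cyt_ratio``
    Nuclear over cytosolic concentration of all Hog1 forms, with the nucleus
    occupying a fixed fraction of cell volume (single-cell microscopy).
``cell_area``
    Projected cell area, volume^(2/3), normalized to its pre-stress value.

Datasets are tidy tables (one row per measurement) whose ``strain`` and
``protocol_id`` columns refer to named entries in the registries below, so
they round-trip losslessly through TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import (NUCLEAR_VOLUME_FRACTION, ReactionNetwork, StrainSpec,
                      WILD_TYPE, apply_strain)
from .simulate import (CompiledModel, EquilibrationError, InputProtocol,
                       Trajectory, compile_model, equilibrate, run)

__all__ = [
    "MODALITIES",
    "STRAINS",
    "PROTOCOLS",
    "DATASET_COLUMNS",
    "ObservableSpec",
    "DataPoint",
    "Dataset",
    "ErrorModel",
    "ObjectiveFunction",
    "evaluate_observable",
    "hog1_species_sets",
    "objective",
]

MODALITIES = ("ms_fold_change", "wb_percent_total_phospho", "wb_percent_pY",
              "nuc_cyt_ratio", "cell_area")

#: Finite penalty added per failed condition inside fitting loops.
FAILURE_PENALTY = 1.0e8

#: Named genetic backgrounds used by the packaged datasets.
STRAINS: dict[str, StrainSpec] = {
    "wt": WILD_TYPE,
    "pbs2D": StrainSpec(deletions={"PBS2"}),
    "sln1D": StrainSpec(deletions={"SLN1"}),
    "sho1D": StrainSpec(deletions={"SHO1"}),
    "ptp2D_ptp3D": StrainSpec(deletions={"PTP2", "PTP3"}),
    "pbs2_S248A": StrainSpec(pbs2_s248="S248A"),
    "pbs2_S248E": StrainSpec(pbs2_s248="S248E"),
    "ssk2_fb_dead": StrainSpec(ssk2_feedback_dead=True),
    "hog1_as": StrainSpec(hog1_inhibited=True),
    "pbs2_10x": StrainSpec(overexpression=(("Pbs2", 10.0),)),
}

#: Named stimulus protocols used by the packaged datasets.
PROTOCOLS: dict[str, InputProtocol] = {
    "none": InputProtocol(kind="none", amplitude=0.0, horizon=2400.0),
    "step_0.05": InputProtocol(kind="step", amplitude=0.05, horizon=2400.0),
    "step_0.1": InputProtocol(kind="step", amplitude=0.1, horizon=2400.0),
    "step_0.15": InputProtocol(kind="step", amplitude=0.15, horizon=2400.0),
    "step_0.2": InputProtocol(kind="step", amplitude=0.2, horizon=2400.0),
    "step_0.3": InputProtocol(kind="step", amplitude=0.3, horizon=2400.0),
    "step_0.4": InputProtocol(kind="step", amplitude=0.4, horizon=2400.0),
    "step_0.6": InputProtocol(kind="step", amplitude=0.6, horizon=2400.0),
    "ramp_0.2": InputProtocol(kind="ramp", amplitude=0.2, ramp_duration=1200.0,
                              horizon=2400.0),
    "pulse_0.2_2min": InputProtocol(kind="pulse_train", amplitude=0.2,
                                    pulse_period=2, horizon=2400.0),
    "pulse_0.2_4min": InputProtocol(kind="pulse_train", amplitude=0.2,
                                    pulse_period=4, horizon=2400.0),
    "pulse_0.2_8min": InputProtocol(kind="pulse_train", amplitude=0.2,
                                    pulse_period=8, horizon=2400.0),
    "pulse_0.2_16min": InputProtocol(kind="pulse_train", amplitude=0.2,
                                     pulse_period=16, horizon=2400.0),
}

DATASET_COLUMNS = ("dataset_id", "strain", "protocol_id", "modality",
                   "time_s", "value", "sigma", "error_class", "use")


def hog1_species_sets(network: ReactionNetwork) -> dict[str, tuple[str, ...]]:
    """Species sets underlying the Hog1 observables of *network*."""
    names = network.species_names
    hog1 = [s for s in names if "Hog1" in s]
    pp = tuple(s for s in ("Hog1PP_c", "Hog1PP_n") if s in names)
    # mono-phospho pool: free mono forms plus every mono-phospho complex
    mono = tuple(s for s in hog1 if "Hog1P" in s and "Hog1PP" not in s)
    nuc = tuple(s for s in hog1 if network.compartment(s) == "nucleus")
    cyt = tuple(s for s in hog1 if network.compartment(s) != "nucleus")
    return {"hog1_all": tuple(hog1), "hog1_pp": pp, "hog1_mono": mono,
            "hog1_nuclear": nuc, "hog1_cytosolic": cyt}


@dataclass(frozen=True)
class ObservableSpec:
    """Mapping from model species to one measured quantity."""

    modality: str
    numerator: tuple = ()
    denominator: tuple | str = "t0"   # species set, "t0" or "total"
    strain: str = "wt"
    protocol_id: str = "step_0.4"

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @classmethod
    def for_network(cls, modality: str, network: ReactionNetwork,
                    strain: str = "wt", protocol_id: str = "step_0.4",
                    species: str = "hog1_pp") -> "ObservableSpec":
        sets = hog1_species_sets(network)
        if modality == "ms_fold_change":
            return cls(modality, sets[species], "t0", strain, protocol_id)
        if modality in ("wb_percent_total_phospho", "wb_percent_pY"):
            num = tuple(sorted(set(sets["hog1_pp"]) | set(sets["hog1_mono"])))
            return cls(modality, num, sets["hog1_all"], strain, protocol_id)
        if modality == "nuc_cyt_ratio":
            return cls(modality, sets["hog1_nuclear"], sets["hog1_cytosolic"],
                       strain, protocol_id)
        if modality == "cell_area":
            return cls(modality, (), "t0", strain, protocol_id)
        raise ValueError(modality)


def evaluate_observable(trajectory: Trajectory, spec: ObservableSpec) -> np.ndarray:
    """Evaluate one observable along a trajectory.

    Returns an array over the trajectory's time grid; a zero reference
    (fold-change at a vanishing basal amount, empty cytosol) yields NaN,
    which downstream scoring converts into a penalty.
    """
    if not trajectory.success:
        raise ValueError("cannot evaluate observables on a failed trajectory")
    m = spec.modality
    if m == "cell_area":
        V = trajectory.cell_volume
        ref = V[0] ** (2.0 / 3.0)
        return (V ** (2.0 / 3.0)) / ref
    num = trajectory.total(spec.numerator)
    if m == "ms_fold_change":
        ref = num[0]
        if ref <= 0:
            return np.full_like(num, np.nan)
        return num / ref
    if m in ("wb_percent_total_phospho", "wb_percent_pY"):
        tot = trajectory.total(spec.denominator)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * num / tot
        return np.where(tot > 0, out, np.nan)
    if m == "nuc_cyt_ratio":
        cyt = trajectory.total(spec.denominator)
        nv = NUCLEAR_VOLUME_FRACTION
        conv = (1.0 - nv) / nv  # amount ratio -> concentration ratio
        with np.errstate(invalid="ignore", divide="ignore"):
            out = conv * num / cyt
        return np.where(cyt > 0, out, np.nan)
    raise ValueError(m)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataPoint:
    """One multimodal measurement."""

    dataset_id: str
    strain: str
    protocol_id: str
    modality: str
    time_s: float
    value: float
    sigma: float
    error_class: str
    use: str = "fit"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.use not in ("fit", "test"):
            raise ValueError("use must be 'fit' or 'test'")


@dataclass(frozen=True)
class ErrorModel:
    """Additive Gaussian error on the observable's own scale.

    ``mode`` is ``fixed`` (sigma taken from the data rows) or ``fitted``
    (a per-class scale profiled analytically at its conditional maximum
    likelihood, bounded below by ``sigma_floor``).
    """

    error_class: str
    mode: str = "fixed"
    sigma_floor: float = 1e-3

    def __post_init__(self):
        if self.mode not in ("fixed", "fitted"):
            raise ValueError("error model mode must be 'fixed' or 'fitted'")
        if self.sigma_floor <= 0:
            raise ValueError("sigma floor must be positive")


class Dataset:
    """A tidy multimodal dataset plus its error-model classes."""

    def __init__(self, frame: pd.DataFrame,
                 error_models: Mapping[str, ErrorModel] | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing column(s): {', '.join(missing)}")
        if len(frame) == 0:
            raise ValueError("empty dataset")
        bad = frame.index[frame["sigma"] <= 0].tolist()
        if bad:
            raise ValueError(f"non-positive sigma in row(s) {bad}")
        bad = frame.index[~frame["use"].isin(["fit", "test"])].tolist()
        if bad:
            raise ValueError(f"invalid 'use' in row(s) {bad}")
        unknown = sorted(set(frame["strain"]) - set(STRAINS))
        if unknown:
            raise ValueError(f"unknown strain id(s): {', '.join(unknown)}")
        unknown = sorted(set(frame["protocol_id"]) - set(PROTOCOLS))
        if unknown:
            raise ValueError(f"unknown protocol id(s): {', '.join(unknown)}")
        self.frame = frame.reset_index(drop=True)
        if error_models is None:
            error_models = {c: ErrorModel(c) for c in frame["error_class"].unique()}
        self.error_models = dict(error_models)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_fit(self) -> int:
        return int((self.frame["use"] == "fit").sum())

    def fit_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["use"] == "fit"]

    def subset(self, mask) -> "Dataset":
        sub = self.frame[mask]
        return Dataset(sub.reset_index(drop=True), self.error_models)

    def points(self) -> list[DataPoint]:
        return [DataPoint(**{k: row[k] for k in DATASET_COLUMNS})
                for _, row in self.frame.iterrows()]

    def n_fitted_error_parameters(self) -> int:
        fit_classes = set(self.fit_frame()["error_class"])
        return sum(1 for c, m in self.error_models.items()
                   if m.mode == "fitted" and c in fit_classes)

    def conditions(self, use: str | None = "fit") -> list[tuple[str, str]]:
        frame = self.frame if use is None else self.frame[self.frame["use"] == use]
        return sorted({(r.strain, r.protocol_id)
                       for r in frame.itertuples(index=False)})


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

class ObjectiveFunction:
    """-2*log(likelihood) of a dataset under one network, as a callable.

    Precompiles one model per experimental condition (strain x protocol) and
    re-scores parameter vectors given on the log10 scale.  Simulation
    failures contribute a large finite penalty instead of raising, so the
    objective is safe to call from multistart optimizers.
    """

    def __init__(self, network: ReactionNetwork, dataset: Dataset,
                 free_names: Sequence[str] | None = None,
                 use: str = "fit", rtol: float = 1e-6, atol: float = 1e-9,
                 min_step: float = 1e-6, t_cap: float = 1e5):
        frame = dataset.frame if use is None else \
            dataset.frame[dataset.frame["use"] == use].reset_index(drop=True)
        if len(frame) == 0:
            raise ValueError("no data rows selected for the objective")
        self.network = network
        self.dataset = dataset
        self.free_names = list(free_names if free_names is not None
                               else network.free_parameter_names())
        self.rtol, self.atol = rtol, atol
        self.min_step, self.t_cap = min_step, t_cap
        self._base = {p.name: p.log10_value for p in network.parameters.values()}

        self._conditions = []
        for (strain_id, protocol_id), grp in frame.groupby(
                ["strain", "protocol_id"], sort=True):
            strained = apply_strain(network, STRAINS[strain_id])
            model = compile_model(strained)
            protocol = PROTOCOLS[protocol_id]
            times = np.unique(grp["time_s"].to_numpy(dtype=float))
            tgrid = np.unique(np.concatenate([[0.0], times]))
            specs = {}
            for modality in grp["modality"].unique():
                specs[modality] = ObservableSpec.for_network(
                    modality, strained, strain_id, protocol_id)
            rows = []
            for modality, g2 in grp.groupby("modality"):
                t_idx = np.searchsorted(tgrid, g2["time_s"].to_numpy(dtype=float))
                rows.append((modality, t_idx,
                             g2["value"].to_numpy(dtype=float),
                             g2["sigma"].to_numpy(dtype=float),
                             g2["error_class"].to_numpy()))
            self._conditions.append(
                {"strain": strain_id, "protocol": protocol, "model": model,
                 "tgrid": tgrid, "specs": specs, "rows": rows})

    # -- parameter plumbing -------------------------------------------------

    def full_params(self, x: Sequence[float] | Mapping[str, float] | None) -> dict:
        params = dict(self._base)
        if x is None:
            return params
        if isinstance(x, Mapping):
            params.update(x)
        else:
            x = np.asarray(x, dtype=float)
            if x.shape != (len(self.free_names),):
                raise ValueError("parameter vector length mismatch")
            params.update(zip(self.free_names, x))
        return params

    # -- scoring ------------------------------------------------------------

    def residuals(self, x=None) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """(residuals, sigmas, error classes, n_failed) for parameter point x."""
        params = self.full_params(x)
        res, sig, cls = [], [], []
        n_failed = 0
        for cond in self._conditions:
            model = cond["model"]
            model.set_params(params)
            try:
                y0 = equilibrate(cond["model"].network, model=model,
                                 rtol=self.rtol, atol=self.atol,
                                 min_step=self.min_step, t_cap=self.t_cap,
                                 rhs_budget=30000)
            except EquilibrationError:
                n_failed += 1
                continue
            traj = run(cond["model"].network, protocol=cond["protocol"],
                       tgrid=cond["tgrid"], model=model, y0=y0,
                       rtol=self.rtol, atol=self.atol, min_step=self.min_step,
                       rhs_budget=100000)
            if not traj.success:
                n_failed += 1
                continue
            series = {m: evaluate_observable(traj, spec)
                      for m, spec in cond["specs"].items()}
            for modality, t_idx, values, sigmas, classes in cond["rows"]:
                pred = series[modality][t_idx]
                bad = ~np.isfinite(pred)
                if bad.any():
                    n_failed += 1
                    pred = np.where(bad, values + 1e3 * sigmas, pred)
                res.append(values - pred)
                sig.append(sigmas)
                cls.append(classes)
        if res:
            return (np.concatenate(res), np.concatenate(sig),
                    np.concatenate(cls), n_failed)
        return np.array([]), np.array([]), np.array([]), n_failed

    def __call__(self, x=None) -> float:
        r, s, c, n_failed = self.residuals(x)
        value = FAILURE_PENALTY * n_failed
        for class_id in np.unique(c):
            mask = c == class_id
            model = self.dataset.error_models.get(class_id, ErrorModel(class_id))
            ri = r[mask]
            if model.mode == "fitted":
                sigma2 = max(float(np.mean(ri ** 2)), model.sigma_floor ** 2)
                value += ri.size * (1.0 + np.log(2.0 * np.pi * sigma2))
            else:
                si = s[mask]
                value += float(np.sum(ri ** 2 / si ** 2 + np.log(2.0 * np.pi * si ** 2)))
        return float(value)


def predict(network: ReactionNetwork, frame: pd.DataFrame,
            rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Noise-free model predictions for every row of a dataset frame.

    Simulates each (strain, protocol) condition once and evaluates the row's
    modality at its time point.  Raises on simulation failure, naming the
    condition; intended for data generation and plotting rather than for
    fitting loops (which use :class:`ObjectiveFunction`).
    """
    out = np.full(len(frame), np.nan)
    frame = frame.reset_index(drop=True)
    for (strain_id, protocol_id), grp in frame.groupby(["strain", "protocol_id"],
                                                       sort=True):
        strained = apply_strain(network, STRAINS[strain_id])
        model = compile_model(strained)
        try:
            y0 = equilibrate(strained, model=model, rtol=rtol, atol=atol)
        except EquilibrationError as e:
            raise RuntimeError(
                f"equilibration failed for condition ({strain_id}, {protocol_id}): {e}")
        times = np.unique(grp["time_s"].to_numpy(dtype=float))
        tgrid = np.unique(np.concatenate([[0.0], times]))
        protocol = PROTOCOLS[protocol_id]
        traj = run(strained, protocol=protocol, tgrid=tgrid, model=model,
                   y0=y0, rtol=rtol, atol=atol)
        if not traj.success:
            raise RuntimeError(
                f"simulation failed for condition ({strain_id}, {protocol_id}): "
                f"{traj.diagnostics.get('message')}")
        for modality, g2 in grp.groupby("modality"):
            spec = ObservableSpec.for_network(modality, strained, strain_id,
                                              protocol_id)
            series = evaluate_observable(traj, spec)
            idx = np.searchsorted(tgrid, g2["time_s"].to_numpy(dtype=float))
            out[g2.index.to_numpy()] = series[idx]
    return out


def objective(network: ReactionNetwork, dataset: Dataset,
              params: Mapping[str, float] | Sequence[float] | None = None,
              **kwargs) -> float:
    """One-shot -2*logL of *dataset* under *network* at *params*."""
    fn = ObjectiveFunction(network, dataset, **kwargs)
    return fn(params)
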