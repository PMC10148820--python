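"""Synthetic multimodal datasets emulating the Hog1-activation fitting corpus.

The packaged design catalogue mirrors the structure of the experimental
corpus the model family was built for: mass-spectrometry fold-change time
courses of doubly and mono-phosphorylated Hog1 (dense over the first minute,
sparse later), western-blot percent-phosphorylation series (wild type,
ptp2Δ ptp3Δ, Hog1-inhibited with and without salt), single-cell
nuclear:cytosolic Hog1 ratios (NaCl steps up to 0.6 M, a 0.2 M ramp held out
as test data, pulse trains of 2/4/8/16 min period, and sensor/feedback
mutants), and cell-area traces for wild type and pbs2Δ.  Rows marked
``use='fit'`` total exactly 533.

Datasets are generated from any ground-truth network by simulating every
catalogue condition and adding Gaussian noise of each entry's sigma; at the
60-s mass-spectrometry time point the generator averages two independent
noisy draws, emulating the averaging of two source studies at that overlap
point.  Simulate-and-refit experiments (parameter recovery) are provided on
top of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import REFERENCE_VOLUME_PARAMS, reference_params
from .fit import FitResult, FitSettings, fit_network
from .network import ReactionNetwork, TopologyConfig, build_network
from .observation import (DATASET_COLUMNS, Dataset, ErrorModel, predict)

__all__ = [
    "DesignEntry",
    "GroundTruth",
    "design_catalogue",
    "generate",
    "recovery_experiment",
    "model_recovery_experiment",
    "MECHANISM_FREE_PARAMS",
    "FIT_ROW_TOTAL",
]

#: Mechanism-defining rate constants freed when competing topologies are
#: refit to synthetic data in model-recovery experiments; each topology
#: frees exactly the rates its reaction set contains.
MECHANISM_FREE_PARAMS = {
    "mixed": ("k_phospho", "k_off", "k_phospho2"),
    "distributive": ("k_off", "k_phospho2"),
    "processive": ("k_phospho",),
}

#: Number of use='fit' rows in the packaged catalogue.
FIT_ROW_TOTAL = 533

#: Error classes whose scale is fitted rather than fixed (the ptp2Δ ptp3Δ
#: western-blot series gets an independent, free error scale).
FITTED_ERROR_CLASSES = ("wb_ptp",)


@dataclass(frozen=True)
class DesignEntry:
    """One dataset of the catalogue: a modality/strain/protocol time series."""

    dataset_id: str
    modality: str
    strain: str
    protocol_id: str
    times: tuple
    error_class: str
    sigma: float | str   # absolute scale, or "rel:<frac>:<floor>"
    use: str = "fit"
    mono_ms: bool = False

    def __post_init__(self):
        if list(self.times) != sorted(self.times):
            raise ValueError(f"{self.dataset_id}: time points must be sorted")
        if isinstance(self.sigma, (int, float)) and self.sigma <= 0:
            raise ValueError(f"{self.dataset_id}: sigma must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """A topology plus log10 parameter vector used to generate data."""

    topology: TopologyConfig
    params: tuple  # ((name, log10 value), ...)
    seed: int = 0

    @classmethod
    def reference(cls, mechanism: str = "mixed", seed: int = 0) -> "GroundTruth":
        top = TopologyConfig(mechanism=mechanism)
        return cls(top, tuple(sorted(reference_params(mechanism).items())), seed)

    def network(self) -> ReactionNetwork:
        net = build_network(self.topology, params=dict(self.params),
                            volume_params=REFERENCE_VOLUME_PARAMS)
        for name, lv in self.params:
            if name in net.parameters:
                p = net.parameters[name]
                if not (p.lower <= lv <= p.upper):
                    raise ValueError(
                        f"ground-truth parameter {name}={lv} outside bounds "
                        f"[{p.lower}, {p.upper}]")
        return net


def _grid(start: float, stop: float, step: float) -> tuple:
    return tuple(np.round(np.arange(start, stop + step / 2, step), 6))


_MS_TIMES = _grid(0, 60, 5) + _grid(300, 1800, 300)          # 13 + 6 = 19
_WB_TIMES = (0.0, 300.0, 600.0, 900.0, 1800.0, 2400.0)       # 6
_MIC_TIMES = _grid(0, 2340, 90)                              # 27
_AREA_TIMES_WT = _grid(0, 2280, 120)                         # 20
_AREA_TIMES_PBS2 = _grid(120, 2280, 120)                     # 19


def design_catalogue() -> list[DesignEntry]:
    """The packaged design catalogue (fit-use rows total exactly 533).

    Mass-spectrometry sigmas are relative (10 % of the noise-free value with
    a floor), reflecting fold-change measurements; western-blot, microscopy
    and area sigmas are absolute on the observable's scale.
    """
    entries: list[DesignEntry] = []
    add = entries.append

    # mass spectrometry: Hog1-PP and mono-phosphorylated Hog1-P176, 0.4 M step
    add(DesignEntry("ms_hog1pp_wt", "ms_fold_change", "wt", "step_0.4",
                    _MS_TIMES, "ms", "rel:0.10:0.10"))
    add(DesignEntry("ms_hog1p176_wt", "ms_fold_change", "wt", "step_0.4",
                    _MS_TIMES, "ms", "rel:0.10:0.10", mono_ms=True))

    # western blots (percent phosphorylation)
    add(DesignEntry("wb_wt", "wb_percent_total_phospho", "wt", "step_0.4",
                    _WB_TIMES, "wb_wt", 5.0))
    add(DesignEntry("wb_ptp2ptp3", "wb_percent_pY", "ptp2D_ptp3D", "step_0.4",
                    _WB_TIMES, "wb_ptp", 8.0))
    add(DesignEntry("wb_hog1as_basal", "wb_percent_total_phospho", "hog1_as",
                    "none", _WB_TIMES, "wb_inhib", 5.0))
    add(DesignEntry("wb_hog1as_salt", "wb_percent_total_phospho", "hog1_as",
                    "step_0.4", _WB_TIMES, "wb_inhib", 5.0))

    # single-cell nuclear:cytosolic ratios, NaCl steps
    for dose in ("0.05", "0.1", "0.15", "0.2", "0.4", "0.6"):
        add(DesignEntry(f"mic_wt_step{dose}", "nuc_cyt_ratio", "wt",
                        f"step_{dose}", _MIC_TIMES, "mic_wt", 0.3))
    # held-out ramp (test data, not counted in the 533)
    add(DesignEntry("mic_wt_ramp", "nuc_cyt_ratio", "wt", "ramp_0.2",
                    _MIC_TIMES, "mic_wt", 0.3, use="test"))
    # pulse trains
    for period in (2, 4, 8, 16):
        add(DesignEntry(f"mic_wt_pulse{period}", "nuc_cyt_ratio", "wt",
                        f"pulse_0.2_{period}min", _MIC_TIMES, "mic_pulse", 0.3))
    # mutants, 0.4 M step
    for strain in ("sln1D", "sho1D", "pbs2_S248A", "pbs2_S248E",
                   "ssk2_fb_dead", "pbs2D"):
        add(DesignEntry(f"mic_{strain}", "nuc_cyt_ratio", strain, "step_0.4",
                        _MIC_TIMES, "mic_mut", 0.3))

    # cell area (volume module)
    add(DesignEntry("area_wt", "cell_area", "wt", "step_0.4",
                    _AREA_TIMES_WT, "area", 0.02))
    add(DesignEntry("area_pbs2D", "cell_area", "pbs2D", "step_0.4",
                    _AREA_TIMES_PBS2, "area", 0.02))

    n_fit = sum(len(e.times) for e in entries if e.use == "fit")
    assert n_fit == FIT_ROW_TOTAL, f"catalogue drifted: {n_fit} fit rows"
    return entries


def catalogue_frame(entries: Sequence[DesignEntry] | None = None) -> pd.DataFrame:
    """Expand a catalogue into one tidy row per measurement."""
    entries = design_catalogue() if entries is None else entries
    rows = []
    for e in entries:
        for t in e.times:
            rows.append({
                "dataset_id": e.dataset_id, "strain": e.strain,
                "protocol_id": e.protocol_id, "modality": e.modality,
                "time_s": float(t), "value": np.nan, "sigma": e.sigma,
                "error_class": e.error_class, "use": e.use,
                "mono_ms": e.mono_ms,
            })
    return pd.DataFrame(rows)


def generate(ground_truth: GroundTruth,
             catalogue: Sequence[DesignEntry] | pd.DataFrame | None = None,
             noise_on: bool = True, seed: int | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> Dataset:
    """Simulate the catalogue conditions and emit a (noisy) dataset.

    With ``noise_on`` each value receives additive Gaussian noise of its
    entry's sigma; relative sigma specs are resolved against the noise-free
    value first.  At the 60-s mass-spectrometry time point two independent
    draws are averaged.  Reproducible for a given seed (defaults to the
    ground truth's own seed).
    """
    if isinstance(catalogue, pd.DataFrame):
        frame = catalogue.copy().reset_index(drop=True)
    else:
        frame = catalogue_frame(catalogue)
    net = ground_truth.network()
    truth = predict(net, frame, rtol=rtol, atol=atol)

    sigma = np.empty(len(frame))
    for i, s in enumerate(frame["sigma"]):
        if isinstance(s, str) and s.startswith("rel:"):
            _, frac, floor = s.split(":")
            sigma[i] = max(float(frac) * abs(truth[i]), float(floor))
        else:
            sigma[i] = float(s)

    values = truth.copy()
    if noise_on:
        rng = np.random.default_rng(ground_truth.seed if seed is None else seed)
        noise = rng.normal(0.0, 1.0, size=len(frame))
        is_ms60 = ((frame["modality"] == "ms_fold_change")
                   & (frame["time_s"] == 60.0)).to_numpy()
        # two emulated studies overlap at 60 s; their mean halves the variance
        second = rng.normal(0.0, 1.0, size=len(frame))
        noise = np.where(is_ms60, 0.5 * (noise + second), noise)
        values = truth + sigma * noise

    out = frame.copy()
    out["value"] = values
    out["sigma"] = sigma
    error_models = {
        c: ErrorModel(c, mode="fitted" if c in FITTED_ERROR_CLASSES else "fixed")
        for c in out["error_class"].unique()}
    return Dataset(out, error_models)


def model_recovery_experiment(settings: FitSettings,
                              base_seed: int = 0,
                              n_replicates: int = 5,
                              mechanisms: Sequence[str] = ("mixed",
                                                           "distributive",
                                                           "processive"),
                              dataset_ids: Sequence[str] = ("ms_hog1pp_wt",
                                                            "ms_hog1p176_wt"),
                              rtol: float = 1e-5, atol: float = 1e-8) -> dict:
    """Can model selection recover the generating phosphorylation mechanism?

    For each replicate, data are generated from the mixed-mechanism reference
    ground truth (two-component positive feedback on Pbs2 plus negative
    feedback) on the named catalogue datasets; each competing topology is
    refit with its mechanism-defining rates free (shared parameters held at
    the generating base values) and the topologies are ranked by AIC.
    Reports the fraction of replicates ranking a mixed topology first.
    """
    from dataclasses import replace as _replace

    from .fit import rank_models

    entries = [e for e in design_catalogue() if e.dataset_id in set(dataset_ids)]
    if not entries:
        raise ValueError(f"no catalogue entries match {dataset_ids}")
    base = reference_params("mixed")
    replicates = []
    n_mixed_best = 0
    for rep in range(n_replicates):
        seed = base_seed + 101 * rep
        gt = GroundTruth(TopologyConfig(mechanism="mixed"),
                         tuple(sorted(base.items())), seed)
        dataset = generate(gt, entries, noise_on=True, seed=seed)
        results = []
        for mech in mechanisms:
            top = TopologyConfig(mechanism=mech)
            net = build_network(top, params=base,
                                volume_params=REFERENCE_VOLUME_PARAMS)
            free = [p for p in MECHANISM_FREE_PARAMS[mech]
                    if p in net.parameters]
            results.append(fit_network(net, dataset, free_names=free,
                                       settings=_replace(settings, seed=seed),
                                       rtol=rtol, atol=atol))
        ranking = rank_models(results)
        best_mech = ranking[0]["result"].topology.mechanism
        n_mixed_best += int(best_mech == "mixed")
        replicates.append({
            "seed": seed,
            "best_mechanism": best_mech,
            "aic": {r["result"].topology.mechanism: r["aic"] for r in ranking},
        })
    return {
        "replicates": replicates,
        "n_replicates": n_replicates,
        "n_mixed_best": n_mixed_best,
        "fraction_mixed_best": n_mixed_best / n_replicates,
    }


def recovery_experiment(ground_truth: GroundTruth,
                        settings: FitSettings,
                        free_names: Sequence[str],
                        dataset: Dataset | None = None,
                        noise_on: bool = True,
                        catalogue: Sequence[DesignEntry] | pd.DataFrame | None = None,
                        rtol: float = 1e-6, atol: float = 1e-9) -> dict:
    """Simulate data from known parameters, refit, and report recovery.

    Generates a dataset from *ground_truth* (unless one is supplied), refits
    the same topology with ``free_names`` free, and reports each parameter's
    absolute log10 deviation from truth, their median, and how many fall
    within one order of magnitude.
    """
    if dataset is None:
        dataset = generate(ground_truth, catalogue, noise_on=noise_on,
                           seed=ground_truth.seed)
    net = ground_truth.network()
    screen = None
    if settings.n_screen:
        # rank starting vectors on the wild-type step response only; the
        # refit itself scores the whole dataset
        mask = ((dataset.frame["strain"] == "wt")
                & (dataset.frame["protocol_id"] == "step_0.4"))
        if mask.any():
            screen = dataset.subset(mask)
    result = fit_network(net, dataset, free_names=list(free_names),
                         settings=settings, rtol=rtol, atol=atol,
                         screen_dataset=screen)
    truth = dict(ground_truth.params)
    deviations = {name: abs(result.parameters[name] - truth[name])
                  for name in free_names}
    devs = np.array(list(deviations.values()))
    return {
        "fit": result,
        "deviations": deviations,
        "median_abs_log10_deviation": float(np.median(devs)),
        "n_within_one_order": int(np.sum(devs <= 1.0)),
        "n_parameters": len(devs),
    }
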