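"""Configuration, dataset I/O, logging and the command-line interface.

The workbench ties the stages together: topology enumeration, simulation of
reference calibrations, synthetic-data generation, multistart fitting,
AIC-based selection, parameter-recovery experiments and the post-fit
analyses.  Every artifact written by the CLI embeds a manifest (config hash,
seed, package versions) sufficient to regenerate it.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (dose_response, hill_fit, perturbation_ensemble,
                       processivity_timecourse, quantile_shift)
from .calibration import reference_network
from .fit import FitResult, FitSettings, fit_network, rank_models
from .network import StrainSpec, TopologyConfig, enumerate_topologies
from .observation import (DATASET_COLUMNS, Dataset, ErrorModel, PROTOCOLS,
                          STRAINS)
from .simulate import InputProtocol, equilibrate, run
from .synthetic import (FITTED_ERROR_CLASSES, GroundTruth, generate,
                        recovery_experiment)

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "write_results",
    "config_hash",
    "cli",
    "main",
]

log = logging.getLogger("hogpath")


# ---------------------------------------------------------------------------
# Config and manifests
# ---------------------------------------------------------------------------

class RunConfig:
    """A YAML/JSON run configuration with dotted-key access."""

    def __init__(self, data: Mapping | None = None):
        self.data = dict(data or {})

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping: {path}")
        return cls(data)

    def get(self, dotted: str, default=None):
        node = self.data
        for key in dotted.split("."):
            if not isinstance(node, dict) or key not in node:
                return default
            node = node[key]
        return node

    def topology(self) -> TopologyConfig:
        return TopologyConfig.from_dict(self.get("topology", {}))

    def strain(self) -> StrainSpec:
        return StrainSpec.from_dict(self.get("strain", {}))

    def protocol(self) -> InputProtocol:
        return InputProtocol.from_dict(self.get("protocol", {"kind": "step"}))


def config_hash(payload) -> str:
    """Stable hash of a JSON-serializable configuration."""
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _manifest(payload, seed=None) -> dict:
    return {
        "config_hash": config_hash(payload),
        "seed": seed,
        "versions": {
            "hogpath": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def write_results(path: str | Path, artifact: Mapping, *,
                  config=None, seed=None) -> None:
    """Serialize an artifact plus its regeneration manifest as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dict(artifact)
    out["manifest"] = _manifest(config if config is not None else artifact,
                                seed=seed)
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_default)
    log.info("wrote %s", path)


# ---------------------------------------------------------------------------
# Dataset TSV I/O
# ---------------------------------------------------------------------------

def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset TSV with full numeric precision and schema checks.

    Schema violations are reported with 1-based data row numbers; unknown
    columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"empty dataset file: {path}")
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if len(frame) == 0:
        raise ValueError(f"dataset has a header but no rows: {path}")
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    bad = frame.index[~(frame["sigma"] > 0)] + 1
    if len(bad):
        raise ValueError(
            f"{path}: non-positive sigma in row(s) {list(map(int, bad))}")
    bad = frame.index[~frame["use"].isin(["fit", "test"])] + 1
    if len(bad):
        raise ValueError(
            f"{path}: invalid 'use' value in row(s) {list(map(int, bad))}")
    error_models = {
        c: ErrorModel(c, mode="fitted" if c in FITTED_ERROR_CLASSES else "fixed")
        for c in frame["error_class"].unique()}
    return Dataset(frame, error_models)


def write_dataset(path: str | Path, dataset: Dataset) -> None:
    """Write a dataset as TSV (lossless round-trip with read_dataset)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.frame.to_csv(path, sep="\t", index=False)
    log.info("wrote %s (%d rows)", path, len(dataset.frame))


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _add_common(p):
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--strain", default="wt", choices=sorted(STRAINS))
    p.add_argument("--protocol", default="step_0.4", choices=sorted(PROTOCOLS))
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, default=None)


def _build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="hogpath",
        description="ODE modelling of Hog1 activation in the yeast HOG pathway")
    parser.add_argument("-v", "--verbose", action="store_true")
    parser.add_argument("-q", "--quiet", action="store_true")
    sub = parser.add_subparsers(dest="command", required=True)

    p = sub.add_parser("topologies", help="enumerate canonical topologies")
    p.add_argument("--mixed", action="store_true",
                   help="include the mixed-mechanism combinations")
    p.add_argument("--out", type=Path, default=None)

    p = sub.add_parser("simulate", help="simulate a reference calibration")
    _add_common(p)

    p = sub.add_parser("synth", help="generate a synthetic dataset")
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--no-noise", action="store_true")
    p.add_argument("--out", type=Path, required=True)

    p = sub.add_parser("fit", help="multistart fit of one topology to a dataset")
    p.add_argument("--data", type=Path, required=True)
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--free", required=True,
                   help="comma-separated free parameter names")
    p.add_argument("--starts", type=int, default=20)
    p.add_argument("--top", type=int, default=5)
    p.add_argument("--iters", type=int, default=60)
    p.add_argument("--rounds", type=int, default=2)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, required=True)

    p = sub.add_parser("select", help="rank fit results by AIC")
    p.add_argument("fits", nargs="+", type=Path)
    p.add_argument("--out", type=Path, default=None)

    p = sub.add_parser("recover", help="simulate-and-refit identifiability check")
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--free", required=True)
    p.add_argument("--starts", type=int, default=12)
    p.add_argument("--top", type=int, default=4)
    p.add_argument("--iters", type=int, default=40)
    p.add_argument("--rounds", type=int, default=2)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, required=True)

    p = sub.add_parser("processivity", help="processivity score time course")
    _add_common(p)

    p = sub.add_parser("hill", help="Hill fit of the simulated dose-response")
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--doses",
                   default="0.0125,0.025,0.05,0.075,0.1,0.125,0.15,0.2,0.3,0.4,0.6")
    p.add_argument("--out", type=Path, default=None)

    p = sub.add_parser("robustness", help="protein-abundance perturbation ensemble")
    p.add_argument("--mechanism", default="mixed",
                   choices=("distributive", "processive", "mixed"))
    p.add_argument("--n-runs", type=int, default=50)
    p.add_argument("--amplitude", type=float, default=0.4)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, required=True)

    p = sub.add_parser("qshift", help="Harrell-Davis quantile shift of two samples")
    p.add_argument("--a", type=Path, required=True,
                   help="TSV/headerless file with one value per line")
    p.add_argument("--b", type=Path, required=True)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out", type=Path, required=True)

    return parser


def _load_sample(path: Path) -> np.ndarray:
    vals = np.loadtxt(path, ndmin=1)
    return np.asarray(vals, dtype=float).ravel()


def cli(argv: Sequence[str] | None = None) -> int:
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as e:
        return int(e.code or 0)
    level = (logging.DEBUG if args.verbose
             else logging.ERROR if args.quiet else logging.INFO)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    try:
        return _dispatch(args)
    except (ValueError, FileNotFoundError, RuntimeError, KeyError) as e:
        log.error("%s", e)
        return 2


def _dispatch(args) -> int:
    cmd = args.command

    if cmd == "topologies":
        tops = enumerate_topologies(include_mixed=args.mixed)
        for t in tops:
            print(t.label)
        if args.out:
            write_results(args.out, {"topologies": [t.to_dict() for t in tops]},
                          config={"mixed": args.mixed})
        return 0

    if cmd == "simulate":
        net = reference_network(args.mechanism, strain=STRAINS[args.strain])
        protocol = PROTOCOLS[args.protocol]
        y0 = equilibrate(net)
        traj = run(net, protocol=protocol, y0=y0)
        if not traj.success:
            log.error("simulation failed: %s", traj.diagnostics.get("message"))
            return 1
        frame = traj.to_frame()
        out = args.out or Path(f"trajectory_{args.mechanism}_{args.strain}.tsv")
        out.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out, sep="\t", index=False)
        write_results(out.with_suffix(".manifest.json"),
                      {"rows": len(frame)},
                      config={"mechanism": args.mechanism,
                              "strain": args.strain,
                              "protocol": args.protocol},
                      seed=args.seed)
        return 0

    if cmd == "synth":
        gt = GroundTruth.reference(args.mechanism, seed=args.seed)
        ds = generate(gt, noise_on=not args.no_noise, seed=args.seed)
        write_dataset(args.out, ds)
        write_results(args.out.with_suffix(".manifest.json"),
                      {"rows": len(ds.frame), "fit_rows": ds.n_fit,
                       "mechanism": args.mechanism},
                      config={"mechanism": args.mechanism, "seed": args.seed,
                              "noise": not args.no_noise},
                      seed=args.seed)
        return 0

    if cmd == "fit":
        ds = read_dataset(args.data)
        net = reference_network(args.mechanism)
        free = [s.strip() for s in args.free.split(",") if s.strip()]
        settings = FitSettings(n_starts=args.starts, top_set=args.top,
                               max_iter=args.iters, max_rounds=args.rounds,
                               seed=args.seed)
        result = fit_network(net, ds, free_names=free, settings=settings)
        write_results(args.out, result.to_dict(),
                      config={"mechanism": args.mechanism, "free": free,
                              "starts": args.starts, "top": args.top,
                              "iters": args.iters, "data": str(args.data)},
                      seed=args.seed)
        return 0

    if cmd == "select":
        results = []
        for path in args.fits:
            with open(path) as fh:
                d = json.load(fh)
            top = TopologyConfig.from_dict(d["topology"]) if d.get("topology") else None
            results.append(FitResult(
                parameter_names=list(d["parameters"]),
                x=np.array(list(d["parameters"].values())),
                goodness_of_fit=d["goodness_of_fit"], k=d["k"], aic=d["aic"],
                log_l_max=d["log_l_max"], history=d.get("history", []),
                seed=d.get("seed", 0), topology=top))
        ranking = rank_models(results)
        for rec in ranking:
            flag = "  (highly significant vs best)" if rec["highly_significant"] else ""
            print(f"{rec['rank']}. {rec['topology']}: AIC={rec['aic']:.2f} "
                  f"dAIC={rec['delta_aic']:.2f}{flag}")
        if args.out:
            clean = [{k: v for k, v in rec.items() if k != "result"}
                     for rec in ranking]
            write_results(args.out, {"ranking": clean},
                          config=[str(p) for p in args.fits])
        return 0

    if cmd == "recover":
        gt = GroundTruth.reference(args.mechanism, seed=args.seed)
        free = [s.strip() for s in args.free.split(",") if s.strip()]
        settings = FitSettings(n_starts=args.starts, top_set=args.top,
                               max_iter=args.iters, max_rounds=args.rounds,
                               seed=args.seed)
        report = recovery_experiment(gt, settings, free)
        payload = {k: v for k, v in report.items() if k != "fit"}
        payload["fit"] = report["fit"].to_dict()
        write_results(args.out, payload,
                      config={"mechanism": args.mechanism, "free": free,
                              "starts": args.starts}, seed=args.seed)
        print(f"median |dlog10| = {report['median_abs_log10_deviation']:.3f}; "
              f"{report['n_within_one_order']}/{report['n_parameters']} within one order")
        return 0

    if cmd == "processivity":
        net = reference_network(args.mechanism, strain=STRAINS[args.strain])
        y0 = equilibrate(net)
        protocol = PROTOCOLS[args.protocol]
        traj = run(net, protocol=protocol, y0=y0)
        score = processivity_timecourse(traj)
        frame = pd.DataFrame({"time_s": traj.t, "processivity_score": score})
        out = args.out or Path(f"processivity_{args.mechanism}.tsv")
        out.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out, sep="\t", index=False)
        write_results(out.with_suffix(".manifest.json"),
                      {"basal_score": float(score[0]),
                       "peak_score": float(np.nanmax(score))},
                      config={"mechanism": args.mechanism,
                              "strain": args.strain,
                              "protocol": args.protocol},
                      seed=args.seed)
        print(f"basal score {score[0]:.4f}, peak {np.nanmax(score):.4f}")
        return 0

    if cmd == "hill":
        doses = [float(x) for x in args.doses.split(",")]
        net = reference_network(args.mechanism)
        resp = dose_response(net, doses)
        fit = hill_fit(doses, resp)
        print(f"Hill n={fit.n:.2f} EC50={fit.ec50:.3f} M "
              f"basal={fit.basal:.1f}% max={fit.maximum:.1f}%")
        if args.out:
            write_results(args.out, {
                "doses": doses, "responses": list(map(float, resp)),
                "hill": {"n": fit.n, "ec50": fit.ec50, "basal": fit.basal,
                         "maximum": fit.maximum}},
                config={"mechanism": args.mechanism, "doses": doses})
        return 0

    if cmd == "robustness":
        net = reference_network(args.mechanism)
        protocol = InputProtocol(kind="step", amplitude=args.amplitude)
        ens = perturbation_ensemble(net, args.n_runs, protocol, seed=args.seed)
        rows = []
        for i, (scheme, mx) in enumerate(zip(ens["schemes"], ens["maxima"])):
            row = {"run": i, "max_hog1pp_percent": mx}
            row.update(scheme.as_dict())
            rows.append(row)
        frame = pd.DataFrame(rows)
        args.out.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(args.out, sep="\t", index=False)
        write_results(args.out.with_suffix(".manifest.json"),
                      {"n_runs": args.n_runs,
                       "multiplier_sampling": ens["multiplier_sampling"]},
                      config={"mechanism": args.mechanism,
                              "amplitude": args.amplitude,
                              "n_runs": args.n_runs},
                      seed=args.seed)
        ok = np.isfinite(ens["maxima"])
        print(f"{ok.sum()}/{args.n_runs} runs ok; median max Hog1-PP "
              f"{np.nanmedian(ens['maxima']):.1f}%")
        return 0

    if cmd == "qshift":
        a = _load_sample(args.a)
        b = _load_sample(args.b)
        res = quantile_shift(a, b, seed=args.seed)
        args.out.parent.mkdir(parents=True, exist_ok=True)
        res.to_frame().to_csv(args.out, sep="\t", index=False)
        write_results(args.out.with_suffix(".manifest.json"),
                      {"n_significant": int(res.significant.sum())},
                      config={"a": str(args.a), "b": str(args.b)},
                      seed=args.seed)
        print(f"{int(res.significant.sum())}/19 grid points significant")
        return 0

    raise ValueError(f"unknown command {cmd!r}")


def main() -> None:  # console entry point
    sys.exit(cli())
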