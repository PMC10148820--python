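"""Parameter estimation and model selection.

Fitting follows a multistart scheme in log10 parameter space: a first round
of uniformly sampled starting vectors is polished by a bound-constrained
deterministic local optimizer; subsequent rounds resample starting vectors
from a multivariate normal whose mean and covariance are estimated from the
best-fitting vectors of the previous round, stopping as soon as a round no
longer improves the best goodness of fit.  Competing topologies are ranked
by the Akaike Information Criterion

    AIC = 2k - 2 ln(L_max),

with k the number of fitted parameters (kinetic plus fitted error-model
scales) and L_max the maximal likelihood; a difference greater than ten
between two models is flagged as highly significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .network import ReactionNetwork, TopologyConfig
from .observation import Dataset, ObjectiveFunction

__all__ = [
    "FitSettings",
    "FitResult",
    "AIC_HIGHLY_SIGNIFICANT",
    "sample_starts",
    "local_optimize",
    "refine",
    "fit_network",
    "compute_aic",
    "rank_models",
]

#: AIC difference regarded as highly significant evidence between two models.
AIC_HIGHLY_SIGNIFICANT = 10.0

_BAD = 1.0e12


@dataclass(frozen=True)
class FitSettings:
    """Multistart configuration.

    Defaults mirror a full production run (10,000 starts per round, top-100
    refinement set, 400 local iterations, 1e-6 objective-change stop); tests
    and examples scale these down.
    """

    n_starts: int = 10000
    top_set: int = 100
    max_iter: int = 400
    f_tol: float = 1e-6
    max_rounds: int = 20
    cov_floor: float = 1e-4
    seed: int = 0
    verbose: bool = False
    #: finite-difference step (log10 units) for the local optimizer; must
    #: exceed the objective's numerical noise from the ODE solver tolerances
    grad_eps: float = 1e-3
    #: optional pre-screen: sample this many vectors per round, score them
    #: once, and run the local optimizer only from the best ``n_starts``.
    #: At small budgets this preserves the exploration breadth of a large
    #: multistart while keeping the number of local optimizations low.
    n_screen: int | None = None

    def __post_init__(self):
        if self.n_starts < self.top_set:
            raise ValueError("n_starts must be >= top_set")
        if self.n_screen is not None and self.n_screen < self.n_starts:
            raise ValueError("n_screen must be >= n_starts")
        if self.top_set < 1 or self.max_iter < 1 or self.max_rounds < 1:
            raise ValueError("top_set, max_iter and max_rounds must be >= 1")


@dataclass
class FitResult:
    """Outcome of one multistart fit."""

    parameter_names: list
    x: np.ndarray                  # best log10 vector
    goodness_of_fit: float         # -2 log L
    k: int
    aic: float
    log_l_max: float
    history: list = field(default_factory=list)  # per-round best objective
    seed: int = 0
    n_rounds: int = 0
    topology: TopologyConfig | None = None
    status: str = "ok"

    @property
    def parameters(self) -> dict:
        return dict(zip(self.parameter_names, map(float, self.x)))

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "goodness_of_fit": self.goodness_of_fit,
            "k": self.k,
            "aic": self.aic,
            "log_l_max": self.log_l_max,
            "history": list(map(float, self.history)),
            "seed": self.seed,
            "n_rounds": self.n_rounds,
            "topology": self.topology.to_dict() if self.topology else None,
            "status": self.status,
        }


def _safe(objective: Callable[[np.ndarray], float]) -> Callable[[np.ndarray], float]:
    def wrapped(x):
        try:
            v = float(objective(x))
        except Exception:
            return _BAD
        return v if np.isfinite(v) else _BAD
    return wrapped


def sample_starts(bounds: np.ndarray, n: int,
                  seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw *n* starting vectors, each coordinate uniform within its bounds."""
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("bounds must be an (n_params, 2) array with lower < upper")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, len(bounds)))


def local_optimize(objective: Callable[[np.ndarray], float],
                   start: Sequence[float], bounds: np.ndarray,
                   settings: FitSettings = FitSettings(n_starts=100, top_set=1),
                   ) -> tuple[np.ndarray, float, str]:
    """Bound-constrained deterministic descent from one start.

    Terminates at the iteration cap or when the objective change falls below
    ``settings.f_tol``.  The returned value never exceeds the start value;
    if the objective fails everywhere the start is returned with status
    ``failed``.
    """
    start = np.asarray(start, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    f = _safe(objective)
    f0 = f(start)
    if f0 >= _BAD:
        return start, f0, "failed"
    res = minimize(f, start, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": settings.max_iter,
                            "maxfun": settings.max_iter * 2 * (start.size + 1),
                            "ftol": settings.f_tol,
                            "eps": settings.grad_eps})
    if res.fun <= f0:
        status = "converged" if res.success else "maxiter"
        return np.clip(res.x, bounds[:, 0], bounds[:, 1]), float(res.fun), status
    return start, f0, "no_improvement"


def _resample_mvn(top: np.ndarray, bounds: np.ndarray, n: int,
                  rng: np.random.Generator, cov_floor: float) -> tuple[np.ndarray, bool]:
    """MVN resampling around the previous round's top set, clipped to bounds."""
    mean = top.mean(axis=0)
    if top.shape[0] >= 2:
        cov = np.atleast_2d(np.cov(top, rowvar=False))
    else:
        cov = np.zeros((len(mean), len(mean)))
    regularized = False
    if not np.all(np.isfinite(cov)):
        cov = np.zeros_like(cov)
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < cov_floor:
        cov = cov + np.eye(len(mean)) * (cov_floor - min(eig.min(), 0.0))
        regularized = True
    draws = rng.multivariate_normal(mean, cov, size=n, method="svd")
    return np.clip(draws, bounds[:, 0], bounds[:, 1]), regularized


def refine(objective: Callable[[np.ndarray], float], bounds: np.ndarray,
           settings: FitSettings = FitSettings(),
           parameter_names: Sequence[str] | None = None,
           k_extra: int = 0,
           topology: TopologyConfig | None = None,
           anchor_starts: np.ndarray | None = None,
           screen_objective: Callable[[np.ndarray], float] | None = None) -> FitResult:
    """Iterative multistart optimization with MVN resampling.

    Each round samples ``n_starts`` vectors (uniform in the first round,
    multivariate normal around the previous round's top set afterwards),
    polishes each with :func:`local_optimize`, and keeps the ``top_set``
    best.  Rounds stop when the best goodness of fit no longer improves.
    ``k_extra`` counts additional fitted parameters (e.g. profiled
    error-model scales) for the AIC.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = len(bounds)
    rng = np.random.default_rng(settings.seed)
    f = _safe(objective)

    n_sample = settings.n_screen or settings.n_starts
    f_screen = _safe(screen_objective) if screen_objective is not None else f

    def _screen(cands: np.ndarray) -> np.ndarray:
        if cands.shape[0] <= settings.n_starts:
            return cands
        scores = np.array([f_screen(x) for x in cands])
        order = np.argsort(scores, kind="stable")[: settings.n_starts]
        return cands[np.sort(order)]

    best_x, best_val = None, np.inf
    history: list[float] = []
    starts = _screen(sample_starts(bounds, n_sample, rng))
    if anchor_starts is not None:
        # deterministic anchors (e.g. nominal parameter values) join the
        # first round's random starts
        anchors = np.atleast_2d(np.asarray(anchor_starts, dtype=float))
        starts = np.vstack([np.clip(anchors, bounds[:, 0], bounds[:, 1]),
                            starts])
    n_rounds = 0
    status = "ok"
    for round_idx in range(settings.max_rounds):
        n_rounds += 1
        results = []
        for i, x0 in enumerate(starts):
            x, val, _ = local_optimize(f, x0, bounds, settings)
            results.append((val, i, x))
        # stable ranking: ties broken by start index for reproducibility
        results.sort(key=lambda t: (t[0], t[1]))
        round_best_val = results[0][0]
        round_best_x = results[0][2]
        if settings.verbose:
            print(f"[refine] round {round_idx + 1}: best objective {round_best_val:.6g}")
        improved = round_best_val < best_val
        if improved:
            best_val, best_x = round_best_val, round_best_x
        history.append(float(round_best_val))
        if round_idx > 0 and not improved:
            break  # as good or worse than the round before
        top = np.array([r[2] for r in results[: settings.top_set]])
        if round_idx == settings.max_rounds - 1:
            status = "max_rounds"
            break
        starts, regularized = _resample_mvn(top, bounds, n_sample,
                                            rng, settings.cov_floor)
        starts = _screen(starts)
        if regularized and settings.verbose:
            print("[refine] covariance regularized by diagonal floor")

    if best_x is None:
        best_x = np.full(d, np.nan)
        status = "failed"
    k = d + k_extra
    log_l_max = -0.5 * best_val
    return FitResult(
        parameter_names=list(parameter_names) if parameter_names is not None
        else [f"p{i}" for i in range(d)],
        x=np.asarray(best_x, dtype=float),
        goodness_of_fit=float(best_val),
        k=k, aic=compute_aic(k, log_l_max=log_l_max),
        log_l_max=float(log_l_max),
        history=history, seed=settings.seed, n_rounds=n_rounds,
        topology=topology, status=status)


def fit_network(network: ReactionNetwork, dataset: Dataset,
                free_names: Sequence[str] | None = None,
                settings: FitSettings = FitSettings(),
                rtol: float = 1e-6, atol: float = 1e-9,
                screen_dataset: Dataset | None = None) -> FitResult:
    """Fit a network's free parameters to a dataset and score it by AIC.

    ``screen_dataset`` optionally provides a cheaper dataset (typically one
    informative condition) used only to rank the sampled starting vectors
    when ``settings.n_screen`` is set; the local optimizations and all
    reported values use the full dataset.
    """
    fn = ObjectiveFunction(network, dataset, free_names=free_names,
                           rtol=rtol, atol=atol)
    screen_fn = None
    if screen_dataset is not None:
        screen_fn = ObjectiveFunction(network, screen_dataset,
                                      free_names=fn.free_names,
                                      rtol=rtol, atol=atol)
    bounds = network.bounds(fn.free_names)
    return refine(fn, bounds, settings, parameter_names=fn.free_names,
                  k_extra=dataset.n_fitted_error_parameters(),
                  topology=network.topology, screen_objective=screen_fn)


def compute_aic(k: int, L_max: float | None = None,
                log_l_max: float | None = None) -> float:
    """Akaike Information Criterion, 2k - 2 ln(L_max)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if log_l_max is None:
        if L_max is None or L_max <= 0 or not np.isfinite(L_max):
            raise ValueError("L_max must be a positive finite likelihood")
        log_l_max = float(np.log(L_max))
    if not np.isfinite(log_l_max):
        raise ValueError("log-likelihood must be finite")
    return float(2.0 * k - 2.0 * log_l_max)


def rank_models(results: Sequence[FitResult]) -> list[dict]:
    """Order fits by AIC (ascending) and flag highly significant gaps.

    Returns one record per fit with its AIC difference to the best model and
    a flag set when that difference exceeds ten.
    """
    if not results:
        raise ValueError("no fit results to rank")
    ordered = sorted(results, key=lambda r: r.aic)
    best = ordered[0].aic
    out = []
    for rank, r in enumerate(ordered):
        delta = r.aic - best
        out.append({
            "rank": rank + 1,
            "topology": r.topology.label if r.topology else None,
            "aic": float(r.aic),
            "delta_aic": float(delta),
            "goodness_of_fit": float(r.goodness_of_fit),
            "k": r.k,
            "highly_significant": bool(delta > AIC_HIGHLY_SIGNIFICANT),
            "result": r,
        })
    return out
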