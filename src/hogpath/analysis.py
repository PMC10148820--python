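"""Post-fit interrogation of HOG models.

Covers the processivity score of the Hog1-Pbs2 reaction, Hill/EC50
ultrasensitivity of simulated dose-responses, robustness ensembles under
protein-abundance perturbation, Harrell-Davis quantile-shift statistics, and
supporting regression/bootstrap utilities.

Processivity score
------------------
For the mixed mechanism, the propensity of Pbs2-bound mono-phosphorylated
Hog1 to undergo the immediate second phosphorylation rather than dissociate:

    ([Pbs2PPHog1P] k_phospho + [Pbs2PPHog1P_feedback] k_phospho_feed)
    -----------------------------------------------------------------
    ([Pbs2PPHog1P] + [Pbs2PPHog1P_feedback]) k_off

where the feedback-modified complex carries a catalytically boosted second
step while the dissociation rate is shared.  Scores well below one indicate
distributive-like behaviour, scores above one processive-like behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .network import ReactionNetwork, StrainSpec, apply_strain
from .observation import hog1_species_sets
from .simulate import (CompiledModel, EquilibrationError, InputProtocol,
                       Trajectory, compile_model, equilibrate, run)

__all__ = [
    "ProcessivityInputs",
    "HillFit",
    "PerturbationScheme",
    "QuantileShiftResult",
    "PERTURBED_PROTEINS",
    "processivity_score",
    "processivity_timecourse",
    "dose_response",
    "hill_fit",
    "perturbation_ensemble",
    "harrell_davis",
    "quantile_shift",
    "regress_perturbations",
    "histogram_with_bootstrap",
]

#: Proteins whose abundance is varied in robustness ensembles (the Sln1
#: sub-branch plus the tyrosine phosphatases).
PERTURBED_PROTEINS = ("Sln1", "Ssk1", "Ssk2", "Ste20", "Pbs2", "Ptp2", "Ptp3")

QUANTILE_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))  # 19 points
N_BOOTSTRAP = 200


# ---------------------------------------------------------------------------
# Processivity score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessivityInputs:
    """Amounts and rates entering the processivity score."""

    complex_amount: float          # [Pbs2PPHog1P]
    feedback_complex_amount: float  # [Pbs2PPHog1P_feedback]
    k_phospho: float
    k_phospho_feed: float
    k_off: float

    def __post_init__(self):
        if self.complex_amount < 0 or self.feedback_complex_amount < 0:
            raise ValueError("complex amounts must be non-negative")
        if min(self.k_phospho, self.k_phospho_feed, self.k_off) <= 0:
            raise ValueError("rate constants must be strictly positive")


def processivity_score(inputs: ProcessivityInputs) -> float:
    """Immediate-second-step flux over dissociation flux of the mono complex."""
    c, cf = inputs.complex_amount, inputs.feedback_complex_amount
    denom = (c + cf) * inputs.k_off
    if denom == 0.0:
        raise ZeroDivisionError(
            "processivity score undefined: both complex amounts are zero")
    return (c * inputs.k_phospho + cf * inputs.k_phospho_feed) / denom


def processivity_timecourse(trajectory: Trajectory,
                            network: ReactionNetwork | None = None) -> np.ndarray:
    """Processivity score along a trajectory (NaN where undefined).

    Requires a mixed-mechanism network: both the immediate second-step rate
    ``k_phospho`` and the dissociation rate ``k_off`` must exist.
    """
    net = network or trajectory.network
    for p in ("k_phospho", "k_off"):
        if p not in net.parameters:
            raise ValueError(
                f"processivity score needs parameter {p!r}: it is defined for "
                "the mixed mechanism (topology must include both the immediate "
                "second phosphorylation and complex dissociation)")
    if "Pbs2PPHog1P" not in net.species_names:
        raise ValueError("network lacks the Pbs2PPHog1P complex species")
    kp = net.param_value("k_phospho")
    koff = net.param_value("k_off")
    c = trajectory.amount("Pbs2PPHog1P")
    if "Pbs2PPHog1P_feedback" in net.species_names:
        cf = trajectory.amount("Pbs2PPHog1P_feedback")
        kpf = kp * (net.param_value("fb_catalytic")
                    if "fb_catalytic" in net.parameters else 1.0)
    else:
        cf = np.zeros_like(c)
        kpf = kp
    denom = (c + cf) * koff
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (c * kp + cf * kpf) / denom
    return np.where(denom > 0, score, np.nan)


# ---------------------------------------------------------------------------
# Dose response and Hill fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFit:
    """Fitted Hill curve: basal + (maximum-basal) d^n / (EC50^n + d^n)."""

    basal: float
    maximum: float
    ec50: float
    n: float
    residual_norm: float = 0.0
    flagged: bool = False
    message: str = ""

    def __post_init__(self):
        if self.ec50 <= 0 or self.n <= 0:
            raise ValueError("EC50 and Hill coefficient must be positive")

    def __call__(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.basal + (self.maximum - self.basal) * d ** self.n / (
            self.ec50 ** self.n + d ** self.n)


def dose_response(network: ReactionNetwork, doses: Sequence[float],
                  params: Mapping[str, float] | None = None,
                  protocol_kind: str = "step", horizon: float = 2400.0,
                  rtol: float = 1e-8, atol: float = 1e-10,
                  min_step: float = 0.0,
                  rhs_budget: int | None = None,
                  fail_fast: bool = False) -> np.ndarray:
    """Maximal Hog1-PP percent (of total Hog1) per stimulus dose.

    For HOG networks each dose is a NaCl step amplitude; for the basic
    cascade each dose sets the ``input`` parameter and the steady response is
    read from a long unstimulated integration.
    """
    net = network
    model = compile_model(net)
    if params:
        model.set_params(params)
    out = np.empty(len(doses))
    if net.kind == "cascade":
        idx = net.species_index("K_PP")
        tot_idx = [net.species_index(s) for s in net.conserved_totals["MAPK"]]
        y_guess = None  # continue from the previous dose's steady state
        for i, d in enumerate(doses):
            model.set_params({"input": np.log10(max(d, 1e-12))})
            try:
                y = equilibrate(net, model=model, rtol=rtol, atol=atol,
                                t_cap=1e5, y0=y_guess, min_step=min_step,
                                rhs_budget=rhs_budget)
            except EquilibrationError:
                out[i] = np.nan
                if fail_fast:
                    out[i:] = np.nan
                    break
                y_guess = None
                continue
            y_guess = y
            total = y[tot_idx].sum()
            out[i] = 100.0 * y[idx] / total
        return out
    sets = hog1_species_sets(net)
    y0 = equilibrate(net, model=model, rtol=rtol, atol=atol,
                     min_step=min_step, rhs_budget=rhs_budget)
    tgrid = np.linspace(0.0, horizon, 201)
    for i, d in enumerate(doses):
        protocol = InputProtocol(kind=protocol_kind, amplitude=float(d),
                                 horizon=horizon)
        traj = run(net, protocol=protocol, tgrid=tgrid, model=model, y0=y0,
                   rtol=rtol, atol=atol, min_step=min_step,
                   rhs_budget=rhs_budget)
        if not traj.success:
            out[i] = np.nan
            if fail_fast:
                out[i:] = np.nan
                break
            continue
        pp = traj.total(sets["hog1_pp"])
        total = traj.total(sets["hog1_all"])[0]
        out[i] = 100.0 * pp.max() / total
    return out


def hill_fit(doses: Sequence[float], responses: Sequence[float]) -> HillFit:
    """Least-squares Hill fit with a deterministic initialization policy.

    Starts from n = 2 and EC50 at the interpolated half-maximal dose, with
    the Hill coefficient bounded to (0.1, 20).  Non-monotone or degenerate
    data yield a flagged fit rather than an exception.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 doses spanning the transition")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    order = np.argsort(d)
    d, y = d[order], y[order]

    basal0, max0 = float(y[0]), float(y[-1])
    span = max0 - basal0
    flagged = False
    message = ""
    if span <= 0 or np.max(y) - np.min(y) < 1e-12:
        flagged = True
        message = "degenerate or non-increasing response"
        span = max(np.max(y) - np.min(y), 1e-9)
        basal0, max0 = float(np.min(y)), float(np.max(y))
    half = basal0 + span / 2.0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        frac = (half - y[i - 1]) / max(y[i] - y[i - 1], 1e-12)
        ec50_0 = d[i - 1] + frac * (d[i] - d[i - 1])
    else:
        ec50_0 = d[max(1, d.size // 2)]
    ec50_0 = float(np.clip(ec50_0, max(d[d > 0].min(), 1e-6), d.max()))

    def model(dd, basal, maximum, ec50, n):
        return basal + (maximum - basal) * dd ** n / (ec50 ** n + dd ** n)

    p0 = [basal0, max0, ec50_0, 2.0]
    lo = [-np.inf, -np.inf, 1e-9, 0.1]
    hi = [np.inf, np.inf, 10.0 * d.max(), 20.0]
    try:
        popt, _ = curve_fit(model, d, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except Exception as e:  # pragma: no cover - curve_fit rarely fails here
        return HillFit(basal0, max0, ec50_0, 2.0, np.inf, True,
                       f"fit failed: {e}")
    resid = float(np.linalg.norm(y - model(d, *popt)))
    return HillFit(float(popt[0]), float(popt[1]), float(popt[2]),
                   float(popt[3]), resid, flagged, message)


# ---------------------------------------------------------------------------
# Robustness ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationScheme:
    """Per-protein abundance multipliers, each within [0.5, 2]."""

    multipliers: tuple  # ((protein, factor), ...)

    def __post_init__(self):
        for prot, f in self.multipliers:
            if not 0.5 <= f <= 2.0:
                raise ValueError(
                    f"multiplier for {prot} outside [0.5, 2]: {f}")

    def as_dict(self) -> dict:
        return dict(self.multipliers)


def perturbation_ensemble(network: ReactionNetwork, n_runs: int,
                          protocol: InputProtocol,
                          seed: int = 0,
                          proteins: Sequence[str] = PERTURBED_PROTEINS,
                          interval: tuple[float, float] = (0.5, 2.0),
                          rtol: float = 1e-6, atol: float = 1e-9,
                          n_time: int = 121) -> dict:
    """Distribution of maximal Hog1-PP percent under abundance perturbation.

    Draws ``n_runs`` independent schemes with log-uniform multipliers on
    ``interval``, re-equilibrates each perturbed cell, applies the protocol
    and records the maximal percent of doubly phosphorylated Hog1.  Failed
    runs are recorded (NaN maxima plus indices), never silently dropped.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    lo, hi = interval
    if not (0.5 <= lo <= hi <= 2.0):
        raise ValueError("multiplier interval must lie within [0.5, 2]")
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi),
                               size=(n_runs, len(proteins))))
    sets = hog1_species_sets(network)
    tgrid = np.linspace(0.0, protocol.horizon, n_time)
    maxima = np.full(n_runs, np.nan)
    schemes: list[PerturbationScheme] = []
    failures: list[int] = []
    for i in range(n_runs):
        scheme = PerturbationScheme(tuple(zip(proteins, map(float, draws[i]))))
        schemes.append(scheme)
        strain = StrainSpec(overexpression=scheme.multipliers)
        net = apply_strain(network, strain)
        model = compile_model(net)
        try:
            y0 = equilibrate(net, model=model, rtol=rtol, atol=atol)
        except EquilibrationError:
            failures.append(i)
            continue
        traj = run(net, protocol=protocol, tgrid=tgrid, model=model, y0=y0,
                   rtol=rtol, atol=atol)
        if not traj.success:
            failures.append(i)
            continue
        total = traj.total(sets["hog1_all"])[0]
        maxima[i] = 100.0 * traj.total(sets["hog1_pp"]).max() / total
    return {"maxima": maxima, "schemes": schemes, "failures": failures,
            "proteins": tuple(proteins), "interval": (lo, hi), "seed": seed,
            "multiplier_sampling": "log-uniform"}


# ---------------------------------------------------------------------------
# Harrell-Davis quantiles and the shift function
# ---------------------------------------------------------------------------

def harrell_davis(sample: Sequence[float], q: float | Sequence[float]):
    """Harrell-Davis quantile estimate(s).

    The estimator is a Beta-weighted average of the order statistics: for a
    sample of size m the weight of the i-th order statistic is the increment
    of the Beta((m+1)q, (m+1)(1-q)) CDF over ((i-1)/m, i/m].
    """
    x = np.sort(np.asarray(sample, dtype=float))
    m = x.size
    if m < 2:
        raise ValueError("need at least 2 observations")
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any((qs <= 0) | (qs >= 1)):
        raise ValueError("quantiles must lie strictly between 0 and 1")
    edges = np.arange(m + 1) / m
    out = np.empty(qs.size)
    for j, qq in enumerate(qs):
        cdf = stats.beta.cdf(edges, (m + 1) * qq, (m + 1) * (1 - qq))
        w = np.diff(cdf)
        out[j] = float(w @ x)
    return out if np.ndim(q) else float(out[0])


@dataclass
class QuantileShiftResult:
    """Harrell-Davis quantile differences between two samples with CIs."""

    quantiles: np.ndarray
    qa: np.ndarray
    qb: np.ndarray
    difference: np.ndarray         # qb - qa
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray        # multiplicity-controlled flags
    n_boot: int = N_BOOTSTRAP
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "q": self.quantiles, "qa": self.qa, "qb": self.qb,
            "diff": self.difference, "lo": self.ci_low, "hi": self.ci_high,
            "p": self.p_values, "flag": self.significant})


def _hochberg(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Hochberg step-up rejections at level alpha."""
    m = p.size
    order = np.argsort(p)[::-1]  # descending
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        # rank 0 is the largest p-value (threshold alpha/1)
        if p[idx] <= alpha / (rank + 1):
            # reject this and all smaller p-values
            reject[order[rank:]] = True
            break
    return reject


def quantile_shift(sample_a: Sequence[float], sample_b: Sequence[float],
                   seed: int = 0, n_boot: int = N_BOOTSTRAP,
                   alpha: float = 0.05) -> QuantileShiftResult:
    """Wilcox-style quantile shift function between two samples.

    Estimates the 0.05..0.95 quantiles (step 0.05) of both samples with the
    Harrell-Davis estimator, forms their differences (b - a), percentile
    bootstrap 95% confidence intervals from ``n_boot`` resamples, and flags
    grid points whose bootstrap p-values survive Hochberg's step-up control
    at level ``alpha``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("each sample needs at least 10 observations")
    qs = np.asarray(QUANTILE_GRID)
    qa = harrell_davis(a, qs)
    qb = harrell_davis(b, qs)
    diff = qb - qa

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, qs.size))
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        boot[i] = harrell_davis(rb, qs) - harrell_davis(ra, qs)
    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    # bootstrap sign test p-values, with the usual +1 continuity correction
    n_pos = (boot > 0).sum(axis=0)
    n_neg = (boot < 0).sum(axis=0)
    p = 2.0 * (np.minimum(n_pos, n_neg) + 1) / (n_boot + 1)
    p = np.minimum(p, 1.0)
    flags = _hochberg(p, alpha)
    if np.array_equal(a, b):
        flags = np.zeros_like(flags)  # identical samples: no shift by definition
    return QuantileShiftResult(qs, qa, qb, diff, lo, hi, p, flags,
                               n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Regression and histogram utilities
# ---------------------------------------------------------------------------

#: Parameters freed when fitting the basic cascade to dose-response data:
#: the input gain and the kinase/phosphatase balances of the lower tiers,
#: identical for both mechanisms so the comparison is purely structural
#: (tier-3 binding/catalysis and the saturation constants are model
#: constants, with the tier enzymes operating near saturation as in the
#: classic three-tier cascade formulation).
CASCADE_FREE_PARAMS = ("k1", "k2", "d2", "d3", "d3_mono")


def cascade_mechanism_comparison(doses: Sequence[float],
                                 responses: Sequence[float],
                                 sigma: float,
                                 settings=None) -> dict:
    """Fit distributive and processive basic cascades to one dose-response.

    Both three-tier cascade variants are fitted by the multistart scheme to
    the same steady-state MAPK-PP dose-response data (Gaussian error
    ``sigma``) and compared by AIC.  Returns the two fits, their AIC
    difference, and whether the mechanisms are statistically
    indistinguishable (|dAIC| <= 10).
    """
    from .fit import FitSettings, compute_aic, refine
    from .network import build_basic_cascade

    settings = settings or FitSettings(n_starts=6, top_set=3, max_iter=40,
                                       max_rounds=1, seed=0, grad_eps=1e-4)
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    fits = {}
    for mech in ("distributive", "processive"):
        names = CASCADE_FREE_PARAMS
        net = build_basic_cascade(mech)
        anchor = net.log10_values(list(names))

        def objective(x, net=net, names=names):
            p = dict(zip(names, x))
            r = dose_response(net, d, params=p, rtol=1e-6, atol=1e-8,
                              rhs_budget=4000, fail_fast=True)
            if not np.all(np.isfinite(r)):
                return 1e8
            return float(np.sum((y - r) ** 2 / sigma ** 2
                                + np.log(2 * np.pi * sigma ** 2)))

        fits[mech] = refine(objective, net.bounds(list(names)), settings,
                            parameter_names=names, anchor_starts=anchor)
    delta = abs(fits["distributive"].aic - fits["processive"].aic)
    return {
        "fits": fits,
        "aic_distributive": fits["distributive"].aic,
        "aic_processive": fits["processive"].aic,
        "delta_aic": float(delta),
        "indistinguishable": bool(delta <= 10.0),
    }


def regress_perturbations(schemes: Sequence[PerturbationScheme],
                          maxima: Sequence[float]) -> dict:
    """OLS of maximal Hog1-PP on the abundance multipliers plus intercept.

    Raises on a rank-deficient design instead of silently pseudo-inverting.
    """
    y = np.asarray(maxima, dtype=float)
    if len(schemes) != y.size:
        raise ValueError("schemes and maxima length mismatch")
    proteins = [p for p, _ in schemes[0].multipliers]
    if y.size < 2 * (len(proteins) + 1):
        raise ValueError("need at least twice as many runs as coefficients")
    X = np.column_stack([np.ones(y.size)] +
                        [[s.as_dict()[p] for s in schemes] for p in proteins])
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear design: rank {rank} < {X.shape[1]} columns "
            f"(condition number {np.linalg.cond(X):.3g})")
    coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "intercept": float(coef[0]),
        "coefficients": dict(zip(proteins, map(float, coef[1:]))),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        "n": int(y.size),
        "condition_number": float(np.linalg.cond(X)),
    }


def calibration_report(rtol: float = 1e-6, atol: float = 1e-9,
                       horizon: float = 3600.0, n_time: int = 181) -> dict:
    """Physiological signatures of the reference calibrations.

    Simulates the per-mechanism reference calibrations under a 0.4 M NaCl
    step for the wild type and the key genetic perturbations and summarizes
    the quantities used to judge the calibration: basal/peak/adapted Hog1-PP
    percent, volume undershoot and recovery, mono-phosphorylated Hog1 shape
    (timing of its global maximum), processivity-score dynamics, and the
    Pbs2-dosage behaviour of each mechanism.
    """
    from .calibration import reference_network
    from .network import StrainSpec

    tgrid = np.linspace(0.0, horizon, n_time)
    protocol = InputProtocol(kind="step", amplitude=0.4, horizon=horizon)

    def simulate(mechanism, strain=None):
        net = reference_network(mechanism, strain=strain or StrainSpec())
        model = compile_model(net)
        y0 = equilibrate(net, model=model, rtol=rtol, atol=atol)
        traj = run(net, protocol=protocol, tgrid=tgrid, model=model, y0=y0,
                   rtol=rtol, atol=atol)
        if not traj.success:
            raise RuntimeError(
                f"reference simulation failed ({mechanism}, {strain}): "
                f"{traj.diagnostics.get('message')}")
        return net, traj

    def pp_percent(net, traj):
        sets = hog1_species_sets(net)
        total = traj.total(sets["hog1_all"])[0]
        return 100.0 * traj.total(sets["hog1_pp"]) / total

    def mono_percent(net, traj):
        sets = hog1_species_sets(net)
        total = traj.total(sets["hog1_all"])[0]
        return 100.0 * traj.total(sets["hog1_mono"]) / total

    out: dict = {"time_grid": tgrid}
    ten_x = StrainSpec(overexpression=(("Pbs2", 10.0),))

    for mech in ("mixed", "distributive", "processive"):
        net, traj = simulate(mech)
        pp = pp_percent(net, traj)
        mono = mono_percent(net, traj)
        rec = {
            "basal_pp": float(pp[0]),
            "peak_pp": float(pp.max()),
            "final_pp": float(pp[-1]),
            "t_peak_pp": float(tgrid[pp.argmax()]),
            "mono_t_max": float(tgrid[mono.argmax()]),
            "mono_max": float(mono.max()),
            "volume_min": float(traj.cell_volume.min()),
            "t_volume_min": float(tgrid[traj.cell_volume.argmin()]),
            "volume_final": float(traj.cell_volume[-1]),
        }
        net10, traj10 = simulate(mech, ten_x)
        pp10 = pp_percent(net10, traj10)
        rec["pbs2_10x_basal_pp"] = float(pp10[0])
        rec["pbs2_10x_peak_pp"] = float(pp10.max())
        out[mech] = rec

    # mixed-calibration strain panel
    panel = {}
    for label, strain in [
        ("pbs2D", StrainSpec(deletions={"PBS2"})),
        ("ptp2D_ptp3D", StrainSpec(deletions={"PTP2", "PTP3"})),
        ("S248A", StrainSpec(pbs2_s248="S248A")),
        ("S248E", StrainSpec(pbs2_s248="S248E")),
    ]:
        net, traj = simulate("mixed", strain)
        pp = pp_percent(net, traj)
        score = processivity_timecourse(traj, net)
        panel[label] = {
            "basal_pp": float(pp[0]),
            "peak_pp": float(pp.max()),
            "final_pp": float(pp[-1]),
            "score_basal": float(score[0]),
            "score_peak": float(np.nanmax(score)),
        }
    out["strains"] = panel

    net, traj = simulate("mixed")
    score = processivity_timecourse(traj, net)
    out["mixed"]["score_basal"] = float(score[0])
    out["mixed"]["score_peak"] = float(np.nanmax(score))
    return out


def histogram_with_bootstrap(sample: Sequence[float],
                             bin_edges: Sequence[float],
                             seed: int = 0,
                             n_boot: int = N_BOOTSTRAP) -> dict:
    """Per-bin proportions with bootstrap standard deviations.

    Proportions are relative to the full sample size, so in-range bins plus
    the reported out-of-range mass sum to one.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one bin (two edges)")
    counts, _ = np.histogram(x, bins=edges)
    props = counts / x.size
    out_of_range = 1.0 - props.sum()
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, props.size))
    for i in range(n_boot):
        res = x[rng.integers(0, x.size, x.size)]
        boot[i] = np.histogram(res, bins=edges)[0] / x.size
    return {
        "bin_edges": edges,
        "proportions": props,
        "sd": boot.std(axis=0, ddof=0),
        "out_of_range": float(out_of_range),
        "n": int(x.size),
        "seed": seed,
    }
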