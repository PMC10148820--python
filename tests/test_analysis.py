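"""Post-fit analyses: processivity, Hill fits, ensembles, quantile shifts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hogpath.analysis import (PerturbationScheme, ProcessivityInputs,
                              dose_response, harrell_davis, hill_fit,
                              histogram_with_bootstrap, perturbation_ensemble,
                              processivity_score, processivity_timecourse,
                              quantile_shift, regress_perturbations)
from hogpath.calibration import reference_network
from hogpath.network import StrainSpec
from hogpath.simulate import InputProtocol


class TestProcessivityScore:
    def test_no_feedback_complex_reduces_to_rate_ratio(self):
        inp = ProcessivityInputs(0.4, 0.0, k_phospho=0.05, k_phospho_feed=1.5,
                                 k_off=1.0)
        assert processivity_score(inp) == pytest.approx(0.05)

    def test_equal_rates_collapse(self):
        inp = ProcessivityInputs(0.3, 0.7, k_phospho=0.2, k_phospho_feed=0.2,
                                 k_off=0.5)
        assert processivity_score(inp) == pytest.approx(0.4)

    def test_boosting_feedback_rate_increases_score(self):
        base = ProcessivityInputs(0.3, 0.2, 0.05, 1.0, 1.0)
        boosted = ProcessivityInputs(0.3, 0.2, 0.05, 2.0, 1.0)
        assert processivity_score(boosted) > processivity_score(base)

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(1e-6, 10.0), cf=st.floats(0.0, 10.0),
           scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, c, cf, scale):
        a = ProcessivityInputs(c, cf, 0.05, 1.5, 1.0)
        b = ProcessivityInputs(c * scale, cf * scale, 0.05, 1.5, 1.0)
        assert processivity_score(a) == pytest.approx(processivity_score(b),
                                                      rel=1e-9)

    def test_zero_complexes_undefined(self):
        with pytest.raises(ZeroDivisionError):
            processivity_score(ProcessivityInputs(0.0, 0.0, 0.1, 1.0, 1.0))

    def test_timecourse_rises_after_onset(self, mixed_network,
                                          mixed_step_trajectory):
        score = processivity_timecourse(mixed_step_trajectory, mixed_network)
        assert score[0] < np.nanmax(score)

    def test_timecourse_requires_mixed_topology(self):
        net = reference_network("processive")
        from hogpath.simulate import equilibrate, run

        y0 = equilibrate(net)
        traj = run(net, tgrid=np.linspace(0, 60, 4), y0=y0)
        with pytest.raises(ValueError, match="k_off"):
            processivity_timecourse(traj, net)


class TestHillFit:
    doses = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6])

    def _curve(self, n, basal=2.0, maximum=90.0, ec50=0.15):
        d = self.doses
        return basal + (maximum - basal) * d ** n / (ec50 ** n + d ** n)

    @pytest.mark.parametrize("n_true", [1.0, 3.0])
    def test_noiseless_self_consistency(self, n_true):
        fit = hill_fit(self.doses, self._curve(n_true))
        assert fit.n == pytest.approx(n_true, abs=1e-3)
        assert fit.ec50 == pytest.approx(0.15, rel=1e-3)

    def test_matches_grid_search_oracle_on_noisy_curve(self):
        rng = np.random.default_rng(5)
        y = self._curve(2.5) + rng.normal(0, 1.0, self.doses.size)
        fit = hill_fit(self.doses, y)
        # independent brute-force grid over (n, ec50) with analytic
        # linear-in-(basal, max) profiling at each grid point
        n_grid = np.arange(0.5, 6.0, 0.05)
        e_grid = np.geomspace(0.02, 0.8, 120)
        best = (np.inf, None, None)
        for n in n_grid:
            for e in e_grid:
                h = self.doses ** n / (e ** n + self.doses ** n)
                A = np.column_stack([1.0 - h, h])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                r = float(np.sum((y - A @ coef) ** 2))
                if r < best[0]:
                    best = (r, n, e)
        assert fit.n == pytest.approx(best[1], abs=0.05)
        assert fit.ec50 == pytest.approx(best[2], rel=0.05)

    def test_degenerate_data_flagged(self):
        fit = hill_fit(self.doses, np.full(self.doses.size, 5.0))
        assert fit.flagged

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            hill_fit([0.1, 0.2, 0.3], [1, 2, 3])


class TestHarrellDavis:
    def test_weights_sum_to_one(self):
        """Telescoping Beta-CDF weights: HD of a constant sample is exact."""
        for m in (7, 20, 55):
            sample = np.full(m, 3.25)
            for q in (0.05, 0.5, 0.93):
                assert harrell_davis(sample, q) == pytest.approx(3.25, abs=1e-12)

    def test_matches_direct_beta_weighted_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=23)
        m = x.size
        for q in (0.1, 0.5, 0.8):
            edges = np.arange(m + 1) / m
            w = np.diff(stats.beta.cdf(edges, (m + 1) * q, (m + 1) * (1 - q)))
            expected = float(w @ np.sort(x))
            assert harrell_davis(x, q) == pytest.approx(expected, rel=1e-12)

    def test_median_of_symmetric_sample(self):
        x = np.arange(1, 102, dtype=float)  # symmetric around 51
        assert harrell_davis(x, 0.5) == pytest.approx(51.0, abs=1e-9)


class TestQuantileShift:
    def test_identical_samples_zero_shift_no_flags(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        res = quantile_shift(x, x, seed=0)
        assert np.allclose(res.difference, 0.0)
        assert not res.significant.any()

    def test_location_shift_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        c = 1.3
        res = quantile_shift(a, a + c, seed=0)
        assert res.quantiles.size == 19
        assert np.allclose(res.difference, c, atol=1e-9)
        assert np.all(res.ci_low <= res.difference + 1e-9)
        assert np.all(res.difference <= res.ci_high + 1e-9)
        assert res.significant.all()

    def test_type_one_error_controlled(self):
        """Same-distribution samples: flagged fraction stays near alpha."""
        rng = np.random.default_rng(7)
        n_flagged, n_total = 0, 0
        for rep in range(15):
            a = rng.normal(size=60)
            b = rng.normal(size=60)
            res = quantile_shift(a, b, seed=rep)
            n_flagged += int(res.significant.sum())
            n_total += res.significant.size
        # familywise Hochberg control at 5% => well under 20% of grid points
        assert n_flagged / n_total < 0.2

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            quantile_shift(np.arange(5), np.arange(20), seed=0)


class TestRegression:
    def _schemes(self, n, seed=0):
        rng = np.random.default_rng(seed)
        from hogpath.analysis import PERTURBED_PROTEINS

        draws = np.exp(rng.uniform(np.log(0.5), np.log(2.0),
                                   (n, len(PERTURBED_PROTEINS))))
        return [PerturbationScheme(tuple(zip(PERTURBED_PROTEINS, row)))
                for row in draws]

    def test_exact_linear_model_recovered(self):
        schemes = self._schemes(40)
        y = np.array([3.0 + 7.5 * s.as_dict()["Pbs2"] for s in schemes])
        res = regress_perturbations(schemes, y)
        assert res["coefficients"]["Pbs2"] == pytest.approx(7.5, abs=1e-8)
        for prot, c in res["coefficients"].items():
            if prot != "Pbs2":
                assert c == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_zero_slopes(self):
        schemes = self._schemes(30)
        res = regress_perturbations(schemes, np.full(30, 42.0))
        assert all(abs(c) < 1e-8 for c in res["coefficients"].values())

    def test_matches_normal_equations_oracle(self):
        schemes = self._schemes(20, seed=4)
        rng = np.random.default_rng(5)
        y = rng.normal(50, 5, 20)
        res = regress_perturbations(schemes, y)
        X = np.column_stack(
            [np.ones(20)] + [[s.as_dict()[p] for s in schemes]
                             for p in res["coefficients"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["intercept"] == pytest.approx(beta[0], rel=1e-8)
        assert np.allclose(list(res["coefficients"].values()), beta[1:],
                           rtol=1e-8)

    def test_collinear_design_raises(self):
        schemes = self._schemes(30)
        # force perfect collinearity: every multiplier identical
        flat = [PerturbationScheme(tuple((p, 1.0) for p, _ in s.multipliers))
                for s in schemes]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            regress_perturbations(flat, np.arange(30.0))


class TestHistogramBootstrap:
    def test_single_covering_bin(self):
        res = histogram_with_bootstrap(np.arange(10.0), [-1.0, 11.0], seed=0)
        assert res["proportions"][0] == 1.0
        assert res["sd"][0] == 0.0

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        res = histogram_with_bootstrap(x, np.linspace(-1, 1, 6), seed=0)
        assert res["proportions"].sum() + res["out_of_range"] == pytest.approx(1.0)

    def test_sd_matches_large_b_reference(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        edges = np.array([-2.0, -0.5, 0.5, 2.0])
        small = histogram_with_bootstrap(x, edges, seed=0, n_boot=200)
        big = histogram_with_bootstrap(x, edges, seed=1, n_boot=10_000)
        assert np.all(np.abs(small["sd"] - big["sd"])
                      <= 0.3 * np.maximum(big["sd"], 1e-12))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            histogram_with_bootstrap([], [0, 1], seed=0)


class TestPerturbationEnsemble:
    def test_collapsed_interval_gives_identical_maxima(self, mixed_network):
        protocol = InputProtocol(kind="step", amplitude=0.4, horizon=1200.0)
        ens = perturbation_ensemble(mixed_network, 3, protocol, seed=0,
                                    interval=(1.0, 1.0), n_time=41)
        mx = ens["maxima"]
        assert np.all(np.isfinite(mx))
        assert np.allclose(mx, mx[0], rtol=1e-6)

    def test_schemes_within_interval_and_deterministic(self, mixed_network):
        protocol = InputProtocol(kind="step", amplitude=0.4, horizon=900.0)
        a = perturbation_ensemble(mixed_network, 4, protocol, seed=5, n_time=31)
        b = perturbation_ensemble(mixed_network, 4, protocol, seed=5, n_time=31)
        for scheme in a["schemes"]:
            for _, f in scheme.multipliers:
                assert 0.5 <= f <= 2.0
        assert np.array_equal(a["maxima"], b["maxima"])

    def test_dose_response_of_reference_is_sigmoid(self, mixed_network):
        doses = [0.0125, 0.05, 0.1, 0.2, 0.4, 0.6]
        resp = dose_response(mixed_network, doses, rtol=1e-6, atol=1e-9)
        assert resp[0] < 5.0
        assert resp[-1] > 40.0
        assert np.all(np.diff(resp) > -1.0)

    def test_s248e_strain_raises_basal_activity(self, mixed_network):
        from hogpath.calibration import reference_network
        from hogpath.simulate import equilibrate

        y_wt = equilibrate(mixed_network)
        net_e = reference_network("mixed", strain=StrainSpec(pbs2_s248="S248E"))
        y_e = equilibrate(net_e)
        idx = [mixed_network.species_index(s) for s in ("Hog1PP_c", "Hog1PP_n")]
        assert y_e[idx].sum() > y_wt[idx].sum()
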