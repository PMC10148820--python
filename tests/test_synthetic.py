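"""Synthetic-data generation: catalogue structure, noise model, recovery."""

import numpy as np
import pandas as pd
import pytest

from hogpath.fit import FitSettings
from hogpath.observation import predict
from hogpath.synthetic import (DesignEntry, GroundTruth, catalogue_frame,
                               design_catalogue, generate,
                               recovery_experiment, FIT_ROW_TOTAL)


class TestCatalogue:
    def test_fit_rows_total(self):
        frame = catalogue_frame()
        assert int((frame["use"] == "fit").sum()) == FIT_ROW_TOTAL == 533

    def test_pulse_periods_present(self):
        protos = {e.protocol_id for e in design_catalogue()}
        for period in (2, 4, 8, 16):
            assert f"pulse_0.2_{period}min" in protos

    def test_no_duplicate_dataset_time_pairs(self):
        frame = catalogue_frame()
        assert not frame.duplicated(["dataset_id", "time_s"]).any()

    def test_held_out_ramp_marked_test(self):
        ramp = [e for e in design_catalogue() if e.protocol_id == "ramp_0.2"]
        assert ramp and all(e.use == "test" for e in ramp)

    def test_mono_ms_flagged(self):
        flags = {e.dataset_id: e.mono_ms for e in design_catalogue()}
        assert flags["ms_hog1p176_wt"] is True
        assert flags["ms_hog1pp_wt"] is False

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            DesignEntry("x", "cell_area", "wt", "step_0.4", (10.0, 5.0),
                        "area", 0.02)


class TestGenerate:
    def test_noise_free_equals_predictions(self, small_dataset):
        gt, _ = small_dataset
        entries = [e for e in design_catalogue()
                   if e.dataset_id == "ms_hog1pp_wt"]
        ds = generate(gt, entries, noise_on=False)
        truth = predict(gt.network(), ds.frame)
        assert np.allclose(ds.frame["value"].to_numpy(), truth, rtol=1e-9)

    def test_same_seed_identical(self, small_dataset):
        gt, ds = small_dataset
        ds2 = generate(gt, [e for e in design_catalogue()
                            if e.dataset_id in ("ms_hog1pp_wt",
                                                "ms_hog1p176_wt")],
                       noise_on=True, seed=11)
        pd.testing.assert_frame_equal(ds.frame, ds2.frame)

    def test_noise_scale_matches_sigma(self):
        """Sample SD across many iid replicates of one entry approximates
        its sigma (one shared simulation, per-row Gaussian draws)."""
        gt = GroundTruth.reference("mixed", seed=0)
        entries = [DesignEntry(f"rep{i}", "nuc_cyt_ratio", "wt", "step_0.4",
                               (600.0,), "mic_wt", 0.3) for i in range(1000)]
        ds = generate(gt, entries, noise_on=True, seed=21)
        truth = predict(gt.network(), ds.frame.iloc[:1])
        resid = ds.frame["value"].to_numpy() - truth[0]
        assert np.std(resid) == pytest.approx(0.3, rel=0.10)

    def test_observable_invariants_pre_noise(self, full_dataset):
        gt, _ = full_dataset
        ds = generate(gt, noise_on=False)
        wb = ds.frame[ds.frame["modality"].str.startswith("wb")]
        assert (wb["value"] >= 0).all() and (wb["value"] <= 100).all()
        ms0 = ds.frame[(ds.frame["modality"] == "ms_fold_change")
                       & (ds.frame["time_s"] == 0.0)]
        assert np.allclose(ms0["value"], 1.0)

    def test_ms_60s_rows_average_two_draws(self, small_dataset):
        """The 60-s MS point averages two studies: its noise variance is
        halved relative to other MS rows of the same relative sigma."""
        gt, _ = small_dataset
        entries = [DesignEntry(f"r{i}", "ms_fold_change", "wt", "step_0.4",
                               (55.0, 60.0), "ms", 1.0) for i in range(400)]
        ds = generate(gt, entries, noise_on=True, seed=3)
        frame = ds.frame
        sd55 = frame[frame.time_s == 55.0]["value"].std()
        sd60 = frame[frame.time_s == 60.0]["value"].std()
        assert sd60 < sd55 * 0.85  # expect ~1/sqrt(2)


class TestRecovery:
    def test_report_arithmetic(self, small_dataset):
        """Median equals the brute-force median; counts partition."""
        gt, ds = small_dataset
        rep = recovery_experiment(
            gt, FitSettings(n_starts=1, top_set=1, max_iter=2, max_rounds=1,
                            seed=0),
            free_names=["k_phospho", "k_off"], dataset=ds)
        devs = np.array(list(rep["deviations"].values()))
        assert rep["median_abs_log10_deviation"] == pytest.approx(
            float(np.median(devs)))
        outside = int(np.sum(devs > 1.0))
        assert rep["n_within_one_order"] + outside == rep["n_parameters"] == 2

    def test_identifiable_toy_recovery(self):
        """Noiseless transient time courses from a known 5-parameter basic
        cascade are recovered almost exactly under a generous budget.

        Transient (rather than steady-state) data break the rate-ratio
        degeneracies that make steady-state dose-responses sloppy, so every
        freed rate is individually identifiable here.
        """
        from hogpath.fit import refine
        from hogpath.network import build_basic_cascade
        from hogpath.simulate import InputProtocol, compile_model, run

        net = build_basic_cascade("distributive")
        model = compile_model(net)
        tgrid = np.linspace(0.0, 60.0, 13)
        y_init = model.initial_state()
        proto = InputProtocol(kind="none", amplitude=0.0, horizon=60.0)
        i_pp = net.species_index("K_PP")
        i_p = net.species_index("K_P")

        def simulate(params):
            out = []
            for u in (0.1, 1.0):
                p = dict(params)
                p["input"] = np.log10(u)
                model.set_params(p)
                tr = run(net, protocol=proto, tgrid=tgrid, model=model,
                         y0=y_init, rtol=1e-7, atol=1e-10, rhs_budget=30000)
                if not tr.success:
                    return None
                out.extend([tr.amounts[i_pp], tr.amounts[i_p]])
            return np.concatenate(out)

        names = ["k2", "d2", "kcat_mapk1", "d3", "k_phospho2"]
        truth = net.log10_values(names)
        data = simulate(dict(zip(names, truth)))

        def obj(x):
            sim = simulate(dict(zip(names, x)))
            if sim is None:
                return 1e8
            return float(np.sum((data - sim) ** 2))

        res = refine(obj, net.bounds(names),
                     FitSettings(n_starts=6, top_set=3, max_iter=80,
                                 max_rounds=2, seed=0, n_screen=200,
                                 f_tol=1e-14))
        devs = np.abs(res.x - truth)
        assert float(np.median(devs)) < 0.05
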