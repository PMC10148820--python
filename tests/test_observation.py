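"""Observable mapping and the -2 logL objective."""

import numpy as np
import pandas as pd
import pytest

from hogpath.observation import (Dataset, ErrorModel, ObjectiveFunction,
                                 ObservableSpec, evaluate_observable,
                                 hog1_species_sets, objective, predict)
from hogpath.simulate import Trajectory


class TestEvaluateObservable:
    def test_fold_change_is_one_at_t0(self, mixed_network, mixed_step_trajectory):
        spec = ObservableSpec.for_network("ms_fold_change", mixed_network)
        series = evaluate_observable(mixed_step_trajectory, spec)
        assert series[0] == pytest.approx(1.0)

    def test_wb_percent_within_range(self, mixed_network, mixed_step_trajectory):
        spec = ObservableSpec.for_network("wb_percent_total_phospho",
                                          mixed_network)
        series = evaluate_observable(mixed_step_trajectory, spec)
        assert np.all(series >= 0.0) and np.all(series <= 100.0)

    def test_equal_concentrations_give_unit_ratio(self, mixed_network):
        """Nuclear and cytosolic Hog1 at equal concentration -> ratio 1."""
        from hogpath.network import NUCLEAR_VOLUME_FRACTION as nv

        sets = hog1_species_sets(mixed_network)
        n_sp = len(mixed_network.species)
        amounts = np.zeros((n_sp, 3))
        i_c = mixed_network.species_index("Hog1_c")
        i_n = mixed_network.species_index("Hog1_n")
        amounts[i_c] = 0.9
        amounts[i_n] = 0.9 * nv / (1.0 - nv)
        traj = Trajectory(t=np.array([0.0, 1.0, 2.0]), amounts=amounts,
                          network=mixed_network)
        spec = ObservableSpec("nuc_cyt_ratio", sets["hog1_nuclear"],
                              sets["hog1_cytosolic"])
        assert evaluate_observable(traj, spec) == pytest.approx([1.0] * 3)

    def test_cell_area_normalized_to_prestress(self, mixed_step_trajectory):
        spec = ObservableSpec("cell_area")
        series = evaluate_observable(mixed_step_trajectory, spec)
        assert series[0] == pytest.approx(1.0)
        assert series.min() == pytest.approx(
            (mixed_step_trajectory.cell_volume.min()
             / mixed_step_trajectory.cell_volume[0]) ** (2.0 / 3.0))


def _toy_dataset(gt, n=10, sigma=0.25, seed=2):
    """Small nuc:cyt dataset with known residual structure."""
    frame = pd.DataFrame({
        "dataset_id": "toy", "strain": "wt", "protocol_id": "step_0.4",
        "modality": "nuc_cyt_ratio",
        "time_s": np.linspace(0.0, 900.0, n),
        "value": 0.0, "sigma": sigma, "error_class": "toy", "use": "fit"})
    truth = predict(gt.network(), frame, rtol=1e-6, atol=1e-9)
    frame["value"] = truth
    return Dataset(frame, {"toy": ErrorModel("toy")}), truth


class TestObjective:
    def test_zero_residuals_closed_form(self, small_dataset):
        gt, _ = small_dataset
        ds, _ = _toy_dataset(gt, sigma=1.0)
        value = objective(gt.network(), ds, rtol=1e-6, atol=1e-9)
        n = len(ds.frame)
        assert value == pytest.approx(n * np.log(2.0 * np.pi), abs=1e-3)

    def test_matches_brute_force_sum(self, small_dataset):
        """Objective equals an independent per-point summation."""
        gt, _ = small_dataset
        ds, truth = _toy_dataset(gt)
        rng = np.random.default_rng(0)
        noisy = ds.frame.copy()
        noisy["value"] = truth + rng.normal(0, 0.25, len(truth))
        ds2 = Dataset(noisy, ds.error_models)
        value = objective(gt.network(), ds2, rtol=1e-6, atol=1e-9)
        pred = predict(gt.network(), noisy, rtol=1e-6, atol=1e-9)
        brute = sum((row.value - p) ** 2 / row.sigma ** 2
                    + np.log(2 * np.pi * row.sigma ** 2)
                    for row, p in zip(noisy.itertuples(), pred))
        assert value == pytest.approx(brute, rel=1e-9)

    def test_growing_residual_increases_objective(self, small_dataset):
        gt, _ = small_dataset
        ds, truth = _toy_dataset(gt)
        bumped = ds.frame.copy()
        bumped.loc[3, "value"] = truth[3] + 1.0
        more = bumped.copy()
        more.loc[3, "value"] = truth[3] + 2.0
        v1 = objective(gt.network(), Dataset(bumped, ds.error_models),
                       rtol=1e-6, atol=1e-9)
        v2 = objective(gt.network(), Dataset(more, ds.error_models),
                       rtol=1e-6, atol=1e-9)
        assert v2 > v1

    def test_row_order_and_split_invariance(self, small_dataset):
        gt, ds = small_dataset
        fn = ObjectiveFunction(gt.network(), ds)
        v = fn(None)
        shuffled = ds.frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
        v_shuffled = ObjectiveFunction(gt.network(),
                                       Dataset(shuffled, ds.error_models))(None)
        assert v_shuffled == pytest.approx(v, rel=1e-12)
        half = len(ds.frame) // 2
        a = Dataset(ds.frame.iloc[:half].reset_index(drop=True), ds.error_models)
        b = Dataset(ds.frame.iloc[half:].reset_index(drop=True), ds.error_models)
        va = ObjectiveFunction(gt.network(), a)(None)
        vb = ObjectiveFunction(gt.network(), b)(None)
        assert va + vb == pytest.approx(v, rel=1e-9)

    def test_deterministic(self, small_dataset):
        gt, ds = small_dataset
        fn = ObjectiveFunction(gt.network(), ds,
                               free_names=["k_phospho", "k_off"])
        x = np.array([-1.0, 0.2])
        assert fn(x) == fn(x)

    def test_fitted_sigma_never_worse_than_fixed(self, small_dataset):
        """Profiling an error scale cannot increase -2 logL."""
        gt, _ = small_dataset
        ds, truth = _toy_dataset(gt)
        rng = np.random.default_rng(3)
        noisy = ds.frame.copy()
        noisy["value"] = truth + rng.normal(0, 0.4, len(truth))
        fixed = objective(gt.network(), Dataset(noisy, {"toy": ErrorModel("toy")}),
                          rtol=1e-6, atol=1e-9)
        fitted = objective(gt.network(),
                           Dataset(noisy, {"toy": ErrorModel("toy", mode="fitted")}),
                           rtol=1e-6, atol=1e-9)
        assert fitted <= fixed + 1e-9


class TestDatasetValidation:
    def test_missing_column_named(self):
        frame = pd.DataFrame({"dataset_id": ["a"], "strain": ["wt"]})
        with pytest.raises(ValueError, match="missing column"):
            Dataset(frame)

    def test_nonpositive_sigma_rejected(self, small_dataset):
        _, ds = small_dataset
        bad = ds.frame.copy()
        bad.loc[5, "sigma"] = -1.0
        with pytest.raises(ValueError, match="sigma"):
            Dataset(bad)

    def test_unknown_strain_rejected(self, small_dataset):
        _, ds = small_dataset
        bad = ds.frame.copy()
        bad.loc[0, "strain"] = "hog1D_superman"
        with pytest.raises(ValueError, match="strain"):
            Dataset(bad)

    def test_empty_dataset_rejected(self):
        frame = pd.DataFrame(columns=["dataset_id", "strain", "protocol_id",
                                      "modality", "time_s", "value", "sigma",
                                      "error_class", "use"])
        with pytest.raises(ValueError):
            Dataset(frame)
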