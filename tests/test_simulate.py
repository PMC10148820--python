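"""Simulation: pre-equilibration, protocols, conservation, mechanism limits."""

import numpy as np
import pytest

from hogpath.calibration import reference_network, reference_params
from hogpath.network import (StrainSpec, TopologyConfig, apply_strain,
                             build_network)
from hogpath.simulate import (InputProtocol, compile_model, equilibrate, run)


class TestProtocols:
    def test_step_and_ramp_values(self):
        step = InputProtocol(kind="step", amplitude=0.4, onset=10.0)
        assert step.external(5.0) == 0.0
        assert step.external(10.0) == 0.4
        ramp = InputProtocol(kind="ramp", amplitude=0.2, ramp_duration=100.0)
        assert ramp.external(50.0) == pytest.approx(0.1)
        assert ramp.external(500.0) == pytest.approx(0.2)

    def test_pulse_train_period_exact(self):
        p = InputProtocol(kind="pulse_train", amplitude=0.2, pulse_period=4,
                          horizon=2400.0)
        period = 4 * 60.0
        t = np.linspace(0.0, 2000.0, 501)
        e = np.array([p.external(ti) for ti in t])
        e_shift = np.array([p.external(ti + period) for ti in t])
        assert np.array_equal(e, e_shift)
        # half-periods alternate high/low
        assert p.external(1.0) == 0.2 and p.external(period / 2 + 1.0) == 0.0

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            InputProtocol(kind="step", amplitude=1.5)
        with pytest.raises(ValueError):
            InputProtocol(kind="ramp", amplitude=0.2)
        with pytest.raises(ValueError):
            InputProtocol(kind="pulse_train", amplitude=0.2, pulse_period=3)


class TestEquilibrate:
    def test_returns_fixed_point(self, mixed_network, mixed_equilibrium):
        """A further long integration moves no species appreciably."""
        model, y0 = mixed_equilibrium
        traj = run(mixed_network, protocol=InputProtocol(kind="none", amplitude=0.0,
                                                         horizon=1e4),
                   tgrid=np.array([0.0, 1e4]), model=model, y0=y0)
        rel = np.abs(traj.amounts[:, -1] - traj.amounts[:, 0]) / np.maximum(
            traj.amounts[:, 0], 1e-9)
        assert rel.max() < 1e-6

    def test_two_starting_states_same_equilibrium(self, mixed_network):
        model = compile_model(mixed_network)
        y_a = equilibrate(mixed_network, model=model)
        alt = model.initial_state()
        # move half the free Hog1 into the nucleus before relaxing
        i_c = mixed_network.species_index("Hog1_c")
        i_n = mixed_network.species_index("Hog1_n")
        alt[i_n] = alt[i_c] * 0.5
        alt[i_c] *= 0.5
        y_b = equilibrate(mixed_network, model=model, y0=alt)
        assert np.allclose(y_a, y_b, rtol=1e-5, atol=1e-8)

    def test_phosphatase_deletion_raises_basal_hog1pp(self, mixed_network,
                                                      mixed_equilibrium):
        _, y_wt = mixed_equilibrium
        net = apply_strain(mixed_network, StrainSpec(deletions={"PTP2", "PTP3"}))
        y_mut = equilibrate(net)
        idx = [mixed_network.species_index(s) for s in ("Hog1PP_c", "Hog1PP_n")]
        assert y_mut[idx].sum() > y_wt[idx].sum()


class TestRun:
    def test_no_stimulus_keeps_equilibrium(self, mixed_network, mixed_equilibrium):
        model, y0 = mixed_equilibrium
        traj = run(mixed_network, protocol=InputProtocol(kind="none", amplitude=0.0),
                   tgrid=np.linspace(0, 2400, 25), model=model, y0=y0)
        drift = np.abs(traj.amounts - traj.amounts[:, :1]).max()
        assert drift < 1e-6

    def test_volume_drops_then_recovers(self, mixed_step_trajectory):
        """Osmotic shock shrinks the cell within a minute; glycerol
        accumulation then restores volume toward its pre-stress value."""
        traj = mixed_step_trajectory
        V = traj.cell_volume
        early = V[traj.t <= 60.0]
        assert early.min() < V[0] - 0.02
        assert V[-1] > V.min() + 0.5 * (V[0] - V.min())

    def test_conservation_across_pulse_events(self, mixed_network,
                                              mixed_equilibrium):
        model, y0 = mixed_equilibrium
        protocol = InputProtocol(kind="pulse_train", amplitude=0.2,
                                 pulse_period=4, horizon=1920.0)
        traj = run(mixed_network, protocol=protocol,
                   tgrid=np.linspace(0, 1920, 49), model=model, y0=y0)
        assert traj.success
        for protein in ("Hog1", "Pbs2", "Sln1", "Ste11"):
            assert traj.conservation_error(protein) < 1e-6

    def test_time_grid_strictly_increasing_amounts_nonnegative(
            self, mixed_step_trajectory):
        traj = mixed_step_trajectory
        assert np.all(np.diff(traj.t) > 0)
        assert traj.amounts.min() >= 0.0

    def test_tolerance_refinement_stable(self, mixed_network):
        """Tightening solver tolerances changes observables by < 0.1 %."""
        model = compile_model(mixed_network)
        y0 = equilibrate(mixed_network, model=model, rtol=1e-8, atol=1e-10)
        tgrid = np.linspace(0, 2400, 25)
        kw = dict(protocol=InputProtocol(kind="step", amplitude=0.4),
                  tgrid=tgrid, model=model, y0=y0)
        a = run(mixed_network, rtol=1e-8, atol=1e-10, **kw)
        b = run(mixed_network, rtol=1e-9, atol=1e-11, **kw)
        idx = [mixed_network.species_index(s) for s in ("Hog1PP_c", "Hog1PP_n")]
        pa, pb = a.amounts[idx].sum(0), b.amounts[idx].sum(0)
        assert np.max(np.abs(pa - pb)) / pb.max() < 1e-3


class TestMechanismLimits:
    """The mixed network reduces exactly to the pure mechanisms."""

    @staticmethod
    def _hog1pp(net, params, tgrid):
        model = compile_model(net)
        if params:
            model.set_params(params)
        y0 = equilibrate(net, model=model)
        traj = run(net, protocol=InputProtocol(kind="step", amplitude=0.4),
                   tgrid=tgrid, model=model, y0=y0)
        assert traj.success
        idx = [net.species_index(s) for s in ("Hog1PP_c", "Hog1PP_n")]
        return traj.amounts[idx].sum(0)

    def test_mixed_to_distributive_limit(self):
        tgrid = np.linspace(0, 1200, 25)
        params = reference_params("mixed")
        mixed = reference_network("mixed")
        dist = reference_network("distributive",
                                 topology=TopologyConfig(mechanism="distributive"))
        pp_mixed = self._hog1pp(mixed, {"k_phospho": -12.0}, tgrid)
        pp_dist = self._hog1pp(dist, {k: v for k, v in params.items()
                                      if k != "k_phospho"}, tgrid)
        assert np.max(np.abs(pp_mixed - pp_dist)) < 1e-6

    def test_mixed_to_processive_limit(self):
        tgrid = np.linspace(0, 1200, 25)
        params = reference_params("mixed")
        mixed = build_network(TopologyConfig(mechanism="mixed"), params=params)
        proc = build_network(TopologyConfig(mechanism="processive"), params=params)
        pp_mixed = self._hog1pp(mixed, {"k_off": -12.0, "kon_hog1p": -12.0}, tgrid)
        pp_proc = self._hog1pp(proc, None, tgrid)
        assert np.max(np.abs(pp_mixed - pp_proc)) < 1e-6
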