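"""Explicit time marching: stability guard, positivity, conservation,
steady-limit consistency and schedule semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bioheatfd as bh
from bioheatfd.transient import (
    StabilityError,
    TransientState,
    initial_field,
    layer_stability_limits,
    update_weights,
)
from conftest import make_slab_cfg

# rho c h^2 / (6 k + h^2 m_b c_b) per layer at h = 2 mm with the published
# constants; frozen from direct arithmetic.
LIMIT_SKULL = 2.47490000864808
LIMIT_SCALP = 7.508416259219982
LIMIT_CSF = 6.379861645266062


class TestStabilityLimit:
    def test_layer_bounds_match_frozen_arithmetic(self, case1):
        lims = layer_stability_limits(case1)
        assert lims["skull"] == pytest.approx(LIMIT_SKULL, rel=1e-12)
        assert lims["scalp"] == pytest.approx(LIMIT_SCALP, rel=1e-12)
        assert lims["csf"] == pytest.approx(LIMIT_CSF, rel=1e-12)

    def test_global_limit_is_the_skull_bound(self, case1):
        # the skull is the stiffest layer; surface Robin rows are softer here
        assert bh.stability_limit(case1) == pytest.approx(LIMIT_SKULL, rel=1e-12)

    def test_vanishing_conductivity_limit(self):
        # as k -> 0 the bound tends to rho c / (m_b c_b)
        cfg = make_slab_cfg(k=1e-9, rho=1000.0, c=3000.0, mb=6e-3, cb=4000.0,
                            he=0.0)
        lim = layer_stability_limits(cfg)["slab"]
        assert lim == pytest.approx(1000.0 * 3000.0 / (6e-3 * 4000.0), rel=1e-3)

    def test_strong_surface_exchange_tightens_the_bound(self):
        cfg = make_slab_cfg(he=1e5)
        assert bh.stability_limit(cfg) < layer_stability_limits(cfg)["slab"]


class TestFtcsStep:
    def test_refuses_unstable_step(self, case1):
        cfg = case1.with_(mode="transient")
        state = TransientState(time=0.0, field=initial_field(cfg))
        with pytest.raises(StabilityError, match="stability limit"):
            bh.ftcs_step(state, 1.05 * bh.stability_limit(cfg), cfg)

    def test_weights_nonnegative_at_the_bound(self, case1):
        dt = bh.stability_limit(case1)
        w = update_weights(case1, dt)
        assert w.toarray().min() >= -1e-12
        w_bad = update_weights(case1, 1.05 * dt)
        assert w_bad.toarray().min() < 0.0

    def test_uniform_insulated_field_is_a_fixed_point(self):
        cfg = make_slab_cfg(mb=6e-3, qm=0.0, he=0.0, deep="neumann_zero",
                            lateral="ghost_mirror", ta=38.0, tw=38.0,
                            mode="transient")
        state = TransientState(time=0.0,
                               field=initial_field(cfg.with_(initial_condition="uniform_arterial")))
        out = bh.ftcs_step(state, 0.9 * bh.stability_limit(cfg), cfg)
        assert np.allclose(out.field.values, 38.0, atol=1e-12)
        assert out.time == pytest.approx(0.9 * bh.stability_limit(cfg))

    def test_insulated_hot_spot_conserves_energy(self):
        # no perfusion, no sources, all faces insulated: the cell-volume
        # weighted rho c T sum is invariant under the explicit update
        cfg = make_slab_cfg(mb=0.0, qm=0.0, he=0.0, deep="neumann_zero",
                            lateral="ghost_mirror", mode="transient")
        from bioheatfd.transient import _Stepper

        stp = _Stepper(cfg)
        g = cfg.grid
        t = np.full(stp.system.n, 20.0)
        t[stp.cls.row_of[2, 2, 2]] += 10.0
        w = np.ones(g.node_shape)
        for ax, n in ((0, g.nx), (1, g.ny), (2, g.nz)):
            sl0, sl1 = [slice(None)] * 3, [slice(None)] * 3
            sl0[ax], sl1[ax] = 0, n
            w[tuple(sl0)] *= 0.5
            w[tuple(sl1)] *= 0.5
        wu = np.array([w[i, aj, ak] for (i, aj, ak) in stp.cls.unknowns])
        total0 = float((wu * t).sum())
        for _ in range(150):
            t = stp.explicit(t, 0.9 * stp.dt_max)
        assert (wu * t).sum() == pytest.approx(total0, abs=1e-9)

    @given(dt_frac=st.floats(0.1, 1.0), tw=st.floats(0.0, 20.0))
    @settings(max_examples=15, deadline=None)
    def test_boundedness_within_input_range(self, dt_frac, tw):
        """No over/undershoot: updates are convex combinations of inputs."""
        cfg = make_slab_cfg(mb=6e-3, qm=0.0, tw=tw, ta=40.0, he=800.0,
                            mode="transient")
        state = TransientState(time=0.0, field=initial_field(cfg))
        dt = dt_frac * bh.stability_limit(cfg)
        for _ in range(5):
            state = bh.ftcs_step(state, dt, cfg)
        assert state.field.values.min() >= min(tw, 40.0) - 1e-9
        assert state.field.values.max() <= 40.0 + 1e-9


class TestRunTransient:
    def test_output_at_time_zero_is_the_initial_condition(self, case1):
        cfg = case1.with_(mode="transient")
        caps = bh.run_transient(cfg, t_end=10.0, output_times=[0.0, 10.0])
        assert np.array_equal(caps[0].values, initial_field(cfg).values)
        assert caps[0].time == 0.0 and caps[1].time == 10.0

    def test_long_time_march_reaches_steady_state(self):
        cfg = make_slab_cfg(mb=6e-3, qm=500.0, he=700.0, mode="transient")
        cfg = cfg.with_(initial_condition="uniform_body",
                        schedule=cfg.schedule.__class__(
                            reset_action="refresh_robin_reference"))
        steady = bh.solve_steady(cfg)
        caps = bh.run_transient(cfg, t_end=2000.0, output_times=[2000.0])
        assert np.abs(caps[0].values - steady.values).max() <= 1e-3

    def test_substep_refinement_self_consistency(self, case1, case1_transient):
        cfg = case1.with_(mode="transient", safety_factor=0.45)
        halved = bh.run_transient(cfg)
        assert np.abs(halved[-1].values - case1_transient[-1].values).max() < 1e-3

    def test_symmetry_preserved_every_capture(self, case1_transient):
        for f in case1_transient:
            assert np.abs(f.values - f.values[:, ::-1, :]).max() < 1e-11
            assert np.abs(f.values - f.values[:, :, ::-1]).max() < 1e-11

    def test_cloth_reset_recools_the_surface(self, case1):
        # weak exchange lets the surface warm well above the cloth between
        # resets; the 2-minute reset clamps it back
        cfg = case1.with_(mode="transient",
                          shared=case1.shared.__class__(
                              mb=6.06e-3, cb=4010.0, ta=38.0, he=0.64, tw=7.0))
        caps = bh.run_transient(cfg, t_end=125.0, output_times=[120.0, 125.0])
        pre, post = caps[0].at(0, 0, 0), caps[1].at(0, 0, 0)
        assert pre > 15.0          # warmed since t = 0
        assert post < pre - 5.0    # clamped back towards 7 C at the tick

    def test_backward_euler_long_step_reaches_steady_state(self, case1):
        cfg = case1.with_(mode="transient",
                          schedule=case1.schedule.__class__(
                              reset_action="refresh_robin_reference"))
        steady = bh.solve_steady(cfg)
        caps = bh.run_transient(cfg, t_end=7200.0, output_times=[7200.0],
                                method="backward_euler", dt=120.0)
        assert np.abs(caps[0].values - steady.values).max() <= 1e-3

    def test_initial_condition_variants(self, case1):
        cfg = case1.with_(mode="transient")
        lin = initial_field(cfg)
        assert lin.at(0, 0, 0) == 7.0 and lin.at(4, 0, 0) == 38.0
        assert lin.at(2, 1, -1) == pytest.approx(7.0 + (38.0 - 7.0) * 0.5)
        uni = initial_field(cfg.with_(initial_condition="uniform_body"))
        assert uni.at(2, 0, 0) == 37.0 and uni.at(0, 2, 2) == 7.0


class TestCoolingCurve:
    def test_constant_problem_gives_constant_series(self):
        cfg = make_slab_cfg(mb=6e-3, qm=0.0, ta=38.0, tw=38.0, mode="transient",
                            initial_condition="uniform_arterial")
        caps = bh.run_transient(cfg, t_end=240.0, output_times=[0.0, 120.0, 240.0])
        times, temps = bh.cooling_curve(caps, (1, 1, 1))
        assert np.allclose(temps, 38.0, atol=1e-9)
        assert list(times) == [0.0, 120.0, 240.0]

    def test_missing_node_raises(self, case1_transient):
        with pytest.raises(IndexError):
            bh.cooling_curve(case1_transient, (0, 7, 0))

    def test_two_initial_conditions_contract_to_one_curve(self, case1, case1_transient):
        """The stable scheme forgets its initial data: runs started from
        different interior profiles converge onto the same cooling curve."""
        other = bh.run_transient(case1.with_(mode="transient",
                                             initial_condition="uniform_body"))
        diffs = [np.abs(a.values - b.values).max()
                 for a, b in zip(case1_transient, other)]
        assert diffs[0] > 10 * diffs[-1]      # strong contraction by 6 min
        assert all(d2 < d1 for d1, d2 in zip(diffs, diffs[1:]))
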