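"""Closed-form slab oracle, grid convergence, and reference-table tooling."""

from pathlib import Path

import numpy as np
import pytest

import bioheatfd as bh
from bioheatfd.geometry import ConfigurationError, SharedConstants, TissueProperties
from bioheatfd.verification import (
    TABLE_IDS,
    _tables_dir,
    compare_reference,
    load_reference_table,
    serialize_reference_table,
    slab_config,
    symmetry_audit,
)

SCALP = TissueProperties(k=0.342, rho=1070.0, c=3600.0, qm=0.0)


def scalp_slab(he=0.64, qm=0.0, qe=0.0, mb=6.06e-3, ta=38.0, tw=7.0, L=8e-3):
    return bh.SlabProblem(
        props=TissueProperties(k=SCALP.k, rho=SCALP.rho, c=SCALP.c, qm=qm),
        shared=SharedConstants(mb=mb, cb=4010.0, ta=ta, qe=qe, he=he, tw=tw),
        L=L,
    )


# Frozen oracle values for the scalp-only slab with the published weak
# exchange coefficient (h_e = 0.64 W m^-2 K^-1): computed once by two
# independent routes (closed form and a 10,000-node 1D finite-difference
# solve), which agreed to < 1e-6 C.
SLAB_T0 = 37.54343344728004
SLAB_T4MM = 37.77184642642387


class TestAnalyticSlab:
    def test_insulated_surface_perfusion_equilibrium(self):
        p = scalp_slab(he=0.0)
        xs = np.linspace(0, p.L, 9)
        assert np.allclose(bh.analytic_slab(p, xs), 38.0, atol=1e-12)

    def test_huge_exchange_approaches_cloth_clamp(self):
        # surface flux here is ~1.3 kW/m^2, so T(0) - T_w ~ flux / h_e
        p = scalp_slab(he=1e7)
        assert abs(bh.analytic_slab(p, 0.0) - 7.0) < 1e-3
        assert abs(bh.analytic_slab(scalp_slab(he=1e6), 0.0) - 7.0) < 1e-2

    def test_frozen_values_and_dense_fd_cross_check(self):
        p = scalp_slab()
        assert bh.analytic_slab(p, 0.0) == pytest.approx(SLAB_T0, abs=1e-9)
        assert bh.analytic_slab(p, 4e-3) == pytest.approx(SLAB_T4MM, abs=1e-9)
        xs, t_fd = bh.slab_fd_reference(p, n=10000)
        for x, ref in ((0.0, SLAB_T0), (4e-3, SLAB_T4MM)):
            i = int(round(x / (p.L / 10000)))
            assert t_fd[i] == pytest.approx(ref, abs=1e-6)

    def test_zero_perfusion_quadratic_branch(self):
        # with m_b = 0 and a uniform source the profile is quadratic; the
        # dense FD route is the independent check
        p = scalp_slab(mb=0.0, qm=1000.0, he=300.0)
        xs, t_fd = bh.slab_fd_reference(p, n=4000)
        samples = np.array([0.0, 2e-3, 6e-3])
        closed = bh.analytic_slab(p, samples)
        fd = np.interp(samples, xs, t_fd)
        assert np.allclose(closed, fd, atol=1e-5)

    def test_ode_residual_via_symbolic_derivative(self):
        """The closed form satisfies k T'' - w (T - T_A) + Q = 0."""
        import sympy as sp

        p = scalp_slab(qm=0.0, qe=250.0)
        w = p.shared.mb * p.shared.cb
        # rebuild the profile symbolically from two sampled values
        m = sp.sqrt(w / p.props.k)
        x = sp.Symbol("x")
        t_inf = p.shared.ta + (p.props.qm + p.shared.qe) / w
        x1, x2 = 1e-3, 5e-3
        t1, t2 = bh.analytic_slab(p, x1), bh.analytic_slab(p, x2)
        a_sym, b_sym = sp.symbols("A B")
        sol = sp.solve(
            [t_inf + a_sym * sp.cosh(m * x1) + b_sym * sp.sinh(m * x1) - t1,
             t_inf + a_sym * sp.cosh(m * x2) + b_sym * sp.sinh(m * x2) - t2],
            [a_sym, b_sym],
        )
        T = t_inf + sol[a_sym] * sp.cosh(m * x) + sol[b_sym] * sp.sinh(m * x)
        resid = p.props.k * sp.diff(T, x, 2) - w * (T - p.shared.ta) \
            + p.props.qm + p.shared.qe
        for xv in np.linspace(0, p.L, 100):
            assert abs(float(resid.subs(x, xv))) < 1e-8


class TestSolverAgainstSlab:
    def test_3d_solver_degenerates_to_the_1d_profile(self):
        # laterally insulated homogeneous box: every lateral position must
        # carry the 1D profile; refined grid agrees to well under 0.5%
        p = scalp_slab(he=640.0)
        cfg = slab_config(p, h=0.25e-3)
        fld = bh.solve_steady(cfg)
        for i in range(cfg.grid.nx + 1):
            exact = bh.analytic_slab(p, i * cfg.grid.h)
            plane = fld.values[i]
            assert np.abs(plane - exact).max() < 5e-3
            assert np.ptp(plane) < 1e-10   # laterally flat

    def test_convergence_second_order(self):
        res = bh.convergence_order(scalp_slab(he=640.0), [2e-3, 1e-3, 0.5e-3])
        assert not res.exact
        assert all(1.8 <= o <= 2.2 for o in res.orders)
        assert res.errors[0] > res.errors[-1]

    def test_first_order_robin_option_degrades_order(self):
        res = bh.convergence_order(scalp_slab(he=640.0), [2e-3, 1e-3, 0.5e-3],
                                   robin_order=1)
        assert all(0.8 <= o <= 1.4 for o in res.orders)

    def test_degenerate_exact_case_reported_as_exact(self):
        # T_w = T_A with no sources: uniform exact solution, errors at
        # round-off, no meaningful order
        res = bh.convergence_order(scalp_slab(he=640.0, tw=38.0),
                                   [2e-3, 1e-3, 0.5e-3])
        assert res.exact
        assert "exact" in res.summary()

    def test_rejects_non_nested_spacings(self):
        with pytest.raises(ConfigurationError, match="nested"):
            bh.convergence_order(scalp_slab(), [2e-3, 1.5e-3, 1e-3])


class TestReferenceTables:
    @pytest.mark.parametrize("table_id", TABLE_IDS)
    def test_fixture_roundtrip_byte_identical(self, table_id):
        path = _tables_dir() / f"{table_id}.csv"
        df = load_reference_table(table_id)
        assert serialize_reference_table(df) == path.read_text()

    def test_unknown_fixture(self):
        with pytest.raises(LookupError, match="unknown fixture"):
            load_reference_table("table9")

    def test_self_comparison_is_exact(self, case1):
        df = load_reference_table("table1")
        values = np.full(case1.grid.node_shape, np.nan)
        g = case1.grid
        for _, r in df.iterrows():
            values[int(r.i), g.axis_index(int(r.j)), g.axis_index(int(r.k), "z")] = r["T"]
        fld = bh.TemperatureField(values, g)
        report = compare_reference(fld, "table1")
        assert report.n == 72
        assert report.max_abs_dev == 0.0

    def test_symmetry_audit_flags_published_anomaly(self):
        audit = symmetry_audit(load_reference_table("table3"), threshold=0.5)
        pairs = {(r.i, r.j1, r.k1, r.j2, r.k2) for r in audit.itertuples()}
        assert (3, 0, -1, 0, 1) in pairs     # 31.19 vs 32.19
        worst = audit.loc[audit.abs_diff.idxmax()]
        assert worst.abs_diff == pytest.approx(1.0, abs=1e-6)

    def test_steady_comparison_report(self, case1, case1_steady):
        report = compare_reference(case1_steady, "table1")
        assert report.n == 72
        assert report.max_abs_dev >= report.mean_abs_dev >= 0.0
        assert 0 <= report.n_within_tol <= report.n
        # misses are surfaced, never hidden
        assert len(report.misses()) + report.n_within_tol >= report.n - \
            report.table["suspect"].sum()
        assert "comparison against table1" in report.summary()

    def test_transient_comparison_needs_all_captures(self, case1, case1_transient):
        with pytest.raises(ValueError, match="missing capture"):
            compare_reference(case1_transient[:2], "table4")
        report = compare_reference(case1_transient, "table4")
        assert report.n == 70 * 3
        assert report.table["t_s"].nunique() == 3

    def test_suspect_exclusion_changes_only_flagged_rows(self, case1_steady):
        with_susp = compare_reference(case1_steady, "table3")
        without = compare_reference(case1_steady, "table3", exclude_suspects=True)
        n_flagged = int(with_susp.table["suspect"].sum())
        assert n_flagged > 0
        assert len(without._included()) == with_susp.n - n_flagged
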