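"""Independent oracles and comparison tooling.

Three kinds of checks live here:

* the closed-form 1D steady slab ("fin equation") solution, used as an
  exact oracle for the 3D solver on laterally-insulated homogeneous
  configurations, plus a dense 1D finite-difference reference that
  cross-checks the closed form itself;
* a grid-refinement harness that estimates the spatial convergence order
  of the steady solver against the slab oracle;
* diffing of computed fields against the published temperature tables
  (shipped as CSV fixtures, transcribed verbatim including their
  symmetry-violating entries, which are flagged rather than corrected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ConfigurationError,
    LayerField,
    LayerMaterial,
    ScenarioConfig,
    SharedConstants,
    TissueProperties,
    build_grid,
)
from .steady import TemperatureField, solve_steady

__all__ = [
    "SlabProblem",
    "analytic_slab",
    "slab_fd_reference",
    "slab_config",
    "ConvergenceResult",
    "convergence_order",
    "ComparisonReport",
    "load_reference_table",
    "serialize_reference_table",
    "symmetry_audit",
    "compare_reference",
    "TABLE_IDS",
]

TABLE_IDS = tuple(f"table{n}" for n in range(1, 7))
STEADY_TABLES = ("table1", "table2", "table3")
TRANSIENT_COLUMNS = ("T_2min", "T_4min", "T_6min")
TRANSIENT_TIMES = (120.0, 240.0, 360.0)


# --------------------------------------------------------------------------
# closed-form slab
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabProblem:
    """Homogeneous 1D steady slab with a Robin surface and a deep clamp.

    The steady bioheat ODE  k T'' - w (T - T_A) + Q = 0  with
    w = m_b c_b and Q = Q_m + Q_e, subject to

        k T'(0) = h_e (T(0) - T_w)      (Robin at the cooled surface)
        T(L)    = T_A                   (deep arterial clamp)
    """

    props: TissueProperties
    shared: SharedConstants
    L: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ConfigurationError("slab length must be > 0")


def analytic_slab(p: SlabProblem, x) -> np.ndarray | float:
    """Closed-form steady temperature at depth ``x`` (scalar or array, m).

    For w > 0:  T(x) = T_inf + A cosh(m x) + B sinh(m x) with
    m = sqrt(w/k) and T_inf = T_A + Q/w; A, B solve the 2x2 end-condition
    system

        -h_e A + k m B          = h_e (T_inf - T_w)
        cosh(mL) A + sinh(mL) B = T_A - T_inf .

    For w = 0 the profile is the quadratic -Q x^2 / 2k + C1 x + C0 fixed
    by the same two end conditions.
    """
    xs = np.asarray(x, dtype=float)
    scalar = xs.ndim == 0
    xs = np.atleast_1d(xs)
    if xs.min() < -1e-12 or xs.max() > p.L * (1 + 1e-12):
        raise ValueError(f"x outside slab [0, {p.L}]")
    k, he, tw, ta = p.props.k, p.shared.he, p.shared.tw, p.shared.ta
    q = p.props.qm + p.shared.qe
    w = p.shared.mb * p.shared.cb
    if w > 0:
        m = math.sqrt(w / k)
        t_inf = ta + q / w
        mat = np.array([
            [-he, k * m],
            [math.cosh(m * p.L), math.sinh(m * p.L)],
        ])
        rhs = np.array([he * (t_inf - tw), ta - t_inf])
        a, b = np.linalg.solve(mat, rhs)
        out = t_inf + a * np.cosh(m * xs) + b * np.sinh(m * xs)
    else:
        # k C1 - h_e C0 = -h_e T_w ;  C0 + L C1 = T_A + Q L^2 / 2k
        mat = np.array([[-he, k], [1.0, p.L]])
        rhs = np.array([-he * tw, ta + q * p.L * p.L / (2.0 * k)])
        c0, c1 = np.linalg.solve(mat, rhs)
        out = -q * xs * xs / (2.0 * k) + c1 * xs + c0
    return float(out[0]) if scalar else out


def slab_fd_reference(p: SlabProblem, n: int = 10000) -> tuple[np.ndarray, np.ndarray]:
    """Dense 1D finite-difference solve of the slab problem.

    An independent numerical route to the same solution (second-order
    stencil with Robin ghost elimination); used to cross-check the
    closed form.  Returns ``(x_nodes, T)`` including the deep node.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    h = p.L / n
    k, he, tw, ta = p.props.k, p.shared.he, p.shared.tw, p.shared.ta
    q = p.props.qm + p.shared.qe
    w = p.shared.mb * p.shared.cb
    a = h * h * w / k
    b = (h * h / k) * (w * ta + q)
    beta = 2.0 * h * he / k

    rows, cols, vals = [], [], []
    rhs = np.full(n, -b)
    for i in range(n):  # unknowns T_0 .. T_{n-1}
        rows.append(i); cols.append(i); vals.append(-(2.0 + a))
        if i == 0:
            rows.append(0); cols.append(0); vals.append(-beta)
            rows.append(0); cols.append(1); vals.append(2.0)
            rhs[0] -= beta * tw
        else:
            rows.append(i); cols.append(i - 1); vals.append(1.0)
            if i + 1 < n:
                rows.append(i); cols.append(i + 1); vals.append(1.0)
            else:
                rhs[i] -= ta
    mat = sp.csc_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    sol = spla.spsolve(mat, rhs)
    xs = np.arange(n + 1) * h
    return xs, np.append(sol, ta)


def slab_config(
    p: SlabProblem,
    h: float,
    lateral_cells: int = 4,
    lateral: str = "copy_face",
    robin_order: int = 2,
) -> ScenarioConfig:
    """3D scenario that degenerates to the 1D slab: one homogeneous layer,
    zero-flux lateral faces, Robin surface, deep Dirichlet clamp."""
    from .geometry import BoundarySpec, Schedule

    grid = build_grid(p.L, lateral_cells * h, lateral_cells * h, h)
    layers = LayerField(names=("slab",), thicknesses=(p.L,))
    mats = {"slab": LayerMaterial(p.props.k, p.props.rho, p.props.c, p.props.qm)}
    return ScenarioConfig(
        grid=grid,
        layers=layers,
        materials=mats,
        shared=p.shared,
        boundaries=BoundarySpec(surface="robin", deep="dirichlet",
                                lateral=lateral, robin_order=robin_order),
        mode="steady",
        schedule=Schedule(),
        name="slab",
    )


# --------------------------------------------------------------------------
# convergence
# --------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    h_list: list[float]
    errors: list[float]
    orders: list[float]
    exact: bool = False

    def summary(self) -> str:
        if self.exact:
            return "exact (errors below 1e-12 C)"
        lines = [f"h = {h * 1e3:.3g} mm : max error {e:.3e} C"
                 for h, e in zip(self.h_list, self.errors)]
        lines += [f"observed order: {o:.3f}" for o in self.orders]
        return "\n".join(lines)


def convergence_order(
    p: SlabProblem,
    h_list: list[float],
    robin_order: int = 2,
    lateral: str = "copy_face",
) -> ConvergenceResult:
    """Richardson-style order estimate of the steady 3D solver against the
    closed-form slab oracle.

    ``h_list`` must contain at least three spacings, each commensurate
    with the slab length and successively nested (factor-2 refinement).
    Returns max-errors per spacing and ``log2`` ratios of successive
    errors; if every error is below 1e-12 C the result is reported as
    exact instead of an order.
    """
    if len(h_list) < 3:
        raise ConfigurationError("need at least three grid spacings")
    for ha, hb in zip(h_list, h_list[1:]):
        if abs(ha / hb - 2.0) > 1e-9:
            raise ConfigurationError(
                f"spacings must be nested by factor 2, got {ha} -> {hb}"
            )
    errors = []
    for h in h_list:
        cfg = slab_config(p, h, lateral=lateral, robin_order=robin_order)
        fld = solve_steady(cfg)
        xs = np.arange(cfg.grid.nx + 1) * h
        exact = analytic_slab(p, xs)
        err = 0.0
        for i in range(cfg.grid.nx + 1):
            err = max(err, np.abs(fld.values[i] - exact[i]).max())
        errors.append(float(err))
    if max(errors) < 1e-12:
        return ConvergenceResult(list(h_list), errors, [], exact=True)
    orders = [float(np.log2(e0 / e1)) for e0, e1 in zip(errors, errors[1:])]
    return ConvergenceResult(list(h_list), errors, orders)


# --------------------------------------------------------------------------
# reference tables
# --------------------------------------------------------------------------

def _tables_dir() -> Path:
    return Path(str(resources.files("bioheatfd").joinpath("data/tables")))


def load_reference_table(table_id: str) -> pd.DataFrame:
    """Load a published-table fixture (``table1`` .. ``table6``)."""
    if table_id not in TABLE_IDS:
        raise LookupError(f"unknown fixture {table_id!r}; have {TABLE_IDS}")
    path = _tables_dir() / f"{table_id}.csv"
    df = pd.read_csv(path, keep_default_na=False, dtype={"note": str})
    return df


def serialize_reference_table(df: pd.DataFrame) -> str:
    """Canonical CSV serialization (2-decimal temperatures); fixtures on
    disk are stored in exactly this form, so parse -> serialize round-trips
    byte-identically."""
    return df.to_csv(index=False, float_format="%.2f")


def symmetry_audit(df: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Find fixture entries that violate the problem's y/z mirror symmetry.

    Every tabulated node (i, j, k) should agree with its mirrors
    (i, -j, k), (i, j, -k), (i, -j, -k).  Returns one row per unordered
    mismatched pair with absolute difference above ``threshold``.
    """
    value_cols = [c for c in df.columns if c.startswith("T")]
    recs = []
    keyed = {}
    for _, row in df.iterrows():
        keyed[(int(row.i), int(row.j), int(row.k))] = row
    seen = set()
    for (i, j, k), row in keyed.items():
        for mj, mk in ((-j, k), (j, -k), (-j, -k)):
            if (mj, mk) == (j, k):
                continue
            other = keyed.get((i, mj, mk))
            if other is None:
                continue
            pair = tuple(sorted([(i, j, k), (i, mj, mk)]))
            if pair in seen:
                continue
            seen.add(pair)
            for col in value_cols:
                d = abs(float(row[col]) - float(other[col]))
                if d > threshold:
                    recs.append({
                        "i": i, "j1": pair[0][1], "k1": pair[0][2],
                        "j2": pair[1][1], "k2": pair[1][2],
                        "column": col,
                        "T1": float(keyed[pair[0]][col]),
                        "T2": float(keyed[pair[1]][col]),
                        "abs_diff": d,
                    })
    return pd.DataFrame.from_records(
        recs, columns=["i", "j1", "k1", "j2", "k2", "column", "T1", "T2", "abs_diff"]
    )


@dataclass
class ComparisonReport:
    """Per-node diff of a computed field against a published table."""

    table_id: str
    table: pd.DataFrame          # i, j, k, [t_s], T_ref, T_model, abs_dev, note, suspect
    tol: float
    symmetry_violations: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclude_suspects: bool = False

    @property
    def n(self) -> int:
        return len(self.table)

    def _included(self) -> pd.DataFrame:
        if self.exclude_suspects and "suspect" in self.table:
            return self.table[~self.table["suspect"]]
        return self.table

    @property
    def max_abs_dev(self) -> float:
        return float(self._included()["abs_dev"].max())

    @property
    def mean_abs_dev(self) -> float:
        return float(self._included()["abs_dev"].mean())

    @property
    def n_within_tol(self) -> int:
        return int((self._included()["abs_dev"] <= self.tol).sum())

    def misses(self) -> pd.DataFrame:
        """Rows deviating beyond the tolerance — reported, never hidden."""
        return self.table[self.table["abs_dev"] > self.tol]

    def summary(self) -> str:
        inc = self._included()
        lines = [
            f"comparison against {self.table_id}: {self.n} tabulated values",
            f"  max |dT|  = {self.max_abs_dev:.2f} C",
            f"  mean |dT| = {self.mean_abs_dev:.2f} C",
            f"  within +/-{self.tol:.2f} C: {self.n_within_tol}/{len(inc)}",
        ]
        nv = len(self.symmetry_violations)
        if nv:
            worst = self.symmetry_violations["abs_diff"].max()
            lines.append(
                f"  fixture symmetry violations: {nv} pairs (worst {worst:.2f} C)"
            )
        nm = len(self.misses())
        if nm:
            lines.append(f"  values outside tolerance: {nm} (see misses())")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_reference(
    fields: TemperatureField | list[TemperatureField],
    table_id: str,
    tol: float = 0.5,
    suspect_threshold: float = 0.5,
    exclude_suspects: bool = False,
) -> ComparisonReport:
    """Diff computed field(s) against one of the published tables.

    Steady tables take a single field; transient tables take the three
    captures at 2, 4 and 6 minutes (matched on ``field.time``).  Fixture
    rows breaking the y/z mirror symmetry by more than
    ``suspect_threshold`` are pre-flagged as transcription suspects and
    can be excluded from the headline maximum.
    """
    df = load_reference_table(table_id)
    steady = table_id in STEADY_TABLES

    if steady:
        if isinstance(fields, list):
            if len(fields) != 1:
                raise ValueError(f"{table_id} is a steady table; pass one field")
            fld = fields[0]
        else:
            fld = fields
        by_time = {None: fld}
        value_cols = [("T", None)]
    else:
        if not isinstance(fields, list):
            raise ValueError(f"{table_id} is a transient table; pass the capture list")
        by_time = {}
        for f in fields:
            if f.time is None:
                raise ValueError("transient fields need a time stamp")
            by_time[round(f.time, 6)] = f
        for t in TRANSIENT_TIMES:
            if round(t, 6) not in by_time:
                raise ValueError(f"missing capture at t = {t} s for {table_id}")
        value_cols = list(zip(TRANSIENT_COLUMNS, TRANSIENT_TIMES))

    violations = symmetry_audit(df)
    suspect_nodes = set()
    for _, v in violations[violations["abs_diff"] > suspect_threshold].iterrows():
        suspect_nodes.add((int(v.i), int(v.j1), int(v.k1)))
        suspect_nodes.add((int(v.i), int(v.j2), int(v.k2)))

    recs = []
    for _, row in df.iterrows():
        i, j, k = int(row.i), int(row.j), int(row.k)
        for col, t in value_cols:
            fld = by_time[None if t is None else round(t, 6)]
            model = fld.at(i, j, k)
            ref = float(row[col])
            rec = {"i": i, "j": j, "k": k}
            if t is not None:
                rec["t_s"] = t
            rec.update({
                "T_ref": ref,
                "T_model": model,
                "abs_dev": abs(model - ref),
                "note": row.get("note", ""),
                "suspect": (i, j, k) in suspect_nodes,
            })
            recs.append(rec)
    table = pd.DataFrame.from_records(recs)
    return ComparisonReport(
        table_id=table_id,
        table=table,
        tol=tol,
        symmetry_violations=violations,
        exclude_suspects=exclude_suspects,
    )
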