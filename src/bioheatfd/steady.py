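"""Steady-state finite-difference solver for the Pennes bioheat equation.

The steady equation

    k (T_xx + T_yy + T_zz) - m_b c_b T = -(m_b c_b T_A + Q_m + Q_e)

is discretized on the uniform lattice with the 7-point stencil

    sum(6 neighbours) - (6 + (h^2/k) m_b c_b) T = -(h^2/k)(m_b c_b T_A + Q_m + Q_e)

with per-node layer constants.  Boundary handling:

* deep face: Dirichlet clamp at the arterial temperature (values folded
  into the right-hand side) or zero flux;
* surface: Robin exchange with the wet cloth, discretized with a ghost
  node eliminated via  k (T_1 - T_ghost) / (2h) = h_e (T_0 - T_w)  so
  surface nodes remain unknowns, or a hard Dirichlet clamp at T_w;
* lateral faces: zero flux, either by dependent face copies
  (``copy_face``; reproduces the compact 27-unknown reference system) or
  by mirror ghosts with face nodes kept as unknowns (``ghost_mirror``).

The assembled matrix is strictly diagonally dominant whenever perfusion
is active, so the direct sparse solve cannot encounter a singular system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ConfigurationError, Grid3D, ScenarioConfig

__all__ = [
    "NodeKind",
    "NodeClassification",
    "LinearSystem",
    "TemperatureField",
    "classify_nodes",
    "assemble_steady",
    "solve_steady",
    "steady_residual",
]

# node kinds
UNKNOWN = 0
DIRICHLET = 1
DEPENDENT = 2


class NodeKind:
    UNKNOWN = UNKNOWN
    DIRICHLET = DIRICHLET
    DEPENDENT = DEPENDENT


class SolverError(RuntimeError):
    """Raised when the linear solve fails its residual post-condition."""


@dataclass
class NodeClassification:
    """Role of every node: solved unknown, known Dirichlet value, or a
    dependent copy of an inner node (zero-flux face in ``copy_face`` mode)."""

    kind: np.ndarray            # int8, node_shape
    dirichlet: np.ndarray       # float, node_shape (NaN where not Dirichlet)
    parent: np.ndarray          # int, node_shape x 3 array indices (dependent only)
    row_of: np.ndarray          # int, node_shape; -1 for non-unknowns
    unknowns: np.ndarray        # (n_unknown, 3) array indices

    @property
    def n_unknowns(self) -> int:
        return len(self.unknowns)


def classify_nodes(cfg: ScenarioConfig) -> NodeClassification:
    g = cfg.grid
    shape = g.node_shape
    kind = np.full(shape, UNKNOWN, dtype=np.int8)
    dirichlet = np.full(shape, np.nan)
    parent = np.stack(np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij"), axis=-1)

    b = cfg.boundaries
    if b.lateral == "copy_face":
        # lateral face slices are dependent copies of the adjacent inner slice
        for axis, n in ((1, g.ny), (2, g.nz)):
            lo, hi = 0, n
            sel_lo = [slice(None)] * 3
            sel_hi = [slice(None)] * 3
            sel_lo[axis] = lo
            sel_hi[axis] = hi
            kind[tuple(sel_lo)] = DEPENDENT
            kind[tuple(sel_hi)] = DEPENDENT
            parent[tuple(sel_lo) + (axis,)] = lo + 1
            parent[tuple(sel_hi) + (axis,)] = hi - 1

    if b.deep == "dirichlet":
        kind[g.nx, :, :] = DIRICHLET
        dirichlet[g.nx, :, :] = cfg.shared.ta
        parent[g.nx, :, :, :] = np.stack(np.meshgrid(
            [g.nx], np.arange(shape[1]), np.arange(shape[2]),
            indexing="ij"), axis=-1)[0]
    elif b.lateral == "copy_face":
        # zero-flux deep face handled like a lateral copy face
        kind[g.nx, :, :] = DEPENDENT
        parent[g.nx, :, :, 0] = g.nx - 1

    if b.surface == "dirichlet":
        kind[0, :, :] = DIRICHLET
        dirichlet[0, :, :] = cfg.shared.tw
        parent[0, :, :, 0] = 0
        parent[0, :, :, 1] = np.arange(shape[1])[:, None]
        parent[0, :, :, 2] = np.arange(shape[2])[None, :]

    # clip dependent parents so corner/edge copies resolve in one hop
    for axis, n in ((1, g.ny), (2, g.nz)):
        dep = kind == DEPENDENT
        parent[..., axis][dep & (parent[..., axis] == 0)] = 1
        parent[..., axis][dep & (parent[..., axis] == n)] = n - 1

    row_of = np.full(shape, -1, dtype=np.int64)
    unknowns = np.argwhere(kind == UNKNOWN)
    for r, (i, aj, ak) in enumerate(unknowns):
        row_of[i, aj, ak] = r
    return NodeClassification(kind, dirichlet, parent, row_of, unknowns)


@dataclass
class LinearSystem:
    """Sparse steady system ``M T = N`` over the unknown nodes."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    classification: NodeClassification
    cfg: ScenarioConfig
    node_k: np.ndarray = field(default=None)    # conductivity per unknown row
    node_rho_c: np.ndarray = field(default=None)  # rho*c per unknown row

    @property
    def n(self) -> int:
        return len(self.rhs)


def _resolve(cls: NodeClassification, i: int, aj: int, ak: int):
    """Follow a dependent node to its parent; returns (kind, i, aj, ak)."""
    k = cls.kind[i, aj, ak]
    if k == DEPENDENT:
        i, aj, ak = cls.parent[i, aj, ak]
        k = cls.kind[i, aj, ak]
    return k, i, aj, ak


def assemble_steady(cfg: ScenarioConfig) -> LinearSystem:
    """Assemble the 7-point-stencil steady system for ``cfg``.

    Per-node coefficients use the layer of the node's depth (ties to the
    deeper layer); no conductivity averaging is applied across interfaces.
    """
    g = cfg.grid
    sh = cfg.shared
    cls = classify_nodes(cfg)
    h = g.h
    n = cls.n_unknowns
    if n == 0:
        raise ConfigurationError("no unknown nodes to solve for")

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(n)
    node_k = np.zeros(n)
    node_rho_c = np.zeros(n)

    w = sh.mb * sh.cb  # perfusion conductance, W m^-3 K^-1

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for r, (i, aj, ak) in enumerate(cls.unknowns):
        props = cfg.properties_at_node(i)
        node_k[r] = props.k
        node_rho_c[r] = props.rho * props.c
        a = h * h * w / props.k
        rhs[r] = -(h * h / props.k) * (w * sh.ta + props.qm + sh.qe)

        if i == 0 and cfg.boundaries.surface == "robin" and cfg.boundaries.robin_order == 1:
            # one-sided first-order Robin row replaces the stencil
            gamma = h * sh.he / props.k
            rhs[r] = -gamma * sh.tw
            add(r, r, -(1.0 + gamma))
            kk, pi, paj, pak = _resolve(cls, 1, aj, ak)
            if kk == DIRICHLET:
                rhs[r] -= cls.dirichlet[pi, paj, pak]
            else:
                add(r, cls.row_of[pi, paj, pak], 1.0)
            continue

        add(r, r, -(6.0 + a))

        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ii, jj, kk_ = i + di, aj + dj, ak + dk
            if ii < 0:
                # Robin ghost at the surface:
                #   k (T_1 - T_ghost) / (2h) = h_e (T_0 - T_w)
                # => T_ghost = T_1 - beta (T_0 - T_w),  beta = 2 h h_e / k
                beta = 2.0 * h * sh.he / props.k
                kk, pi, paj, pak = _resolve(cls, 1, aj, ak)
                if kk == DIRICHLET:
                    rhs[r] -= cls.dirichlet[pi, paj, pak]
                else:
                    add(r, cls.row_of[pi, paj, pak], 1.0)
                add(r, r, -beta)
                rhs[r] -= beta * sh.tw
                continue
            if ii > g.nx:
                # zero-flux deep face in ghost_mirror mode: mirror ghost
                kk, pi, paj, pak = _resolve(cls, g.nx - 1, aj, ak)
                if kk == DIRICHLET:
                    rhs[r] -= cls.dirichlet[pi, paj, pak]
                else:
                    add(r, cls.row_of[pi, paj, pak], 1.0)
                continue
            if jj < 0 or jj > g.ny or kk_ < 0 or kk_ > g.nz:
                # lateral mirror ghost (ghost_mirror mode only)
                mj = min(max(jj, 1), g.ny - 1) if (jj < 0 or jj > g.ny) else jj
                mk = min(max(kk_, 1), g.nz - 1) if (kk_ < 0 or kk_ > g.nz) else kk_
                kk, pi, paj, pak = _resolve(cls, ii, mj, mk)
                if kk == DIRICHLET:
                    rhs[r] -= cls.dirichlet[pi, paj, pak]
                else:
                    add(r, cls.row_of[pi, paj, pak], 1.0)
                continue
            kk, pi, paj, pak = _resolve(cls, ii, jj, kk_)
            if kk == DIRICHLET:
                rhs[r] -= cls.dirichlet[pi, paj, pak]
            else:
                add(r, cls.row_of[pi, paj, pak], 1.0)

    matrix = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))
    return LinearSystem(matrix, rhs, cls, cfg, node_k, node_rho_c)


# --------------------------------------------------------------------------
# temperature field
# --------------------------------------------------------------------------

@dataclass
class TemperatureField:
    """Nodal temperatures (deg C) on a grid at one time (or steady state)."""

    values: np.ndarray          # node_shape
    grid: Grid3D
    time: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.node_shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid "
                f"{self.grid.node_shape}"
            )

    def at(self, i: int, j: int, k: int) -> float:
        return float(self.values[i, self.grid.axis_index(j, "y"), self.grid.axis_index(k, "z")])

    def copy(self) -> "TemperatureField":
        return TemperatureField(self.values.copy(), self.grid, self.time, dict(self.metadata))

    def to_frame(self, cfg: ScenarioConfig | None = None):
        import pandas as pd

        recs = []
        for i, j, k in self.grid.iter_nodes():
            rec = {
                "i": i, "j": j, "k": k,
                "x_mm": i * self.grid.h * 1e3,
                "y_mm": j * self.grid.h * 1e3,
                "z_mm": k * self.grid.h * 1e3,
                "T_C": self.at(i, j, k),
            }
            if cfg is not None:
                rec["layer"] = cfg.layer_at_depth(i * self.grid.h)
            if self.time is not None:
                rec["t_s"] = self.time
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def fill_field(cfg: ScenarioConfig, cls: NodeClassification, solution: np.ndarray,
               time: float | None = None, metadata: dict | None = None) -> TemperatureField:
    """Expand an unknown-vector solution to a full nodal field."""
    values = np.full(cfg.grid.node_shape, np.nan)
    for r, (i, aj, ak) in enumerate(cls.unknowns):
        values[i, aj, ak] = solution[r]
    dirich = cls.kind == DIRICHLET
    values[dirich] = cls.dirichlet[dirich]
    # dependent copies (single hop after clipping)
    dep = np.argwhere(cls.kind == DEPENDENT)
    for i, aj, ak in dep:
        pi, paj, pak = cls.parent[i, aj, ak]
        values[i, aj, ak] = values[pi, paj, pak]
    return TemperatureField(values, cfg.grid, time, metadata or {})


def solve_steady(cfg: ScenarioConfig, method: str = "direct", tol: float = 1e-12) -> TemperatureField:
    """Solve the steady bioheat system and return the full nodal field.

    Post-condition: the relative residual ``||M T - N||_inf / ||N||_inf``
    is at most 1e-10 (checked; violation raises ``SolverError``).
    """
    system = assemble_steady(cfg)
    if method == "direct":
        sol = spla.spsolve(system.matrix.tocsc(), system.rhs)
    elif method == "iterative":
        sol, info = spla.bicgstab(system.matrix, system.rhs, rtol=tol, maxiter=10000)
        if info != 0:
            raise SolverError(f"iterative solve failed to converge (info={info})")
    else:
        raise ConfigurationError(f"unknown solve method {method!r}")

    resid = np.abs(system.matrix @ sol - system.rhs).max()
    scale = max(np.abs(system.rhs).max(), 1.0)
    if not np.isfinite(sol).all() or resid > 1e-10 * scale:
        raise SolverError(
            f"steady solve residual {resid:.3e} exceeds 1e-10 x ||N||_inf; "
            f"n={system.n}, method={method}"
        )
    meta = {"residual_inf": float(resid), "method": method, "n_unknowns": system.n}
    return fill_field(cfg, system.classification, sol, metadata=meta)


def steady_residual(field_: TemperatureField, cfg: ScenarioConfig) -> float:
    """Maximum absolute stencil residual (deg C) of a field under ``cfg``.

    Evaluates the assembled equations at every unknown node; a field
    produced by :func:`solve_steady` returns essentially round-off.
    """
    if field_.values.shape != cfg.grid.node_shape:
        raise ValueError("field does not match the configuration's grid")
    system = assemble_steady(cfg)
    t_u = np.array([
        field_.values[i, aj, ak] for (i, aj, ak) in system.classification.unknowns
    ])
    return float(np.abs(system.matrix @ t_u - system.rhs).max())
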