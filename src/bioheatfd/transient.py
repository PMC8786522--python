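"""Explicit time marching of the bioheat equation with wet-cloth resets.

The update is the consistent forward-time centred-space (FTCS)
discretization of the transient Pennes equation,

    T^{n+1} = T^n + (dt / rho c) [ k (sum of 6 neighbours - 6 T^n)/h^2
                                   + m_b c_b (T_A - T^n) + Q_m + Q_e ],

with the same ghost-node boundary treatment as the steady solver.  In
operator form the update is ``T += dt * s * (M T - N)`` where ``M T = N``
is the steady system and ``s = k / (rho c h^2)`` per node, which makes the
steady solution an exact fixed point of the march.

The scheme is conditionally stable: every update weight stays
non-negative only for

    dt <= rho c h^2 / (k |M_ii|),

whose interior value is ``rho c h^2 / (6 k + h^2 m_b c_b)`` per layer.
On the default 2 mm grid the binding layer is the skull (about 2.47 s);
a Robin surface tightens its own rows further when ``2 h h_e / k`` is
large.  Steps above the bound are refused outright.  The requested output
cadence (the 2-minute reading interval) is reached by internal
substepping at ``safety_factor`` times the limit.

An unconditionally stable backward-Euler stepper is provided to probe
what large time steps (e.g. a full 2-minute step) would produce.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .geometry import ConfigurationError, ScenarioConfig
from .steady import (
    DIRICHLET,
    LinearSystem,
    TemperatureField,
    assemble_steady,
    fill_field,
)

__all__ = [
    "StabilityError",
    "TransientState",
    "stability_limit",
    "initial_field",
    "ftcs_step",
    "run_transient",
    "cooling_curve",
]


class StabilityError(RuntimeError):
    """Raised when an explicit step exceeds the positivity bound."""


@dataclass
class TransientState:
    """March state: current time, field, and step bookkeeping."""

    time: float
    field: TemperatureField
    steps: int = 0
    dt_last: float = 0.0


def _row_scales(system: LinearSystem) -> np.ndarray:
    h = system.cfg.grid.h
    return system.node_k / (system.node_rho_c * h * h)


def stability_limit(cfg: ScenarioConfig, system: LinearSystem | None = None) -> float:
    """Largest explicit step (s) keeping every update weight non-negative.

    Equals ``min over layers of rho c h^2 / (6 k + h^2 m_b c_b)`` for
    interior rows; Robin surface rows and mirror-coupled edge rows are
    included, so the returned bound is safe for the whole operator.
    """
    if system is None:
        system = assemble_steady(cfg)
    s = _row_scales(system)
    diag = system.matrix.diagonal()
    # diag < 0 by construction; self weight is 1 + dt * s * diag
    return float((-1.0 / (s * diag)).min())


def layer_stability_limits(cfg: ScenarioConfig) -> dict[str, float]:
    """Per-layer interior bound rho c h^2 / (6 k + h^2 m_b c_b)."""
    h = cfg.grid.h
    w = cfg.shared.mb * cfg.shared.cb
    out = {}
    for name in cfg.layers.names:
        m = cfg.materials[name]
        out[name] = m.rho * m.c * h * h / (6.0 * m.k + h * h * w)
    return out


def update_weights(cfg: ScenarioConfig, dt: float, system: LinearSystem | None = None):
    """Explicit-update weight matrix ``I + dt S M`` (rows over unknowns).

    All entries are non-negative iff ``dt`` is at or below the stability
    limit; exposed so the positivity property can be audited directly.
    """
    import scipy.sparse as sp

    if system is None:
        system = assemble_steady(cfg)
    s = _row_scales(system)
    n = system.n
    return sp.eye(n, format="csr") + sp.diags(dt * s) @ system.matrix


# --------------------------------------------------------------------------
# initial condition
# --------------------------------------------------------------------------

def initial_field(cfg: ScenarioConfig) -> TemperatureField:
    """Initial condition: cloth temperature on the surface plane, arterial
    temperature on the deep plane, and the configured interior profile
    (default: linear interpolation in depth between the two)."""
    g = cfg.grid
    sh = cfg.shared
    values = np.empty(g.node_shape)
    if cfg.initial_condition == "linear_depth":
        prof = sh.tw + (sh.ta - sh.tw) * np.arange(g.nx + 1) / g.nx
    elif cfg.initial_condition == "uniform_arterial":
        prof = np.full(g.nx + 1, sh.ta)
    else:  # uniform_body
        prof = np.full(g.nx + 1, 37.0)
    values[:] = prof[:, None, None]
    values[0, :, :] = sh.tw
    values[g.nx, :, :] = sh.ta if cfg.boundaries.deep == "dirichlet" else values[g.nx - 1, :, :]
    return TemperatureField(values, g, time=0.0)


# --------------------------------------------------------------------------
# stepping
# --------------------------------------------------------------------------

class _Stepper:
    """Caches the assembled operator and maps fields <-> unknown vectors."""

    def __init__(self, cfg: ScenarioConfig):
        self.cfg = cfg
        self.system = assemble_steady(cfg)
        self.cls = self.system.classification
        self.s = _row_scales(self.system)
        self.dt_max = stability_limit(cfg, self.system)
        self._be_solves: dict[float, object] = {}

    def extract(self, field: TemperatureField) -> np.ndarray:
        v = field.values
        return np.array([v[i, aj, ak] for (i, aj, ak) in self.cls.unknowns])

    def expand(self, t_u: np.ndarray, time: float) -> TemperatureField:
        return fill_field(self.cfg, self.cls, t_u, time=time)

    def explicit(self, t_u: np.ndarray, dt: float) -> np.ndarray:
        if dt > self.dt_max * (1.0 + 1e-12):
            raise StabilityError(
                f"dt = {dt:.6g} s exceeds the explicit stability limit "
                f"{self.dt_max:.6g} s for this configuration"
            )
        return t_u + dt * self.s * (self.system.matrix @ t_u - self.system.rhs)

    def backward_euler(self, t_u: np.ndarray, dt: float) -> np.ndarray:
        import scipy.sparse as sp

        key = round(dt, 12)
        if key not in self._be_solves:
            n = self.system.n
            mat = sp.eye(n, format="csc") - sp.diags(dt * self.s) @ self.system.matrix
            self._be_solves[key] = spla.factorized(mat.tocsc())
        return self._be_solves[key](t_u - dt * self.s * self.system.rhs)

    def apply_reset(self, t_u: np.ndarray) -> np.ndarray:
        """Clamp the surface-plane unknowns back to the cloth temperature."""
        for r, (i, aj, ak) in enumerate(self.cls.unknowns):
            if i == 0:
                t_u[r] = self.cfg.shared.tw
        return t_u


def ftcs_step(state: TransientState, dt: float, cfg: ScenarioConfig) -> TransientState:
    """One explicit update of all non-Dirichlet nodes.

    Refuses ``dt`` above the stability limit (no silent damping).
    """
    stepper = _Stepper(cfg)
    t_u = stepper.extract(state.field)
    t_u = stepper.explicit(t_u, dt)
    return TransientState(
        time=state.time + dt,
        field=stepper.expand(t_u, state.time + dt),
        steps=state.steps + 1,
        dt_last=dt,
    )


def run_transient(
    cfg: ScenarioConfig,
    t_end: float | None = None,
    output_times: list[float] | None = None,
    method: str = "ftcs",
    dt: float | None = None,
) -> list[TemperatureField]:
    """March the bioheat equation and capture fields at requested times.

    Output captures at a reset tick happen *before* the cloth reset, so a
    2-minute reading reflects the full warming interval since the previous
    reset.  With ``method='ftcs'`` the march substeps internally at
    ``cfg.safety_factor`` times the stability limit (events are hit
    exactly via a shortened final substep).  ``method='backward_euler'``
    steps directly between events with ``dt`` (default: the event gap).
    """
    if cfg.schedule is None:
        raise ConfigurationError("run_transient requires a schedule")
    sched = cfg.schedule
    if t_end is None:
        t_end = sched.end_time_s
    if output_times is None:
        output_times = list(sched.output_times())
        output_times = [t for t in output_times if t <= t_end + 1e-9]
    output_times = sorted(output_times)
    if any(t < 0 or t > t_end + 1e-9 for t in output_times):
        raise ConfigurationError("output times must lie within [0, t_end]")
    if method not in ("ftcs", "backward_euler"):
        raise ConfigurationError(f"unknown transient method {method!r}")

    resets: list[float] = []
    clamping = (
        cfg.boundaries.surface != "dirichlet"
        and sched.reset_action == "clamp_surface_dirichlet"
    )
    if clamping:
        # with a Dirichlet surface the cloth is permanently clamped;
        # resets are a no-op
        n_res = int(np.floor(t_end / sched.reset_interval_s + 1e-9))
        resets = [m * sched.reset_interval_s for m in range(1, n_res + 1)]

    events = sorted(set(round(t, 9) for t in output_times + resets if t > 0))
    out_set = set(round(t, 9) for t in output_times)
    res_set = set(round(t, 9) for t in resets)

    stepper = _Stepper(cfg)
    state_field = initial_field(cfg)
    t_u = stepper.extract(state_field)
    captured: list[TemperatureField] = []
    if round(0.0, 9) in out_set or 0.0 in output_times:
        captured.append(stepper.expand(t_u, 0.0))

    t_now = 0.0
    dt_sub = cfg.safety_factor * stepper.dt_max
    for ev in events:
        span = ev - t_now
        if span > 1e-12:
            if method == "ftcs":
                n_steps = max(1, int(np.ceil(span / dt_sub - 1e-9)))
                step = span / n_steps
                for _ in range(n_steps):
                    t_u = stepper.explicit(t_u, step)
            else:
                step = dt if dt is not None else span
                n_steps = max(1, int(np.ceil(span / step - 1e-9)))
                step = span / n_steps
                for _ in range(n_steps):
                    t_u = stepper.backward_euler(t_u, step)
        t_now = ev
        if round(ev, 9) in out_set:
            captured.append(stepper.expand(t_u, ev))
        if round(ev, 9) in res_set:
            t_u = stepper.apply_reset(t_u)
    return captured


def cooling_curve(fields: list[TemperatureField], node: tuple[int, int, int]):
    """Extract the time series T(node, t) across captured outputs.

    Returns ``(times, temps)`` as float arrays.
    """
    if not fields:
        raise ValueError("no fields given")
    i, j, k = node
    times = np.array([f.time if f.time is not None else np.nan for f in fields])
    temps = np.array([f.at(i, j, k) for f in fields])
    return times, temps
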