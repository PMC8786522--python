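"""Domain geometry, tissue layers, material constants and boundary specification.

The model domain is a small cuboidal patch of the forehead directly under a
cool wet cloth.  The depth axis ``x`` (index ``i``) points inward from the
skin surface (``i = 0``) towards the brain; the lateral axes ``y`` (index
``j``) and ``z`` (index ``k``) are centred on the patch midline, so lateral
indices run over ``-ny/2 .. ny/2``.  Tissue is layered in depth only:
scalp, then skull, then cerebrospinal fluid (CSF).

Temperatures are handled in degrees Celsius throughout.  Every equation in
the model is linear in ``T`` and involves only temperature differences
(surface exchange ``h_e (T - T_w)``, perfusion ``m_b c_b (T_A - T)``), so
the Celsius/Kelvin offset never enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

__all__ = [
    "ConfigurationError",
    "TissueProperties",
    "LayerMaterial",
    "SharedConstants",
    "Grid3D",
    "LayerField",
    "BoundarySpec",
    "Schedule",
    "ScenarioConfig",
    "build_grid",
    "assign_layer",
    "lookup_properties",
]


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent scenario configuration."""


# --------------------------------------------------------------------------
# material constants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProperties:
    """Thermal constants of one tissue at one location.

    Parameters
    ----------
    k : float
        Thermal conductivity, W m^-1 K^-1.
    rho : float
        Density, kg m^-3.
    c : float
        Specific heat capacity, J kg^-1 K^-1.
    qm : float
        Metabolic heat generation, W m^-3.
    """

    k: float
    rho: float
    c: float
    qm: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ConfigurationError(f"thermal conductivity must be > 0, got {self.k}")
        if not self.rho > 0:
            raise ConfigurationError(f"density must be > 0, got {self.rho}")
        if not self.c > 0:
            raise ConfigurationError(f"specific heat must be > 0, got {self.c}")
        if self.qm < 0:
            raise ConfigurationError(f"metabolic heat must be >= 0, got {self.qm}")


@dataclass(frozen=True)
class LayerMaterial:
    """Per-layer material entry, optionally with a depth-split metabolic rate.

    The scalp distinguishes an outer (avascular, ``qm``) and inner
    (vascular, ``qm_inner``) half.  When ``qm_inner`` is set, ``qm``
    applies to relative depths below ``split_fraction`` of the layer
    thickness and ``qm_inner`` from the split on inward (midpoint goes to
    the inner half).
    """

    k: float
    rho: float
    c: float
    qm: float = 0.0
    qm_inner: float | None = None
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        TissueProperties(self.k, self.rho, self.c, self.qm)  # validate
        if self.qm_inner is not None and self.qm_inner < 0:
            raise ConfigurationError("qm_inner must be >= 0")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigurationError("split_fraction must lie in (0, 1)")

    def at_relative_depth(self, frac: float) -> TissueProperties:
        qm = self.qm
        # tolerance keeps the split-depth node itself in the inner half
        if self.qm_inner is not None and frac >= self.split_fraction - 1e-9:
            qm = self.qm_inner
        return TissueProperties(self.k, self.rho, self.c, qm)


@dataclass(frozen=True)
class SharedConstants:
    """Constants shared by all layers.

    Parameters
    ----------
    mb : float
        Blood perfusion rate, kg m^-3 s^-1.
    cb : float
        Specific heat of blood, J kg^-1 K^-1.
    ta : float
        Arterial blood temperature (the fever temperature), deg C.
    qe : float
        External volumetric source, W m^-3.  The wet cloth acts through
        the surface boundary condition, so this defaults to zero.
    he : float
        Surface heat-transfer coefficient, W m^-2 K^-1.
    tw : float
        Wet-cloth temperature, deg C.
    """

    mb: float
    cb: float
    ta: float
    qe: float = 0.0
    he: float = 0.0
    tw: float = 0.0

    def __post_init__(self) -> None:
        if self.mb < 0:
            raise ConfigurationError("perfusion rate mb must be >= 0")
        if not self.cb > 0:
            raise ConfigurationError("blood specific heat cb must be > 0")
        if self.he < 0:
            raise ConfigurationError("heat transfer coefficient he must be >= 0")


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid3D:
    """Uniform cuboidal node lattice.

    ``h`` is the node spacing (m); ``nx, ny, nz`` are subinterval counts,
    so there are ``nx + 1`` node planes in depth.  Depth index ``i`` runs
    ``0 .. nx`` with ``i = 0`` at the skin; lateral indices ``j, k`` run
    ``-ny/2 .. ny/2`` and ``-nz/2 .. nz/2``.
    """

    h: float
    nx: int
    ny: int
    nz: int

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ConfigurationError("grid spacing h must be > 0")
        if self.nx < 2:
            raise ConfigurationError("nx must be >= 2")
        for name, n in (("ny", self.ny), ("nz", self.nz)):
            if n < 2 or n % 2:
                raise ConfigurationError(f"{name} must be even and >= 2, got {n}")

    # -- extents ----------------------------------------------------------
    @property
    def L(self) -> float:
        return self.nx * self.h

    @property
    def H(self) -> float:
        return self.ny * self.h

    @property
    def W(self) -> float:
        return self.nz * self.h

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return (self.nx + 1, self.ny + 1, self.nz + 1)

    @property
    def n_nodes(self) -> int:
        return (self.nx + 1) * (self.ny + 1) * (self.nz + 1)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def n_interior(self) -> int:
        return (self.nx - 1) * (self.ny - 1) * (self.nz - 1)

    # -- index conversions ------------------------------------------------
    def j_range(self) -> range:
        return range(-self.ny // 2, self.ny // 2 + 1)

    def k_range(self) -> range:
        return range(-self.nz // 2, self.nz // 2 + 1)

    def axis_index(self, j: int, axis: str = "y") -> int:
        """Centered lateral index -> 0-based array index."""
        half = self.ny // 2 if axis == "y" else self.nz // 2
        a = j + half
        n = self.ny if axis == "y" else self.nz
        if not 0 <= a <= n:
            raise IndexError(f"lateral index {j} outside grid along {axis}")
        return a

    def coords(self, i: int, j: int, k: int) -> tuple[float, float, float]:
        if not 0 <= i <= self.nx:
            raise IndexError(f"depth index {i} outside grid")
        self.axis_index(j, "y")
        self.axis_index(k, "z")
        return (i * self.h, j * self.h, k * self.h)

    def indices(self, x: float, y: float, z: float) -> tuple[int, int, int]:
        ijk = []
        for v, lo, hi, name in (
            (x / self.h, 0, self.nx, "x"),
            (y / self.h, -self.ny // 2, self.ny // 2, "y"),
            (z / self.h, -self.nz // 2, self.nz // 2, "z"),
        ):
            n = round(v)
            if abs(v - n) > 1e-9 * max(1.0, abs(v)) or not lo <= n <= hi:
                raise IndexError(f"coordinate not on a grid node along {name}")
            ijk.append(int(n))
        return tuple(ijk)  # type: ignore[return-value]

    def iter_nodes(self) -> Iterator[tuple[int, int, int]]:
        for i in range(self.nx + 1):
            for j in self.j_range():
                for k in self.k_range():
                    yield (i, j, k)


def build_grid(L: float, H: float, W: float, h: float) -> Grid3D:
    """Build a uniform lattice over a box of depth ``L``, height ``H``,
    width ``W`` with spacing ``h`` (all in metres).

    Each extent must be an integer multiple of ``h`` (to within 1e-9
    relative tolerance); lateral extents must give an even number of
    subintervals so the patch midline lies on a node plane.
    """
    if not h > 0:
        raise ConfigurationError("grid spacing h must be > 0")
    counts = []
    for name, extent in (("x", L), ("y", H), ("z", W)):
        n = extent / h
        if abs(n - round(n)) > 1e-9 * max(1.0, abs(n)):
            raise ConfigurationError(
                f"extent along {name} ({extent} m) is not an integer multiple "
                f"of the spacing h = {h} m"
            )
        counts.append(int(round(n)))
    return Grid3D(h=h, nx=counts[0], ny=counts[1], nz=counts[2])


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerField:
    """Ordered depth layering: names with thicknesses (m), outermost first.

    Layer membership is a function of depth only, with half-open intervals
    ``[start, start + thickness)`` and ties going to the deeper layer; the
    innermost interval is closed at the deep end.
    """

    names: tuple[str, ...]
    thicknesses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.thicknesses) or not self.names:
            raise ConfigurationError("layer names and thicknesses must align and be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("layer names must be unique")
        for name, t in zip(self.names, self.thicknesses):
            if not t > 0:
                raise ConfigurationError(f"layer {name!r} thickness must be > 0, got {t}")

    @property
    def total(self) -> float:
        return float(sum(self.thicknesses))

    def boundaries(self) -> tuple[float, ...]:
        """Cumulative layer start depths plus the total depth."""
        out = [0.0]
        for t in self.thicknesses:
            out.append(out[-1] + t)
        return tuple(out)

    def assign(self, x: float) -> str:
        return assign_layer(x, self)

    def start_of(self, name: str) -> float:
        b = self.boundaries()
        try:
            idx = self.names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown layer {name!r}") from None
        return b[idx]

    def thickness_of(self, name: str) -> float:
        return self.thicknesses[self.names.index(name)]


def assign_layer(x: float, layers: LayerField) -> str:
    """Map a depth ``x`` (m) to its layer name.

    Half-open convention: a depth exactly on an interface belongs to the
    deeper layer.  The total depth itself belongs to the innermost layer.
    """
    eps = 1e-12 * max(1.0, layers.total)
    if x < -eps or x > layers.total + eps:
        raise ValueError(
            f"depth {x} m outside the layered stack [0, {layers.total}] m"
        )
    b = layers.boundaries()
    for idx, name in enumerate(layers.names):
        if x < b[idx + 1] - eps:
            return name
    return layers.names[-1]


def lookup_properties(
    layer: str, x: float, layers: LayerField, materials: Mapping[str, LayerMaterial]
) -> TissueProperties:
    """Resolve the thermal constants at depth ``x`` within ``layer``.

    For a split layer (scalp), the relative depth within the layer decides
    between the outer and inner metabolic rate.
    """
    if layer not in materials:
        raise ConfigurationError(f"no material entry for layer {layer!r}")
    mat = materials[layer]
    frac = (x - layers.start_of(layer)) / layers.thickness_of(layer)
    return mat.at_relative_depth(frac)


# --------------------------------------------------------------------------
# boundaries, schedule, scenario
# --------------------------------------------------------------------------

SURFACE_MODES = ("robin", "dirichlet")
DEEP_MODES = ("dirichlet", "neumann_zero")
LATERAL_MODES = ("copy_face", "ghost_mirror")
RESET_ACTIONS = ("clamp_surface_dirichlet", "refresh_robin_reference")
INITIAL_CONDITIONS = ("linear_depth", "uniform_arterial", "uniform_body")


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary conditions on the six faces of the box.

    surface : {'robin', 'dirichlet'}
        At the skin (``x = 0``): Robin exchange ``k dT/dx = h_e (T - T_w)``
        with the wet cloth, or a hard clamp ``T = T_w``.
    deep : {'dirichlet', 'neumann_zero'}
        At the deep face (``x = L``): arterial clamp ``T = T_A`` (default)
        or zero flux.
    lateral : {'copy_face', 'ghost_mirror'}
        Zero-flux handling on the four lateral faces.  ``copy_face``
        reproduces the compact system of the reference computation: lateral
        face nodes are dependent copies of the adjacent inner nodes (the
        mirror plane sits half a cell inside the face), so the default grid
        has exactly 27 interior unknowns when the surface is clamped.
        ``ghost_mirror`` keeps face nodes as unknowns and imposes zero flux
        with second-order mirror ghosts on the face itself.
    robin_order : {2, 1}
        Order of the Robin surface discretization: ghost-node central
        difference (2) or one-sided difference (1).
    """

    surface: str = "robin"
    deep: str = "dirichlet"
    lateral: str = "copy_face"
    robin_order: int = 2

    def __post_init__(self) -> None:
        if self.surface not in SURFACE_MODES:
            raise ConfigurationError(f"surface must be one of {SURFACE_MODES}")
        if self.deep not in DEEP_MODES:
            raise ConfigurationError(f"deep must be one of {DEEP_MODES}")
        if self.lateral not in LATERAL_MODES:
            raise ConfigurationError(f"lateral must be one of {LATERAL_MODES}")
        if self.robin_order not in (1, 2):
            raise ConfigurationError("robin_order must be 1 or 2")


@dataclass(frozen=True)
class Schedule:
    """Transient output and cloth-reset schedule (seconds)."""

    output_interval_s: float = 120.0
    end_time_s: float = 360.0
    reset_interval_s: float = 120.0
    reset_action: str = "clamp_surface_dirichlet"

    def __post_init__(self) -> None:
        if not self.output_interval_s > 0:
            raise ConfigurationError("output interval must be > 0")
        if not self.reset_interval_s > 0:
            raise ConfigurationError("reset interval must be > 0")
        if not self.end_time_s > 0:
            raise ConfigurationError("end time must be > 0")
        if self.reset_action not in RESET_ACTIONS:
            raise ConfigurationError(f"reset_action must be one of {RESET_ACTIONS}")

    def output_times(self) -> tuple[float, ...]:
        n = int(round(self.end_time_s / self.output_interval_s))
        times = [m * self.output_interval_s for m in range(1, n + 1)]
        if not times or times[-1] < self.end_time_s - 1e-9:
            times.append(self.end_time_s)
        return tuple(times)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full problem description: grid + layers + materials + boundaries."""

    grid: Grid3D
    layers: LayerField
    materials: Mapping[str, LayerMaterial]
    shared: SharedConstants
    boundaries: BoundarySpec = field(default_factory=BoundarySpec)
    mode: str = "steady"
    schedule: Schedule | None = None
    initial_condition: str = "linear_depth"
    safety_factor: float = 0.9
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.mode not in ("steady", "transient"):
            raise ConfigurationError("mode must be 'steady' or 'transient'")
        if self.initial_condition not in INITIAL_CONDITIONS:
            raise ConfigurationError(
                f"initial_condition must be one of {INITIAL_CONDITIONS}"
            )
        if not 0 < self.safety_factor <= 1:
            raise ConfigurationError("safety_factor must lie in (0, 1]")
        missing = [n for n in self.layers.names if n not in self.materials]
        if missing:
            raise ConfigurationError(f"materials missing for layers: {missing}")
        if self.grid.L > self.layers.total + 1e-12:
            raise ConfigurationError(
                f"grid depth {self.grid.L} m exceeds the layered stack "
                f"({self.layers.total} m); every node needs a layer"
            )
        if self.mode == "transient" and self.schedule is None:
            raise ConfigurationError("transient mode requires a schedule")

    # -- conveniences ------------------------------------------------------
    def layer_at_depth(self, x: float) -> str:
        return assign_layer(x, self.layers)

    def properties_at_depth(self, x: float) -> TissueProperties:
        return lookup_properties(self.layer_at_depth(x), x, self.layers, self.materials)

    def properties_at_node(self, i: int) -> TissueProperties:
        return self.properties_at_depth(i * self.grid.h)

    def with_(self, **changes) -> "ScenarioConfig":
        """Functional update (dataclasses.replace wrapper)."""
        return replace(self, **changes)


def default_layers() -> LayerField:
    """Average forehead layering: scalp 4.5 mm, skull 3.5 mm, CSF 2 mm."""
    return LayerField(names=("scalp", "skull", "csf"), thicknesses=(4.5e-3, 3.5e-3, 2.0e-3))
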