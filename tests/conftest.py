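import numpy as np
import pytest

import bioheatfd as bh
from bioheatfd.geometry import (
    BoundarySpec,
    LayerField,
    LayerMaterial,
    Schedule,
    ScenarioConfig,
    SharedConstants,
)


@pytest.fixture(scope="session")
def case1():
    return bh.load_preset("case1_38C")


@pytest.fixture(scope="session")
def case1_steady(case1):
    return bh.solve_steady(case1)


@pytest.fixture(scope="session")
def case1_transient(case1):
    return bh.run_transient(case1.with_(mode="transient"))


def make_slab_cfg(
    k=0.5,
    rho=1000.0,
    c=3000.0,
    qm=0.0,
    mb=0.0,
    cb=4000.0,
    ta=38.0,
    tw=7.0,
    he=500.0,
    qe=0.0,
    L=8e-3,
    h=2e-3,
    lateral_cells=4,
    surface="robin",
    deep="dirichlet",
    lateral="copy_face",
    robin_order=2,
    mode="steady",
    initial_condition="linear_depth",
):
    """Single-layer scenario used across property tests."""
    grid = bh.build_grid(L, lateral_cells * h, lateral_cells * h, h)
    return ScenarioConfig(
        grid=grid,
        layers=LayerField(("slab",), (L,)),
        materials={"slab": LayerMaterial(k=k, rho=rho, c=c, qm=qm)},
        shared=SharedConstants(mb=mb, cb=cb, ta=ta, qe=qe, he=he, tw=tw),
        boundaries=BoundarySpec(surface=surface, deep=deep, lateral=lateral,
                                robin_order=robin_order),
        mode=mode,
        schedule=Schedule(),
        initial_condition=initial_condition,
    )


@pytest.fixture
def slab_cfg_factory():
    return make_slab_cfg
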