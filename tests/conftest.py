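import numpy as np
import pytest

from actoring.params import Params
from actoring.state import (BoundaryGeometry, CompartmentGrid, Cylinder,
                            Filament, NetworkState, BARBED_FREE)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_boundary():
    return BoundaryGeometry(shape="oblate", diameter=2000.0, height=400.0)


def make_filament(fid, p0, direction, n_monomers, state=None):
    """Straight filament starting at p0 along a unit direction."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    f = Filament(fid=fid, cylinders=[], barbed_state=BARBED_FREE)
    remaining = n_monomers
    p = np.asarray(p0, dtype=float)
    while remaining > 0:
        n = min(40, remaining)
        q = p + 2.7 * n * direction
        f.cylinders.append(Cylinder(p_minus=p.copy(), p_plus=q.copy(),
                                    n_monomers=n, cid=f.new_cid()))
        p = q
        remaining -= n
    f.L, f.R = 0, n_monomers
    if state is not None:
        state.filaments[fid] = f
        state._next_fid = max(state._next_fid, fid + 1)
    return f


@pytest.fixture
def empty_state(small_boundary):
    params = Params()
    params.compartment_edge = 4000.0      # single compartment
    grid = CompartmentGrid(small_boundary, params.compartment_edge)
    return NetworkState(boundary=small_boundary, grid=grid, params=params)
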