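"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from emligfit.densmap import MapSimParams, grid_like, simulate_density
from emligfit.structio import Atom, DensityGrid, Selection, Structure
from emligfit.synthfix import FixtureSpec, make_fixture


def random_structure(n: int, seed: int = 0, lo: float = 5.0,
                     hi: float = 25.0, min_sep: float = 1.2) -> Structure:
    """A random cluster of carbon atoms with a minimum separation."""
    rng = np.random.default_rng(seed)
    coords = []
    while len(coords) < n:
        p = rng.uniform(lo, hi, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
    atoms = [Atom(i + 1, "C", "C", "ALA", i + 1, "A", coords[i])
             for i in range(n)]
    return Structure(atoms)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic complex/map/candidates (seed 0)."""
    return make_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def gt_map_and_params(default_fixture):
    fx = default_fixture
    params = MapSimParams(resolution=fx.provenance.map_resolution,
                          grid_spec=fx.target_map)
    return fx.ground_truth, fx.target_map, params


@pytest.fixture
def small_structure():
    return random_structure(10, seed=3)


@pytest.fixture
def pdb_text_3atoms():
    return (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00"
        "           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00"
        "           C\n"
        "ATOM      3  O   ALA A   1      12.669   5.512  -4.852  1.00 10.00"
        "           O\n"
        "END\n"
    )
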