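"""Shared fixtures: programmatically built structures and toy systems."""

from __future__ import annotations

import numpy as np
import pytest

from cleftdyn import GatingSpec, ToyLayout, build_toy_system
from cleftdyn.structio import Atom, Structure, mass_of


def make_structure(records, title="test"):
    """Build a Structure from (name, element, resname, resid, chain, xyz)."""
    atoms = []
    for i, (name, el, resname, resid, chain, xyz) in enumerate(records, start=1):
        atoms.append(
            Atom(i, name, el, mass_of(el), resname, resid, chain, np.asarray(xyz, float))
        )
    return Structure.from_atoms(atoms, title=title)


@pytest.fixture(scope="session")
def toy_system():
    """A short hinged-rod trajectory with a scheduled cofactor release."""
    spec = GatingSpec(duration_ns=3.0, seed=11)
    return build_toy_system(spec, ToyLayout(release_time_ns=1.0))


@pytest.fixture(scope="session")
def toy_structure(toy_system):
    return toy_system.structure


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
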