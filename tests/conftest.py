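import numpy as np
import pytest

from halomode.structio import Atom, Topology, Trajectory


def make_topology(rows, donors=None, acceptors=None):
    """Build a Topology from (name, element, res_name, res_id, chain) rows."""
    atoms = [Atom(i, *row) for i, row in enumerate(rows)]
    kwargs = {}
    if donors is not None:
        kwargs["donor_names"] = frozenset(donors)
    if acceptors is not None:
        kwargs["acceptor_names"] = frozenset(acceptors)
    return Topology(atoms=atoms, **kwargs)


def make_trajectory(frames):
    return Trajectory(coords=np.asarray(frames, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def arg_pair_topology():
    """Two arginine-like residues plus a phosphate-bearing substrate."""
    rows = [
        ("NH1", "N", "ARG", 178, "A"),
        ("NH2", "N", "ARG", 178, "A"),
        ("NE", "N", "ARG", 178, "A"),
        ("NH1", "N", "ARG", 238, "A"),
        ("NH2", "N", "ARG", 238, "A"),
        ("NE", "N", "ARG", 238, "A"),
        ("O1P", "O", "NUC", 401, "A"),
        ("O2P", "O", "NUC", 401, "A"),
        ("O1", "O", "FEO", 301, "A"),
        ("H2'", "H", "NUC", 401, "A"),
        ("C2'", "C", "NUC", 401, "A"),
        ("CL", "CL", "FEO", 301, "A"),
    ]
    return make_topology(rows)
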