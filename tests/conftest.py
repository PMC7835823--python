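import numpy as np
import pytest

from redoxtraj.core import Topology, Trajectory


def build_structure(residues):
    """Assemble a (Topology, frame) pair from a residue description list.

    ``residues`` is a list of (res_name, res_number, chain_id, atoms) with
    atoms a list of (atom_name, element, xyz).
    """
    names, elements, res_idx, coords = [], [], [], []
    res_names, res_numbers, chain_ids = [], [], []
    for r, (rn, num, chain, atoms) in enumerate(residues):
        res_names.append(rn)
        res_numbers.append(num)
        chain_ids.append(chain)
        for nm, el, xyz in atoms:
            names.append(nm)
            elements.append(el)
            res_idx.append(r)
            coords.append(np.asarray(xyz, dtype=float))
    topo = Topology(
        atom_names=np.array(names),
        elements=np.array(elements),
        atom_residue=np.array(res_idx),
        res_names=np.array(res_names),
        res_numbers=np.array(res_numbers),
        chain_ids=np.array(chain_ids),
    )
    return topo, np.stack(coords)


def as_trajectory(topo, frames):
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return Trajectory(frames, np.arange(len(frames), dtype=float), topo)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_state():
    """Two-state switching fixture: occupancies 0.7/0.3, 8 A apart, 0.3 A jitter."""
    from redoxtraj.synthetic import (
        MultiStateSpec,
        displaced_states,
        make_multistate_trajectory,
    )

    ref = np.random.default_rng(7).normal(scale=6.0, size=(20, 3))
    states = displaced_states(ref, 2, 8.0, seed=11)
    spec = MultiStateSpec(
        states=states,
        n_frames=2000,
        seed=13,
        occupancies=np.array([0.7, 0.3]),
        jitter_sd=0.3,
    )
    traj, labels = make_multistate_trajectory(spec)
    return spec, traj, labels


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
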