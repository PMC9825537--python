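import numpy as np
import pytest

from quatclust.fixtures import make_template_chain
from quatclust.structure_io import Chain


@pytest.fixture(scope="session")
def template():
    return make_template_chain(30, seed=1)


@pytest.fixture(scope="session")
def toy_corpus(tmp_path_factory):
    """One shared toy corpus on disk (generated once per session)."""
    from quatclust.fixtures import make_toy_corpus

    out = tmp_path_factory.mktemp("corpus")
    structures, specs, tables = make_toy_corpus(out, seed=0)
    return out, structures, specs, tables


def chain_from_points(
    chain_id: str,
    rep_points,
    extra_atoms=None,
    sequence: str | None = None,
) -> Chain:
    """Minimal chain whose representative points are given explicitly.

    ``extra_atoms`` maps residue seq_pos -> list of extra atom coordinates
    (used to create atomic contacts independent of the representative
    points).
    """
    rep = np.asarray(rep_points, dtype=float)
    n = len(rep)
    seq = sequence or "A" * n
    atom_coords, atom_res, atom_names = [], [], []
    for i in range(n):
        atom_coords.append(rep[i])
        atom_res.append(i)
        atom_names.append("CA")
        for xyz in (extra_atoms or {}).get(i + 1, []):
            atom_coords.append(np.asarray(xyz, dtype=float))
            atom_res.append(i)
            atom_names.append("CG")
    return Chain(
        chain_id=chain_id,
        sequence=seq,
        seq_pos=np.arange(1, n + 1),
        rep=rep,
        atom_coords=np.array(atom_coords),
        atom_res=np.array(atom_res),
        atom_names=atom_names,
    )


def random_rigid_motion(rng):
    """A uniformly random rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot.as_matrix(), trans


def transform_assembly(assembly, rot, trans):
    """Apply one rigid-body motion to every chain of an assembly."""
    import dataclasses

    from quatclust.interfaces import find_interfaces

    chains = [c.transformed(rot, trans, c.chain_id) for c in assembly.chains]
    moved = dataclasses.replace(assembly, chains=chains, interfaces=[])
    moved.interfaces = find_interfaces(moved)
    if hasattr(moved, "_ifc_cache"):
        del moved._ifc_cache
    return moved
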