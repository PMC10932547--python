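import numpy as np
import pandas as pd
import pytest

from unbind.contacts import TrajectoryEnsemble


def build_ensemble(lig_xyz, prot_atoms, frame_interval_ns=1.0):
    """One-frame, one-trajectory ensemble from explicit coordinates.

    ``lig_xyz``: (n,3) ligand heavy-atom coordinates.
    ``prot_atoms``: list of (resid, resname, element, xyz).
    """
    rows, coords = [], []
    for i, xyz in enumerate(lig_xyz):
        rows.append((f"L{i}", "C", 1, "LIG", "LIG", True))
        coords.append(xyz)
    for resid, resname, element, xyz in prot_atoms:
        rows.append((f"A{len(coords)}", element, resid, resname, "PROT", False))
        coords.append(xyz)
    atoms = pd.DataFrame(
        rows, columns=["name", "element", "resid", "resname", "segid",
                       "is_ligand"])
    frames = np.asarray(coords, dtype=float)[None, :, :]
    return TrajectoryEnsemble(atoms, [frames], frame_interval_ns)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_ensemble(rng):
    """30 heavy atoms (5 ligand + 25 protein over 5 residues), 4 frames."""
    n_lig, n_prot, n_frames = 5, 25, 4
    rows = []
    for i in range(n_lig):
        rows.append((f"L{i}", "C", 1, "LIG", "LIG", True))
    for i in range(n_prot):
        rows.append((f"P{i}", "C", 10 + i // 5, "ALA", "PROT", False))
    atoms = pd.DataFrame(
        rows, columns=["name", "element", "resid", "resname", "segid",
                       "is_ligand"])
    frames = 8.0 * rng.random((n_frames, n_lig + n_prot, 3))
    return TrajectoryEnsemble(atoms, [frames], 0.5)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
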