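"""Shared fixtures: small programmatically built structures and series."""

import numpy as np
import pytest
import biotite.structure as struc

from spectrobind.poses import Pose
from spectrobind.simulate import _build_ligand, _build_receptor


def make_atoms(records, chain_id="A"):
    """Build an AtomArray from (res_id, res_name, atom_name, element, xyz) tuples."""
    atoms = [
        struc.Atom(
            np.asarray(xyz, dtype=float),
            chain_id=chain_id,
            res_id=res_id,
            res_name=res_name,
            atom_name=atom_name,
            element=element,
            hetero=False,
        )
        for res_id, res_name, atom_name, element, xyz in records
    ]
    return struc.array(atoms)


def make_pose(dda_nm=4.2, direction=(0.0, 0.0, 1.0), rank=1, with_phosphate=True,
              donor_residue=214):
    """A toy pose whose 5'-P sits exactly ``dda_nm`` from the Trp ring centroid."""
    from spectrobind.poses import trp_ring_center

    receptor = _build_receptor(donor_residue)
    ref = Pose(receptor=receptor, ligand=_build_ligand(np.zeros(3), [1, 0, 0]), rank=0)
    center = trp_ring_center(ref, donor_residue) * 10.0  # Angstrom
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    p1 = center + dda_nm * 10.0 * u
    ligand = _build_ligand(p1, u, with_phosphate=with_phosphate)
    return Pose(receptor=receptor.copy(), ligand=ligand, rank=rank,
                model_id=f"model_{rank}")


@pytest.fixture
def toy_pose():
    return make_pose()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
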