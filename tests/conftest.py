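import numpy as np
import pytest

from nbens.structure_io import Atom, Ensemble, StructureModel

# idealized backbone internal coordinates
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.0
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom D from A-B-C internal coordinates."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_peptide(phis, psis, omegas=None, residue_names=None) -> StructureModel:
    """Build an N/CA/C backbone with prescribed torsions (ideal geometry).

    ``phis[0]`` and ``psis[-1]`` are ignored (undefined at the termini).
    """
    n_res = len(phis)
    assert len(psis) == n_res
    if omegas is None:
        omegas = [180.0] * n_res
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([_BOND_N_CA, 0.0, 0.0]),
    ]
    coords.append(place_atom(
        np.array([-1.0, 1.0, 0.0]), coords[0], coords[1],
        _BOND_CA_C, _ANG_N_CA_C, 120.0))
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_new = place_atom(n_prev, ca_prev, c_prev,
                           _BOND_C_N, _ANG_CA_C_N, psis[i - 1])
        ca_new = place_atom(ca_prev, c_prev, n_new,
                            _BOND_N_CA, _ANG_C_N_CA, omegas[i - 1])
        c_new = place_atom(c_prev, n_new, ca_new,
                           _BOND_CA_C, _ANG_N_CA_C, phis[i])
        coords.extend([n_new, ca_new, c_new])
    atoms = []
    for i in range(n_res):
        for j, name in enumerate(("N", "CA", "C")):
            atoms.append(Atom(
                name=name, element=name[0], residue_index=i + 1,
                residue_name=residue_names[i], coordinates=coords[3 * i + j],
            ))
    return StructureModel(atoms=atoms, model_id=1)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=np.random.RandomState(rng.integers(2**31)))


def rigid_move(model: StructureModel, rng) -> StructureModel:
    rot = random_rotation(rng)
    shift = rng.normal(0, 10, 3)
    return model.with_coordinates(rot.apply(model.coordinates) + shift)


@pytest.fixture
def extended_tetrapeptide():
    return make_peptide(phis=[180.0] * 4, psis=[180.0] * 4)


@pytest.fixture
def five_residue_peptide():
    rng = np.random.default_rng(7)
    phis = rng.uniform(-170, 170, 5)
    psis = rng.uniform(-170, 170, 5)
    return make_peptide(phis=list(phis), psis=list(psis)), phis, psis


@pytest.fixture
def small_ensemble():
    """4-model ensemble: same peptide with tiny coordinate perturbations."""
    rng = np.random.default_rng(11)
    base = make_peptide(phis=[-60.0] * 5, psis=[-45.0] * 5)
    models = []
    for m in range(4):
        coords = base.coordinates + rng.normal(0, 0.05, (base.n_atoms, 3))
        model = base.with_coordinates(coords)
        model.model_id = m + 1
        models.append(model)
    return Ensemble(models=models, source_label="synthetic")
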