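"""Structure, ensemble, trajectory and restraint I/O plus geometric primitives.

This module provides the domain types used everywhere else (atoms, models,
ensembles, trajectories, distance restraints), readers/writers for
multi-model PDB files, CYANA-style ``.upl`` upper-limit restraint lists and
a minimal plain-text per-frame coordinate table, and the geometric
primitives (Kabsch superposition, backbone phi/psi torsions) that the
analysis modules build on.

Conventions
-----------
* Residue numbering is 1-based and taken verbatim from the PDB records.
* Torsion angles follow the IUPAC sign convention and are reported in
  degrees in the half-open interval (-180, 180].
* Undefined torsions (chain termini, missing backbone atoms) are carried
  as ``None`` / ``NaN`` markers, never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "Trajectory",
    "AtomSelector",
    "DistanceRestraint",
    "FormatError",
    "GeometryError",
    "RestraintParseError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "parse_upl",
    "write_upl",
    "read_coord_table",
    "write_coord_table",
    "superpose",
    "kabsch_rmsd",
    "backbone_torsions",
    "backbone_torsion_trajectory",
    "dihedral",
    "PSEUDOATOMS",
]


class FormatError(ValueError):
    """Structural file does not conform to the expected dialect."""


class GeometryError(ValueError):
    """A geometric operation received degenerate input."""


class RestraintParseError(ValueError):
    """A restraint file line could not be interpreted."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB-convention name, element, residue and position (Å)."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    coordinates: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.name}: residue_index must be >= 1")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class StructureModel:
    """One structural model: an ordered list of atoms with a model id."""

    atoms: list[Atom]
    model_id: int = 1

    def __post_init__(self):
        keys = [(a.residue_index, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate (residue_index, atom_name) pair {dup}")
        self._index = {k: i for i, k in enumerate(keys)}

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coordinates for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def atom_index(self, residue_index: int, atom_name: str) -> int | None:
        """Position of (residue_index, atom_name) in the atom order, or None."""
        return self._index.get((residue_index, atom_name))

    def residue_name(self, residue_index: int) -> str | None:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        return None

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (same atom order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, coordinates=c) for a, c in zip(self.atoms, coords)]
        return StructureModel(atoms=atoms, model_id=self.model_id)


@dataclass
class Ensemble:
    """A set of models sharing one atom order (an NMR-style ensemble)."""

    models: list[StructureModel]
    source_label: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = [(a.residue_index, a.name) for a in self.models[0].atoms]
        for m in self.models[1:]:
            keys = [(a.residue_index, a.name) for a in m.atoms]
            if keys != ref:
                raise FormatError(
                    f"model {m.model_id} atom ordering differs from model "
                    f"{self.models[0].model_id}"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_models, n_atoms, 3) array."""
        return np.array([m.coordinates for m in self.models])


@dataclass
class Trajectory:
    """Ordered frames with a fixed time step.

    ``kind`` selects the payload layout:

    * ``"cartesian"`` — frames of shape (n_frames, n_atoms, 3), Å, with a
      reference topology;
    * ``"torsion"`` — frames of shape (n_frames, n_torsions), degrees
      (NaN marks undefined torsions), with ``labels`` naming each column;
    * ``"vector"`` — unit vectors, (n_frames, 3) or (n_frames, n_vectors, 3);
    * ``"scalar"`` — one value per frame (1-D systems).
    """

    frames: np.ndarray
    dt: float = 1.0
    topology: StructureModel | None = None
    kind: str = "cartesian"
    labels: list | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind == "cartesian":
            if self.frames.ndim != 3 or self.frames.shape[-1] != 3:
                raise ValueError("cartesian frames must have shape (F, N, 3)")
            if self.topology is not None and self.frames.shape[1] != self.topology.n_atoms:
                raise ValueError(
                    f"frame atom count {self.frames.shape[1]} does not match "
                    f"topology atom count {self.topology.n_atoms}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class AtomSelector:
    """Identifies one atom by residue index, residue name and atom name."""

    residue_index: int
    residue_name: str
    atom_name: str


@dataclass
class DistanceRestraint:
    """An upper-limit distance restraint between two (pseudo)atom groups.

    ``label_a``/``label_b`` keep the original atom token from the restraint
    file (a pseudoatom code like ``QD1`` for expanded groups) so that
    writing a parsed list back reproduces the input.
    """

    group_a: tuple[AtomSelector, ...]
    group_b: tuple[AtomSelector, ...]
    upper_limit: float
    kind: str = "noe"
    label_a: str | None = None
    label_b: str | None = None

    def __post_init__(self):
        self.group_a = tuple(self.group_a)
        self.group_b = tuple(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("restraint groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("restraint groups must be disjoint")
        if not self.upper_limit > 0:
            raise ValueError("upper_limit must be positive")
        if self.kind not in ("noe", "hbond"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.label_a is None:
            self.label_a = self.group_a[0].atom_name
        if self.label_b is None:
            self.label_b = self.group_b[0].atom_name


# ---------------------------------------------------------------------------
# Pseudoatom expansion (CYANA Q-codes)
# ---------------------------------------------------------------------------

_METHYLENE_QB = ("HB2", "HB3")
#: (residue_name, pseudoatom_code) -> tuple of proton names.
PSEUDOATOMS: dict[tuple[str, str], tuple[str, ...]] = {
    ("GLY", "QA"): ("HA2", "HA3"),
    ("ALA", "QB"): ("HB1", "HB2", "HB3"),
    ("VAL", "QG1"): ("HG11", "HG12", "HG13"),
    ("VAL", "QG2"): ("HG21", "HG22", "HG23"),
    ("VAL", "QQG"): ("HG11", "HG12", "HG13", "HG21", "HG22", "HG23"),
    ("THR", "QG2"): ("HG21", "HG22", "HG23"),
    ("ILE", "QG1"): ("HG12", "HG13"),
    ("ILE", "QG2"): ("HG21", "HG22", "HG23"),
    ("ILE", "QD1"): ("HD11", "HD12", "HD13"),
    ("LEU", "QD1"): ("HD11", "HD12", "HD13"),
    ("LEU", "QD2"): ("HD21", "HD22", "HD23"),
    ("LEU", "QQD"): ("HD11", "HD12", "HD13", "HD21", "HD22", "HD23"),
    ("MET", "QG"): ("HG2", "HG3"),
    ("MET", "QE"): ("HE1", "HE2", "HE3"),
    ("GLU", "QG"): ("HG2", "HG3"),
    ("GLN", "QG"): ("HG2", "HG3"),
    ("GLN", "QE2"): ("HE21", "HE22"),
    ("ASN", "QD2"): ("HD21", "HD22"),
    ("ARG", "QG"): ("HG2", "HG3"),
    ("ARG", "QD"): ("HD2", "HD3"),
    ("ARG", "QH1"): ("HH11", "HH12"),
    ("ARG", "QH2"): ("HH21", "HH22"),
    ("LYS", "QG"): ("HG2", "HG3"),
    ("LYS", "QD"): ("HD2", "HD3"),
    ("LYS", "QE"): ("HE2", "HE3"),
    ("LYS", "QZ"): ("HZ1", "HZ2", "HZ3"),
    ("PRO", "QG"): ("HG2", "HG3"),
    ("PRO", "QD"): ("HD2", "HD3"),
    ("PHE", "QD"): ("HD1", "HD2"),
    ("PHE", "QE"): ("HE1", "HE2"),
    ("PHE", "QR"): ("HD1", "HD2", "HE1", "HE2", "HZ"),
    ("TYR", "QD"): ("HD1", "HD2"),
    ("TYR", "QE"): ("HE1", "HE2"),
    ("TYR", "QR"): ("HD1", "HD2", "HE1", "HE2"),
}
for _res in ("ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "HIS", "LEU",
             "LYS", "MET", "PHE", "PRO", "SER", "TRP", "TYR"):
    PSEUDOATOMS[(_res, "QB")] = _METHYLENE_QB


def expand_pseudoatom(residue_index: int, residue_name: str,
                      atom_name: str) -> tuple[AtomSelector, ...]:
    """Expand a pseudoatom code into its proton group; plain atoms pass through."""
    if atom_name.startswith("Q"):
        key = (residue_name.upper(), atom_name.upper())
        if key not in PSEUDOATOMS:
            raise RestraintParseError(
                f"unknown pseudoatom code {atom_name!r} for residue {residue_name}"
            )
        return tuple(
            AtomSelector(residue_index, residue_name, h) for h in PSEUDOATOMS[key]
        )
    return (AtomSelector(residue_index, residue_name, atom_name),)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _stack_to_ensemble(stack: struc.AtomArrayStack, label: str) -> Ensemble:
    models = []
    names = stack.atom_name
    res_ids = stack.res_id
    res_names = stack.res_name
    elements = stack.element
    for i in range(stack.stack_depth()):
        coords = stack.coord[i]
        atoms = [
            Atom(
                name=str(names[j]),
                element=str(elements[j]) or str(names[j])[0],
                residue_index=int(res_ids[j]),
                residue_name=str(res_names[j]),
                coordinates=coords[j],
            )
            for j in range(stack.array_length())
        ]
        models.append(StructureModel(atoms=atoms, model_id=i + 1))
    return Ensemble(models=models, source_label=label)


def _diagnose_pdb(path: Path) -> None:
    """Scan a PDB file for the problems biotite reports only generically."""
    counts: dict[int, int] = {}
    model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                model = int(line.split()[1])
                counts.setdefault(model, 0)
            elif rec in ("ATOM", "HETATM"):
                counts[model] = counts.get(model, 0) + 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise FormatError(
                        f"{path}: unreadable coordinates at line {lineno}"
                    ) from None
    if len(set(counts.values())) > 1:
        ref = counts[min(counts)]
        for mid, n in counts.items():
            if n != ref:
                raise FormatError(
                    f"{path}: model {mid} has {n} atoms, expected {ref}"
                )


def read_multimodel_pdb(path, keep_hetero: bool = True,
                        keep_hydrogens: bool = True) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    A file without ``MODEL`` records yields a one-model ensemble.  Alternate
    locations other than blank/first are dropped (count reported via a
    warning).  Waters are always discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_altloc_dropped = 0
    with open(path) as fh:
        for line in fh:
            if line[:6].strip() in ("ATOM", "HETATM") and len(line) > 16:
                if line[16] not in (" ", "A"):
                    n_altloc_dropped += 1
    if n_altloc_dropped:
        warnings.warn(
            f"{path.name}: dropped {n_altloc_dropped} alternate-location atoms"
        )
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdbio.get_structure(pdb_file, altloc="first")
    except Exception as exc:
        _diagnose_pdb(path)
        raise FormatError(f"{path}: {exc}") from exc
    mask = stack.res_name != "HOH"
    if not keep_hetero:
        mask &= ~stack.hetero
    if not keep_hydrogens:
        mask &= ~np.isin(stack.element, ("H", "D"))
    stack = stack[..., mask]
    return _stack_to_ensemble(stack, label=path.stem)


def write_multimodel_pdb(path, ensemble: Ensemble) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB file."""
    n = ensemble.models[0].n_atoms
    template = struc.AtomArray(n)
    m0 = ensemble.models[0]
    template.atom_name = np.array([a.name for a in m0.atoms])
    template.res_id = np.array([a.residue_index for a in m0.atoms])
    template.res_name = np.array([a.residue_name for a in m0.atoms])
    template.element = np.array([a.element for a in m0.atoms])
    template.chain_id = np.full(n, "A")
    template.hetero = np.full(n, False)
    arrays = []
    for m in ensemble.models:
        arr = template.copy()
        arr.coord = m.coordinates
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# CYANA .upl restraint lists
# ---------------------------------------------------------------------------


def _is_proton_group(group: tuple[AtomSelector, ...]) -> bool:
    return all(sel.atom_name.startswith("H") for sel in group)


def parse_upl(path) -> list[DistanceRestraint]:
    """Parse a CYANA-dialect ``.upl`` upper-limit restraint file.

    Expected columns per non-comment line::

        residue_index residue_name atom_name residue_index residue_name atom_name limit

    Pseudoatom codes beginning with ``Q`` expand to their proton groups via
    :data:`PSEUDOATOMS`.  A restraint whose two groups are both protons is
    tagged ``noe``; anything touching a non-proton (e.g. backbone O in
    hydrogen-bond restraints) is tagged ``hbond``.
    """
    path = Path(path)
    restraints: list[DistanceRestraint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 7:
                raise RestraintParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                ia, ib = int(parts[0]), int(parts[3])
                limit = float(parts[6])
            except ValueError as exc:
                raise RestraintParseError(f"{path.name}:{lineno}: {exc}") from None
            if not limit > 0:
                raise RestraintParseError(
                    f"{path.name}:{lineno}: non-positive upper limit {limit}"
                )
            na, nb = parts[2], parts[5]
            group_a = expand_pseudoatom(ia, parts[1], na)
            group_b = expand_pseudoatom(ib, parts[4], nb)
            kind = "noe" if (_is_proton_group(group_a) and _is_proton_group(group_b)) \
                else "hbond"
            restraints.append(
                DistanceRestraint(
                    group_a=group_a, group_b=group_b, upper_limit=limit,
                    kind=kind, label_a=na, label_b=nb,
                )
            )
    return restraints


def write_upl(path, restraints: Iterable[DistanceRestraint]) -> None:
    """Write restraints in the CYANA ``.upl`` column layout."""
    with open(path, "w") as fh:
        for r in restraints:
            a, b = r.group_a[0], r.group_b[0]
            fh.write(
                f"{a.residue_index:4d} {a.residue_name:<4s} {r.label_a:<5s} "
                f"{b.residue_index:4d} {b.residue_name:<4s} {r.label_b:<5s} "
                f"{r.upper_limit:8.2f}\n"
            )


# ---------------------------------------------------------------------------
# Plain-text coordinate-table trajectories
# ---------------------------------------------------------------------------


def write_coord_table(path, traj: Trajectory) -> None:
    """Write a cartesian trajectory as ``frame atom x y z`` rows."""
    if traj.kind != "cartesian":
        raise ValueError("coordinate tables hold cartesian trajectories only")
    with open(path, "w") as fh:
        fh.write(f"# dt_ps {traj.dt}\n")
        fh.write("# frame atom x y z\n")
        for f in range(traj.n_frames):
            for a in range(traj.frames.shape[1]):
                x, y, z = traj.frames[f, a]
                fh.write(f"{f} {a} {x:.6f} {y:.6f} {z:.6f}\n")


def read_coord_table(path, topology: StructureModel | None = None) -> Trajectory:
    """Read the ``frame atom x y z`` table written by :func:`write_coord_table`."""
    dt = 1.0
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["dt_ps"]:
                    dt = float(parts[1])
                continue
            parts = line.split()
            if parts:
                rows.append([float(v) for v in parts])
    data = np.array(rows)
    n_frames = int(data[:, 0].max()) + 1
    n_atoms = int(data[:, 1].max()) + 1
    frames = np.full((n_frames, n_atoms, 3), np.nan)
    frames[data[:, 0].astype(int), data[:, 1].astype(int)] = data[:, 2:5]
    if np.isnan(frames).any():
        raise FormatError(f"{path}: incomplete frame/atom grid")
    return Trajectory(frames=frames, dt=dt, topology=topology, kind="cartesian")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def resolve_selection(model: StructureModel, selection) -> np.ndarray:
    """Resolve a selection into atom indices.

    Accepts ``"CA"``-style single atom names, ``"backbone"`` (N, CA, C, O),
    an iterable of (residue_index, atom_name) pairs, or an iterable of
    integer atom indices.
    """
    if isinstance(selection, str):
        names = ("N", "CA", "C", "O") if selection == "backbone" else (selection,)
        idx = [i for i, a in enumerate(model.atoms) if a.name in names]
    else:
        selection = list(selection)
        if selection and isinstance(selection[0], (int, np.integer)):
            idx = [int(i) for i in selection]
        else:
            idx = []
            for res_idx, name in selection:
                i = model.atom_index(res_idx, name)
                if i is not None:
                    idx.append(i)
    return np.asarray(idx, dtype=int)


def _check_superposable(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 atom pairs")
    for pts in (a, b):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise GeometryError("selection is collinear; rotation is underdetermined")


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid motions."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    _check_superposable(a, b)
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(len(a)))


def superpose(mobile: StructureModel, reference: StructureModel,
              selection="CA") -> tuple[StructureModel, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile`` and the RMSD over the
    selection.  The reference is left untouched.
    """
    idx_pairs = []
    sel_m = resolve_selection(mobile, selection)
    for i in sel_m:
        a = mobile.atoms[i]
        j = reference.atom_index(a.residue_index, a.name)
        if j is not None:
            idx_pairs.append((i, j))
    if len(idx_pairs) < 3:
        raise GeometryError(
            f"selection resolves to only {len(idx_pairs)} common atom pairs"
        )
    im, ir = map(np.array, zip(*idx_pairs))
    mob = mobile.coordinates
    ref = reference.coordinates
    a = ref[ir]
    b = mob[im]
    _check_superposable(a, b)
    a_centroid = a.mean(axis=0)
    b_centroid = b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - a_centroid, b - b_centroid)
    transformed = rot.apply(mob - b_centroid) + a_centroid
    rmsd = float(rssd / np.sqrt(len(a)))
    return mobile.with_coordinates(transformed), rmsd


# ---------------------------------------------------------------------------
# Backbone torsions
# ---------------------------------------------------------------------------


def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral angle (degrees) of four points.

    Works on single points (shape (3,)) or batched points (..., 3).
    Output lies in (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is the half-open (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang if np.ndim(ang) else float(ang)


def _phi_psi_quadruples(model: StructureModel, residues: Sequence[int]):
    """Atom-index quadruples for phi and psi per residue (None if incomplete)."""
    quads = {}
    for resi in residues:
        n = model.atom_index(resi, "N")
        ca = model.atom_index(resi, "CA")
        c = model.atom_index(resi, "C")
        c_prev = model.atom_index(resi - 1, "C")
        n_next = model.atom_index(resi + 1, "N")
        phi = (c_prev, n, ca, c) if None not in (c_prev, n, ca, c) else None
        psi = (n, ca, c, n_next) if None not in (n, ca, c, n_next) else None
        quads[resi] = (phi, psi)
    return quads


def backbone_torsions(model: StructureModel,
                      residues: Sequence[int] | None = None,
                      ) -> dict[int, tuple[float | None, float | None]]:
    """Per-residue (phi, psi) in degrees; ``None`` marks undefined angles.

    Terminal residues (or residues with missing backbone atoms) yield an
    explicit ``None`` for the affected angle, with a warning — never a 0.
    """
    if residues is None:
        residues = model.residue_indices
    coords = model.coordinates
    out: dict[int, tuple[float | None, float | None]] = {}
    missing = []
    for resi, (phi_q, psi_q) in _phi_psi_quadruples(model, residues).items():
        phi = dihedral(*(coords[i] for i in phi_q)) if phi_q else None
        psi = dihedral(*(coords[i] for i in psi_q)) if psi_q else None
        if phi is None or psi is None:
            missing.append(resi)
        out[resi] = (phi, psi)
    if missing:
        warnings.warn(
            f"torsions undefined for residues {missing} (missing neighbours/atoms)"
        )
    return out


def backbone_torsion_trajectory(traj: Trajectory,
                                residues: Sequence[int],
                                angle: str = "psi") -> Trajectory:
    """Extract one backbone torsion per residue for every frame.

    Returns a torsion-kind trajectory of shape (n_frames, n_residues) in
    degrees with NaN for undefined angles and labels ``(residue, angle)``.
    """
    if traj.kind != "cartesian" or traj.topology is None:
        raise ValueError("needs a cartesian trajectory with a topology")
    if angle not in ("phi", "psi"):
        raise ValueError("angle must be 'phi' or 'psi'")
    quads = _phi_psi_quadruples(traj.topology, residues)
    sel = 0 if angle == "phi" else 1
    cols = []
    labels = []
    for resi in residues:
        q = quads[resi][sel]
        if q is None:
            cols.append(np.full(traj.n_frames, np.nan))
        else:
            i0, i1, i2, i3 = q
            cols.append(dihedral(traj.frames[:, i0], traj.frames[:, i1],
                                 traj.frames[:, i2], traj.frames[:, i3]))
        labels.append((resi, angle))
    return Trajectory(frames=np.column_stack(cols), dt=traj.dt,
                      kind="torsion", labels=labels)
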