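"""Ensemble quality statistics: precision and accuracy RMSDs, four-class
Ramachandran classification, van der Waals close contacts, and a combined
refinement-statistics report.

The Ramachandran region grids (10°x10°, labels most-favored / additionally
allowed / generously allowed / disallowed, with dedicated glycine and
proline maps) are shipped as inspectable plain-text package data.
Aggregate percentages follow the usual reporting convention and exclude
glycine and proline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .structure_io import (
    Ensemble,
    StructureModel,
    backbone_torsions,
    resolve_selection,
    superpose,
)
from .nmr_observables import ViolationReport, violation_report

__all__ = [
    "RamachandranReport",
    "EnsembleQualityReport",
    "ramachandran_classify",
    "ramachandran_report",
    "ensemble_precision",
    "accuracy_to_reference",
    "mean_structure",
    "vdw_close_contacts",
    "table1_report",
    "REGION_LABELS",
]

REGION_LABELS = {
    "F": "most_favored",
    "A": "additionally_allowed",
    "G": "generously_allowed",
    "D": "disallowed",
}
_REGION_ORDER = ["most_favored", "additionally_allowed",
                 "generously_allowed", "disallowed"]


def _load_grid(name: str) -> np.ndarray:
    text = resources.files("nbens").joinpath("data").joinpath(name).read_text()
    rows = [line.split() for line in text.splitlines()
            if line and not line.startswith("#")]
    grid = np.array(rows, dtype="U1")
    if grid.shape != (36, 36):
        raise ValueError(f"{name}: expected a 36x36 grid, got {grid.shape}")
    return grid


_GRIDS: dict[str, np.ndarray] = {}


def _grid_for(residue_name: str) -> np.ndarray:
    key = {"GLY": "rama_gly.txt", "PRO": "rama_pro.txt"}.get(
        residue_name.upper(), "rama_general.txt")
    if key not in _GRIDS:
        _GRIDS[key] = _load_grid(key)
    return _GRIDS[key]


def _load_vdw() -> dict[str, float]:
    text = resources.files("nbens").joinpath("data/vdw_radii.txt").read_text()
    radii = {}
    for line in text.splitlines():
        if line and not line.startswith("#"):
            el, r = line.split()
            radii[el] = float(r)
    return radii


def ramachandran_classify(phi: float, psi: float,
                          residue_name: str = "ALA") -> str:
    """Four-class region label for a (phi, psi) pair in degrees.

    Lookup in the shipped 10°x10° grid; glycine and proline use their own
    maps.  Angles are wrapped periodically, so +180° falls in the -180°
    cell.
    """
    if phi is None or psi is None:
        raise ValueError("both angles must be defined")
    grid = _grid_for(residue_name)
    i = int(np.floor(((phi + 180.0) % 360.0) / 10.0)) % 36
    j = int(np.floor(((psi + 180.0) % 360.0) / 10.0)) % 36
    return REGION_LABELS[grid[i, j]]


@dataclass
class RamachandranReport:
    """Per-residue-per-model labels with aggregate counts and percentages.

    ``percentages`` cover non-Gly/Pro residues with defined angles (the
    standard reporting convention); Gly/Pro classifications are still in
    the table.  ``n_undefined`` counts (model, residue) pairs skipped for
    missing angles.
    """

    table: pd.DataFrame
    counts: dict[str, int]
    percentages: dict[str, float]
    n_undefined: int

    @property
    def n_disallowed(self) -> int:
        return self.counts["disallowed"]


def ramachandran_report(ensemble: Ensemble,
                        residues=None) -> RamachandranReport:
    """Classify every defined (phi, psi) of every model."""
    rows = []
    n_undefined = 0
    for model in ensemble.models:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            torsions = backbone_torsions(model, residues)
        for resi, (phi, psi) in torsions.items():
            if phi is None or psi is None:
                n_undefined += 1
                continue
            resn = model.residue_name(resi) or "ALA"
            rows.append({
                "model": model.model_id, "residue": resi,
                "residue_name": resn, "phi": phi, "psi": psi,
                "region": ramachandran_classify(phi, psi, resn),
                "counted": resn not in ("GLY", "PRO"),
            })
    table = pd.DataFrame(rows)
    counted = table[table["counted"]] if len(table) else table
    counts = {lab: int((counted["region"] == lab).sum()) if len(counted) else 0
              for lab in _REGION_ORDER}
    total = sum(counts.values())
    percentages = {lab: (100.0 * c / total if total else 0.0)
                   for lab, c in counts.items()}
    return RamachandranReport(table=table, counts=counts,
                              percentages=percentages,
                              n_undefined=n_undefined)


# ---------------------------------------------------------------------------
# Precision / accuracy RMSDs
# ---------------------------------------------------------------------------


def _range_selection(model: StructureModel, residue_range, atoms):
    lo, hi = residue_range
    sel = [(a.residue_index, a.name) for a in model.atoms
           if lo <= a.residue_index <= hi and a.name in atoms]
    if not sel:
        raise ValueError(f"residue range {residue_range} selects no atoms")
    return sel


def _superpose_to_mean(ensemble: Ensemble, sel, max_iter=50, tol=1e-4):
    """Iteratively superpose all models on the selection until the mean
    structure stops moving.  Returns (superposed models, mean coords)."""
    models = list(ensemble.models)
    idx = resolve_selection(models[0], sel)
    models = [
        superpose(m, models[0], sel)[0] if k else m
        for k, m in enumerate(models)
    ]
    mean = np.mean([m.coordinates for m in models], axis=0)
    for _ in range(max_iter):
        mean_model = models[0].with_coordinates(mean)
        models = [superpose(m, mean_model, sel)[0] for m in models]
        new_mean = np.mean([m.coordinates for m in models], axis=0)
        shift = float(np.max(np.linalg.norm(new_mean[idx] - mean[idx], axis=1)))
        mean = new_mean
        if shift < tol:
            break
    return models, mean


def ensemble_precision(ensemble: Ensemble, residue_range,
                       atoms=("N", "CA", "C", "O"),
                       pairwise: bool = False) -> float:
    """Ensemble precision RMSD (Å) over backbone atoms of a residue range.

    Default: mean per-model RMSD to the converged mean structure after
    iterative superposition.  ``pairwise=True`` reports the mean of all
    pairwise RMSDs instead.
    """
    if ensemble.n_models < 2:
        raise ValueError("precision needs at least 2 models")
    sel = _range_selection(ensemble.models[0], residue_range, atoms)
    models, mean = _superpose_to_mean(ensemble, sel)
    idx = resolve_selection(models[0], sel)
    if pairwise:
        from .structure_io import kabsch_rmsd
        vals = [
            kabsch_rmsd(models[i].coordinates[idx], models[j].coordinates[idx])
            for i in range(len(models)) for j in range(i + 1, len(models))
        ]
        return float(np.mean(vals))
    rmsds = [
        float(np.sqrt(np.mean(
            np.sum((m.coordinates[idx] - mean[idx]) ** 2, axis=1))))
        for m in models
    ]
    return float(np.mean(rmsds))


def mean_structure(ensemble: Ensemble, residue_range=None,
                   atoms=("N", "CA", "C", "O")) -> StructureModel:
    """Mean-coordinate model after iterative superposition."""
    if residue_range is None:
        indices = ensemble.models[0].residue_indices
        residue_range = (min(indices), max(indices))
    sel = _range_selection(ensemble.models[0], residue_range, atoms)
    _, mean = _superpose_to_mean(ensemble, sel)
    return ensemble.models[0].with_coordinates(mean)


def accuracy_to_reference(ensemble: Ensemble, reference: StructureModel,
                          residue_range=None,
                          exclude_residues=()) -> tuple[float, int]:
    """Cα RMSD (Å) of the ensemble mean-coordinate model to a reference.

    The common Cα set is the residue-index intersection of ensemble and
    reference minus ``exclude_residues`` (flexible termini etc.).  Returns
    (rmsd, n_common_ca).
    """
    mean_model = mean_structure(ensemble, residue_range)
    common = []
    for a in mean_model.atoms:
        if a.name != "CA" or a.residue_index in exclude_residues:
            continue
        if residue_range is not None and not (
                residue_range[0] <= a.residue_index <= residue_range[1]):
            continue
        if reference.atom_index(a.residue_index, "CA") is not None:
            common.append((a.residue_index, "CA"))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common Cα atoms")
    _, rmsd = superpose(mean_model, reference, common)
    return rmsd, len(common)


# ---------------------------------------------------------------------------
# Van der Waals close contacts
# ---------------------------------------------------------------------------

_BACKBONE_LINK = {"C", "N", "CA", "O", "H"}


def vdw_close_contacts(model: StructureModel, overlap: float = 0.4,
                       ) -> list[tuple[int, int, float]]:
    """Heavy-atom pairs closer than r_i + r_j - ``overlap`` Å.

    Pairs within one residue, and backbone-linkage pairs of adjacent
    residues, are excluded.  Approximate by construction — the exact
    refinement-program criterion is not reproduced.
    """
    radii = _load_vdw()
    heavy = [(i, a) for i, a in enumerate(model.atoms)
             if not a.element.upper().startswith("H")]
    coords = np.array([a.coordinates for _, a in heavy])
    out = []
    for p in range(len(heavy)):
        for q in range(p + 1, len(heavy)):
            ap, aq = heavy[p][1], heavy[q][1]
            sep = abs(ap.residue_index - aq.residue_index)
            if sep == 0:
                continue
            if sep == 1 and ap.name in _BACKBONE_LINK and aq.name in _BACKBONE_LINK:
                continue
            limit = (radii.get(ap.element.upper(), 1.7)
                     + radii.get(aq.element.upper(), 1.7) - overlap)
            d = float(np.linalg.norm(coords[p] - coords[q]))
            if d < limit:
                out.append((heavy[p][0], heavy[q][0], d))
    return out


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------


@dataclass
class EnsembleQualityReport:
    """Refinement-statistics style summary of an ensemble."""

    n_models: int
    restraint_counts: dict[str, int]
    backbone_rmsd: float | None
    ca_rmsd_to_reference: float | None
    n_common_ca: int | None
    ramachandran: RamachandranReport | None
    noe_violations: ViolationReport | None
    vdw_close_contact_count: int | None
    threshold: float = 0.2

    _ROWS = [
        ("NOE upper limits", lambda r: r.restraint_counts.get("noe", 0)),
        ("H-bond restraints", lambda r: r.restraint_counts.get("hbond", 0)),
        ("Backbone RMSD (Å)", lambda r: _fmt(r.backbone_rmsd)),
        ("Cα RMSD to reference (Å)", lambda r: _fmt(r.ca_rmsd_to_reference)),
        ("Most favored (%)", lambda r: _rama_pct(r, "most_favored")),
        ("Additionally allowed (%)",
         lambda r: _rama_pct(r, "additionally_allowed")),
        ("Generously allowed (%)",
         lambda r: _rama_pct(r, "generously_allowed")),
        ("Disallowed (%)", lambda r: _rama_pct(r, "disallowed")),
        ("Disallowed (count)",
         lambda r: r.ramachandran.counts["disallowed"]
         if r.ramachandran else ""),
        ("NOE violations (ensemble-averaged)",
         lambda r: r.noe_violations.n_violated_ensemble
         if r.noe_violations else ""),
        ("NOE violations (any model)",
         lambda r: r.noe_violations.n_violated_per_model
         if r.noe_violations else ""),
        ("VDW close contacts", lambda r: _fmt(r.vdw_close_contact_count)),
    ]

    def to_tsv(self) -> str:
        lines = ["statistic\tvalue"]
        for label, getter in self._ROWS:
            lines.append(f"{label}\t{getter(self)}")
        return "\n".join(lines) + "\n"


def _fmt(v):
    if v is None:
        return ""
    return f"{v:.2f}" if isinstance(v, float) else v


def _rama_pct(report: EnsembleQualityReport, label: str):
    if report.ramachandran is None:
        return ""
    return f"{report.ramachandran.percentages[label]:.1f}"


def table1_report(ensemble: Ensemble, reference: StructureModel | None = None,
                  restraints=None, threshold: float = 0.2,
                  residue_range=None,
                  count_vdw: bool = False) -> EnsembleQualityReport:
    """Build the combined quality report for an ensemble.

    ``residue_range`` bounds the precision RMSD (defaults to the full
    residue span); NOE violations and restraint counts appear when a
    restraint list is supplied; the close-contact scan is opt-in (it is
    quadratic in atom count).
    """
    indices = ensemble.models[0].residue_indices
    if residue_range is None:
        residue_range = (min(indices), max(indices))
    backbone_rmsd = (ensemble_precision(ensemble, residue_range)
                     if ensemble.n_models >= 2 else None)
    ca_rmsd = n_ca = None
    if reference is not None:
        ca_rmsd, n_ca = accuracy_to_reference(ensemble, reference,
                                              residue_range)
    rama = ramachandran_report(ensemble)
    counts: dict[str, int] = {}
    noe = None
    if restraints is not None:
        for r in restraints:
            counts[r.kind] = counts.get(r.kind, 0) + 1
        noe = violation_report(ensemble, restraints, threshold=threshold)
    vdw_count = None
    if count_vdw:
        seen = set()
        for model in ensemble.models:
            for i, j, _ in vdw_close_contacts(model):
                seen.add((i, j))
        vdw_count = len(seen)
    return EnsembleQualityReport(
        n_models=ensemble.n_models,
        restraint_counts=counts,
        backbone_rmsd=backbone_rmsd,
        ca_rmsd_to_reference=ca_rmsd,
        n_common_ca=n_ca,
        ramachandran=rama,
        noe_violations=noe,
        vdw_close_contact_count=vdw_count,
        threshold=threshold,
    )
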