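"""Torsion featurization, collective variables, tICA, free-energy surfaces
and average-linkage RMSD clustering.

The analysis chain mirrors the standard enhanced-sampling workflow for
loop ensembles: backbone torsions are embedded as (sin, cos) pairs, the
slowest linear modes are extracted with time-lagged independent component
analysis (reversible, symmetrized estimator), densities over the leading
two components are turned into relative free energies, and conformations
are grouped by average-linkage hierarchical clustering on pairwise
best-fit RMSD with a distance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .constants import KB_KCAL
from .structure_io import (
    GeometryError,
    Trajectory,
    kabsch_rmsd,
    resolve_selection,
)

__all__ = [
    "TorsionFeatures",
    "CollectiveVariable",
    "TicaModel",
    "FreeEnergySurface",
    "ClusterResult",
    "featurize",
    "eval_cv",
    "tica_fit",
    "tica_transform",
    "free_energy_surface",
    "average_linkage_cluster",
    "pairwise_rmsd_matrix",
]


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------


@dataclass
class TorsionFeatures:
    """(sin, cos) embedding of k torsions: matrix of shape (n_frames, 2k)."""

    matrix: np.ndarray
    labels: list  # k (residue, angle-name) tuples, selection order
    dt: float = 1.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 2 * len(self.labels):
            raise ValueError("feature matrix must have 2 columns per torsion")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def featurize(traj: Trajectory, torsion_selection=None) -> TorsionFeatures:
    """Embed selected torsions as (sin, cos) pairs.

    ``traj`` must be a torsion-kind trajectory (degrees).  The selection is
    a list of labels (entries of ``traj.labels``) or column indices; by
    default all torsions are used.  Columns come in selection order as
    (sin, cos) per torsion.  Undefined (NaN) torsions in the selection are
    an error naming the residue — downstream code must exclude them
    explicitly, never zero-fill.
    """
    if traj.kind != "torsion":
        raise ValueError(
            "featurize expects a torsion trajectory; extract torsions first "
            "(structure_io.backbone_torsion_trajectory)"
        )
    labels = traj.labels or [(i, "torsion") for i in range(traj.frames.shape[1])]
    if torsion_selection is None:
        cols = list(range(traj.frames.shape[1]))
    else:
        cols = []
        for sel in torsion_selection:
            if isinstance(sel, (int, np.integer)):
                cols.append(int(sel))
            else:
                cols.append(labels.index(tuple(sel)))
    angles = traj.frames[:, cols]
    for c, col in enumerate(cols):
        if np.isnan(angles[:, c]).any():
            raise ValueError(
                f"torsion {labels[col]} is undefined in some frames; "
                "exclude it from the selection"
            )
    rad = np.radians(angles)
    matrix = np.empty((angles.shape[0], 2 * len(cols)))
    matrix[:, 0::2] = np.sin(rad)
    matrix[:, 1::2] = np.cos(rad)
    return TorsionFeatures(matrix=matrix, labels=[labels[c] for c in cols],
                           dt=traj.dt)


# ---------------------------------------------------------------------------
# Collective variable
# ---------------------------------------------------------------------------


@dataclass
class CollectiveVariable:
    """Weighted sum of sines and cosines of selected torsions.

    value = sum_i a_i sin(psi_i) + b_i cos(psi_i) — smooth and invariant
    under full-turn shifts of any torsion.
    """

    sin_weights: np.ndarray
    cos_weights: np.ndarray
    torsion_selection: list | None = None

    def __post_init__(self):
        self.sin_weights = np.asarray(self.sin_weights, float)
        self.cos_weights = np.asarray(self.cos_weights, float)
        if self.sin_weights.shape != self.cos_weights.shape:
            raise ValueError("sin and cos weight vectors must have equal length")

    @property
    def n_torsions(self) -> int:
        return self.sin_weights.shape[0]

    def value_from_angles(self, angles_deg: np.ndarray) -> np.ndarray:
        """Evaluate on angles in degrees, shape (..., k)."""
        rad = np.radians(np.asarray(angles_deg, float))
        if rad.shape[-1] != self.n_torsions:
            raise ValueError(
                f"expected {self.n_torsions} torsions, got {rad.shape[-1]}"
            )
        return rad_sin_cos_combine(rad, self.sin_weights, self.cos_weights)

    def gradient_from_angles(self, angles_deg: np.ndarray) -> np.ndarray:
        """d(value)/d(angle_rad) per torsion, for bias-force propagation."""
        rad = np.radians(np.asarray(angles_deg, float))
        return self.sin_weights * np.cos(rad) - self.cos_weights * np.sin(rad)


def rad_sin_cos_combine(rad, a, b):
    return np.sum(a * np.sin(rad) + b * np.cos(rad), axis=-1)


def eval_cv(data, cv: CollectiveVariable) -> np.ndarray:
    """Per-frame CV value from torsion features or a torsion trajectory."""
    if isinstance(data, TorsionFeatures):
        if data.matrix.shape[1] != 2 * cv.n_torsions:
            raise ValueError("CV weights do not match feature dimensionality")
        return (data.matrix[:, 0::2] @ cv.sin_weights
                + data.matrix[:, 1::2] @ cv.cos_weights)
    if isinstance(data, Trajectory):
        if data.kind != "torsion":
            raise ValueError("eval_cv expects torsion data")
        return cv.value_from_angles(data.frames)
    return cv.value_from_angles(np.asarray(data, float))


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------


@dataclass
class TicaModel:
    """Solution of the generalized eigenproblem C_tau v = lambda C0 v."""

    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    lag: float  # time units (ps)
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # one column per eigenvalue, unit C0-norm
    epsilon: float

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _lagged_pairs(blocks: list[np.ndarray], lag_frames: int):
    x0 = np.concatenate([b[:-lag_frames] for b in blocks])
    xt = np.concatenate([b[lag_frames:] for b in blocks])
    return x0, xt


def tica_fit(features, lag: float, epsilon: float = 1e-6) -> TicaModel:
    """Fit tICA with the symmetrized (reversible) covariance estimator.

    ``features`` is a TorsionFeatures, a raw (n_frames, d) array, or a list
    of either — a list is treated as independent trajectories fitted in a
    joint coordinate system (no lagged pair spans a boundary).  ``lag`` is
    in the trajectory time unit and is converted with dt.
    """
    if not isinstance(features, (list, tuple)):
        features = [features]
    dts = {f.dt if isinstance(f, TorsionFeatures) else 1.0 for f in features}
    if len(dts) > 1:
        raise ValueError("all trajectories must share one dt")
    dt = dts.pop()
    blocks = [
        np.asarray(f.matrix if isinstance(f, TorsionFeatures) else f, float)
        for f in features
    ]
    lag_frames = int(round(lag / dt))
    if lag_frames < 1:
        raise ValueError(f"lag {lag} is below one frame (dt={dt})")
    for b in blocks:
        if b.shape[0] <= lag_frames + 2:
            raise ValueError(
                f"trajectory of {b.shape[0]} frames too short for lag "
                f"{lag_frames} frames"
            )
    x0, xt = _lagged_pairs(blocks, lag_frames)
    mean = np.concatenate([x0, xt]).mean(axis=0)
    x0 = x0 - mean
    xt = xt - mean
    n = x0.shape[0]
    c0 = (x0.T @ x0 + xt.T @ xt) / (2.0 * n)
    ctau = (x0.T @ xt + xt.T @ x0) / (2.0 * n)
    if np.allclose(c0, 0.0, atol=1e-14):
        raise ValueError("features are constant in time; tICA is degenerate")
    c0_reg = c0 + epsilon * np.eye(c0.shape[0])
    cond = np.linalg.cond(c0_reg)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"C0 is singular beyond epsilon rescue (condition number {cond:.3e})"
        )
    eigvals, eigvecs = scipy.linalg.eigh(ctau, c0_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # scipy.linalg.eigh returns B-orthonormal vectors (unit C0-norm already);
    # fix the sign so the largest-magnitude loading is positive
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    return TicaModel(mean=mean, c0=c0, ctau=ctau, lag=lag,
                     eigenvalues=eigvals, components=eigvecs, epsilon=epsilon)


def tica_transform(model: TicaModel, features, n_components: int | None = None,
                   ) -> np.ndarray:
    """Project (possibly out-of-sample) features onto the tICA components."""
    x = np.asarray(
        features.matrix if isinstance(features, TorsionFeatures) else features,
        float,
    )
    single = x.ndim == 1
    if single:
        x = x[None]
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.mean.shape[0]}"
        )
    proj = (x - model.mean) @ model.components[:, :n_components]
    return proj[0] if single else proj


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergySurface:
    """Relative free energy -kT ln(count/max_count) over a 2-D grid.

    ``delta_g`` is in kcal/mol with NaN marking unsampled bins; ``occupied``
    is the corresponding boolean mask.  The minimum over occupied bins is
    exactly 0.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_table(self) -> np.ndarray:
        """Rows of (x_center, y_center, count, delta_g) for plain-text output."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return np.column_stack([
            xx.ravel(), yy.ravel(), self.counts.ravel(), self.delta_g.ravel()
        ])


def free_energy_surface(projected: np.ndarray, bins: int = 50,
                        temperature: float = 300.0,
                        weights: np.ndarray | None = None,
                        ) -> FreeEnergySurface:
    """Histogram (tIC1, tIC2) points into a relative free-energy surface.

    Optional per-point weights (e.g. metadynamics reweighting factors
    exp(+V_bias/kT)) enter the histogram; the global minimum of the
    occupied bins is gauged to 0 and unsampled bins are NaN, never the
    result of log(0) arithmetic.
    """
    pts = np.asarray(projected, float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("projected points must have at least two columns")
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins, weights=weights
    )
    kt = KB_KCAL * temperature
    delta_g = np.full_like(counts, np.nan)
    occ = counts > 0
    delta_g[occ] = -kt * np.log(counts[occ] / counts.max())
    return FreeEnergySurface(x_edges=x_edges, y_edges=y_edges, counts=counts,
                             delta_g=delta_g, temperature=temperature)


# ---------------------------------------------------------------------------
# Average-linkage RMSD clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0-based, by first frame)
    representatives: list[int]  # medoid frame per cluster id
    cutoff: float
    merge_history: list  # (cluster_a_frames, cluster_b_frames, linkage) per merge

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pairwise_rmsd_matrix(traj: Trajectory, selection="CA") -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs over the selection."""
    if traj.kind != "cartesian":
        raise ValueError("RMSD clustering needs a cartesian trajectory")
    if selection is None:
        idx = np.arange(traj.frames.shape[1])
    elif traj.topology is not None:
        idx = resolve_selection(traj.topology, selection)
    else:
        idx = np.asarray(list(selection), dtype=int)
    if len(idx) < 3:
        raise GeometryError("selection must contain at least 3 atoms")
    coords = traj.frames[:, idx]
    n = traj.n_frames
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kabsch_rmsd(coords[i], coords[j])
    return dist


def average_linkage_cluster(traj: Trajectory, selection="CA",
                            cutoff: float = 1.2) -> ClusterResult:
    """Agglomerative average-linkage clustering with an RMSD cutoff.

    Clusters merge while the smallest average inter-cluster RMSD is at or
    below ``cutoff``; ties break toward the pair containing the lowest
    frame index.  Each cluster reports its medoid (the frame minimizing
    the summed RMSD to its cluster mates).
    """
    dist = pairwise_rmsd_matrix(traj, selection)
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    history = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                link = dist[np.ix_(clusters[a], clusters[b])].mean()
                key = (link, min(clusters[a][0], clusters[b][0]),
                       max(clusters[a][0], clusters[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (link, _, _), a, b = best
        if link > cutoff:
            break
        history.append((list(clusters[a]), list(clusters[b]), link))
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    clusters.sort(key=lambda c: c[0])
    assignments = np.empty(n, dtype=int)
    representatives = []
    for cid, members in enumerate(clusters):
        assignments[members] = cid
        sub = dist[np.ix_(members, members)]
        representatives.append(members[int(np.argmin(sub.sum(axis=1)))])
    return ClusterResult(assignments=assignments,
                         representatives=representatives,
                         cutoff=cutoff, merge_history=history)
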