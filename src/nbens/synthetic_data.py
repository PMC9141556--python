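"""Synthetic trajectory generators with analytically known ground truth.

Each generator returns its data together with the exact quantity a
downstream estimator is supposed to recover (order parameter, state
labels, free-energy curve, pairwise distances), so every analysis stage
can be validated without external data.  All generators are deterministic
functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KJ
from .structure_io import Trajectory

__all__ = [
    "ConeModelParams",
    "TwoStateLoopParams",
    "DoubleWellParams",
    "ToyChainParams",
    "DoubleWellPotential",
    "gen_cone_vectors",
    "gen_two_state_loop",
    "gen_double_well",
    "gen_toy_chain",
    "cone_s2",
]


def cone_s2(semi_angle_deg: float) -> float:
    """Closed-form order parameter for diffusion in a cone of given semi-angle."""
    c = np.cos(np.radians(semi_angle_deg))
    return float((c * (1 + c) / 2) ** 2)


# ---------------------------------------------------------------------------
# Diffusion in a cone
# ---------------------------------------------------------------------------


@dataclass
class ConeModelParams:
    """Unit bond vectors uniform over a spherical cap around +z."""

    semi_angle: float  # degrees, (0, 90]
    n_frames: int = 10000
    frame_correlation: float = 0.0  # AR(1)-style mixing in [0, 1)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.semi_angle <= 90:
            raise ValueError("semi_angle must be in (0, 90] degrees")
        if not 0 <= self.frame_correlation < 1:
            raise ValueError("frame_correlation must be in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


def _sample_cap(rng: np.random.Generator, n: int, cos_min: float) -> np.ndarray:
    """Uniform unit vectors on the spherical cap cos(theta) >= cos_min."""
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def gen_cone_vectors(params: ConeModelParams) -> tuple[Trajectory, float]:
    """Generate cone-model unit vectors and the exact S² they encode.

    With ``frame_correlation`` rho > 0 successive frames keep the previous
    orientation with probability rho (a resampling chain whose stationary
    law is still uniform on the cap), giving tunable time correlation
    without changing the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    cos_min = np.cos(np.radians(params.semi_angle))
    fresh = _sample_cap(rng, params.n_frames, cos_min)
    if params.frame_correlation > 0:
        keep = rng.random(params.n_frames) < params.frame_correlation
        keep[0] = False
        vectors = fresh.copy()
        for t in range(1, params.n_frames):
            if keep[t]:
                vectors[t] = vectors[t - 1]
    else:
        vectors = fresh
    traj = Trajectory(frames=vectors, dt=1.0, kind="vector")
    return traj, cone_s2(params.semi_angle)


# ---------------------------------------------------------------------------
# Two-state hopping torsion loop
# ---------------------------------------------------------------------------


@dataclass
class TwoStateLoopParams:
    """Markov hopping of a torsion vector between two metastable centers."""

    n_residues: int
    state_centers: tuple  # two psi-angle vectors, degrees
    hop_probability: float
    angular_noise_sd: float = 5.0
    n_frames: int = 10000
    seed: int = 0

    def __post_init__(self):
        centers = np.asarray(self.state_centers, float)
        if centers.shape != (2, self.n_residues):
            raise ValueError("state_centers must be two vectors of length n_residues")
        # 0 is allowed (frozen chain); 1 is not (period-2 determinism)
        if not 0 <= self.hop_probability < 1:
            raise ValueError("hop_probability must be in [0, 1)")
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be non-negative")
        self.state_centers = centers


def _wrap_angles(a: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    wrapped = (np.asarray(a, float) + 180.0) % 360.0 - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def gen_two_state_loop(params: TwoStateLoopParams,
                       ) -> tuple[Trajectory, np.ndarray]:
    """Torsion trajectory hopping between two centers, plus per-frame labels."""
    rng = np.random.default_rng(params.seed)
    hops = rng.random(params.n_frames) < params.hop_probability
    hops[0] = False
    labels = np.cumsum(hops) % 2
    angles = params.state_centers[labels]
    if params.angular_noise_sd > 0:
        angles = angles + rng.normal(
            0.0, params.angular_noise_sd, size=angles.shape
        )
    traj = Trajectory(
        frames=_wrap_angles(angles), dt=1.0, kind="torsion",
        labels=[(i + 1, "psi") for i in range(params.n_residues)],
    )
    return traj, labels


# ---------------------------------------------------------------------------
# 1-D double-well Langevin particle
# ---------------------------------------------------------------------------


@dataclass
class DoubleWellPotential:
    """U(x) = h * ((x/a)^2 - 1)^2 — minima at ±a, barrier h at x = 0."""

    barrier_height: float  # kJ/mol
    well_separation: float = 1.0  # a

    def energy(self, x):
        u = (np.asarray(x, float) / self.well_separation) ** 2 - 1.0
        return self.barrier_height * u**2

    def gradient(self, x):
        x = np.asarray(x, float)
        a2 = self.well_separation**2
        return 4.0 * self.barrier_height * x * (x**2 / a2 - 1.0) / a2

    def free_energy(self, grid: np.ndarray) -> np.ndarray:
        """Exact 1-D free energy (equals the potential, gauged to min 0)."""
        f = self.energy(grid)
        return f - f.min()


@dataclass
class DoubleWellParams:
    barrier_height: float  # kJ/mol
    well_separation: float = 1.0
    temperature: float = 300.0  # K
    friction: float = 5.0  # gamma*m, ps^-1 * mass-scale (overdamped)
    dt: float = 0.01  # ps
    n_steps: int = 100000
    seed: int = 0
    x0: float | None = None

    def __post_init__(self):
        if self.temperature <= 0 or self.friction <= 0:
            raise ValueError("temperature and friction must be positive")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt and n_steps must be positive")
        # stability heuristic for the overdamped update
        if self.dt * self.friction >= 10.0:
            raise ValueError("dt*friction too large for a stable update")


def overdamped_langevin(gradient, x0: float, n_steps: int, dt: float,
                        friction: float, temperature: float,
                        rng: np.random.Generator,
                        extra_force=None) -> np.ndarray:
    """Euler–Maruyama overdamped Langevin integration of a 1-D coordinate.

    x <- x - grad(x)/(gamma m) dt + sqrt(2 kB T dt/(gamma m)) xi.
    ``extra_force(x)`` (if given) is added to the physical force.
    """
    kt = KB_KJ * temperature
    inv_gm = 1.0 / friction
    sigma = np.sqrt(2.0 * kt * dt * inv_gm)
    noise = rng.normal(0.0, sigma, size=n_steps)
    xs = np.empty(n_steps + 1)
    xs[0] = x0
    x = x0
    for t in range(n_steps):
        force = -gradient(x)
        if extra_force is not None:
            force = force + extra_force(x)
        x = x + force * inv_gm * dt + noise[t]
        xs[t + 1] = x
    return xs


def gen_double_well(params: DoubleWellParams,
                    grid: np.ndarray | None = None,
                    ) -> tuple[Trajectory, np.ndarray, np.ndarray,
                               DoubleWellPotential]:
    """Unbiased Langevin trajectory in the double well + analytic free energy.

    Returns (trajectory, grid, analytic_F_on_grid, potential).
    """
    potential = DoubleWellPotential(params.barrier_height, params.well_separation)
    rng = np.random.default_rng(params.seed)
    x0 = params.x0 if params.x0 is not None else -params.well_separation
    xs = overdamped_langevin(
        potential.gradient, x0, params.n_steps, params.dt,
        params.friction, params.temperature, rng,
    )
    if grid is None:
        lim = 2.0 * params.well_separation
        grid = np.linspace(-lim, lim, 201)
    traj = Trajectory(frames=xs[:, None], dt=params.dt, kind="scalar")
    return traj, grid, potential.free_energy(grid), potential


# ---------------------------------------------------------------------------
# Toy fluctuating chain
# ---------------------------------------------------------------------------


@dataclass
class ToyChainParams:
    n_atoms: int
    bond_length: float = 3.8  # Å
    fluctuation_sd: float = 0.3  # Å
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 2:
            raise ValueError("n_atoms must be at least 2")
        if self.bond_length <= 0 or self.fluctuation_sd < 0:
            raise ValueError("bond_length > 0 and fluctuation_sd >= 0 required")


def gen_toy_chain(params: ToyChainParams) -> tuple[Trajectory, dict]:
    """Linear bead chain with Gaussian coordinate noise.

    Returns the cartesian trajectory plus the generator's own exact record
    of every pairwise distance in every frame:
    ``{(i, j): array of length n_frames}`` with i < j (0-based atom indices).
    """
    rng = np.random.default_rng(params.seed)
    base = np.zeros((params.n_atoms, 3))
    base[:, 0] = np.arange(params.n_atoms) * params.bond_length
    frames = np.repeat(base[None], params.n_frames, axis=0)
    if params.fluctuation_sd > 0:
        frames = frames + rng.normal(
            0.0, params.fluctuation_sd, size=frames.shape
        )
    distances = {}
    for i in range(params.n_atoms):
        for j in range(i + 1, params.n_atoms):
            d = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
            distances[(i, j)] = d
    traj = Trajectory(frames=frames, dt=1.0, kind="cartesian")
    return traj, distances
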