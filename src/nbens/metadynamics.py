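"""Well-tempered metadynamics on low-dimensional toy systems.

A history-dependent bias of Gaussian hills is deposited along a scalar
collective variable while an overdamped Langevin particle explores a toy
potential; hill heights are tempered by the deposit-time bias, and the
free energy is recovered from the accumulated bias with the standard
well-tempered rescaling.  Optional bias-exchange moves swap configurations
between replicas carrying different biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ
from .structure_io import Trajectory

__all__ = [
    "HillRecord",
    "MetadBias",
    "WTMetadParams",
    "IdentityCV",
    "bias_value",
    "bias_gradient",
    "run_wt_metad",
    "estimate_free_energy",
    "bias_exchange_step",
    "write_hills",
    "read_hills",
]


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian: center, tempered height (kJ/mol), width, step."""

    center: float
    height: float
    width: float
    deposit_step: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("hill height and width must be positive")


@dataclass
class MetadBias:
    """Accumulated well-tempered bias along one CV."""

    hills: list[HillRecord] = field(default_factory=list)
    bias_factor: float = 10.0
    pace: int = 1000
    temperature: float = 300.0
    periodic: bool = False
    period: float = 2.0 * np.pi

    def __post_init__(self):
        if self.bias_factor <= 1.0:
            raise ValueError("bias_factor must exceed 1")

    def arrays(self):
        c = np.array([h.center for h in self.hills])
        h = np.array([h.height for h in self.hills])
        w = np.array([h.width for h in self.hills])
        return c, h, w


def _displacement(s, centers, periodic: bool, period: float):
    d = np.subtract.outer(np.asarray(s, float), centers)
    if periodic:
        d = d - period * np.round(d / period)
    return d


def bias_value(bias: MetadBias, s) -> np.ndarray | float:
    """Bias potential V(s) = sum_i h_i exp(-(s-c_i)^2 / (2 w_i^2)), kJ/mol.

    Periodic CVs use the minimum-image angular distance.
    """
    if not bias.hills:
        return np.zeros_like(np.asarray(s, float)) if np.ndim(s) else 0.0
    c, h, w = bias.arrays()
    d = _displacement(s, c, bias.periodic, bias.period)
    v = np.sum(h * np.exp(-0.5 * (d / w) ** 2), axis=-1)
    return v if np.ndim(s) else float(v)


def bias_gradient(bias: MetadBias, s) -> np.ndarray | float:
    """dV/ds at s (kJ/mol per CV unit)."""
    if not bias.hills:
        return np.zeros_like(np.asarray(s, float)) if np.ndim(s) else 0.0
    c, h, w = bias.arrays()
    d = _displacement(s, c, bias.periodic, bias.period)
    g = np.sum(-h * d / w**2 * np.exp(-0.5 * (d / w) ** 2), axis=-1)
    return g if np.ndim(s) else float(g)


class IdentityCV:
    """CV for 1-D particles: s = x, ds/dx = 1."""

    periodic = False

    @staticmethod
    def value(x):
        return x

    @staticmethod
    def gradient(x):
        return 1.0


@dataclass
class WTMetadParams:
    """Bias-deposition schedule; defaults follow the torsion-CV protocol
    (10 kJ/mol hills of 0.3 rad every 1000 steps, bias factor 10, 300 K)."""

    height0: float = 10.0  # kJ/mol
    width: float = 0.3  # CV units (rad for torsion CVs)
    pace: int = 1000  # steps between deposits
    bias_factor: float = 10.0
    temperature: float = 300.0  # K

    def __post_init__(self):
        if self.bias_factor <= 1.0:
            raise ValueError("bias_factor must exceed 1")
        if self.height0 < 0 or self.width <= 0 or self.pace < 1:
            raise ValueError("invalid hill schedule")


def run_wt_metad(system, cv, params: WTMetadParams, n_steps: int,
                 seed: int = 0, dt: float = 0.01, friction: float = 5.0,
                 x0: float | None = None) -> tuple[Trajectory, MetadBias]:
    """Run well-tempered metadynamics on a 1-D overdamped Langevin particle.

    ``system`` supplies the physical potential via ``gradient(x)`` (and
    optionally ``energy(x)``); ``cv`` maps x to the biased coordinate.
    Deposited heights follow height0 * exp(-V(s_t)/(kB*dT)) with
    dT = (bias_factor - 1) * T, evaluated with the bias present at deposit
    time.  With ``height0 == 0`` the run reduces exactly to the unbiased
    integrator under the same noise stream.

    Returns the scalar trajectory (n_steps + 1 frames) and the full bias.
    """
    rng = np.random.default_rng(seed)
    kt = KB_KJ * params.temperature
    delta_t = (params.bias_factor - 1.0) * params.temperature
    kb_dt = KB_KJ * delta_t
    inv_gm = 1.0 / friction
    sigma = np.sqrt(2.0 * kt * dt * inv_gm)
    noise = rng.normal(0.0, sigma, size=n_steps)

    periodic = bool(getattr(cv, "periodic", False))
    period = float(getattr(cv, "period", 2.0 * np.pi))
    centers: list[float] = []
    heights: list[float] = []
    hills: list[HillRecord] = []
    c_arr = np.empty(0)
    h_arr = np.empty(0)
    w = params.width

    def local_bias(s: float) -> float:
        if c_arr.size == 0:
            return 0.0
        d = s - c_arr
        if periodic:
            d = d - period * np.round(d / period)
        return float(np.sum(h_arr * np.exp(-0.5 * (d / w) ** 2)))

    def local_bias_grad(s: float) -> float:
        if c_arr.size == 0:
            return 0.0
        d = s - c_arr
        if periodic:
            d = d - period * np.round(d / period)
        return float(np.sum(-h_arr * d / w**2 * np.exp(-0.5 * (d / w) ** 2)))

    x = float(x0) if x0 is not None else 0.0
    xs = np.empty(n_steps + 1)
    xs[0] = x
    for t in range(n_steps):
        if params.height0 > 0 and t % params.pace == 0:
            s = float(cv.value(x))
            v_here = local_bias(s)
            h_new = params.height0 * np.exp(-v_here / kb_dt)
            hills.append(HillRecord(center=s, height=h_new, width=w,
                                    deposit_step=t))
            centers.append(s)
            heights.append(h_new)
            c_arr = np.asarray(centers)
            h_arr = np.asarray(heights)
        s = float(cv.value(x))
        force = -system.gradient(x)
        if params.height0 > 0:
            force = force - local_bias_grad(s) * cv.gradient(x)
        x = x + force * inv_gm * dt + noise[t]
        if not np.isfinite(x):
            raise FloatingPointError(f"non-finite coordinate at step {t}")
        xs[t + 1] = x

    bias = MetadBias(hills=hills, bias_factor=params.bias_factor,
                     pace=params.pace, temperature=params.temperature,
                     periodic=periodic, period=period)
    traj = Trajectory(frames=xs[:, None], dt=dt, kind="scalar")
    return traj, bias


def estimate_free_energy(bias: MetadBias, grid: np.ndarray) -> np.ndarray:
    """Well-tempered free-energy estimate on a grid, gauged to min 0.

    F(s) = -(gamma / (gamma - 1)) * V(s) + const.
    """
    if not bias.hills:
        raise ValueError("bias contains no hills")
    gamma = bias.bias_factor
    f = -(gamma / (gamma - 1.0)) * bias_value(bias, np.asarray(grid, float))
    return f - f.min()


def bias_exchange_step(replicas: list[tuple[float, MetadBias]],
                       rng: np.random.Generator,
                       temperature: float | None = None):
    """Attempt one nearest-neighbour configuration swap between replicas.

    Each replica is (coordinate, bias).  A random adjacent pair (i, i+1) is
    proposed and accepted with the Metropolis probability
    min(1, exp(-(V_swapped - V_current)/kT)) where both biases are
    evaluated at both configurations.  Returns (replicas, log) with the
    swap applied in place in the returned list.
    """
    if len(replicas) < 2:
        raise ValueError("bias exchange needs at least 2 replicas")
    temps = {b.temperature for _, b in replicas}
    if temperature is None:
        if len(temps) > 1:
            raise ValueError("replicas must share one temperature")
        temperature = temps.pop()
    kt = KB_KJ * temperature
    i = int(rng.integers(0, len(replicas) - 1))
    j = i + 1
    xi, bi = replicas[i]
    xj, bj = replicas[j]
    si, sj = float(xi), float(xj)
    current = bias_value(bi, si) + bias_value(bj, sj)
    swapped = bias_value(bi, sj) + bias_value(bj, si)
    prob = min(1.0, float(np.exp(-(swapped - current) / kt)))
    accepted = rng.random() < prob
    out = list(replicas)
    if accepted:
        out[i] = (xj, bi)
        out[j] = (xi, bj)
    log = {"pair": (i, j), "probability": prob, "accepted": bool(accepted)}
    return out, log


# ---------------------------------------------------------------------------
# HILLS-style plain-text persistence
# ---------------------------------------------------------------------------


def write_hills(path, bias: MetadBias, dt: float = 1.0) -> None:
    """Persist the hill history as a PLUMED-HILLS-like text table."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time center sigma height biasf\n")
        for h in bias.hills:
            fh.write(
                f"{h.deposit_step * dt:.4f} {h.center:.6f} {h.width:.6f} "
                f"{h.height:.6f} {bias.bias_factor:.3f}\n"
            )


def read_hills(path, pace: int = 1000, temperature: float = 300.0,
               dt: float = 1.0, periodic: bool = False) -> MetadBias:
    """Read a HILLS-style file written by :func:`write_hills`."""
    hills = []
    bias_factor = 10.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            t, c, w, h, bf = (float(v) for v in line.split())
            bias_factor = bf
            hills.append(HillRecord(center=c, height=h, width=w,
                                    deposit_step=int(round(t / dt))))
    return MetadBias(hills=hills, bias_factor=bias_factor, pace=pace,
                     temperature=temperature, periodic=periodic)
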