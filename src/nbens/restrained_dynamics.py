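"""Toy bead-chain Langevin dynamics with flat-bottom distance restraints,
either instantaneous or driven by an exponential-memory time average.

The integrator is BAOAB Langevin on a harmonic bead chain (one bead per
residue); with friction -> 0 it reduces to plain velocity Verlet, which
keeps total energy bounded (symplectic sanity check).  Time-averaged
restraints maintain an exponentially weighted running average of r^-p
(memory constant tau) and derive the restraint force from the averaged
distance rather than the instantaneous one, letting the system make
transient excursions above the upper limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import KB_KJ
from .structure_io import (
    Atom,
    DistanceRestraint,
    StructureModel,
    Trajectory,
)

__all__ = [
    "RestraintMemory",
    "FlatBottomRestraint",
    "ChainSystem",
    "chain_topology",
    "memory_update",
    "restraint_energy_force",
    "run_restrained",
]

#: 1 kJ/mol expressed in amu Å^2 ps^-2 (the integrator's internal units)
KJ_TO_INTERNAL = 100.0


# ---------------------------------------------------------------------------
# Exponential-memory distance averaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RestraintMemory:
    """Running r^-p average with exponential memory.

    ``m`` holds the current average of r^-p (None before the first
    update); ``r_bar = m**(-1/p)``.  With constant input the fixed point
    is the input itself; with alternating inputs and dt << tau the average
    converges to the stationary power mean.
    """

    tau: float  # ps
    p: int = 3
    m: float | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.p not in (1, 3, 6):
            raise ValueError("averaging exponent p must be 1, 3 or 6")

    @property
    def r_bar(self) -> float:
        if self.m is None:
            raise ValueError("memory not initialized; no update applied yet")
        return self.m ** (-1.0 / self.p)


def memory_update(state: RestraintMemory, r_t: float, dt: float,
                  ) -> RestraintMemory:
    """One exponential-memory update with the instantaneous distance r_t.

    m <- m * exp(-dt/tau) + r_t^-p * (1 - exp(-dt/tau)); the first update
    initializes m = r_t^-p.  The update is independent of how dt is
    partitioned when r is constant over the interval.
    """
    if r_t <= 0:
        raise ValueError("distance must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rp = r_t ** (-float(state.p))
    if state.m is None:
        return replace(state, m=rp)
    decay = np.exp(-dt / state.tau)
    return replace(state, m=state.m * decay + rp * (1.0 - decay))


# ---------------------------------------------------------------------------
# Flat-bottom upper-limit restraint
# ---------------------------------------------------------------------------


@dataclass
class FlatBottomRestraint:
    """Half-harmonic upper-limit restraint: zero inside [0, U]."""

    restraint: DistanceRestraint
    force_constant: float = 20.0  # kJ/(mol Å^2)

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")

    @property
    def upper_limit(self) -> float:
        return self.restraint.upper_limit


def restraint_energy_force(r_bar: float, fb: FlatBottomRestraint,
                           ) -> tuple[float, float]:
    """Energy (kJ/mol) and radial force -dE/dr at the averaged distance.

    E = 0 for r <= U and 1/2 k (r - U)^2 beyond; both energy and force
    are continuous at the limit.  The returned force is negative
    (attractive along the pair vector) when the limit is exceeded.
    """
    if r_bar <= 0:
        raise ValueError("distance must be positive")
    u = fb.upper_limit
    if r_bar <= u:
        return 0.0, 0.0
    excess = r_bar - u
    energy = 0.5 * fb.force_constant * excess**2
    force = -fb.force_constant * excess
    return energy, force


# ---------------------------------------------------------------------------
# Bead-chain system
# ---------------------------------------------------------------------------


def chain_topology(n_atoms: int, residue_name: str = "ALA") -> StructureModel:
    """One CA bead per residue, residues numbered from 1."""
    atoms = [
        Atom(name="CA", element="C", residue_index=i + 1,
             residue_name=residue_name, coordinates=np.zeros(3))
        for i in range(n_atoms)
    ]
    return StructureModel(atoms=atoms, model_id=1)


@dataclass
class ChainSystem:
    """Harmonic bead chain: neighbours bonded at ``bond_length`` Å."""

    n_atoms: int
    bond_length: float = 3.8  # Å
    k_bond: float = 100.0  # kJ/(mol Å^2)
    mass: float = 12.0  # amu per bead
    temperature: float = 300.0  # K
    friction: float = 1.0  # ps^-1
    dt: float = 0.002  # ps

    def __post_init__(self):
        if self.n_atoms < 2:
            raise ValueError("chain needs at least 2 beads")

    def initial_coordinates(self) -> np.ndarray:
        x = np.zeros((self.n_atoms, 3))
        x[:, 0] = np.arange(self.n_atoms) * self.bond_length
        return x

    def bond_energy_forces(self, coords: np.ndarray,
                           ) -> tuple[float, np.ndarray]:
        d = coords[1:] - coords[:-1]
        r = np.linalg.norm(d, axis=1)
        stretch = r - self.bond_length
        energy = 0.5 * self.k_bond * np.sum(stretch**2)
        f_pair = (-self.k_bond * stretch / r)[:, None] * d
        forces = np.zeros_like(coords)
        forces[1:] += f_pair
        forces[:-1] -= f_pair
        return float(energy), forces


def _resolve_bead_pair(topology: StructureModel, restraint: DistanceRestraint,
                       ) -> tuple[int, int]:
    a = restraint.group_a[0]
    b = restraint.group_b[0]
    ia = topology.atom_index(a.residue_index, "CA")
    ib = topology.atom_index(b.residue_index, "CA")
    if ia is None or ib is None:
        raise KeyError(
            f"restraint residues {a.residue_index}/{b.residue_index} not in "
            "the toy chain topology"
        )
    return ia, ib


def run_restrained(system: ChainSystem,
                   restraints: list[FlatBottomRestraint],
                   mode: str = "instantaneous",
                   tau: float = 100.0,
                   p: int = 3,
                   n_steps: int = 10000,
                   seed: int = 0,
                   coords0: np.ndarray | None = None,
                   blowup_bound: float = 1e4,
                   ) -> tuple[Trajectory, np.ndarray]:
    """Langevin dynamics of the chain with upper-limit restraints.

    ``mode`` is ``"instantaneous"`` (force from the current distance) or
    ``"time_averaged"`` (force from the exponential-memory average with
    time constant ``tau`` ps and exponent ``p``; the force acts along the
    instantaneous pair vector).  Returns the trajectory (n_steps + 1
    frames, including the start) and the per-step total restraint energy.
    """
    if mode not in ("instantaneous", "time_averaged"):
        raise ValueError("mode must be 'instantaneous' or 'time_averaged'")
    topology = chain_topology(system.n_atoms)
    pairs = [_resolve_bead_pair(topology, fb.restraint) for fb in restraints]

    rng = np.random.default_rng(seed)
    dt = system.dt
    kt_int = KB_KJ * system.temperature * KJ_TO_INTERNAL
    c1 = np.exp(-system.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1**2)) * np.sqrt(kt_int / system.mass)

    x = (coords0.copy() if coords0 is not None
         else system.initial_coordinates())
    v = np.zeros_like(x)
    memories = [RestraintMemory(tau=tau, p=p) for _ in restraints]

    def restraint_forces(coords, mems):
        forces = np.zeros_like(coords)
        energy = 0.0
        new_mems = []
        for (ia, ib), fb, mem in zip(pairs, restraints, mems):
            d = coords[ib] - coords[ia]
            r = float(np.linalg.norm(d))
            if mode == "time_averaged":
                mem = memory_update(mem, r, dt)
                r_drive = mem.r_bar
            else:
                r_drive = r
            e, f_radial = restraint_energy_force(r_drive, fb)
            energy += e
            unit = d / r
            forces[ib] += f_radial * unit
            forces[ia] -= f_radial * unit
            new_mems.append(mem)
        return energy, forces, new_mems

    frames = np.empty((n_steps + 1,) + x.shape)
    frames[0] = x
    energies = np.empty(n_steps + 1)
    _, bond_f = system.bond_energy_forces(x)
    e_r, rest_f, memories = restraint_forces(x, memories)
    energies[0] = e_r
    force = (bond_f + rest_f) * KJ_TO_INTERNAL  # amu Å ps^-2

    for t in range(n_steps):
        v = v + 0.5 * dt * force / system.mass
        x = x + 0.5 * dt * v
        if system.friction > 0:
            v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v
        if np.max(np.abs(x)) > blowup_bound:
            raise FloatingPointError(
                f"integrator blow-up at step {t}: coordinate beyond "
                f"{blowup_bound} Å"
            )
        _, bond_f = system.bond_energy_forces(x)
        e_r, rest_f, memories = restraint_forces(x, memories)
        force = (bond_f + rest_f) * KJ_TO_INTERNAL
        v = v + 0.5 * dt * force / system.mass
        frames[t + 1] = x
        energies[t + 1] = e_r

    traj = Trajectory(frames=frames, dt=dt, topology=topology,
                      kind="cartesian")
    return traj, energies
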