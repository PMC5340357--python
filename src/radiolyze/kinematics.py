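"""Unit conversions and projectile energetics.

Internal units are Å, fs, eV and unified atomic mass units (u).  With those,
kinetic energy is ``½ m v²`` with ``m`` in u and ``v`` in Å/fs, times the
conversion factor ``EV_PER_AMU_A2_FS2``.  The canonical speed unit at the
interface is Bohr/fs: a 12.011 u carbon at 1, 2, 3, 4 Bohr/fs carries 174,
698, 1570, 2790 eV, matching the nominal 175 eV / 700 eV / 1.6 keV / 2.8 keV
grid within 1.5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import Frame, Trajectory

__all__ = [
    "BOHR_IN_ANGSTROM",
    "EV_PER_AMU_A2_FS2",
    "CARBON_MASS_U",
    "ATOMIC_MASSES_U",
    "speed_to_energy",
    "energy_to_speed",
    "kinetic_energy_of",
    "EnergyLossProfile",
    "energy_loss_profile",
    "FinalKEStatus",
    "FinalKE",
    "final_kinetic_energy",
]

BOHR_IN_ANGSTROM = 0.529177  # Å per Bohr
EV_PER_AMU_A2_FS2 = 103.6427  # eV per u·(Å/fs)²
CARBON_MASS_U = 12.011

ATOMIC_MASSES_U = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}


def speed_to_energy(speed: float, mass: float = CARBON_MASS_U) -> float:
    """Kinetic energy (eV) of a particle at ``speed`` Bohr/fs and ``mass`` u."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    v = speed * BOHR_IN_ANGSTROM  # Å/fs
    out = 0.5 * mass * v * v * EV_PER_AMU_A2_FS2
    return float(out) if out.ndim == 0 else out


def energy_to_speed(energy: float, mass: float = CARBON_MASS_U) -> float:
    """Speed (Bohr/fs) of a particle with kinetic ``energy`` eV and ``mass`` u."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < 0):
        raise ValueError("energy must be non-negative")
    v = np.sqrt(2.0 * energy / (mass * EV_PER_AMU_A2_FS2))  # Å/fs
    out = v / BOHR_IN_ANGSTROM
    return float(out) if out.ndim == 0 else out


def kinetic_energy_of(frame: Frame, atom: int) -> float:
    """Kinetic energy in eV of one atom in a frame (requires velocities)."""
    if frame.velocities is None:
        raise ValueError(
            "frame has no velocities; regenerate tracks with velocities enabled"
        )
    m = ATOMIC_MASSES_U[str(frame.symbols[atom])]
    v2 = float(np.dot(frame.velocities[atom], frame.velocities[atom]))
    return 0.5 * m * v2 * EV_PER_AMU_A2_FS2


@dataclass
class EnergyLossProfile:
    """Cumulative projectile energy loss sampled at every frame.

    ``x`` is the projectile x coordinate (Å); samples keep time order, so x
    may decrease on backscattered segments.  ``loss[0]`` is 0 by construction.
    """

    x: np.ndarray  # Å, projectile coordinate per frame
    time: np.ndarray  # fs
    loss: np.ndarray  # eV, cumulative KE loss, loss[0] == 0
    initial_ke: float  # eV

    @property
    def terminal_loss(self) -> float:
        return float(self.loss[-1])


def energy_loss_profile(traj: Trajectory) -> EnergyLossProfile:
    """Energy lost by the projectile vs its x position, one sample per frame."""
    pidx = traj.projectile_index
    if pidx is None:
        raise ValueError("trajectory has no projectile")
    ke = np.empty(traj.n_frames)
    x = np.empty(traj.n_frames)
    t = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        ke[k] = kinetic_energy_of(frame, pidx)
        x[k] = frame.positions[pidx, 0]
        t[k] = frame.time
    return EnergyLossProfile(x=x, time=t, loss=ke[0] - ke, initial_ke=float(ke[0]))


class FinalKEStatus(Enum):
    EXITED = "exited"
    STOPPED = "stopped"
    INDETERMINATE = "indeterminate"


@dataclass
class FinalKE:
    """Terminal state of the projectile: energy if it exited, else a marker."""

    status: FinalKEStatus
    energy: float | None = None  # eV, defined when status == EXITED

    @property
    def stopped(self) -> bool:
        return self.status is FinalKEStatus.STOPPED


def final_kinetic_energy(
    traj: Trajectory,
    slab_interval: tuple[float, float] | None = None,
    buffer: float = 2.0,
    stop_threshold: float = 1.0,
    stop_window: float = 50.0,
) -> FinalKE:
    """Classify the terminal projectile state and measure its exit energy.

    Exited: the projectile crossed ``x_exit + buffer``; the energy is the mean
    kinetic energy over all post-exit frames.  Stopped: kinetic energy below
    ``stop_threshold`` eV sustained for at least ``stop_window`` fs while the
    projectile is inside the slab.  Anything else (a run truncated mid-slab
    with energy left) is INDETERMINATE.
    """
    if slab_interval is None:
        slab_interval = traj.slab_interval
    if slab_interval is None:
        raise ValueError("slab_interval not given and absent from trajectory")
    x_exit = slab_interval[1]
    prof = energy_loss_profile(traj)
    ke = prof.initial_ke - prof.loss
    out_mask = prof.x > x_exit + buffer
    if np.any(out_mask):
        return FinalKE(FinalKEStatus.EXITED, float(np.mean(ke[out_mask])))
    inside = (prof.x >= slab_interval[0]) & (prof.x <= x_exit)
    low = ke < stop_threshold
    trailing = low & inside
    if trailing[-1]:
        # duration of the trailing low-energy stretch
        k = len(trailing) - 1
        while k > 0 and trailing[k - 1]:
            k -= 1
        if prof.time[-1] - prof.time[k] >= stop_window:
            return FinalKE(FinalKEStatus.STOPPED)
    return FinalKE(FinalKEStatus.INDETERMINATE)
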