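"""Charge-state labels for fragments from per-atom electron populations.

Coordination numbers say nothing about charge: an OH fragment may be a
radical or an anion, a lone H an atom or a proton.  Mulliken-style electron
populations, consumed as input, settle this.  For hydrogen the working rules
are: a population of 0.9–1 electron marks a neutral atom, below 0.4 a
proton (the residue accounts for H basis functions serving neighbouring
molecules), and around 0.7 a hydrogen covalently bound inside a molecule.
Populations between 0.4 and 0.9 on an *unbound* H are reported as ambiguous,
never silently binned.  Oxygen fragments get raw populations only — no
threshold convention exists for them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusSeries
from .io import Frame, Trajectory
from .kinematics import ATOMIC_MASSES_U, EV_PER_AMU_A2_FS2

__all__ = [
    "PopulationThresholds",
    "CHARGE_LABELS",
    "group_population",
    "classify_hydrogen_charge",
    "charge_census",
]

CHARGE_LABELS = ("neutral_atom", "cation_like", "molecular_bound", "ambiguous")


@dataclass
class PopulationThresholds:
    """Electron-population cut points for hydrogen charge labels."""

    neutral_min: float = 0.9  # electrons; >= this is a neutral atom
    proton_max: float = 0.4  # electrons; <= this is cation-like

    def __post_init__(self) -> None:
        if not (0 < self.proton_max < self.neutral_min <= 1.2):
            raise ValueError("need 0 < proton_max < neutral_min <= 1.2")


def group_population(frame: Frame, atoms) -> float:
    """Total electron population of a set of atoms (a molecule, radical, ion).

    Summing over a whole fragment suppresses the per-atom ambiguity of any
    population partitioning.
    """
    if frame.populations is None:
        raise ValueError("frame has no populations")
    atoms = list(atoms)
    if not atoms:
        return 0.0
    return float(np.sum(frame.populations[atoms]))


def classify_hydrogen_charge(
    population: float,
    thresholds: PopulationThresholds | None = None,
    molecular_bound: bool = False,
) -> str:
    """Label one hydrogen from its electron population.

    ``molecular_bound`` states whether the census sees this H inside a
    molecule; only then does an intermediate population read as ordinary
    covalent sharing rather than an ambiguous lone atom.
    """
    if thresholds is None:
        thresholds = PopulationThresholds()
    if population < 0:
        raise ValueError("population must be non-negative")
    if population >= thresholds.neutral_min:
        return "neutral_atom"
    if population <= thresholds.proton_max:
        return "cation_like"
    return "molecular_bound" if molecular_bound else "ambiguous"


def charge_census(
    traj: Trajectory,
    census: CensusSeries,
    thresholds: PopulationThresholds | None = None,
    hyperthermal_ke: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Charge labels for every isolated H and OH fragment, per frame.

    Returns ``(table, summary)``: one row per (frame, fragment) with the
    fragment's kinetic energy, population and label, and a summary of label
    fractions for hydrogen fragments split into hyperthermal vs slow at
    ``hyperthermal_ke`` eV.
    """
    if thresholds is None:
        thresholds = PopulationThresholds()
    if traj.frames[0].populations is None:
        raise ValueError("trajectory has no populations")
    rows = []
    for k, (frame, inv) in enumerate(zip(traj.frames, census.inventories)):
        has_vel = frame.velocities is not None
        labels = inv.labels
        for a in np.nonzero(labels == "H_isolated")[0]:
            pop = float(frame.populations[a])
            ke = _atom_ke(frame, int(a)) if has_vel else np.nan
            rows.append(
                {
                    "frame": k,
                    "time": frame.time,
                    "fragment_id": f"H:{int(a)}",
                    "species": "H_isolated",
                    "ke_eV": ke,
                    "population": pop,
                    "label": classify_hydrogen_charge(pop, thresholds),
                }
            )
        for a in np.nonzero((labels == "OH") & (frame.symbols == "O"))[0]:
            members = [int(a)] + _bonded_h(frame, census, k, int(a))
            pop = group_population(frame, members)
            ke = (
                sum(_atom_ke(frame, m) for m in members) if has_vel else np.nan
            )
            rows.append(
                {
                    "frame": k,
                    "time": frame.time,
                    "fragment_id": f"OH:{int(a)}",
                    "species": "OH",
                    "ke_eV": ke,
                    "population": pop,
                    # no threshold convention for O-bearing fragments:
                    # report the population, label stays descriptive
                    "label": "unassigned_O_fragment",
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "time",
            "fragment_id",
            "species",
            "ke_eV",
            "population",
            "label",
        ],
    )
    h = table[table["species"] == "H_isolated"]
    if len(h):
        speed_class = np.where(h["ke_eV"] > hyperthermal_ke, "hyperthermal", "slow")
        summary = (
            h.assign(speed_class=speed_class)
            .groupby(["speed_class", "label"])
            .size()
            .rename("n")
            .reset_index()
        )
        totals = summary.groupby("speed_class")["n"].transform("sum")
        summary["fraction"] = summary["n"] / totals
    else:
        summary = pd.DataFrame(columns=["speed_class", "label", "n", "fraction"])
    return table, summary


def _atom_ke(frame: Frame, atom: int) -> float:
    m = ATOMIC_MASSES_U[str(frame.symbols[atom])]
    v = frame.velocities[atom]
    return 0.5 * m * float(np.dot(v, v)) * EV_PER_AMU_A2_FS2


def _bonded_h(frame: Frame, census: CensusSeries, k: int, o_atom: int) -> list[int]:
    # the OH label guarantees exactly one H within cutoff; find it cheaply
    pos = frame.positions
    box = frame.box
    h_idx = np.nonzero(frame.symbols == "H")[0]
    d = pos[h_idx] - pos[o_atom]
    d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=1)
    close = h_idx[dist <= 1.2]
    return [int(a) for a in close[:1]]
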