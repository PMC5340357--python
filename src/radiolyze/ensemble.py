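"""Ensemble aggregation: species curves, final-energy histograms, nuclear
stopping power and fragment production spacings.

The stopping estimate follows the slab convention: the energy deposited along
each trajectory divided by the slab width, averaged over the ensemble, with
stopped projectiles contributing their full initial energy.  Production
spacing is the ratio estimator (total in-slab track length) / (total
creations of the species), with a bootstrap confidence interval over
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusSeries, CutoffTable, census_vs_projectile
from .io import Trajectory
from .kinematics import FinalKE, FinalKEStatus, final_kinetic_energy

__all__ = [
    "EnsembleSummary",
    "FinalKEHistogram",
    "SpacingResult",
    "average_species_curves",
    "final_ke_histogram",
    "nuclear_stopping",
    "production_spacing",
    "traversed_length",
]


def _check_single_speed(trajectories) -> None:
    speeds = {t.initial_speed for t in trajectories}
    if len(speeds) > 1:
        raise ValueError(f"mixed initial speeds in ensemble: {sorted(speeds)}")


def _censuses(trajectories, censuses, cutoffs):
    if censuses is None:
        cutoffs = cutoffs or CutoffTable.preset("paper-literal")
        censuses = [census_vs_projectile(t, cutoffs) for t in trajectories]
    return censuses


def average_species_curves(
    trajectories: list[Trajectory],
    bin_width: float = 1.0,
    censuses: list[CensusSeries] | None = None,
    cutoffs: CutoffTable | None = None,
) -> pd.DataFrame:
    """Mean species counts per projectile-x bin, averaged over trajectories.

    Bins a trajectory never visits do not contribute to its average; the
    returned frame has one row per visited bin with per-species mean counts
    and the number of contributing trajectories (``n_traj``).
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    _check_single_speed(trajectories)
    censuses = _censuses(trajectories, censuses, cutoffs)
    per_traj = []
    for cs in censuses:
        df = cs.counts_frame()
        df = df[np.isfinite(df["projectile_x"])]
        df["bin"] = np.floor(df["projectile_x"] / bin_width).astype(int)
        per_traj.append(df.drop(columns=["projectile_x", "time"]).groupby("bin").mean())
    allbins = pd.concat(per_traj, keys=range(len(per_traj)))
    mean = allbins.groupby(level="bin").mean()
    mean["n_traj"] = allbins.groupby(level="bin").size()
    mean.insert(0, "x", (mean.index + 0.5) * bin_width)
    return mean.reset_index(drop=True)


@dataclass
class FinalKEHistogram:
    bin_edges: np.ndarray  # eV
    counts: np.ndarray
    stopped_count: int
    indeterminate_count: int
    energies: np.ndarray  # eV, exiting trajectories only

    @property
    def n_trajectories(self) -> int:
        return int(self.counts.sum()) + self.stopped_count


def final_ke_histogram(
    trajectories: list[Trajectory],
    bin_width: float = 25.0,
    finals: list[FinalKE] | None = None,
) -> FinalKEHistogram:
    """Histogram of exit kinetic energies; stopped projectiles tallied apart."""
    if not trajectories:
        raise ValueError("empty ensemble")
    if finals is None:
        finals = [final_kinetic_energy(t) for t in trajectories]
    energies = np.array(
        [f.energy for f in finals if f.status is FinalKEStatus.EXITED]
    )
    stopped = sum(f.status is FinalKEStatus.STOPPED for f in finals)
    indet = sum(f.status is FinalKEStatus.INDETERMINATE for f in finals)
    if len(energies):
        top = float(np.max(energies))
        edges = np.arange(0.0, top + 2 * bin_width, bin_width)
        counts, edges = np.histogram(energies, bins=edges)
    else:
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=int)
    return FinalKEHistogram(
        bin_edges=edges,
        counts=counts,
        stopped_count=int(stopped),
        indeterminate_count=int(indet),
        energies=energies,
    )


def nuclear_stopping(
    trajectories: list[Trajectory],
    slab_width: float | None = None,
    initial_kes: list[float] | None = None,
    finals: list[FinalKE] | None = None,
) -> tuple[float, float]:
    """Nuclear stopping power (eV/Å) with its standard error.

    Per trajectory the deposit is E0 − E_final for exits and the full E0 for
    stopped projectiles (the ratio definition implies full deposition);
    indeterminate runs are excluded.  ``slab_width`` defaults to the
    trajectories' slab interval — the water region, not the vacuum.
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    if slab_width is None:
        iv = trajectories[0].slab_interval
        if iv is None:
            raise ValueError("slab_width not given and absent from trajectories")
        slab_width = iv[1] - iv[0]
    if slab_width <= 0:
        raise ValueError("slab_width must be positive")
    if finals is None:
        finals = [final_kinetic_energy(t) for t in trajectories]
    if initial_kes is None:
        from .kinematics import energy_loss_profile

        initial_kes = [energy_loss_profile(t).initial_ke for t in trajectories]
    deposits = []
    for e0, f in zip(initial_kes, finals):
        if f.status is FinalKEStatus.EXITED:
            deposits.append(e0 - f.energy)
        elif f.status is FinalKEStatus.STOPPED:
            deposits.append(e0)
    if not deposits:
        raise ValueError("no determinate trajectories")
    dep = np.asarray(deposits) / slab_width
    se = float(np.std(dep, ddof=1) / np.sqrt(len(dep))) if len(dep) > 1 else 0.0
    return float(np.mean(dep)), se


def traversed_length(traj: Trajectory, census: CensusSeries | None = None) -> float:
    """In-slab path length of the projectile (Å): to the exit face, or to
    where it stopped."""
    iv = traj.slab_interval
    if iv is None:
        raise ValueError("trajectory lacks slab_interval")
    pidx = traj.projectile_index
    xs = np.array([f.positions[pidx, 0] for f in traj.frames])
    x_max = float(np.max(xs))
    return float(np.clip(x_max, iv[0], iv[1]) - iv[0])


@dataclass
class SpacingResult:
    """Mean track length per creation of one species, with bootstrap CI."""

    species: str
    mean_spacing: float | None  # Å; None when the species was never created
    se: float | None  # bootstrap standard error
    ci_low: float | None  # 2.5 %
    ci_high: float | None  # 97.5 %
    total_length: float  # Å
    total_creations: int

    @property
    def defined(self) -> bool:
        return self.mean_spacing is not None


def production_spacing(
    trajectories: list[Trajectory],
    species: str,
    censuses: list[CensusSeries] | None = None,
    cutoffs: CutoffTable | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> SpacingResult:
    """Mean distance between cumulative creations of ``species``.

    Computed as Σ(track length) / Σ(creations) over the ensemble; creations
    are cumulative (a later-recombined fragment still counts).  The bootstrap
    resamples whole trajectories.
    """
    if not trajectories:
        raise ValueError("empty ensemble")
    censuses = _censuses(trajectories, censuses, cutoffs)
    lengths = np.array([traversed_length(t) for t in trajectories])
    creations = np.array(
        [len(cs.creations_of(species)) for cs in censuses], dtype=float
    )
    total_len = float(np.sum(lengths))
    total_crea = int(np.sum(creations))
    if total_crea == 0:
        return SpacingResult(species, None, None, None, None, total_len, 0)
    rng = np.random.default_rng(seed)
    n = len(trajectories)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c = creations[idx].sum()
        if c > 0:
            boots.append(lengths[idx].sum() / c)
    boots = np.array(boots)
    return SpacingResult(
        species=species,
        mean_spacing=total_len / total_crea,
        se=float(np.std(boots, ddof=1)),
        ci_low=float(np.percentile(boots, 2.5)),
        ci_high=float(np.percentile(boots, 97.5)),
        total_length=total_len,
        total_creations=total_crea,
    )
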