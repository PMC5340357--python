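import numpy as np
import pytest

import radiolyze as rz
from radiolyze.census import CensusSeries, Creation
from radiolyze.kinematics import FinalKE, FinalKEStatus


def _line_trajectory(length=15.0, n=4):
    """A bare projectile crossing a slab of the given length."""
    frames = []
    for k in range(n):
        x = length * k / (n - 1)
        frames.append(
            rz.Frame(
                k,
                float(k),
                [2 * length, 10, 10],
                ["C"],
                [[x, 5, 5]],
                velocities=[[1.0, 0, 0]],
                projectile_index=0,
            )
        )
    return rz.Trajectory(frames=frames, initial_speed=1.0, slab_interval=(0.0, length))


def _census_stub(traj, xs):
    nf = traj.n_frames
    creations = [
        Creation(species="H_isolated", atom=0, frame=0, time=0.0, projectile_x=x)
        for x in xs
    ]
    return CensusSeries(
        projectile_x=np.array([f.positions[0, 0] for f in traj.frames]),
        times=np.array([f.time for f in traj.frames]),
        inventories=[],
        creations=creations,
        symbols=traj.frames[0].symbols,
    )


def test_spacing_of_three_creations_over_fifteen_angstrom():
    traj = _line_trajectory(15.0)
    cs = _census_stub(traj, [5.0, 10.0, 15.0])
    res = rz.production_spacing([traj], "H_isolated", censuses=[cs])
    assert res.mean_spacing == pytest.approx(5.0)
    assert res.total_creations == 3


def test_spacing_undefined_without_creations():
    traj = _line_trajectory()
    res = rz.production_spacing([traj], "OH", censuses=[_census_stub(traj, [])])
    assert not res.defined
    assert res.mean_spacing is None


def test_bootstrap_interval_covers_true_spacing():
    """95% CI coverage of the ratio estimator on a known renewal process."""
    rng = np.random.default_rng(0)
    true_spacing = 5.0
    length = 15.0
    hits = 0
    reps = 60
    for rep in range(reps):
        trajs, censuses = [], []
        for _ in range(30):
            traj = _line_trajectory(length)
            k = rng.poisson(length / true_spacing)
            censuses.append(_census_stub(traj, list(rng.uniform(0, length, k))))
            trajs.append(traj)
        res = rz.production_spacing(
            trajs, "H_isolated", censuses=censuses, n_boot=200, seed=rep
        )
        if res.ci_low <= true_spacing <= res.ci_high:
            hits += 1
    assert hits / reps >= 0.9


def test_histogram_of_lossless_ensemble_is_a_single_bin():
    params = rz.GeneratorParams(
        n_molecules=12, p_single=0.0, p_double=0.0, continuous_loss_rate=0.0, seed=0
    )
    trajs = [
        rz.generate_track(params, 2.0, (5.0, 5.0), seed=s)[0] for s in range(4)
    ]
    hist = rz.final_ke_histogram(trajs, bin_width=25.0)
    assert hist.stopped_count == 0
    assert (hist.counts > 0).sum() == 1
    assert hist.counts.sum() == 4


def test_histogram_counts_stopped_separately(mini_ensemble):
    trajs, logs, _ = mini_ensemble
    hist = rz.final_ke_histogram(trajs)
    assert hist.stopped_count == sum(l.stopped for l in logs)
    assert hist.n_trajectories == len(trajs) - hist.indeterminate_count


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError):
        rz.final_ke_histogram([])
    with pytest.raises(ValueError):
        rz.nuclear_stopping([])


def test_full_deposition_gives_e0_over_width():
    trajs = [_line_trajectory() for _ in range(5)]
    finals = [FinalKE(FinalKEStatus.STOPPED)] * 5
    val, se = rz.nuclear_stopping(
        trajs, slab_width=10.0, initial_kes=[100.0] * 5, finals=finals
    )
    assert val == pytest.approx(10.0)
    assert se == 0.0


def test_stopping_consistency_with_mean_deposit(mini_ensemble):
    trajs, logs, _ = mini_ensemble
    width = trajs[0].slab_interval[1] - trajs[0].slab_interval[0]
    val, _ = rz.nuclear_stopping(trajs)
    deposits = [l.initial_ke - l.final_ke for l in logs]
    assert val == pytest.approx(np.mean(deposits) / width, rel=1e-6)


def test_mixed_speeds_rejected(mini_ensemble):
    trajs, _, _ = mini_ensemble
    other = _line_trajectory()
    other.initial_speed = 3.0
    with pytest.raises(ValueError, match="mixed"):
        rz.average_species_curves([trajs[0], other])


def test_identical_copies_average_to_single_census(double_track):
    traj, _ = double_track
    cs = rz.census_vs_projectile(traj)
    curves = rz.average_species_curves([traj] * 3, bin_width=2.0, censuses=[cs] * 3)
    single = rz.average_species_curves([traj], bin_width=2.0, censuses=[cs])
    for col in ("H2O", "OH", "O_isolated", "H_isolated"):
        np.testing.assert_allclose(curves[col], single[col])


def test_low_speed_ensemble_h_production_exceeds_oh(mini_ensemble):
    # double-dissociation events add H atoms without adding hydroxyls
    _, _, censuses = mini_ensemble
    n_h = sum(len(cs.creations_of("H_isolated")) for cs in censuses)
    n_oh = sum(len(cs.creations_of("OH")) for cs in censuses)
    assert n_h > n_oh
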