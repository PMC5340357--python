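import numpy as np
import pytest

import radiolyze as rz
from radiolyze.events import EventParams, CollisionEvent, TrajectoryClass
from radiolyze.kinematics import EnergyLossProfile, FinalKE, FinalKEStatus


def profile_from(loss, dx=1.0):
    loss = np.asarray(loss, dtype=float)
    x = np.arange(len(loss)) * dx
    return EnergyLossProfile(x=x, time=x.copy(), loss=loss, initial_ke=700.0)


def discrete(events):
    return [e for e in events if e.x_end is None and e.channel != "elastic_only"]


def test_event_params_validation():
    with pytest.raises(ValueError):
        EventParams(step_threshold=-1)
    with pytest.raises(ValueError):
        EventParams(restoration_fraction=0.0)


def test_step_profile_yields_one_event_with_full_transfer():
    loss = np.zeros(30)
    loss[10:12] = (10.0, 20.0)
    loss[12:] = 30.0
    events = rz.detect_events(profile_from(loss))
    d = discrete(events)
    assert len(d) == 1
    assert d[0].transfer == pytest.approx(30.0, abs=1e-9)
    assert sum(e.transfer for e in events) == pytest.approx(30.0)


def test_restored_excursion_separates_peak_from_transfer():
    loss = np.zeros(30)
    loss[10] = 80.0
    loss[11:] = 30.0
    events = rz.detect_events(profile_from(loss))
    d = discrete(events)
    assert len(d) == 1
    assert d[0].transfer == pytest.approx(30.0, abs=1e-9)
    assert d[0].peak_height == pytest.approx(50.0, abs=1e-9)


def test_linear_ramp_is_continuous_not_discrete():
    ramp = np.concatenate([np.zeros(5), np.linspace(0, 40, 16)[1:], np.full(8, 40.0)])
    events = rz.detect_events(profile_from(ramp))
    assert discrete(events) == []
    segs = [e for e in events if e.channel == "vibrational"]
    assert len(segs) == 1
    assert segs[0].transfer == pytest.approx(40.0)


def test_pure_elastic_peak_detected_as_elastic_only():
    loss = np.zeros(30)
    loss[15] = 25.0  # fully restored
    events = rz.detect_events(profile_from(loss))
    el = [e for e in events if e.channel == "elastic_only"]
    assert len(el) == 1
    assert el[0].peak_height == pytest.approx(25.0)
    assert el[0].transfer == 0.0


def test_profile_shorter_than_window_rejected():
    with pytest.raises(ValueError):
        rz.detect_events(profile_from([0.0, 1.0]))


def test_transfer_sum_closes_against_terminal_loss(mini_ensemble):
    trajs, _, censuses = mini_ensemble
    for traj, cs in zip(trajs, censuses):
        prof = rz.energy_loss_profile(traj)
        events = rz.annotate_channels(rz.detect_events(prof), cs)
        assert sum(e.transfer for e in events) == pytest.approx(
            prof.terminal_loss, abs=1e-6
        )


def test_detected_dissociative_counts_match_truth(mini_ensemble):
    trajs, logs, censuses = mini_ensemble
    ok = 0
    for traj, log, cs in zip(trajs, logs, censuses):
        events = rz.annotate_channels(
            rz.detect_events(rz.energy_loss_profile(traj)), cs
        )
        ndet = sum(
            (e.n_single + e.n_double)
            or (1 if e.channel in ("single_dissociation", "double_dissociation") else 0)
            for e in events
        )
        if abs(ndet - len(log.dissociative_events)) <= 1:
            ok += 1
    assert ok / len(trajs) >= 0.95


@pytest.mark.parametrize(
    "channel,transfer,cost,budget,frac",
    [
        ("single_dissociation", 50.0, 5.0, 45.0, 0.10),
        ("double_dissociation", 150.0, 9.4, 140.6, 9.4 / 150.0),
    ],
)
def test_energy_partition(channel, transfer, cost, budget, frac):
    ev = CollisionEvent(x=0, time=0, transfer=transfer, channel=channel)
    part = rz.event_energy_partition(ev)
    assert part.consistent
    assert part.binding_cost == pytest.approx(cost)
    assert part.fragment_budget == pytest.approx(budget)
    assert part.fraction == pytest.approx(frac)


def test_partition_flags_transfer_below_binding():
    ev = CollisionEvent(x=0, time=0, transfer=4.0, channel="single_dissociation")
    assert not rz.event_energy_partition(ev).consistent


def _exited(e=100.0):
    return FinalKE(FinalKEStatus.EXITED, e)


def test_trajectory_classification_map():
    single = CollisionEvent(x=1, time=1, transfer=30, channel="single_dissociation")
    double = CollisionEvent(x=1, time=1, transfer=120, channel="double_dissociation")
    seg = CollisionEvent(x=0, time=0, transfer=40, channel="vibrational", x_end=15.0)
    assert (
        rz.classify_trajectory([], _exited(), total_loss=3.0).label
        is TrajectoryClass.NON_DISSOCIATIVE_TRANSIT
    )
    assert (
        rz.classify_trajectory([double], _exited()).label
        is TrajectoryClass.COMPLETE_DISSOCIATION
    )
    assert (
        rz.classify_trajectory([single], _exited()).label
        is TrajectoryClass.SINGLE_H_DISSOCIATION
    )
    assert (
        rz.classify_trajectory([single, double], _exited()).label
        is TrajectoryClass.MULTIPLE_SEQUENTIAL
    )
    assert (
        rz.classify_trajectory([seg], _exited()).label
        is TrajectoryClass.CONTINUOUS_LOSS
    )
    assert (
        rz.classify_trajectory(
            [single, double], FinalKE(FinalKEStatus.STOPPED)
        ).label
        is TrajectoryClass.STOPPED
    )
    flagged = rz.classify_trajectory([single], FinalKE(FinalKEStatus.INDETERMINATE))
    assert flagged.truncated


def test_stopped_track_classifies_stopped(stopped_track):
    traj, log = stopped_track
    cs = rz.census_vs_projectile(traj)
    events = rz.annotate_channels(rz.detect_events(rz.energy_loss_profile(traj)), cs)
    cls = rz.classify_trajectory(events, rz.final_kinetic_energy(traj))
    assert cls.label is TrajectoryClass.STOPPED


def test_hyperthermal_fragments_are_tracked(double_track):
    traj, log = double_track
    cs = rz.census_vs_projectile(traj)
    secs = rz.track_secondaries(traj, cs)
    assert len(secs) >= 1
    assert all(s.initial_ke > 10.0 for s in secs)
    assert all(s.path_length >= s.displacement - 1e-9 for s in secs)


def test_no_fragments_above_threshold_gives_empty_list():
    params = rz.GeneratorParams(
        n_molecules=16, p_single=0.0, p_double=0.0, continuous_loss_rate=0.0, seed=0
    )
    traj, _ = rz.generate_track(params, 4.0, (7.0, 7.0), seed=3)
    assert rz.track_secondaries(traj, rz.census_vs_projectile(traj)) == []


def test_secondary_outrunning_stopped_projectile_flags_handover(stopped_track):
    traj, _ = stopped_track
    cs = rz.census_vs_projectile(traj)
    secs = rz.track_secondaries(traj, cs)
    assert any(s.handover for s in secs)


def test_h_fragments_fly_farther_than_o_and_oh(mini_ensemble):
    trajs, _, censuses = mini_ensemble
    disp = {"H_isolated": [], "OH": [], "O_isolated": []}
    for traj, cs in zip(trajs, censuses):
        for s in rz.track_secondaries(traj, cs, ke_threshold=5.0):
            disp[s.species].append(s.displacement)
    heavy = disp["OH"] + disp["O_isolated"]
    assert disp["H_isolated"] and heavy
    assert np.mean(disp["H_isolated"]) > np.mean(heavy)
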