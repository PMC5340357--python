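import numpy as np
import pytest

import radiolyze as rz


def test_slab_geometry_and_counts(default_params):
    slab = rz.build_slab(default_params, snapshot_seed=1)
    assert slab.n_atoms == 384
    x0, x1 = default_params.slab_interval
    # O atoms stay inside the water region; their H atoms may poke out by
    # at most one bond length
    o_x = slab.positions[slab.symbols == "O", 0]
    assert np.all((o_x >= x0) & (o_x <= x1))
    assert np.all(slab.positions[:, 0] >= x0 - 1.0)
    assert np.all(slab.positions[:, 0] <= x1 + 1.0)
    assert list(slab.symbols).count("O") == 128


def test_slab_density_matches_liquid_water(default_params):
    # 128 molecules of 18.015 u in the water region
    amu_g = 1.66053906660e-24
    vol_cm3 = (default_params.box_edge * 1e-8) ** 3
    rho = 128 * 18.015 * amu_g / vol_cm3
    assert rho == pytest.approx(0.98, rel=0.01)


def test_different_snapshot_seeds_differ_in_coordinates(default_params):
    a = rz.build_slab(default_params, snapshot_seed=1)
    b = rz.build_slab(default_params, snapshot_seed=2)
    assert a.n_atoms == b.n_atoms
    assert not np.allclose(a.positions, b.positions)


def test_overcrowded_slab_raises():
    params = rz.GeneratorParams(n_molecules=80, box_edge=6.0, seed=0)
    with pytest.raises(RuntimeError, match="overlap"):
        rz.build_slab(params, snapshot_seed=1)


def test_lossless_configuration_gives_empty_log():
    params = rz.GeneratorParams(
        n_molecules=16, p_single=0.0, p_double=0.0, continuous_loss_rate=0.0, seed=0
    )
    traj, log = rz.generate_track(params, 2.0, (7.0, 7.0), seed=5)
    assert log.events == []
    assert log.final_ke == pytest.approx(log.initial_ke)
    assert not log.stopped


def test_ledger_closure_on_every_track(mini_ensemble):
    _, logs, _ = mini_ensemble
    for log in logs:
        assert abs(log.ledger_residual()) < 1e-6


def test_transfers_stay_inside_configured_intervals(mini_ensemble):
    _, logs, _ = mini_ensemble
    seen = {"single_dissociation": 0, "double_dissociation": 0}
    for log in logs:
        for e, nxt in zip(log.events, log.events[1:] + [None]):
            capped = log.stopped and nxt is None
            if e.channel in seen and not capped:
                lo, hi = (
                    (25.0, 50.0)
                    if e.channel == "single_dissociation"
                    else (100.0, 150.0)
                )
                assert lo - 1e-9 <= e.transfer <= hi + 1e-9
                seen[e.channel] += 1
    assert all(v > 0 for v in seen.values())


def test_first_transfer_exceeding_energy_stops_projectile():
    params = rz.GeneratorParams(
        n_molecules=16,
        p_single=0.0,
        p_double=1.0,
        transfer_double=(5000.0, 6000.0),
        continuous_loss_rate=0.0,
        encounter_spacing=3.0,
        seed=0,
    )
    traj, log = rz.generate_track(params, 1.0, (7.0, 7.0), seed=1)
    assert log.stopped
    assert log.final_ke == 0.0
    assert log.events[0].transfer == pytest.approx(log.initial_ke, abs=1e-9)


def test_entry_outside_transverse_cell_rejected(default_params):
    with pytest.raises(ValueError, match="entry"):
        rz.generate_track(default_params, 1.0, (99.0, 7.0), seed=1)


def test_track_generation_is_deterministic(default_params):
    a, la = rz.generate_track(default_params, 1.0, (7.0, 7.0), seed=9)
    b, lb = rz.generate_track(default_params, 1.0, (7.0, 7.0), seed=9)
    assert la.to_json() == lb.to_json()
    for fa, fb in zip(a.frames, b.frames):
        np.testing.assert_array_equal(fa.positions, fb.positions)
        np.testing.assert_array_equal(fa.velocities, fb.velocities)


def test_ensemble_protocol_grid_times_snapshots():
    params = rz.GeneratorParams(n_molecules=20, seed=0)
    one = rz.generate_ensemble(params, 1.0, grid=(1, 1), snapshots=1, base_seed=1)
    assert len(one) == 1


def test_ensemble_files_reproducible(tmp_path):
    params = rz.GeneratorParams(n_molecules=12, seed=0)
    m1 = rz.generate_ensemble(
        params, 2.0, grid=(2, 1), snapshots=1, base_seed=4, out_dir=tmp_path / "a"
    )
    rz.generate_ensemble(
        params, 2.0, grid=(2, 1), snapshots=1, base_seed=4, out_dir=tmp_path / "b"
    )
    for e in m1.entries:
        fa = (tmp_path / "a" / e["path"]).read_bytes()
        fb = (tmp_path / "b" / e["path"]).read_bytes()
        assert fa == fb
    groups = rz.load_ensemble(tmp_path / "a" / "manifest_v2.csv")
    assert len(groups[2.0]) == 2


def test_params_validation():
    with pytest.raises(ValueError):
        rz.GeneratorParams(transfer_single=(3.0, 4.0))  # below first-H binding
    with pytest.raises(ValueError):
        rz.GeneratorParams(transfer_double=(6.0, 8.0))  # below combined binding
    p = rz.GeneratorParams(p_single=0.9, p_double=0.5)
    with pytest.raises(ValueError):
        p.channel_probs(1.0)


def test_painted_populations_present_by_default(double_track):
    traj, _ = double_track
    assert all(f.populations is not None for f in traj.frames)
    params = rz.GeneratorParams(n_molecules=12, populations_mode=False, seed=0)
    bare, _ = rz.generate_track(params, 2.0, (7.0, 7.0), seed=1)
    assert all(f.populations is None for f in bare.frames)
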