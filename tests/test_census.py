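import numpy as np
import pytest

import radiolyze as rz
from radiolyze.census import CutoffTable

from conftest import water_frame


def frame_of(symbols, positions, box=10.0):
    return rz.Frame(0, 0.0, [box, box, box], symbols, positions)


def brute_force_pairs(frame, cutoffs):
    """Independent oracle: wrap into the cell, scan all 27 periodic images."""
    n = frame.n_atoms
    box = frame.box
    wrapped = np.mod(frame.positions, box)
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = wrapped[j] - wrapped[i]
            best = min(
                np.linalg.norm(d + s * box) for s in shifts
            )
            if best <= cutoffs.get(frame.symbols[i], frame.symbols[j]):
                out.add((i, j))
    return out


def test_oh_pair_at_cutoff_boundary():
    cut = CutoffTable.preset("paper-literal")
    inside = frame_of(["O", "H"], [[1, 1, 1], [2.19, 1, 1]])
    outside = frame_of(["O", "H"], [[1, 1, 1], [2.21, 1, 1]])
    pin, _ = rz.neighbor_pairs(inside, cut)
    pout, _ = rz.neighbor_pairs(outside, cut)
    assert len(pin) == 1 and len(pout) == 0


def test_minimum_image_wraparound():
    cut = CutoffTable.preset("paper-literal")
    f = frame_of(["O", "H"], [[0.1, 5, 5], [9.9, 5, 5]])
    pairs, dist = rz.neighbor_pairs(f, cut)
    assert len(pairs) == 1
    assert dist[0] == pytest.approx(0.2)


def test_neighbor_pairs_match_27_image_oracle():
    cut = CutoffTable(
        pairs={frozenset(["H"]): 0.8, frozenset(["O", "H"]): 1.2},
        default=1.4,
    )
    rng = np.random.default_rng(12345)
    for _ in range(20):
        n = 40
        box = rng.uniform(6.0, 12.0)
        syms = rng.choice(["O", "H", "C"], size=n)
        pos = rng.uniform(-box, 2 * box, size=(n, 3))  # deliberately unwrapped
        f = rz.Frame(0, 0.0, [box, box, box], syms, pos)
        pairs, _ = rz.neighbor_pairs(f, cut)
        got = {tuple(sorted(p)) for p in map(tuple, pairs)}
        assert got == brute_force_pairs(f, cut)


def test_cutoff_larger_than_half_box_rejected():
    f = frame_of(["O", "H"], [[1, 1, 1], [2, 1, 1]], box=3.0)
    with pytest.raises(ValueError, match="half"):
        rz.neighbor_pairs(f, CutoffTable.preset("peroxide-capable"))


def test_water_monomer_coordination():
    f = water_frame()
    Z = rz.coordination_table(f, CutoffTable.preset("paper-literal"))
    assert Z.z(0, "H") == 2
    assert Z.z(1, "O") == 1 and Z.z(2, "O") == 1
    inv = rz.classify_species(f, Z)
    assert inv.unit_counts(f.symbols)["H2O"] == 1


def test_hydronium_coordination_and_label():
    pos = [[5, 5, 5], [5.98, 5, 5], [4.51, 5.85, 5], [4.51, 4.15, 5]]
    f = frame_of(["O", "H", "H", "H"], pos)
    Z = rz.coordination_table(f, CutoffTable.preset("paper-literal"))
    assert Z.z(0, "H") == 3
    inv = rz.classify_species(f, Z)
    assert inv.unit_counts(f.symbols)["H3O_plus"] == 1


def test_h2_molecule_label():
    f = frame_of(["H", "H"], [[5, 5, 5], [5.74, 5, 5]])
    Z = rz.coordination_table(f, CutoffTable.preset("paper-literal"))
    assert Z.z(0, "H") == 1 and Z.z(1, "H") == 1
    inv = rz.classify_species(f, Z)
    assert inv.unit_counts(f.symbols)["H2"] == 1


def test_isolated_atoms_label():
    f = frame_of(["O", "H"], [[1, 1, 1], [8, 8, 8]])
    inv = rz.classify_species(
        f, rz.coordination_table(f, CutoffTable.preset("paper-literal"))
    )
    u = inv.unit_counts(f.symbols)
    assert u["O_isolated"] == 1 and u["H_isolated"] == 1


def test_pristine_slab_is_all_water(default_params):
    slab = rz.build_slab(default_params, snapshot_seed=5)
    inv = rz.classify_species(
        slab, rz.coordination_table(slab, CutoffTable.preset("paper-literal"))
    )
    u = inv.unit_counts(slab.symbols)
    assert u["H2O"] == 128
    assert sum(v for k, v in inv.counts.items()) == slab.n_atoms
    assert u["OH"] == u["O_isolated"] == u["H_isolated"] == 0


def test_peroxide_needs_peroxide_capable_preset():
    # H-O-O-H with O-O 1.47 A
    pos = [
        [5.0, 5.0, 5.0],
        [6.47, 5.0, 5.0],
        [4.68, 5.9, 5.0],
        [6.79, 4.1, 5.0],
    ]
    f = frame_of(["O", "O", "H", "H"], pos)
    comps = rz.molecular_components(f, CutoffTable.preset("peroxide-capable"))
    assert [c[0] for c in comps] == ["H2O2"]
    inv = rz.classify_species(
        f, rz.coordination_table(f, CutoffTable.preset("peroxide-capable"))
    )
    assert inv.unit_counts(f.symbols)["H2O2_O"] == 2
    # the blanket 1.2 A table cannot see the O-O bond: two hydroxyls instead
    comps_lit = rz.molecular_components(f, CutoffTable.preset("paper-literal"))
    assert sorted(c[0] for c in comps_lit) == ["HO", "HO"]


def test_ch_abstraction_component():
    f = frame_of(["C", "H"], [[5, 5, 5], [6.1, 5, 5]])
    comps = rz.molecular_components(f, CutoffTable.preset("paper-literal"))
    assert [c[0] for c in comps] == ["CH"]
    inv = rz.classify_species(
        f, rz.coordination_table(f, CutoffTable.preset("paper-literal"))
    )
    assert inv.counts["C_bound"] == 2


def test_static_slab_census_is_constant(default_params):
    slab = rz.build_slab(default_params, snapshot_seed=5)
    frames = [
        rz.Frame(
            k, float(k), slab.box, slab.symbols, slab.positions, projectile_index=None
        )
        for k in range(4)
    ]
    traj = rz.Trajectory(frames=frames)
    cs = rz.census_vs_projectile(traj)
    df = cs.counts_frame()
    assert (df["H2O"] == 128).all()
    assert cs.creations == []


def test_double_dissociation_creates_isolated_o_near_event(double_track):
    traj, log = double_track
    cs = rz.census_vs_projectile(traj)
    ev = [e for e in log.events if e.channel == "double_dissociation"][0]
    creations = cs.creations_of("O_isolated")
    assert len(creations) == 1
    assert abs(creations[0].projectile_x - ev.x) <= 2.0
    assert len(cs.creations_of("H_isolated")) == 2


def test_atom_conservation_on_every_frame(mini_ensemble):
    trajs, _, censuses = mini_ensemble
    for traj, cs in zip(trajs, censuses):
        for inv in cs.inventories:
            assert sum(inv.counts.values()) == traj.n_atoms


def test_census_recovers_ground_truth_creations(mini_ensemble):
    _, logs, censuses = mini_ensemble
    for log, cs in zip(logs, censuses):
        truth_h = sum(
            {"single_dissociation": 1, "double_dissociation": 2}.get(e.channel, 0)
            for e in log.events
        )
        truth_oh = sum(e.channel == "single_dissociation" for e in log.events)
        assert abs(len(cs.creations_of("H_isolated")) - truth_h) <= 1
        assert abs(len(cs.creations_of("OH")) - truth_oh) <= 1
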