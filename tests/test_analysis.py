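"""Trajectory observables against fixture ground truth and their invariances."""

import numpy as np
import pytest

from absheet import analysis as an
from absheet.engine import SimulationConfig, Snapshot, make_state, run, snapshot_of
from absheet.synthetic import (SheetFixtureSpec, build_random_gas,
                               build_sheet_fixture, _strand_coords)

FIXTURE_CASES = [
    ("antiparallel_in_register", 0),
    ("antiparallel_out_of_register", 1),
    ("parallel_in_register", 0),
    ("parallel_out_of_register", 2),
]


@pytest.fixture(scope="module", params=FIXTURE_CASES, ids=lambda c: c[0])
def sheet(request, topo, table):
    arr, off = request.param
    spec = SheetFixtureSpec(arrangement=arr, n_strands=6, n_layers=1,
                            registry_offset=off or 2)
    state, gt = build_sheet_fixture(spec, topo, table)
    return snapshot_of(state), gt


def test_hbond_map_matches_ground_truth(sheet):
    snap, gt = sheet
    assert len(an.hydrogen_bond_map(snap)) == gt.n_hbonds


def test_classification_matches_ground_truth(sheet):
    snap, gt = sheet
    hb = an.hydrogen_bond_map(snap)
    for (i, j), (ori, off) in gt.pair_classifications.items():
        cls = an.classify_strand_pair(i, j, hb, 7)
        assert cls is not None
        assert (cls.orientation, cls.registry_offset) == (ori, off)
        assert cls.n_hbonds == gt.pair_hbond_counts[(i, j)]


def test_classification_swap_symmetry(sheet):
    snap, gt = sheet
    hb = an.hydrogen_bond_map(snap)
    for (i, j) in gt.pair_classifications:
        a = an.classify_strand_pair(i, j, hb, 7)
        b = an.classify_strand_pair(j, i, hb, 7)
        assert a.orientation == b.orientation
        if a.orientation == "parallel":
            assert a.registry_offset == -b.registry_offset
        else:
            assert a.registry_offset == b.registry_offset  # a+b-(n-1) is symmetric


def test_beta_fraction_matches_ground_truth(sheet):
    snap, gt = sheet
    assert an.beta_sheet_fraction(snap) == pytest.approx(gt.beta_percentage)


def test_beta_fraction_monotone_in_hbonds(sheet, rng):
    """Removing H-bonds never increases the beta fraction (holding geometry)."""
    snap, gt = sheet
    full = an.beta_sheet_fraction(snap)
    prev = 0.0
    hb = list(snap.hbonds)
    for frac in (0.3, 0.6, 1.0):
        k = int(frac * len(hb))
        sub = Snapshot(snap.time, snap.positions, hb[:k],
                       snap.potential_energy, snap.box_length, snap.meta)
        val = an.beta_sheet_fraction(sub)
        assert val >= prev - 1e-12
        prev = val
    assert prev == pytest.approx(full)


def test_classification_invariant_under_rigid_motion(topo, table):
    """Re-deriving the H-bond map from rotated/translated geometry gives the
    same residue-level map, classifications and beta fraction."""
    spec = SheetFixtureSpec("antiparallel_in_register", n_strands=4)
    state, gt = build_sheet_fixture(spec, topo, table)
    snap0 = snapshot_of(state)
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    center = np.full(3, state.box_length / 2)
    newpos = (state.pos - center) @ R.T + center + np.array([5.0, -3.0, 7.0])
    st2 = make_state(state.topology, state.n_chains, newpos,
                     np.zeros_like(newpos), state.box_length, table,
                     detect_hbonds=True)
    snap1 = snapshot_of(st2)
    assert sorted(map(tuple, (r.__dict__.values() for r in an.hydrogen_bond_map(snap1)))) == \
           sorted(map(tuple, (r.__dict__.values() for r in an.hydrogen_bond_map(snap0))))
    assert an.beta_sheet_fraction(snap1) == pytest.approx(an.beta_sheet_fraction(snap0))


def test_monomer_gas_observables(topo, table):
    state = build_random_gas(8, 140.0, 4, topo, table)
    snap = snapshot_of(state)
    assert an.hydrogen_bond_map(snap) == []
    assert an.beta_sheet_fraction(snap) == 0.0
    clusters = an.cluster_oligomers(snap)
    assert len(clusters) == 8 and all(c.size == 1 for c in clusters)


@pytest.mark.parametrize("arrangement,focal,expected", [
    ("antiparallel_in_register", "F20", "V18"),
    ("antiparallel_in_register", "F19", "F19"),
    ("parallel_in_register", "F20", "F20"),
    ("parallel_in_register", "F19", "F19"),
])
def test_nearest_contacts_in_register_lattices(topo, table, arrangement, focal, expected):
    """The modal nearest interpeptide sidechain partner is the structurally
    opposite residue of the lattice."""
    spec = SheetFixtureSpec(arrangement, n_strands=6, n_layers=1)
    state, gt = build_sheet_fixture(spec, topo, table)
    tally = an.nearest_sidechain_contacts(snapshot_of(state), focal)
    assert tally, "no contacts found"
    assert tally.most_common(1)[0][0] == expected
    assert gt.expected_nearest[focal] == expected


def test_two_disjoint_sheets_cluster_separately(topo, table):
    spec = SheetFixtureSpec("antiparallel_in_register", n_strands=8)
    state, _ = build_sheet_fixture(spec, topo, table, box_length=200.0)
    nb = topo.n_beads
    other = state.pos.copy()
    other[:, 2] += 80.0
    both = np.vstack([state.pos, other])
    st2 = make_state(topo, 16, both, np.zeros_like(both), 200.0, table,
                     detect_hbonds=True)
    clusters = an.cluster_oligomers(snapshot_of(st2))
    assert [c.size for c in clusters] == [8, 8]


def test_sheet_plus_monomers_one_ordered_cluster(topo, table):
    spec = SheetFixtureSpec("antiparallel_in_register", n_strands=8)
    state, _ = build_sheet_fixture(spec, topo, table, box_length=220.0)
    rng = np.random.default_rng(0)
    singles = []
    tpl = topo.template_coords - topo.template_coords.mean(axis=0)
    for k in range(4):
        singles.append(tpl + np.array([40.0 + 40.0 * k, 150.0, 150.0]))
    allpos = np.vstack([state.pos] + singles)
    st2 = make_state(topo, 8 + 4, allpos, np.zeros_like(allpos), 220.0, table,
                     detect_hbonds=True)
    clusters = an.cluster_oligomers(snapshot_of(st2))
    assert clusters[0].size == 8
    assert clusters[0].order_parameter >= 0.9
    assert sum(1 for c in clusters if c.size == 1) == 4


@pytest.mark.parametrize("n_layers,expected", [(1, 1), (2, 2), (4, 4)])
def test_sheet_layer_count(topo, table, n_layers, expected):
    spec = SheetFixtureSpec("antiparallel_in_register", n_strands=3,
                            n_layers=n_layers)
    state, gt = build_sheet_fixture(spec, topo, table)
    snap = snapshot_of(state)
    clusters = an.cluster_oligomers(snap)
    assert clusters[0].size == 3 * n_layers
    assert an.sheet_layer_count(snap, clusters[0]) == expected == gt.layer_count


def test_layer_count_undefined_for_amorphous(topo, table):
    state = build_random_gas(4, 120.0, 2, topo, table)
    snap = snapshot_of(state)
    from absheet.analysis import OligomerCluster
    fake = OligomerCluster(chains=[0, 1, 2, 3], size=4, order_parameter=0.0)
    with pytest.raises(ValueError, match="amorphous"):
        an.sheet_layer_count(snap, fake)


def test_energy_and_beta_timeseries_alignment(topo, table):
    cfg = SimulationConfig(n_peptides=1, max_time=50.0, box_length=60.0,
                           seed=2, snapshot_interval=10.0)
    traj = run(cfg)
    prof = an.energy_and_beta_timeseries(traj)
    assert len(prof.times) == len(prof.potential_energies) == len(prof.beta_percentages)
    assert len(prof.times) == len(traj.snapshots)
    assert np.all(prof.beta_percentages == 0.0)   # a lone chain has no sheet
    df = prof.to_frame()
    assert list(df.columns) == ["time_tau", "potential_energy_epsHB", "beta_pct"]


def test_block_average():
    x = np.arange(20, dtype=float)
    b = an.block_average(x, 10)
    assert b.tolist() == [4.5, 14.5]
    assert an.block_average(x[:3], 10).tolist() == [1.0]
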