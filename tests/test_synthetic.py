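"""Fixture generators: ground-truth consistency, engine validity, synthetic
peak lists and calibrant sets."""

import numpy as np
import pandas as pd
import pytest

from absheet import xlink as xl
from absheet.engine import SimulationConfig, run, snapshot_of
from absheet.synthetic import (SheetFixtureSpec, build_random_gas,
                               build_sheet_fixture, synthetic_calibrants,
                               synthetic_peaklist)
from absheet import analysis as an


def test_fixture_spec_validation():
    with pytest.raises(ValueError, match="unknown arrangement"):
        SheetFixtureSpec("sideways")
    with pytest.raises(ValueError, match="nonzero offset"):
        SheetFixtureSpec("antiparallel_out_of_register", registry_offset=0)
    with pytest.raises(ValueError, match="even"):
        SheetFixtureSpec("parallel_out_of_register", registry_offset=1)
    with pytest.raises(ValueError, match="spacings"):
        SheetFixtureSpec("parallel_in_register", strand_spacing=-1.0)


def test_fixture_carries_engine_consistent_hbonds(topo, table):
    """The state's detected H-bonds equal the construction's expectation
    (asserted inside the builder) and every pair has >= 2 bonds."""
    st, gt = build_sheet_fixture(
        SheetFixtureSpec("antiparallel_in_register", n_strands=8), topo, table)
    assert len(st.hbonds()) == gt.n_hbonds
    assert all(c >= 2 for c in gt.pair_hbond_counts.values())
    assert gt.beta_percentage == 100.0


def test_fixture_survives_dynamics_at_low_temperature(topo, table):
    """Running ~1e3 events from a 2-strand fixture at low T* preserves every
    hydrogen bond (sheets are deep minima of the square-well model)."""
    spec = SheetFixtureSpec("antiparallel_in_register", n_strands=2, seed=3)
    st, gt = build_sheet_fixture(spec, topo, table, t_star=0.1)
    bonds_before = set(st.hbonds())
    cfg = SimulationConfig(n_peptides=2, max_time=50.0, box_length=st.box_length,
                           t_star=0.1, seed=3, snapshot_interval=50.0)
    traj = run(cfg, initial_state=st, max_events=2000)
    assert traj.event_counts["events"] >= 1000
    assert set(traj.final_state.hbonds()) == bonds_before


def test_random_gas_properties(topo, table):
    st = build_random_gas(24, 160.0, 7, topo, table)
    snap = snapshot_of(st)
    assert an.beta_sheet_fraction(snap) == 0.0
    assert len(snap.hbonds) == 0
    st2 = build_random_gas(24, 160.0, 7, topo, table)
    assert np.array_equal(st.pos, st2.pos)     # same seed, same state


def test_peaklist_noiseless_recovers_site(topo, table):
    star = xl.abeta_star()
    dim = xl.crosslinked_dimer(star, star, 5, 1)
    peaks = synthetic_peaklist(dim, charge_states=(1,))
    assert peaks.attrs["crosslink"] == ((0, 5), (1, 1))
    ranking, _ = xl.assign_crosslink_site(peaks[["mz", "z"]], [(5, a) for a in range(1, 8)],
                                          star, star, tolerance_da=0.2)
    assert (ranking.loc[0, "site_donor"], ranking.loc[0, "site_acceptor"]) == (5, 1)
    assert ranking.loc[0, "frac_explained"] == 1.0


def test_peaklist_jitter_still_recovered(topo, table):
    star = xl.abeta_star()
    dim = xl.crosslinked_dimer(star, star, 5, 1)
    for seed in range(5):
        peaks = synthetic_peaklist(dim, noise={"mass_jitter_da": 0.05}, seed=seed)
        ranking, _ = xl.assign_crosslink_site(peaks[["mz", "z"]],
                                              [(5, a) for a in (1, 3, 7)],
                                              star, star, tolerance_da=0.2)
        assert (ranking.loc[0, "site_donor"], ranking.loc[0, "site_acceptor"]) == (5, 1)


def test_peaklist_decoys_rarely_flip_ranking(topo, table):
    """50% decoy peaks: the generating site stays top in >= 95/100 seeds."""
    star = xl.abeta_star()
    dim = xl.crosslinked_dimer(star, star, 5, 1)
    wins = 0
    for seed in range(100):
        peaks = synthetic_peaklist(dim, noise={"decoy_fraction": 0.5}, seed=seed)
        ranking, _ = xl.assign_crosslink_site(peaks[["mz", "z"]],
                                              [(5, 1), (5, 3), (5, 7)],
                                              star, star, tolerance_da=0.2)
        if (ranking.loc[0, "site_donor"], ranking.loc[0, "site_acceptor"]) == (5, 1):
            wins += 1
    assert wins >= 95


def test_calibrant_generator_round_trip():
    df = synthetic_calibrants(380.0, 0.55, 8, noise=0.0, seed=0)
    cal = xl.fit_ccs_calibration(df)
    assert cal.A == pytest.approx(380.0, rel=1e-9)
    assert cal.B == pytest.approx(0.55, rel=1e-9)
    # two points, two parameters: exact
    df2 = synthetic_calibrants(200.0, 0.4, 2, seed=1)
    cal2 = xl.fit_ccs_calibration(df2)
    assert cal2.A == pytest.approx(200.0, rel=1e-9)
    df3 = synthetic_calibrants(380.0, 0.55, 8, noise=0.0, seed=0)
    assert df.equals(df3)      # deterministic per seed
    with pytest.raises(ValueError):
        synthetic_calibrants(-1.0, 0.5, 8)
    with pytest.raises(ValueError):
        synthetic_calibrants(380.0, 0.5, 1)
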