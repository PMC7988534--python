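"""Cross-link mass arithmetic, fragment enumeration, site assignment, CCS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from absheet import xlink as xl

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_glycine_free_acid_mass():
    # textbook constants: residue 57.02146 + water 18.01056
    m = xl.peptide_mass("G", terminal_groups=("H", "OH"))
    assert m == pytest.approx(57.02146 + 18.01056, abs=1e-4)


def test_capped_peptide_mass_against_composition_oracle():
    # independent assembly: residue monoisotopic masses + H2O + (acetyl - H2O
    # replacement on each terminus)
    residues = {"K": 128.09496, "L": 113.08406, "V": 99.06841, "F": 147.06841,
                "A": 71.03711, "E": 129.04259}
    base = sum(residues[a] for a in "KLVFFAE") + 18.010565
    expected = base + 42.010565 - 0.984016   # +acetyl, amide C-terminus
    assert xl.peptide_mass("KLVFFAE") == pytest.approx(expected, abs=2e-4)


def test_tfmd_monomer_mass():
    plain = xl.peptide_mass("KLVFFAE")
    star = xl.peptide_mass("KLVFFAE", modifications=[(5, "TFMD")])
    # +C2N2F3 -H
    assert star - plain == pytest.approx(107.99353, abs=1e-4)


def test_crosslinked_dimer_composition_bookkeeping():
    star = xl.abeta_star()
    dim = xl.crosslinked_dimer(star, star, 5, 1)
    two_monomers = 2 * xl.MolecularSpecies(chains=(star,)).mono_mass
    assert dim.mono_mass == pytest.approx(two_monomers - 28.00615, abs=1e-4)
    assert dim.crosslink == ((0, 5), (1, 1))


def test_dimer_matches_printed_precursor():
    # printed precursor m/z 988.58 (2+), i.e. neutral 1975.16; theoretical
    # monoisotopic dimer agrees within the documented 0.2 Da tolerance
    observed = xl.mz_to_neutral_mass(988.58, 2)
    assert observed == pytest.approx(1975.16, abs=0.02)
    dim = xl.crosslinked_dimer(xl.abeta_star(), xl.abeta_star(), 5, 1)
    assert dim.mono_mass == pytest.approx(observed, abs=0.2)


def test_donor_must_carry_diazirine():
    plain = xl.make_chain("KLVFFAE")
    with pytest.raises(ValueError, match="diazirine"):
        xl.crosslinked_dimer(plain, plain, 5, 1)


def test_intramolecular_crosslink_and_water_quench():
    star = xl.abeta_star()
    mono = xl.MolecularSpecies(chains=(star,)).mono_mass
    intra = xl.intramolecular_crosslink(star, 5, 7)   # F20 -> E22
    assert intra.mono_mass == pytest.approx(mono - 28.00615, abs=1e-4)
    quench = xl.water_quench(star)
    assert quench.mono_mass == pytest.approx(mono - 28.00615 + 18.010565, abs=1e-4)


def test_mz_arithmetic():
    assert xl.mz_to_neutral_mass(100.0, 1) == pytest.approx(98.99272)
    for z in (1, 2, 3):
        m = 1975.14544
        assert xl.mz_to_neutral_mass(xl.neutral_mass_to_mz(m, z), z) == pytest.approx(m, abs=1e-10)
    with pytest.raises(ValueError):
        xl.mz_to_neutral_mass(100.0, 0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seq=st.text(alphabet=AA, min_size=2, max_size=12),
       nterm=st.sampled_from(["H", "Ac"]), cterm=st.sampled_from(["OH", "NH2"]))
def test_by_complement_identity(seq, nterm, cterm):
    """b_k + y_(n-k) = precursor neutral for every cleavage of a linear chain."""
    ch = xl.make_chain(seq, (nterm, cterm))
    sp = xl.MolecularSpecies(chains=(ch,))
    frags = {f.label: f.neutral_mass for f in xl.fragment_ions(sp)}
    M = sp.mono_mass
    for k in range(1, len(seq)):
        assert frags[f"b{k}"] + frags[f"y{len(seq) - k}"] == pytest.approx(M, abs=1e-6)


def test_printed_fragment_annotations_within_tolerance():
    """The b/y ions localizing the F20-K16 link: loss of Ac-Lys-Leu (y, printed
    1692.95) and loss of F*-Ala-Glu (b, printed 1503.82), singly charged."""
    dim = xl.crosslinked_dimer(xl.abeta_star(), xl.abeta_star(), 5, 1)
    frags = {f.label: f for f in xl.fragment_ions(dim)}
    y5_donor = frags["y5/0+P"]      # donor chain loses its N-terminal Ac-K-L
    b4_acceptor = frags["b4/1+P"]   # acceptor chain loses its C-terminal F*-A-E
    assert y5_donor.mz(1) == pytest.approx(1692.95, abs=0.2)
    assert b4_acceptor.mz(1) == pytest.approx(1503.82, abs=0.2)
    assert y5_donor.retains_partner and b4_acceptor.retains_partner


def test_crosslink_fragments_partition_precursor():
    """A spanning fragment and its complementary non-spanning fragment sum to
    the dimer mass for every cleavage of either chain."""
    dim = xl.crosslinked_dimer(xl.abeta_star(), xl.abeta_star(), 5, 1)
    M = dim.mono_mass
    frags = {f.label: f for f in xl.fragment_ions(dim)}
    n = 7
    for c, pos in ((0, 5), (1, 1)):
        for k in range(1, n):
            b = frags[f"b{k}/{c}" + ("+P" if pos <= k else "")]
            y = frags[f"y{n - k}/{c}" + ("+P" if pos > k else "")]
            assert b.neutral_mass + y.neutral_mass == pytest.approx(M, abs=1e-6)
            assert b.retains_partner != y.retains_partner  # link on one side only


def test_site_assignment_self_consistency():
    star = xl.abeta_star()
    dim = xl.crosslinked_dimer(star, star, 5, 1)
    peaks = pd.DataFrame({"mz": [f.mz(1) for f in xl.fragment_ions(dim)], "z": 1})
    candidates = [(5, a) for a in (1, 2, 3, 6, 7)]
    ranking, diag = xl.assign_crosslink_site(peaks, candidates, star, star,
                                             tolerance_da=0.2)
    assert (int(ranking.loc[0, "site_donor"]), int(ranking.loc[0, "site_acceptor"])) == (5, 1)
    assert ranking.loc[0, "frac_explained"] == 1.0
    assert diag["top_site"] == (5, 1)


def test_site_assignment_discrimination_control():
    """Peaks generated from an F20->V18 dimer must not rank F20->K16 first."""
    star = xl.abeta_star()
    alt = xl.crosslinked_dimer(star, star, 5, 3)
    peaks = pd.DataFrame({"mz": [f.mz(1) for f in xl.fragment_ions(alt)], "z": 1})
    ranking, _ = xl.assign_crosslink_site(peaks, [(5, 1), (5, 3)], star, star)
    assert (int(ranking.loc[0, "site_donor"]), int(ranking.loc[0, "site_acceptor"])) == (5, 3)


def test_empty_peak_list_rejected():
    star = xl.abeta_star()
    with pytest.raises(ValueError, match="empty peak list"):
        xl.assign_crosslink_site(pd.DataFrame({"mz": [], "z": []}), [(5, 1)], star)


# --- CCS calibration ----------------------------------------------------------

def _make_calibrants(A, B, n, rng, noise=0.0):
    t = np.exp(rng.uniform(0, 3, n))
    z = rng.integers(1, 4, n).astype(float)
    m = rng.uniform(500, 4000, n)
    ccs = A * t ** B * z * np.sqrt(1 / m + 1 / xl.N2_GAS_MASS)
    ccs = ccs * (1 + noise * rng.standard_normal(n))
    return pd.DataFrame({"t_d": t, "z": z, "m_ion": m, "ccs_ref": ccs})


def test_ccs_noiseless_recovery_exact(rng):
    cal = xl.fit_ccs_calibration(_make_calibrants(380.0, 0.55, 8, rng))
    assert cal.A == pytest.approx(380.0, rel=1e-9)
    assert cal.B == pytest.approx(0.55, rel=1e-9)


def test_ccs_two_point_exact(rng):
    cal = xl.fit_ccs_calibration(_make_calibrants(120.0, 0.42, 2, rng))
    assert cal.A == pytest.approx(120.0, rel=1e-9)
    assert cal.B == pytest.approx(0.42, rel=1e-9)


def test_ccs_noise_recovery_within_5pct():
    errs_a, errs_b = [], []
    for seed in range(100):
        r = np.random.default_rng(seed)
        cal = xl.fit_ccs_calibration(_make_calibrants(380.0, 0.55, 8, r, noise=0.01))
        errs_a.append(abs(cal.A - 380.0) / 380.0)
        errs_b.append(abs(cal.B - 0.55) / 0.55)
    assert np.mean(errs_a) < 0.05 and np.mean(errs_b) < 0.05


def test_ccs_linear_in_charge(rng):
    cal = xl.fit_ccs_calibration(_make_calibrants(380.0, 0.55, 8, rng))
    w1 = xl.ccs_from_drift(5.0, 1, 2000.0, cal)
    w2 = xl.ccs_from_drift(5.0, 2, 2000.0, cal)
    assert w2 == pytest.approx(2 * w1)


def test_ccs_input_validation(rng):
    df = _make_calibrants(380.0, 0.55, 8, rng)
    with pytest.raises(ValueError, match="at least 2"):
        xl.fit_ccs_calibration(df.iloc[:1])
    bad = df.copy(); bad.loc[0, "t_d"] = -1.0
    with pytest.raises(ValueError, match="drift time"):
        xl.fit_ccs_calibration(bad)
    cal = xl.fit_ccs_calibration(df)
    with pytest.raises(ValueError, match="drift time"):
        xl.ccs_from_drift(-2.0, 1, 1000.0, cal)
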