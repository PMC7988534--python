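"""Mass arithmetic for photo-induced cross-linking MS and TWIMS CCS calibration.

Covers the in-silico interpretation layer of a PIC (photo-induced
cross-linking) experiment on a diazirine-tagged peptide: exact masses of
modified peptides, cross-linked dimers (two chains minus N2 lost on carbene
formation), b/y backbone fragment enumeration with cross-link bookkeeping,
cross-link-site localization against a peak list, and the power-law
traveling-wave ion-mobility CCS calibration

    Omega = A * t_D**B * z * sqrt(1/m_ion + 1/m_gas)

fitted by linear regression of ln(Omega') on ln(t_D) with
Omega' = Omega / (z * sqrt(1/m_ion + 1/m_gas)).

Element and residue compositions come from pyteomics; monoisotopic masses are
the default throughout.  Printed literature masses for this chemistry are not
always monoisotopic-consistent, so peak matching uses an explicit tolerance
(0.2 Da by default) rather than assuming exactness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as pmass

__all__ = [
    "PROTON_MASS", "N2_MONO_MASS", "N2_GAS_MASS",
    "Chain", "MolecularSpecies", "FragmentIon", "CCSCalibration",
    "composition_mono_mass", "peptide_mass", "make_chain",
    "crosslinked_dimer", "intramolecular_crosslink", "water_quench",
    "mz_to_neutral_mass", "neutral_mass_to_mz",
    "fragment_ions", "assign_crosslink_site",
    "fit_ccs_calibration", "ccs_from_drift",
]

PROTON_MASS = 1.00728          # Da per charge, m/z convention
H2O_MONO = 18.0105646863
N2_MONO_MASS = 28.0061480279   # lost on diazirine -> carbene
N2_GAS_MASS = 28.0134          # average, IMS drift gas
OH_MONO = 17.0027396518

# neutral composition deltas for terminal groups, relative to residue sums
_NTERM = {"H": {}, "Ac": {"C": 2, "H": 2, "O": 1}}            # acetyl caps the amine
_CTERM = {"OH": {}, "NH2": {"N": 1, "H": 1, "O": -1}}         # C-terminal amide

# residue modifications known to this layer: composition deltas
_MOD_DELTA = {"TFMD": {"C": 2, "N": 2, "F": 3, "H": -1}}


def composition_mono_mass(delta: dict) -> float:
    """Monoisotopic mass of an element-count delta (counts may be negative)."""
    return float(sum(n * pmass.nist_mass[el][0][0] for el, n in delta.items()))


def _composition_avg_mass(comp: dict) -> float:
    total = 0.0
    for el, n in comp.items():
        iso = pmass.nist_mass[el]
        avg = sum(m * ab for m, ab in iso.values() if ab > 0)
        total += n * avg
    return float(total)


@dataclass(frozen=True)
class Chain:
    """One peptide chain with terminal groups and residue modifications.

    ``modifications`` is a tuple of (position, mod_id) with 1-based positions.
    """

    sequence: str
    nterm: str = "Ac"
    cterm: str = "NH2"
    modifications: tuple = ()

    def __post_init__(self):
        if self.nterm not in _NTERM or self.cterm not in _CTERM:
            raise ValueError(f"unknown terminal group {self.nterm}/{self.cterm}")
        for pos, mid in self.modifications:
            if mid not in _MOD_DELTA:
                raise ValueError(f"unknown modification {mid!r}")
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside chain")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def composition(self) -> dict:
        comp = dict(pmass.Composition(sequence=self.sequence))
        for delta in (_NTERM[self.nterm], _CTERM[self.cterm]):
            for el, n in delta.items():
                comp[el] = comp.get(el, 0) + n
        for pos, mid in self.modifications:
            for el, n in _MOD_DELTA[mid].items():
                comp[el] = comp.get(el, 0) + n
        return comp

    def residue_masses(self) -> np.ndarray:
        """Monoisotopic residue masses including modification deltas."""
        m = np.array([pmass.std_aa_mass[a] for a in self.sequence], dtype=float)
        for pos, mid in self.modifications:
            m[pos - 1] += composition_mono_mass(_MOD_DELTA[mid])
        return m

    def mono_mass(self) -> float:
        return composition_mono_mass(self.composition())

    def has_diazirine(self, pos: int) -> bool:
        return any(p == pos and mid == "TFMD" for p, mid in self.modifications)


@dataclass
class MolecularSpecies:
    """A peptide monomer or covalent cross-linked product.

    ``crosslink`` is ((chain_index, residue_pos), (chain_index, residue_pos))
    donor first, 1-based positions; ``lost_groups`` lists neutral losses that
    already happened (one "N2" per formed cross-link).
    """

    chains: tuple
    crosslink: tuple = None
    lost_groups: tuple = ()
    gained_groups: tuple = ()

    def __post_init__(self):
        if self.crosslink is not None:
            n_n2 = sum(1 for g in self.lost_groups if g == "N2")
            if n_n2 != 1:
                raise ValueError("a cross-linked species loses exactly one N2 per link")

    def composition(self) -> dict:
        comp = {}
        for ch in self.chains:
            for el, n in ch.composition().items():
                comp[el] = comp.get(el, 0) + n
        for g in self.lost_groups:
            if g != "N2":
                raise ValueError(f"unknown neutral loss {g!r}")
            comp["N"] = comp.get("N", 0) - 2
        for g in self.gained_groups:
            if g != "H2O":
                raise ValueError(f"unknown gained group {g!r}")
            comp["H"] = comp.get("H", 0) + 2
            comp["O"] = comp.get("O", 0) + 1
        return comp

    @property
    def mono_mass(self) -> float:
        return composition_mono_mass(self.composition())

    @property
    def avg_mass(self) -> float:
        return _composition_avg_mass(self.composition())

    def mz(self, z: int) -> float:
        return neutral_mass_to_mz(self.mono_mass, z)


def make_chain(sequence, terminal_groups=("Ac", "NH2"), modifications=()) -> Chain:
    return Chain(sequence, nterm=terminal_groups[0], cterm=terminal_groups[1],
                 modifications=tuple(modifications))


def peptide_mass(sequence, terminal_groups=("Ac", "NH2"), modifications=(),
                 kind="mono") -> float:
    """Neutral mass (Da) of a linear peptide with terminal groups and mods.

    ``terminal_groups`` is (N-terminal, C-terminal) from {H, Ac} x {OH, NH2};
    ``kind`` selects monoisotopic (default) or average mass.
    """
    ch = make_chain(sequence, terminal_groups, modifications)
    sp = MolecularSpecies(chains=(ch,))
    if kind == "mono":
        return sp.mono_mass
    if kind == "avg":
        return sp.avg_mass
    raise ValueError("kind must be 'mono' or 'avg'")


def abeta_star(tfmd_position: int = 5) -> Chain:
    """Ac-KLVFFAE-NH2 with the TFMD photo-label on Phe (position 5 = F20)."""
    return Chain("KLVFFAE", "Ac", "NH2", ((tfmd_position, "TFMD"),))


def crosslinked_dimer(species_a, species_b, site_donor: int,
                      site_acceptor: int) -> MolecularSpecies:
    """Covalent dimer from carbene insertion: sum of chains minus one N2.

    ``species_a`` carries the diazirine at 1-based ``site_donor``;
    ``site_acceptor`` is the insertion residue on ``species_b``.
    """
    a = species_a.chains[0] if isinstance(species_a, MolecularSpecies) else species_a
    b = species_b.chains[0] if isinstance(species_b, MolecularSpecies) else species_b
    if not a.has_diazirine(site_donor):
        raise ValueError(f"donor chain lacks a diazirine at position {site_donor}")
    if not 1 <= site_acceptor <= b.n_residues:
        raise ValueError("acceptor site outside chain")
    return MolecularSpecies(chains=(a, b),
                            crosslink=((0, site_donor), (1, site_acceptor)),
                            lost_groups=("N2",))


def intramolecular_crosslink(species_a, site_donor: int,
                             site_acceptor: int) -> MolecularSpecies:
    """Monomer with an internal carbene insertion (monomer minus N2)."""
    a = species_a.chains[0] if isinstance(species_a, MolecularSpecies) else species_a
    if not a.has_diazirine(site_donor):
        raise ValueError(f"chain lacks a diazirine at position {site_donor}")
    return MolecularSpecies(chains=(a,),
                            crosslink=((0, site_donor), (0, site_acceptor)),
                            lost_groups=("N2",))


def water_quench(species_a) -> MolecularSpecies:
    """Carbene quenched by water: monomer - N2 + H2O (hydroxylated label)."""
    a = species_a.chains[0] if isinstance(species_a, MolecularSpecies) else species_a
    return MolecularSpecies(chains=(a,), crosslink=((0, 0), (0, 0)),
                            lost_groups=("N2",), gained_groups=("H2O",))


def mz_to_neutral_mass(mz: float, z: int) -> float:
    """Neutral mass M = z*(m/z) - z*m_proton (positive-mode protonation)."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return z * mz - z * PROTON_MASS


def neutral_mass_to_mz(mass: float, z: int) -> float:
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mass / z + PROTON_MASS


@dataclass(frozen=True)
class FragmentIon:
    """One backbone fragment: series b/y (or double = one cleavage per chain),
    per-chain residue index, partner-chain retention flag, neutral mass."""

    series: str
    index: tuple          # (chain, residue count) or ((0, k), (1, l)) for double
    retains_partner: bool
    neutral_mass: float
    label: str

    def mz(self, z: int) -> float:
        return neutral_mass_to_mz(self.neutral_mass, z)


def _nterm_b_delta(ch: Chain) -> float:
    return composition_mono_mass(_NTERM[ch.nterm])


def _cterm_y_delta(ch: Chain) -> float:
    return H2O_MONO + composition_mono_mass(_CTERM[ch.cterm])


def _chain_b(ch: Chain, k: int, res=None) -> float:
    res = ch.residue_masses() if res is None else res
    return float(res[:k].sum()) + _nterm_b_delta(ch)


def _chain_y(ch: Chain, k: int, res=None) -> float:
    """Neutral y fragment of the last k residues."""
    res = ch.residue_masses() if res is None else res
    return float(res[ch.n_residues - k:].sum()) + _cterm_y_delta(ch)


def fragment_ions(species: MolecularSpecies, max_charge: int = 1,
                  include_double: bool = True) -> list:
    """Enumerate b/y ions; cross-link-spanning fragments carry the partner chain.

    For a cross-linked dimer each cleavage of one chain yields a b and a y
    fragment; the piece containing that chain's linked residue additionally
    carries the entire partner chain minus N2.  ``include_double`` adds
    products with exactly one cleavage per chain (the connected piece holding
    the cross-link).  ``max_charge`` is not used for enumeration (fragments
    are neutral); it is kept on the ion via ``FragmentIon.mz``.
    """
    out = []
    chains = species.chains
    link = species.crosslink
    if link is not None and link[0][0] == link[1][0] and len(chains) == 1:
        # intramolecular link: enumerate cleavages outside the loop only
        ch = chains[0]
        res = ch.residue_masses()
        lo, hi = sorted((link[0][1], link[1][1]))
        n2 = N2_MONO_MASS if "N2" in species.lost_groups else 0.0
        for k in range(1, ch.n_residues):
            if lo <= k < hi:      # cleaving inside the ring does not separate
                continue
            out.append(FragmentIon("b", (0, k), False, _chain_b(ch, k, res) - (n2 if k >= hi else 0.0),
                                   f"b{k}"))
            ky = ch.n_residues - k
            out.append(FragmentIon("y", (0, ky), False, _chain_y(ch, ky, res) - (n2 if k < lo else 0.0),
                                   f"y{ky}"))
        return out

    res_all = [ch.residue_masses() for ch in chains]
    full = [float(res_all[c].sum()) + _nterm_b_delta(chains[c]) + _cterm_y_delta(chains[c])
            for c in range(len(chains))]

    def partner_extra(c):
        other = 1 - c
        return full[other] - N2_MONO_MASS

    for c, ch in enumerate(chains):
        n = ch.n_residues
        linked_pos = None
        if link is not None:
            for (ci, pos) in link:
                if ci == c:
                    linked_pos = pos
        for k in range(1, n):
            b_mass = _chain_b(ch, k, res_all[c])
            y_mass = _chain_y(ch, n - k, res_all[c])
            b_has_link = linked_pos is not None and linked_pos <= k
            y_has_link = linked_pos is not None and linked_pos > k
            if len(chains) == 2:
                if b_has_link:
                    b_mass += partner_extra(c)
                if y_has_link:
                    y_mass += partner_extra(c)
            tagc = "" if len(chains) == 1 else f"/{c}"
            out.append(FragmentIon("b", (c, k), bool(b_has_link and len(chains) == 2),
                                   b_mass, f"b{k}{tagc}" + ("+P" if b_has_link and len(chains) == 2 else "")))
            out.append(FragmentIon("y", (c, n - k), bool(y_has_link and len(chains) == 2),
                                   y_mass, f"y{n - k}{tagc}" + ("+P" if y_has_link and len(chains) == 2 else "")))

    if include_double and len(chains) == 2 and link is not None:
        (c0, p0), (c1, p1) = link
        ch0, ch1 = chains[c0], chains[c1]
        for k in range(1, ch0.n_residues):
            # the retained piece of each chain must contain its link residue
            m0 = _chain_b(ch0, k, res_all[c0]) if p0 <= k else _chain_y(ch0, ch0.n_residues - k, res_all[c0])
            for l in range(1, ch1.n_residues):
                m1 = _chain_b(ch1, l, res_all[c1]) if p1 <= l else _chain_y(ch1, ch1.n_residues - l, res_all[c1])
                mass_dbl = m0 + m1 - N2_MONO_MASS
                lab0 = f"b{k}" if p0 <= k else f"y{ch0.n_residues - k}"
                lab1 = f"b{l}" if p1 <= l else f"y{ch1.n_residues - l}"
                out.append(FragmentIon("double", ((c0, k), (c1, l)), True, mass_dbl,
                                       f"{lab0}x{lab1}"))
    return out


def _peaks_to_frame(peak_list) -> pd.DataFrame:
    if isinstance(peak_list, pd.DataFrame):
        df = peak_list.copy()
    else:
        arr = np.atleast_2d(np.asarray(peak_list, dtype=float))
        if arr.shape[1] == 1:
            df = pd.DataFrame({"mz": arr[:, 0], "z": 1})
        else:
            df = pd.DataFrame({"mz": arr[:, 0], "z": arr[:, 1].astype(int)})
    if df.empty:
        raise ValueError("empty peak list")
    return df


def assign_crosslink_site(peak_list, candidate_sites, chain_a: Chain,
                          chain_b: Chain = None, tolerance_da: float = 0.2,
                          include_double: bool = True):
    """Rank candidate cross-link site pairs by how many peaks they explain.

    ``peak_list``: DataFrame with columns (mz, z) or an (n, 2) array.
    ``candidate_sites``: iterable of (donor_pos, acceptor_pos), 1-based;
    donor on ``chain_a`` (which must carry the diazirine), acceptor on
    ``chain_b`` (defaults to an unlabelled copy of ``chain_a``'s sequence).

    Returns (ranking DataFrame, diagnostics dict).  Ranking is by explained
    peak count (desc), then summed |error| (asc).  Diagnostics lists the
    fragment labels matched by the top candidate but not the runner-up.
    """
    peaks = _peaks_to_frame(peak_list)
    if chain_b is None:
        chain_b = Chain(chain_a.sequence, chain_a.nterm, chain_a.cterm, ())

    rows, matched_labels = [], {}
    for (dpos, apos) in candidate_sites:
        sp = crosslinked_dimer(chain_a, chain_b, dpos, apos)
        frags = fragment_ions(sp, include_double=include_double)
        fmass = np.array([f.neutral_mass for f in frags])
        labels = [f.label for f in frags]
        n_match, err_sum = 0, 0.0
        hit = set()
        for mz, z in zip(peaks["mz"].to_numpy(), peaks["z"].to_numpy()):
            neutral = mz_to_neutral_mass(float(mz), int(z))
            err = np.abs(fmass - neutral)
            j = int(np.argmin(err))
            if err[j] <= tolerance_da:
                n_match += 1
                err_sum += float(err[j])
                hit.add(labels[j])
        rows.append({"site_donor": dpos, "site_acceptor": apos,
                     "n_matched": n_match, "n_peaks": len(peaks),
                     "frac_explained": n_match / len(peaks),
                     "sum_abs_error": err_sum})
        matched_labels[(dpos, apos)] = hit

    ranking = (pd.DataFrame(rows)
               .sort_values(["n_matched", "sum_abs_error"],
                            ascending=[False, True], kind="mergesort")
               .reset_index(drop=True))
    diagnostics = {}
    if len(ranking) >= 2:
        top = (int(ranking.loc[0, "site_donor"]), int(ranking.loc[0, "site_acceptor"]))
        second = (int(ranking.loc[1, "site_donor"]), int(ranking.loc[1, "site_acceptor"]))
        diagnostics = {
            "top_site": top,
            "runner_up": second,
            "diagnostic_fragments": sorted(matched_labels[top] - matched_labels[second]),
        }
    return ranking, diagnostics


# --- TWIMS CCS calibration ----------------------------------------------------

@dataclass
class CCSCalibration:
    """Power-law TWIMS calibration Omega = A * t_D**B * z * sqrt(1/m + 1/m_gas)."""

    A: float
    B: float
    gas_mass: float = N2_GAS_MASS
    residuals: np.ndarray = field(default=None, repr=False)
    n_calibrants: int = 0

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("calibration constant A must be positive")


def _reduced_ccs(ccs, z, m_ion, m_gas):
    return np.asarray(ccs, float) / (np.asarray(z, float)
                                     * np.sqrt(1.0 / np.asarray(m_ion, float) + 1.0 / m_gas))


def fit_ccs_calibration(calibrants, gas_mass: float = N2_GAS_MASS) -> CCSCalibration:
    """Fit (A, B) from calibrants with columns (t_d, z, m_ion, ccs_ref).

    ln(Omega') = ln A + B ln t_D, least squares; requires >= 2 calibrants with
    positive corrected drift times.
    """
    df = calibrants if isinstance(calibrants, pd.DataFrame) else pd.DataFrame(
        calibrants, columns=["t_d", "z", "m_ion", "ccs_ref"])
    if len(df) < 2:
        raise ValueError("need at least 2 calibrants")
    if (df["t_d"] <= 0).any():
        raise ValueError("non-positive drift time in calibrant set")
    omega_p = _reduced_ccs(df["ccs_ref"], df["z"], df["m_ion"], gas_mass)
    x = np.log(df["t_d"].to_numpy(float))
    y = np.log(omega_p)
    coeff = np.polyfit(x, y, 1)
    B, lnA = float(coeff[0]), float(coeff[1])
    resid = y - (lnA + B * x)
    return CCSCalibration(A=float(np.exp(lnA)), B=B, gas_mass=gas_mass,
                          residuals=np.asarray(resid), n_calibrants=len(df))


def ccs_from_drift(t_d, z, m_ion, calibration: CCSCalibration):
    """Apply the calibration: Omega (A^2) from corrected drift time."""
    t_d = np.asarray(t_d, dtype=float)
    if np.any(t_d <= 0):
        raise ValueError("non-positive drift time")
    out = (calibration.A * t_d ** calibration.B * np.asarray(z, float)
           * np.sqrt(1.0 / np.asarray(m_ion, float) + 1.0 / calibration.gas_mass))
    return float(out) if out.ndim == 0 else out
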