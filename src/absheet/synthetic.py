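"""Fixtures and synthetic data with construction-time ground truth.

Ideal beta-sheet lattices in the four canonical arrangements (antiparallel /
parallel, in- / out-of-register), random monomer gases, synthetic MS/MS peak
lists and TWIMS calibrant sets.  Every fixture carries a :class:`GroundTruth`
computed from the construction itself (never by running the analysis code),
so the analysis stage can be tested against labels it had no hand in.

Lattice geometry note: the strand spacing default (5.8 A) is the spacing at
which the bundled bead geometry satisfies the engine's hydrogen-bond
formation criteria; experimental fibril diffraction spacings are similar but
not identical, and fixtures are built to be valid engine states first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (PeptideTopology, ParameterTable, AMINO_ACIDS,
                    CA_SPACING, NCO_X_OFFSET, PLEAT,
                    KIND_NH, KIND_CA, KIND_CO, KIND_SC)
from .engine import SystemState, make_state
from . import xlink

__all__ = [
    "SheetFixtureSpec", "GroundTruth", "build_sheet_fixture",
    "build_random_gas", "synthetic_peaklist", "synthetic_calibrants",
]

ARRANGEMENTS = ("antiparallel_in_register", "antiparallel_out_of_register",
                "parallel_in_register", "parallel_out_of_register")


@dataclass
class SheetFixtureSpec:
    arrangement: str
    n_strands: int = 8
    n_layers: int = 1
    registry_offset: int = 1          # used by *_out_of_register only
    strand_spacing: float = 5.8       # A, within-layer (see module docstring)
    layer_spacing: float = 9.9        # A, between stacked sheets
    seed: int = 0

    def __post_init__(self):
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.strand_spacing <= 0 or self.layer_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.arrangement.endswith("out_of_register") and self.registry_offset == 0:
            raise ValueError("out-of-register fixture needs a nonzero offset")
        if self.arrangement == "parallel_out_of_register" and self.registry_offset % 2:
            raise ValueError("parallel sheets shift in whole pleat repeats: "
                             "registry_offset must be even")

    @property
    def antiparallel(self) -> bool:
        return self.arrangement.startswith("antiparallel")

    @property
    def offset(self) -> int:
        return self.registry_offset if self.arrangement.endswith("out_of_register") else 0


@dataclass
class GroundTruth:
    """Construction-time labels for a sheet fixture."""

    arrangement: str
    pair_classifications: dict          # (chain_i, chain_j) -> (orientation, offset)
    pair_hbond_counts: dict             # (chain_i, chain_j) -> expected bond count
    n_hbonds: int
    beta_labels: np.ndarray             # (n_chains, n_residues) bool
    beta_percentage: float
    layer_count: int
    expected_nearest: dict              # focal residue label -> partner label
    chain_layer: np.ndarray             # layer index per chain


def _strand_coords(topology: PeptideTopology, reverse: bool, psi: float,
                   sides, x0: float, y0: float, z0: float) -> np.ndarray:
    """Bead coordinates of one ideal strand along x.

    ``reverse`` runs the chain N->C toward -x (180 deg rotation about y);
    ``psi`` (+-1) selects the pleat phase of the NH/CO offsets; ``sides``
    gives the +-z face of each sidechain bead.  All of these leave every
    bond/pseudobond wall at its nominal length.
    """
    seq = topology.sequence
    n = len(seq)
    coords = np.zeros((topology.n_beads, 3))
    b = 0
    for a in range(n):
        s = psi * (1.0 if a % 2 == 0 else -1.0)
        if not reverse:
            xca = x0 + CA_SPACING * a
            xnh, xco = xca - NCO_X_OFFSET, xca + NCO_X_OFFSET
        else:
            xca = x0 + CA_SPACING * (n - 1 - a)
            xnh, xco = xca + NCO_X_OFFSET, xca - NCO_X_OFFSET
        coords[b] = (xnh, y0 + PLEAT * s, z0); b += 1          # NH
        coords[b] = (xca, y0, z0); b += 1                      # CaH
        coords[b] = (xco, y0 + PLEAT * s, z0); b += 1          # CO
        if seq[a] != "G":
            off = AMINO_ACIDS[seq[a]][1]
            coords[b] = (xca, y0, z0 + off * sides[a]); b += 1  # SC
    return coords


def _candidate_bonds(topology, coords_a, coords_b, hb_width, aux_min):
    """Geometric H-bond candidates between two ideal strands.

    Returns a list of (residue_a, residue_b, donor_is_a) for NH...CO pairs
    within the well width whose four auxiliary beads clear ``aux_min`` --
    the same directionality rule the engine applies, evaluated directly on
    the construction coordinates.
    """
    n = topology.n_residues
    nh = {r: topology.backbone_bead_index(r, KIND_NH) for r in range(n)}
    ca = {r: topology.backbone_bead_index(r, KIND_CA) for r in range(n)}
    co = {r: topology.backbone_bead_index(r, KIND_CO) for r in range(n)}

    def dist(p, q):
        return float(np.linalg.norm(p - q))

    def aux_ok(cd, ra, ca_, rb, cb):
        # donor NH on cd[ra]; acceptor CO on cb[rb]
        pn = cd[nh[ra]]; pc = cb[co[rb]]
        checks = [(cd[ca[ra]], pc)]
        if ra > 0:
            checks.append((cd[co[ra - 1]], pc))
        checks.append((cb[ca[rb]], pn))
        if rb + 1 < n:
            checks.append((cb[nh[rb + 1]], pn))
        return all(dist(p, q) >= aux_min for p, q in checks)

    out = []
    for ra in range(n):
        for rb in range(n):
            if dist(coords_a[nh[ra]], coords_b[co[rb]]) < hb_width and \
                    aux_ok(coords_a, ra, None, rb, coords_b):
                out.append((ra, rb, True))
            if dist(coords_b[nh[rb]], coords_a[co[ra]]) < hb_width and \
                    aux_ok(coords_b, rb, None, ra, coords_a):
                out.append((ra, rb, False))
    return out


def build_sheet_fixture(spec: SheetFixtureSpec, topology: PeptideTopology,
                        table: ParameterTable, box_length: float = None,
                        t_star: float = None):
    """Ideal beta-sheet lattice as an engine-ready state plus ground truth.

    Strands run along x, stack along y within a layer, and layers stack along
    z.  The pleat phase of each strand is chosen so that every adjacent pair
    forms the maximal set of hydrogen bonds the directional criterion allows;
    sidechain faces are chosen so structurally opposite residues share a
    sheet face (as in a packed fibril).
    """
    n = topology.n_residues
    D, S = spec.strand_spacing, spec.layer_spacing
    ns, nl = spec.n_strands, spec.n_layers
    if ns < 2:
        raise ValueError("need at least 2 strands")
    f = spec.offset
    if abs(f) >= n:
        raise ValueError("offset magnitude must be below chain length")

    # per-strand parameters within one layer
    reverse = [spec.antiparallel and (k % 2 == 1) for k in range(ns)]
    xshift = [CA_SPACING * f * (k % 2) for k in range(ns)]

    # one side pattern for every strand keeps structurally opposite residues
    # on the same sheet face (as in a packed fibril)
    sides0 = [1.0 if a % 2 == 0 else -1.0 for a in range(n)]

    strand_coords = []
    psis = []
    for k in range(ns):
        sides = sides0
        if k == 0:
            psi = 1.0
        else:
            # pick the pleat phase that bonds to the previous strand
            best, psi = -1, 1.0
            for trial in (1.0, -1.0):
                c = _strand_coords(topology, reverse[k], trial, sides,
                                   xshift[k], k * D, 0.0)
                nb = len(_candidate_bonds(topology, strand_coords[k - 1], c,
                                          table.hb_width, table.hb_aux_min))
                if nb > best:
                    best, psi = nb, trial
        strand_coords.append(_strand_coords(topology, reverse[k], psi, sides,
                                            xshift[k], k * D, 0.0))
        psis.append(psi)

    # replicate layers along z
    all_coords = []
    chain_layer = []
    for l in range(nl):
        for k in range(ns):
            c = strand_coords[k].copy()
            c[:, 2] += l * S
            all_coords.append(c)
            chain_layer.append(l)
    n_chains = ns * nl
    positions = np.vstack(all_coords)

    if box_length is None:
        extent = positions.max(axis=0) - positions.min(axis=0)
        box_length = float(extent.max() + 24.0)
    positions = positions - positions.min(axis=0) + 2.0

    # --- ground truth from the construction --------------------------------
    pair_cls, pair_counts = {}, {}
    bonds_by_pair = {}
    for k in range(ns - 1):
        cands = _candidate_bonds(topology, strand_coords[k], strand_coords[k + 1],
                                 table.hb_width, table.hb_aux_min)
        bonds_by_pair[(k, k + 1)] = cands
        orientation = "antiparallel" if spec.antiparallel else "parallel"
        # registry offset from the construction's own residue pairings: the
        # median pairing offset (ties toward zero).  For in-register lattices
        # this is exactly 0; for shifted lattices it reflects the slot shift
        # (truncated at chain ends for short chains).
        if cands:
            if spec.antiparallel:
                offs = sorted(ra + rb - (n - 1) for (ra, rb, _) in cands)
            else:
                offs = sorted(rb - ra for (ra, rb, _) in cands)
            med = 0.5 * (offs[(len(offs) - 1) // 2] + offs[len(offs) // 2])
            offset = int(np.trunc(med))
        else:
            offset = 0
        pair_counts[(k, k + 1)] = len(cands)
        if len(cands) >= 2:
            pair_cls[(k, k + 1)] = (orientation, offset)

    beta = np.zeros((ns, n), dtype=bool)
    for (k, k2), cands in bonds_by_pair.items():
        if len(cands) < 2:
            continue
        for (ra, rb, donor_a) in cands:
            for c, r in ((k, ra), (k2, rb)):
                beta[c, max(0, r - 1):min(n, r + 2)] = True
    beta_full = np.tile(beta, (nl, 1))
    n_hb_layer = sum(len(c) for c in bonds_by_pair.values())

    # geometric nearest interpeptide sidechain partner per residue (layer 0
    # interior strand), from the lattice coordinates alone.  Only defined for
    # in-register lattices: with a registry shift every residue faces two
    # equally distant partners (a-f and a+f on opposite neighbours), so the
    # modal partner is ambiguous by construction.
    expected_nearest = {}
    sc_of = {r: topology.sc_bead_index(r) for r in range(n)}
    interior = 1 if ns > 2 else 0
    for ra in range(n if f == 0 else 0):
        if sc_of[ra] < 0:
            continue
        p = strand_coords[interior][sc_of[ra]]
        best, best_lab = np.inf, None
        for k in range(ns):
            if k == interior:
                continue
            for rb in range(n):
                if sc_of[rb] < 0:
                    continue
                q = strand_coords[k][sc_of[rb]]
                dd = float(np.linalg.norm(p - q))
                if dd < best:
                    best, best_lab = dd, rb
        if best_lab is not None:
            seq = topology.sequence
            expected_nearest[f"{seq[ra]}{16 + ra}"] = f"{seq[best_lab]}{16 + best_lab}"

    gt = GroundTruth(
        arrangement=spec.arrangement,
        pair_classifications={(i + l * ns, j + l * ns): v
                              for l in range(nl) for (i, j), v in pair_cls.items()},
        pair_hbond_counts={(i + l * ns, j + l * ns): c
                           for l in range(nl) for (i, j), c in pair_counts.items()},
        n_hbonds=n_hb_layer * nl,
        beta_labels=beta_full,
        beta_percentage=100.0 * beta_full.sum() / beta_full.size,
        layer_count=nl,
        expected_nearest=expected_nearest,
        chain_layer=np.array(chain_layer),
    )

    if t_star is not None:
        from .setup_io import init_velocities
        masses = np.tile([b.mass for b in topology.beads], n_chains)
        vel = init_velocities(masses, t_star, spec.seed)
    else:
        vel = np.zeros_like(positions)
    state = make_state(topology, n_chains, positions, vel, box_length, table,
                       detect_hbonds=True, seed=spec.seed)
    nhb = len(state.hbonds())
    if nhb != gt.n_hbonds:
        raise AssertionError(
            f"fixture inconsistency: engine detected {nhb} H-bonds, "
            f"construction expects {gt.n_hbonds}")
    return state, gt


def build_random_gas(n: int, box_length: float, seed: int,
                     topology: PeptideTopology, table: ParameterTable,
                     t_star: float = None) -> SystemState:
    """Random monomer gas: overlap-free, zero H-bonds, zero beta content."""
    from .setup_io import SystemSpec, random_initial_configuration, init_velocities

    spec = SystemSpec(n_peptides=n, sequence=topology.sequence,
                      box_length=box_length)
    positions, L = random_initial_configuration(spec, topology, seed)
    if t_star is not None:
        masses = np.tile([b.mass for b in topology.beads], n)
        vel = init_velocities(masses, t_star, seed + 1)
    else:
        vel = np.zeros_like(positions)
    return make_state(topology, n, positions, vel, L, table,
                      detect_hbonds=True, seed=seed)


def synthetic_peaklist(species: xlink.MolecularSpecies, charge_states=(1,),
                       noise: dict = None, seed: int = 0,
                       include_double: bool = True) -> pd.DataFrame:
    """Peak list (m/z, z) of a species' fragment ions, optionally corrupted.

    ``noise`` keys: ``mass_jitter_da`` (gaussian m/z jitter) and
    ``decoy_fraction`` (extra uniform decoy peaks as a fraction of the true
    count).  The generating cross-link site is recorded in ``.attrs``.
    """
    rng = np.random.default_rng(seed)
    frags = xlink.fragment_ions(species, include_double=include_double)
    rows = []
    for f in frags:
        for z in charge_states:
            rows.append({"mz": f.mz(z), "z": z, "label": f.label})
    df = pd.DataFrame(rows).drop_duplicates(subset=["mz", "z"]).reset_index(drop=True)
    noise = noise or {}
    jitter = float(noise.get("mass_jitter_da", 0.0))
    if jitter > 0:
        df["mz"] = df["mz"] + rng.normal(0.0, jitter, size=len(df))
    decoy = float(noise.get("decoy_fraction", 0.0))
    if decoy > 0:
        n_decoy = int(round(decoy * len(df)))
        lo, hi = df["mz"].min(), df["mz"].max()
        decoys = pd.DataFrame({
            "mz": rng.uniform(lo, hi, size=n_decoy),
            "z": rng.choice(list(charge_states), size=n_decoy),
            "label": ["decoy"] * n_decoy,
        })
        df = pd.concat([df, decoys], ignore_index=True)
    df = df.sort_values("mz").reset_index(drop=True)
    df.attrs["crosslink"] = species.crosslink
    return df


def synthetic_calibrants(A: float, B: float, n: int, noise: float = 0.0,
                         seed: int = 0, gas_mass: float = xlink.N2_GAS_MASS
                         ) -> pd.DataFrame:
    """Calibrant table (t_d, z, m_ion, ccs_ref) from the power law itself.

    Drift times are log-uniform in [0.5, 20] ms; reference CCS values follow
    the calibration equation with optional multiplicative gaussian noise.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    if n < 2:
        raise ValueError("need at least 2 calibrants")
    rng = np.random.default_rng(seed)
    t_d = np.exp(rng.uniform(np.log(0.5), np.log(20.0), size=n))
    z = rng.integers(1, 4, size=n).astype(float)
    m_ion = rng.uniform(500.0, 5000.0, size=n)
    ccs = A * t_d ** B * z * np.sqrt(1.0 / m_ion + 1.0 / gas_mass)
    if noise > 0:
        ccs = ccs * (1.0 + noise * rng.standard_normal(n))
    return pd.DataFrame({"t_d": t_d, "z": z, "m_ion": m_ion, "ccs_ref": ccs})
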