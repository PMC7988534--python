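"""Coarse-grained peptide representation and square-well interaction tables.

The model follows the four-bead-per-residue convention used for square-well
protein simulations: three backbone beads (united-atom NH, CaH, CO) plus a
single sidechain bead per non-glycine residue.  Beads on a chain are held
together by hard-wall bonds (covalent) and pseudobonds (which fix backbone
planarity, pleat alternation and sidechain chirality); every bond length may
fluctuate between ``(1 - tol)`` and ``(1 + tol)`` of its nominal value.

Nonbonded interactions are square wells: a hard core at the contact distance,
a well of given width and depth (in units of the hydrogen-bond well depth
eps_HB) for sidechain-sidechain pairs, and a directional well of depth
1.0 eps_HB for backbone NH...CO hydrogen bonds.

The published parameter set behind this class of models (210 independent
sidechain well widths, 19 shared depths) is not reproduced here; the bundled
default table is an explicitly approximate scheme (mutually attractive
hydrophobics, attractive opposite charges, hard-sphere same charges) in a
versioned plain-text format that can hold any complete 20x20 assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "BeadSpec",
    "Modification",
    "MODIFICATIONS",
    "PeptideTopology",
    "ParameterTable",
    "build_topology",
    "load_parameter_table",
    "default_parameter_table",
    "pair_potential",
    "EPS_HB_KJ_PER_MOL",
]

# hydrogen-bond well depth in laboratory units; everything internal is eps_HB = 1
EPS_HB_KJ_PER_MOL = 12.47

# backbone united-atom beads: diameter (A), mass (u)
BACKBONE_DIAMETER = 3.3
NH_MASS = 15.015
CA_MASS = 13.019
CO_MASS = 28.010

# strand geometry of the extended template (A)
CA_SPACING = 3.8          # Calpha-Calpha along the strand axis
NCO_X_OFFSET = 1.25       # NH / CO displacement along the axis from Calpha
PLEAT = 0.8               # per-residue alternating NH/CO offset normal to the axis
BOND_TOLERANCE = 0.02     # hard walls at nominal * (1 -+ tol)

# per-residue sidechain bead: (diameter A, Calpha-SC offset A, mass u,
# hydrophobicity weight, charge sign)
AMINO_ACIDS = {
    "A": (2.7, 1.60, 15.0, 0.45, 0),
    "R": (4.6, 3.20, 100.1, 0.00, +1),
    "N": (3.8, 2.20, 58.1, 0.00, 0),
    "D": (3.6, 2.10, 59.0, 0.00, -1),
    "C": (3.6, 2.10, 47.1, 0.60, 0),
    "Q": (4.1, 2.50, 72.1, 0.00, 0),
    "E": (3.9, 2.40, 73.1, 0.00, -1),
    "G": (0.0, 0.00, 0.0, 0.00, 0),
    "H": (4.4, 2.60, 81.1, 0.00, 0),
    "I": (4.4, 2.30, 57.1, 1.00, 0),
    "K": (4.4, 2.60, 72.1, 0.00, +1),
    "L": (4.4, 2.30, 57.1, 0.95, 0),
    "M": (4.3, 2.50, 75.1, 0.65, 0),
    "F": (4.5, 2.50, 91.1, 0.90, 0),
    "P": (4.0, 1.90, 41.1, 0.00, 0),
    "S": (3.2, 1.70, 31.0, 0.00, 0),
    "T": (3.7, 2.00, 45.1, 0.00, 0),
    "W": (5.0, 2.90, 130.2, 0.50, 0),
    "Y": (4.7, 2.70, 107.1, 0.30, 0),
    "V": (4.0, 1.95, 43.1, 0.95, 0),
}

RESIDUE_ORDER = sorted(AMINO_ACIDS)
RESIDUE_INDEX = {r: i for i, r in enumerate(RESIDUE_ORDER)}

# bead kind codes shared with the engine kernel
KIND_NH, KIND_CA, KIND_CO, KIND_SC = 0, 1, 2, 3
_KIND_LABEL = {KIND_NH: "NH", KIND_CA: "CaH", KIND_CO: "CO"}


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: label, hard-core diameter (A), mass (u)."""

    label: str
    diameter: float
    mass: float

    def __post_init__(self):
        if self.diameter < 0 or self.mass <= 0:
            raise ValueError(f"bad bead spec {self.label}: diameter/mass must be positive")


@dataclass(frozen=True)
class Modification:
    """A covalent residue modification (used by the MS layer).

    ``composition_delta`` maps element symbol -> count change;
    ``mass_delta_mono`` must equal the monoisotopic mass of that delta.
    """

    id: str
    composition_delta: dict
    mass_delta_mono: float
    attaches_to: str

    def __post_init__(self):
        from .xlink import composition_mono_mass  # local import: avoid cycle

        ref = composition_mono_mass(self.composition_delta)
        if abs(ref - self.mass_delta_mono) > 1e-6:
            raise ValueError(
                f"modification {self.id}: mass delta {self.mass_delta_mono} inconsistent "
                f"with composition (expected {ref:.6f})"
            )


def _tfmd():
    # 4-(trifluoromethyl)diazirine on the phenyl ring: +C2N2F3, -H
    from .xlink import composition_mono_mass

    delta = {"C": 2, "N": 2, "F": 3, "H": -1}
    return Modification("TFMD", delta, composition_mono_mass(delta), attaches_to="F")


MODIFICATIONS = {"TFMD": _tfmd()}


@dataclass
class PeptideTopology:
    """Bead/bond description of one coarse-grained chain.

    ``bonds`` are covalent, ``pseudobonds`` enforce backbone planarity, pleat
    alternation and sidechain placement; both are (bead_i, bead_j, lmin, lmax)
    hard-wall ranges.  ``template_coords`` is an extended (all-trans) strand
    conformation that satisfies every wall at its nominal length.
    """

    sequence: str
    modifications: tuple = ()
    beads: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    pseudobonds: list = field(default_factory=list)
    template_coords: np.ndarray = None
    bead_kind: np.ndarray = None       # KIND_* per bead
    bead_residue: np.ndarray = None    # residue index per bead

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def sc_bead_index(self, residue: int) -> int:
        """Bead index of the sidechain bead of ``residue`` (-1 for glycine)."""
        idx = np.nonzero((self.bead_residue == residue) & (self.bead_kind == KIND_SC))[0]
        return int(idx[0]) if idx.size else -1

    def backbone_bead_index(self, residue: int, kind: int) -> int:
        idx = np.nonzero((self.bead_residue == residue) & (self.bead_kind == kind))[0]
        return int(idx[0])

    def to_text(self) -> str:
        """Human-readable dump of beads and walls for inspection."""
        lines = [f"# topology {self.sequence} ({self.n_beads} beads)"]
        lines.append("# idx  label      res  diameter  mass")
        for i, b in enumerate(self.beads):
            lines.append(
                f"{i:5d}  {b.label:<9s} {int(self.bead_residue[i]):4d}  "
                f"{b.diameter:8.3f}  {b.mass:7.3f}"
            )
        for name, lst in (("bond", self.bonds), ("pseudobond", self.pseudobonds)):
            for i, j, lo, hi in lst:
                lines.append(f"# {name} {i:4d} {j:4d}  [{lo:.4f}, {hi:.4f}]")
        return "\n".join(lines)


def build_topology(sequence: str, modifications=()) -> PeptideTopology:
    """Build the bead/bond topology of one chain.

    Every non-glycine residue contributes NH, CaH, CO and one sidechain bead
    (glycine: backbone only).  Modifications are (position, id) pairs with
    1-based positions; in the dynamics a modified sidechain only changes bead
    mass (the simulated peptide is the unmodified sequence otherwise).
    """
    if not sequence:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in AMINO_ACIDS:
            raise ValueError(f"unknown residue letter {ch!r}")
    mods = {}
    for pos, mid in modifications:
        if mid not in MODIFICATIONS:
            raise ValueError(f"unknown modification {mid!r}")
        if not (1 <= pos <= len(sequence)):
            raise ValueError(f"modification position {pos} outside sequence")
        res = sequence[pos - 1]
        m = MODIFICATIONS[mid]
        if res != m.attaches_to:
            raise ValueError(f"modification {mid} attaches to {m.attaches_to}, not {res}")
        mods[pos - 1] = m

    beads, kinds, resid = [], [], []
    coords = []
    sc_index = {}
    for i, res in enumerate(sequence):
        s = -1.0 if i % 2 else 1.0  # pleat parity
        x = CA_SPACING * i
        sigma_sc, off_sc, m_sc, _, _ = AMINO_ACIDS[res]
        beads.append(BeadSpec("NH", BACKBONE_DIAMETER, NH_MASS))
        coords.append((x - NCO_X_OFFSET, PLEAT * s, 0.0))
        kinds.append(KIND_NH); resid.append(i)
        beads.append(BeadSpec("CaH", BACKBONE_DIAMETER, CA_MASS))
        coords.append((x, 0.0, 0.0))
        kinds.append(KIND_CA); resid.append(i)
        beads.append(BeadSpec("CO", BACKBONE_DIAMETER, CO_MASS))
        coords.append((x + NCO_X_OFFSET, PLEAT * s, 0.0))
        kinds.append(KIND_CO); resid.append(i)
        if res != "G":
            mass = m_sc + (mods[i].mass_delta_mono if i in mods else 0.0)
            label = f"SC-{res}" + (f"+{mods[i].id}" if i in mods else "")
            beads.append(BeadSpec(label, sigma_sc, mass))
            side = 1.0 if i % 2 == 0 else -1.0  # alternate sheet faces
            coords.append((x, 0.0, off_sc * side))
            kinds.append(KIND_SC); resid.append(i)
            sc_index[i] = len(beads) - 1

    coords = np.asarray(coords, dtype=float)
    kinds = np.asarray(kinds, dtype=np.int8)
    resid = np.asarray(resid, dtype=np.int32)

    def bead(i, kind):
        sel = np.nonzero((resid == i) & (kinds == kind))[0]
        return int(sel[0])

    def wall(i, j):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        return (i, j, d * (1 - BOND_TOLERANCE), d * (1 + BOND_TOLERANCE))

    bonds, pseudo = [], []
    n = len(sequence)
    for i in range(n):
        nh, ca, co = bead(i, KIND_NH), bead(i, KIND_CA), bead(i, KIND_CO)
        bonds.append(wall(nh, ca))
        bonds.append(wall(ca, co))
        pseudo.append(wall(nh, co))
        if i in sc_index or sequence[i] != "G":
            if sequence[i] != "G":
                sc = sc_index[i]
                bonds.append(wall(ca, sc))
                pseudo.append(wall(nh, sc))
                pseudo.append(wall(co, sc))
        if i + 1 < n:
            nh2, ca2 = bead(i + 1, KIND_NH), bead(i + 1, KIND_CA)
            bonds.append(wall(co, nh2))
            pseudo.append(wall(ca, ca2))
            pseudo.append(wall(ca, nh2))
            pseudo.append(wall(co, ca2))

    return PeptideTopology(
        sequence=sequence,
        modifications=tuple(modifications),
        beads=beads,
        bonds=bonds,
        pseudobonds=pseudo,
        template_coords=coords,
        bead_kind=kinds,
        bead_residue=resid,
    )


class ParameterTable:
    """Square-well interaction parameters.

    Sidechain pair wells are stored symmetrically per unordered residue-type
    pair: ``width`` (outer well radius, A) and ``depth`` (eps_HB units,
    attractive > 0, 0 = hard sphere only).  Hydrogen bonding uses a single
    well ``hb_width`` of depth ``hb_depth`` (1.0 by definition of the energy
    unit) with the auxiliary-bead linearity distance ``hb_aux_min``.
    """

    def __init__(self, pair_well_width, pair_well_depth, hb_width=5.0,
                 hb_depth=1.0, hb_aux_min=4.5, geom=None, version=1):
        self.pair_well_width = dict(pair_well_width)
        self.pair_well_depth = dict(pair_well_depth)
        self.hb_width = float(hb_width)
        self.hb_depth = float(hb_depth)
        self.hb_aux_min = float(hb_aux_min)
        self.geom = dict(geom or {})
        self.version = version
        self.validate()

    @staticmethod
    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    def sc_diameter(self, res: str) -> float:
        return self.geom.get(("SC_DIAMETER", res), AMINO_ACIDS[res][0])

    def contact_distance(self, a: str, b: str) -> float:
        return 0.5 * (self.sc_diameter(a) + self.sc_diameter(b))

    def width(self, a: str, b: str) -> float:
        return self.pair_well_width[self._key(a, b)]

    def depth(self, a: str, b: str) -> float:
        return self.pair_well_depth[self._key(a, b)]

    def validate(self):
        expected = {self._key(a, b) for a in AMINO_ACIDS for b in AMINO_ACIDS}
        missing = sorted(expected - set(self.pair_well_width))
        if missing:
            raise ValueError(f"parameter table missing pair {missing[0]}")
        for (a, b), w in self.pair_well_width.items():
            if w <= 0:
                raise ValueError(f"non-positive well width for pair ({a},{b})")
            if w < self.contact_distance(a, b) - 1e-9:
                raise ValueError(
                    f"well width {w} for pair ({a},{b}) below contact distance "
                    f"{self.contact_distance(a, b)}"
                )
        if self.hb_width <= 0 or self.hb_depth <= 0:
            raise ValueError("hydrogen-bond well must have positive width and depth")
        return True

    # --- energy unit conversion -------------------------------------------------
    @staticmethod
    def to_kj_per_mol(e_eps_hb: float, eps_hb: float = EPS_HB_KJ_PER_MOL) -> float:
        return e_eps_hb * eps_hb

    @staticmethod
    def from_kj_per_mol(e_kj: float, eps_hb: float = EPS_HB_KJ_PER_MOL) -> float:
        return e_kj / eps_hb

    # --- numeric 20x20 arrays for the engine kernel -------------------------------
    def as_arrays(self):
        nt = len(RESIDUE_ORDER)
        W = np.zeros((nt, nt)); E = np.zeros((nt, nt))
        for a in RESIDUE_ORDER:
            for b in RESIDUE_ORDER:
                W[RESIDUE_INDEX[a], RESIDUE_INDEX[b]] = self.width(a, b)
                E[RESIDUE_INDEX[a], RESIDUE_INDEX[b]] = self.depth(a, b)
        return W, E

    def write(self, path):
        lines = ["# absheet square-well parameter table", f"VERSION {self.version}",
                 f"HB WIDTH {self.hb_width}", f"HB DEPTH {self.hb_depth}",
                 f"HB AUXMIN {self.hb_aux_min}"]
        for key, v in sorted(self.geom.items(), key=lambda kv: str(kv[0])):
            if isinstance(key, tuple):
                lines.append(f"GEOM {' '.join(str(p) for p in key)} {v}")
            else:
                lines.append(f"GEOM {key} {v}")
        for (a, b) in sorted(self.pair_well_width):
            lines.append(
                f"PAIR {a} {b} {self.pair_well_width[(a, b)]:.4f} "
                f"{self.pair_well_depth[(a, b)]:.4f}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def pair_potential(residue_i: str, residue_j: str, table: ParameterTable):
    """Square-well triple (contact_distance, well_width, well_depth) for a
    sidechain-sidechain pair.  Depth 0 means hard-sphere-only."""
    for r in (residue_i, residue_j):
        if r not in AMINO_ACIDS:
            raise KeyError(f"unknown residue type {r!r}")
    return (
        table.contact_distance(residue_i, residue_j),
        table.width(residue_i, residue_j),
        table.depth(residue_i, residue_j),
    )


def _parse_table(lines, source="<table>"):
    width, depth, geom = {}, {}, {}
    hb = {"WIDTH": 5.0, "DEPTH": 1.0, "AUXMIN": 4.5}
    version = None
    for ln, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        tag = parts[0].upper()
        if tag == "VERSION":
            version = int(parts[1])
        elif tag == "HB":
            hb[parts[1].upper()] = float(parts[2])
        elif tag == "GEOM":
            if len(parts) == 3:
                geom[parts[1]] = float(parts[2])
            else:
                geom[(parts[1], parts[2])] = float(parts[3])
        elif tag == "PAIR":
            a, b, w, e = parts[1], parts[2], float(parts[3]), float(parts[4])
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
                raise ValueError(f"{source}:{ln}: unknown residue in pair ({a},{b})")
            key = ParameterTable._key(a, b)
            if key in width and not (math.isclose(width[key], w) and math.isclose(depth[key], e)):
                raise ValueError(f"{source}:{ln}: conflicting duplicate entry for pair {key}")
            width[key] = w
            depth[key] = e
        else:
            raise ValueError(f"{source}:{ln}: unrecognized record {tag!r}")
    if version is None:
        raise ValueError(f"{source}: missing VERSION header")
    return ParameterTable(width, depth, hb_width=hb["WIDTH"], hb_depth=hb["DEPTH"],
                          hb_aux_min=hb["AUXMIN"], geom=geom, version=version)


def load_parameter_table(path) -> ParameterTable:
    """Load a parameter table from the versioned plain-text format."""
    with open(path) as fh:
        return _parse_table(fh, source=str(path))


def default_parameter_table() -> ParameterTable:
    """The bundled approximate default table (see module docstring)."""
    text = resources.files("absheet").joinpath("data/default_table.txt").read_text()
    return _parse_table(text.splitlines(), source="data/default_table.txt")


def make_default_table() -> ParameterTable:
    """Construct the bundled default table programmatically.

    Scheme: hydrophobic pairs attract with depth 0.28 * h_i * h_j (h from the
    per-residue hydrophobicity weight), oppositely charged pairs attract at
    0.25, same-charge pairs are hard-sphere only, everything else is
    hard-sphere only.  Well width = contact distance + 2.0 A for every pair.
    """
    width, depth = {}, {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            key = ParameterTable._key(a, b)
            if key in width:
                continue
            sa, _, _, ha, qa = AMINO_ACIDS[a]
            sb, _, _, hb_, qb = AMINO_ACIDS[b]
            w = 0.5 * (sa + sb) + 2.0
            if ha > 0 and hb_ > 0:
                e = round(0.28 * ha * hb_, 4)
            elif qa * qb < 0:
                e = 0.25
            else:
                e = 0.0
            width[key] = round(w, 4)
            depth[key] = e
    geom = {"BACKBONE_DIAMETER": BACKBONE_DIAMETER, "BOND_TOLERANCE": BOND_TOLERANCE,
            "CA_SPACING": CA_SPACING}
    for r, (sd, off, _, _, _) in AMINO_ACIDS.items():
        geom[("SC_DIAMETER", r)] = sd
        geom[("SC_OFFSET", r)] = off
    return ParameterTable(width, depth, geom=geom)
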