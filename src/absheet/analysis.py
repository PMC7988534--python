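"""Trajectory observables: hydrogen-bond maps, beta-sheet content, strand
orientation/registry classification, oligomer clustering, nearest interpeptide
sidechain contacts, and energy/beta time series.

Conventions (the underlying coarse-grained model does not define secondary
structure, so these are declared here and used consistently):

* A strand pair is *classified* when two chains share at least two hydrogen
  bonds.  Orientation comes from the sign of the covariance between paired
  residue indices across the pair's bonds; the registry offset is the median
  pairing offset (ties broken toward zero, robust to edge fraying):
  ``a + b - (n - 1)`` for antiparallel and ``b - a`` for parallel pairs,
  so offset 0 is in-register in both cases.
* A residue is a *beta-sheet residue* when its chain belongs to a classified
  pair and the residue is within one position of a residue donating or
  accepting one of that pair's hydrogen bonds.
* A sidechain *contact* is an occupied square well; for hard-sphere-only
  pairs the fallback cutoff is 1.2x the contact distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .engine import Snapshot, Trajectory
from .model import KIND_NH, KIND_CO, KIND_SC

__all__ = [
    "HBondRecord", "StrandPairClassification", "EnergyProfile",
    "hydrogen_bond_map", "beta_sheet_fraction", "classify_strand_pair",
    "nearest_sidechain_contacts", "cluster_oligomers", "sheet_layer_count",
    "energy_and_beta_timeseries", "block_average", "residue_label",
]


@dataclass(frozen=True)
class HBondRecord:
    donor_chain: int
    donor_residue: int
    acceptor_chain: int
    acceptor_residue: int


@dataclass(frozen=True)
class StrandPairClassification:
    chain_i: int
    chain_j: int
    orientation: str          # "parallel" | "antiparallel"
    registry_offset: int      # 0 = in-register
    n_hbonds: int


@dataclass
class EnergyProfile:
    times: np.ndarray
    potential_energies: np.ndarray     # eps_HB
    beta_percentages: np.ndarray       # 0..100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_tau": self.times,
                             "potential_energy_epsHB": self.potential_energies,
                             "beta_pct": self.beta_percentages})


def residue_label(snapshot_or_meta, residue_index: int, start_number: int = 16) -> str:
    """Human label like F20 for residue index 4 of KLVFFAE numbered from 16."""
    meta = snapshot_or_meta.meta if hasattr(snapshot_or_meta, "meta") else snapshot_or_meta
    return f"{meta['sequence'][residue_index]}{start_number + residue_index}"


def hydrogen_bond_map(snapshot: Snapshot):
    """The engine's live H-bond set as residue-level records."""
    meta = snapshot.meta
    out = []
    for (d, a) in snapshot.hbonds:
        out.append(HBondRecord(int(meta["chain"][d]), int(meta["resi"][d]),
                               int(meta["chain"][a]), int(meta["resi"][a])))
    return out


def _pair_bonds(hbmap, ci, cj):
    """Residue pairings (a on ci, b on cj) over the bonds between two chains."""
    ab = []
    for r in hbmap:
        if r.donor_chain == ci and r.acceptor_chain == cj:
            ab.append((r.donor_residue, r.acceptor_residue))
        elif r.donor_chain == cj and r.acceptor_chain == ci:
            ab.append((r.acceptor_residue, r.donor_residue))
    return ab


def classify_strand_pair(chain_i: int, chain_j: int, hbmap, n_residues: int):
    """Orientation + registry offset for a hydrogen-bonded strand pair.

    Returns None when the pair shares fewer than two H-bonds or when the
    pairing carries no orientation signal.  Swapping the arguments flips the
    sign of the offset consistently.
    """
    ab = _pair_bonds(hbmap, chain_i, chain_j)
    if len(ab) < 2:
        return None
    a = np.array([p[0] for p in ab], dtype=float)
    b = np.array([p[1] for p in ab], dtype=float)
    cov = float(((a - a.mean()) * (b - b.mean())).sum())
    if cov > 1e-9:
        orientation = "parallel"
        offsets = b - a
    elif cov < -1e-9:
        orientation = "antiparallel"
        offsets = a + b - (n_residues - 1)
    else:
        return None
    med = float(np.median(offsets))
    offset = int(np.trunc(med))  # halfway ties resolve toward zero
    return StrandPairClassification(chain_i, chain_j, orientation, offset, len(ab))


def _chain_count(meta):
    return int(meta["chain"].max()) + 1


def classified_pairs(snapshot: Snapshot):
    """All classified strand pairs (i < j) in a snapshot."""
    meta = snapshot.meta
    n_res = len(meta["sequence"])
    hbmap = hydrogen_bond_map(snapshot)
    counts = Counter()
    for r in hbmap:
        if r.donor_chain != r.acceptor_chain:
            counts[tuple(sorted((r.donor_chain, r.acceptor_chain)))] += 1
    out = []
    for (ci, cj), n in counts.items():
        if n >= 2:
            cls = classify_strand_pair(ci, cj, hbmap, n_res)
            if cls is not None:
                out.append(cls)
    return out


def beta_sheet_fraction(snapshot: Snapshot) -> float:
    """Percentage of residues in beta-sheet structure (see module conventions)."""
    meta = snapshot.meta
    n_res = len(meta["sequence"])
    n_chains = _chain_count(meta)
    hbmap = hydrogen_bond_map(snapshot)
    pairs = classified_pairs(snapshot)
    beta = np.zeros((n_chains, n_res), dtype=bool)
    classified = {(c.chain_i, c.chain_j) for c in pairs}
    classified |= {(j, i) for (i, j) in classified}
    for r in hbmap:
        if r.donor_chain == r.acceptor_chain:
            continue
        if (r.donor_chain, r.acceptor_chain) not in classified:
            continue
        for c, res in ((r.donor_chain, r.donor_residue),
                       (r.acceptor_chain, r.acceptor_residue)):
            lo = max(0, res - 1)
            hi = min(n_res, res + 2)
            beta[c, lo:hi] = True
    return 100.0 * beta.sum() / beta.size


def _sc_positions(snapshot):
    meta = snapshot.meta
    sc = np.nonzero(meta["kind"] == KIND_SC)[0]
    return sc, snapshot.positions[sc]


def nearest_sidechain_contacts(snapshot: Snapshot, focal_residue: int,
                               start_number: int = 16) -> Counter:
    """Nearest interpeptide sidechain partner identities for a focal residue.

    For every chain, the sidechain bead of ``focal_residue`` (index or label
    like "F20") looks for the closest sidechain bead on any *other* chain;
    the partner is tallied iff it lies inside the pair's square well (or
    within 1.2x contact distance for depth-0 pairs).  Returns a Counter of
    partner residue labels.
    """
    meta = snapshot.meta
    seq = meta["sequence"]
    if isinstance(focal_residue, str):
        idx = [i for i in range(len(seq))
               if residue_label(meta, i, start_number) == focal_residue]
        if not idx:
            raise ValueError(f"residue {focal_residue} not in sequence")
        focal = idx[0]
    else:
        focal = int(focal_residue)
        if not 0 <= focal < len(seq):
            raise ValueError("focal residue outside sequence")
    table = meta["table"]
    L = snapshot.box_length
    sc_idx, sc_pos = _sc_positions(snapshot)
    sc_chain = meta["chain"][sc_idx]
    sc_resi = meta["resi"][sc_idx]
    focal_mask = sc_resi == focal
    tally = Counter()
    for a in np.nonzero(focal_mask)[0]:
        d = sc_pos - sc_pos[a]
        d -= L * np.round(d / L)
        dist = np.sqrt((d * d).sum(axis=1))
        other = sc_chain != sc_chain[a]
        if not other.any():
            continue
        dist_other = np.where(other, dist, np.inf)
        b = int(np.argmin(dist_other))
        ra = seq[focal]
        rb = seq[int(sc_resi[b])]
        contact, width, depth = (table.contact_distance(ra, rb),
                                 table.width(ra, rb), table.depth(ra, rb))
        cutoff = width if depth > 0 else 1.2 * contact
        if dist_other[b] <= cutoff:
            tally[residue_label(meta, int(sc_resi[b]), start_number)] += 1
    return tally


def _sc_well_edges(snapshot: Snapshot):
    """Chain pairs sharing at least one occupied (or hard-contact) sidechain well."""
    meta = snapshot.meta
    table = meta["table"]
    L = snapshot.box_length
    sc_idx, sc_pos = _sc_positions(snapshot)
    sc_chain = meta["chain"][sc_idx]
    sc_resi = meta["resi"][sc_idx]
    seq = meta["sequence"]
    edges = set()
    n = sc_idx.size
    d = sc_pos[:, None, :] - sc_pos[None, :, :]
    d -= L * np.round(d / L)
    dist = np.sqrt((d * d).sum(axis=2))
    for a in range(n):
        for b in range(a + 1, n):
            if sc_chain[a] == sc_chain[b]:
                continue
            ra, rb = seq[int(sc_resi[a])], seq[int(sc_resi[b])]
            depth = table.depth(ra, rb)
            cutoff = table.width(ra, rb) if depth > 0 else 1.2 * table.contact_distance(ra, rb)
            if dist[a, b] < cutoff:
                edges.add((int(sc_chain[a]), int(sc_chain[b])))
    return edges


@dataclass
class OligomerCluster:
    chains: list
    size: int
    order_parameter: float     # fraction of chains in >=1 classified strand pair


def cluster_oligomers(snapshot: Snapshot):
    """Connected components of the chain graph (H-bond or shared-well edges),
    each with an order parameter = classified-pair fraction of its edges."""
    meta = snapshot.meta
    n_chains = _chain_count(meta)
    hb_edges = set()
    for r in hydrogen_bond_map(snapshot):
        if r.donor_chain != r.acceptor_chain:
            hb_edges.add(tuple(sorted((r.donor_chain, r.acceptor_chain))))
    edges = hb_edges | _sc_well_edges(snapshot)
    if edges:
        rows = [e[0] for e in edges]; cols = [e[1] for e in edges]
        g = coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n_chains, n_chains))
        n_comp, labels = connected_components(g, directed=False)
    else:
        n_comp, labels = n_chains, np.arange(n_chains)
    ordered_chains = set()
    for c in classified_pairs(snapshot):
        ordered_chains.add(c.chain_i)
        ordered_chains.add(c.chain_j)
    out = []
    for comp in range(n_comp):
        chains = sorted(int(c) for c in np.nonzero(labels == comp)[0])
        order = sum(1 for c in chains if c in ordered_chains) / len(chains)
        out.append(OligomerCluster(chains=chains, size=len(chains),
                                   order_parameter=order))
    out.sort(key=lambda c: -c.size)
    return out


def sheet_layer_count(snapshot: Snapshot, cluster: OligomerCluster,
                      order_threshold: float = 0.5) -> int:
    """Number of beta-sheet layers in an ordered cluster.

    Layers are the connected components of the chain-level hydrogen-bond
    graph restricted to the cluster (layers stack through sidechain wells,
    which do not merge components).  Undefined for amorphous clusters.
    """
    if cluster.size > 1 and cluster.order_parameter < order_threshold:
        raise ValueError("layer count undefined for amorphous clusters")
    chains = cluster.chains
    index = {c: k for k, c in enumerate(chains)}
    pair_counts = Counter()
    for r in hydrogen_bond_map(snapshot):
        if (r.donor_chain != r.acceptor_chain and r.donor_chain in index
                and r.acceptor_chain in index):
            pair_counts[(index[r.donor_chain], index[r.acceptor_chain])] += 1
    hb_edges = {pair for pair, cnt in pair_counts.items() if cnt >= 2}
    n = len(chains)
    if hb_edges:
        rows = [e[0] for e in hb_edges]; cols = [e[1] for e in hb_edges]
        g = coo_matrix((np.ones(len(hb_edges)), (rows, cols)), shape=(n, n))
        n_comp, _ = connected_components(g, directed=False)
    else:
        n_comp = n
    return int(n_comp)


def energy_and_beta_timeseries(trajectory: Trajectory) -> EnergyProfile:
    """Aligned time / potential-energy / beta-percentage series."""
    if len(trajectory.snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    times = trajectory.times
    pe = trajectory.potential_energies
    beta = np.array([beta_sheet_fraction(s) for s in trajectory.snapshots])
    return EnergyProfile(times=times, potential_energies=pe, beta_percentages=beta)


def block_average(series, block: int = 10) -> np.ndarray:
    """Non-overlapping block means (the smoothing used for time-series claims)."""
    x = np.asarray(series, dtype=float)
    n = (x.size // block) * block
    if n == 0:
        return np.array([x.mean()]) if x.size else np.array([])
    return x[:n].reshape(-1, block).mean(axis=1)


def write_contact_table(snapshots, focal_residues, path, start_number=16):
    """Figure-style tidy table: per-snapshot nearest-contact tallies."""
    rows = []
    for s in snapshots:
        for focal in focal_residues:
            tally = nearest_sidechain_contacts(s, focal, start_number)
            for partner, count in sorted(tally.items()):
                rows.append({"time_tau": s.time, "focal": focal,
                             "partner": partner, "count": count})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return rows
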