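"""Event-driven (discontinuous) molecular dynamics of square-well peptides.

The public surface: :class:`SimulationConfig`, :class:`SystemState`,
:func:`run` (event loop with calendar, cell lists, periodic boundaries,
Andersen thermostat), plus single-event wrappers used for auditing and
testing (:func:`predict_pair_event`, :func:`execute_event`,
:func:`attempt_hbond`, :func:`ghost_collision`).

Reduced units: lengths in A, masses in u, energy in eps_HB, temperature
T* = k_B T / eps_HB and time tau = 1 A sqrt(u / eps_HB).  The mapping of tau
to nanoseconds is a documented convention (``NS_PER_TAU``), not a prediction:
with a 3.3 A reference bead of 28 u and eps_HB = 12.47 kJ/mol it evaluates to
~4.9e-4 ns per tau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import kernel
from .model import (PeptideTopology, ParameterTable, RESIDUE_INDEX,
                    KIND_NH, KIND_CA, KIND_CO, KIND_SC)

NS_PER_TAU = 4.94e-4  # convention constant; see module docstring


@dataclass
class SimulationConfig:
    """Run parameters.  Exactly one of box_length / concentration is set."""

    n_peptides: int
    max_time: float                      # reduced time (tau)
    box_length: float = None             # A
    concentration: float = None          # mM
    t_star: float = 0.193                # k_B T / eps_HB
    eps_hb: float = 12.47                # kJ/mol, annotation for unit conversion
    # ghost collisions per bead per tau.  Internal (bond) forces conserve a
    # chain's momentum, so only ghost hits decorrelate its centre-of-mass
    # velocity: strong coupling freezes transport entirely.  0.001 renews a
    # chain's momentum on the ~1e3 tau scale, which absorbs binding heat while
    # leaving inter-chain diffusion near-ballistic.
    thermostat_rate: float = 0.001
    snapshot_interval: float = 10.0      # tau
    seed: int = 0
    sequence: str = "KLVFFAE"
    real_temperature_annotation: float = 326.0  # K, informational only

    def __post_init__(self):
        if self.t_star <= 0:
            raise ValueError("T* must be positive")
        if self.n_peptides < 1:
            raise ValueError("need at least one peptide")


class SystemState:
    """Positions, velocities, bookkeeping and the event-engine scratch arrays.

    Most users build one through :func:`make_state`,
    :func:`absheet.setup_io.random_initial_configuration` or the fixtures in
    :mod:`absheet.synthetic`.
    """

    def __init__(self, topology: PeptideTopology, n_chains: int,
                 positions: np.ndarray, velocities: np.ndarray,
                 box_length: float, table: ParameterTable):
        nb = topology.n_beads
        if positions.shape != (n_chains * nb, 3):
            raise ValueError("positions shape mismatch")
        self.topology = topology
        self.table = table
        self.n_chains = n_chains
        self.box_length = float(box_length)
        self.clock = 0.0
        self.pos = np.ascontiguousarray(positions, dtype=float)
        self.vel = np.ascontiguousarray(velocities, dtype=float)

        # static per-bead arrays
        reps = np.arange(n_chains, dtype=np.int32)
        self.chain = np.repeat(reps, nb)
        self.resi = np.tile(topology.bead_residue.astype(np.int32), n_chains)
        self.kind = np.tile(topology.bead_kind.astype(np.int8), n_chains)
        rt = np.array([RESIDUE_INDEX[topology.sequence[r]]
                       for r in topology.bead_residue], dtype=np.int8)
        self.rtype = np.tile(rt, n_chains)
        self.sigma = np.tile(np.array([b.diameter for b in topology.beads]), n_chains)
        self.mass = np.tile(np.array([b.mass for b in topology.beads]), n_chains)
        self.inv_mass = 1.0 / self.mass

        # bonds + pseudobonds replicated per chain
        walls = list(topology.bonds) + list(topology.pseudobonds)
        bi, bj, lo2, hi2 = [], [], [], []
        for c in range(n_chains):
            off = c * nb
            for (i, j, lo, hi) in walls:
                bi.append(i + off); bj.append(j + off)
                lo2.append(lo * lo); hi2.append(hi * hi)
        self.bond_i = np.array(bi, dtype=np.int32)
        self.bond_j = np.array(bj, dtype=np.int32)
        self.bond_lo2 = np.array(lo2)
        self.bond_hi2 = np.array(hi2)

        # per-bead adjacency over the wall list (CSR)
        N = n_chains * nb
        deg = np.zeros(N, dtype=np.int64)
        for a in range(self.bond_i.size):
            deg[self.bond_i[a]] += 1
            deg[self.bond_j[a]] += 1
        self.badj_ptr = np.zeros(N + 1, dtype=np.int32)
        self.badj_ptr[1:] = np.cumsum(deg)
        self.badj_bond = np.zeros(self.badj_ptr[-1], dtype=np.int32)
        self.badj_other = np.zeros(self.badj_ptr[-1], dtype=np.int32)
        fill = self.badj_ptr[:-1].astype(np.int64).copy()
        for a in range(self.bond_i.size):
            i, j = self.bond_i[a], self.bond_j[a]
            self.badj_bond[fill[i]] = a; self.badj_other[fill[i]] = j; fill[i] += 1
            self.badj_bond[fill[j]] = a; self.badj_other[fill[j]] = i; fill[j] += 1

        # H-bond auxiliary beads: (CaH, CO-prev) flanking each NH;
        # (CaH, NH-next) flanking each CO
        self.aux_a = np.full(N, -1, dtype=np.int32)
        self.aux_b = np.full(N, -1, dtype=np.int32)
        tpl_nh = {r: topology.backbone_bead_index(r, KIND_NH)
                  for r in range(topology.n_residues)}
        tpl_ca = {r: topology.backbone_bead_index(r, KIND_CA)
                  for r in range(topology.n_residues)}
        tpl_co = {r: topology.backbone_bead_index(r, KIND_CO)
                  for r in range(topology.n_residues)}
        for c in range(n_chains):
            off = c * nb
            for r in range(topology.n_residues):
                nh = tpl_nh[r] + off
                self.aux_a[nh] = tpl_ca[r] + off
                if r > 0:
                    self.aux_b[nh] = tpl_co[r - 1] + off
                co = tpl_co[r] + off
                self.aux_a[co] = tpl_ca[r] + off
                if r + 1 < topology.n_residues:
                    self.aux_b[co] = tpl_nh[r + 1] + off

        self.W20, self.E20 = table.as_arrays()
        self.hb_partner = np.full(N, -1, dtype=np.int32)
        self.hb_formed_at = np.full(N, np.nan)

        # engine scratch
        self.t_last = np.zeros(N)
        self.stamp = np.zeros(N, dtype=np.int64)
        rng_max = max(table.hb_width, float(self.W20.max()), 1.05 * np.sqrt(self.bond_hi2.max()))
        ncell = int(self.box_length / rng_max)
        self.ncell = ncell if ncell >= 3 else 1
        self.celli = np.zeros((N, 3), dtype=np.int32)
        self.cell_head = np.full(max(self.ncell, 1) ** 3, -1, dtype=np.int32)
        self.cell_next = np.full(N, -1, dtype=np.int32)
        self.cell_prev = np.full(N, -1, dtype=np.int32)
        cap = 160 * N + 4096
        self.ht = np.zeros(cap)
        self.hm1 = np.zeros(cap, dtype=np.int64)
        self.hm2 = np.zeros(cap, dtype=np.int64)
        self.iscal = np.zeros(kernel.NSCAL_I, dtype=np.int64)
        self.fscal = np.zeros(kernel.NSCAL_F)
        self.rng = np.zeros(1, dtype=np.uint64)
        self._initialized = False
        self.potential_energy = 0.0

    # --- inspection -----------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    def kinetic_energy(self) -> float:
        return 0.5 * float((self.mass[:, None] * self.vel ** 2).sum())

    def instantaneous_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (3.0 * self.n_beads)

    def hbonds(self):
        """List of (donor NH bead, acceptor CO bead) currently bonded."""
        out = []
        for i in np.nonzero(self.hb_partner >= 0)[0]:
            if self.kind[i] == KIND_NH:
                out.append((int(i), int(self.hb_partner[i])))
        return out

    def well_occupancy(self):
        """Sidechain pairs currently inside a shared attractive well
        (derived from geometry; the engine bookkeeps energy by events)."""
        return _sc_pairs_within(self, self.W20, attractive_only=True)

    def recompute_potential_energy(self) -> float:
        """Audit: -sum of occupied sidechain well depths - 1.0 per H-bond."""
        pe = 0.0
        for (i, j) in _sc_pairs_within(self, self.W20, attractive_only=True):
            pe -= self.E20[self.rtype[i], self.rtype[j]]
        pe -= self.table.hb_depth * len(self.hbonds())
        return pe

    def min_nonbonded_gap(self) -> float:
        """min(distance - contact) over nonbonded pairs; >= 0 means no overlap."""
        d, gap = _min_gap(self)
        return gap

    def wrapped_positions(self) -> np.ndarray:
        return self.pos - self.box_length * np.floor(self.pos / self.box_length)


def make_state(topology: PeptideTopology, n_chains: int, positions, velocities,
               box_length: float, table: ParameterTable,
               detect_hbonds: bool = False, seed: int = 0) -> SystemState:
    st = SystemState(topology, n_chains, np.asarray(positions, float),
                     np.asarray(velocities, float), box_length, table)
    st.rng[0] = np.uint64((seed * 2654435761 + 1) % (2 ** 63))
    if detect_hbonds:
        _detect_initial_hbonds(st)
    st.potential_energy = st.recompute_potential_energy()
    st.fscal[kernel.F_PE] = st.potential_energy
    return st


def _sc_pairs_within(st, W20, attractive_only=True):
    sc = np.nonzero(st.kind == KIND_SC)[0]
    if sc.size < 2:
        return []
    P = st.pos[sc]
    L = st.box_length
    d = P[:, None, :] - P[None, :, :]
    d -= L * np.round(d / L)
    dist = np.sqrt((d * d).sum(axis=2))
    out = []
    for a in range(sc.size):
        for b in range(a + 1, sc.size):
            i, j = int(sc[a]), int(sc[b])
            if st.chain[i] == st.chain[j] and abs(int(st.resi[i]) - int(st.resi[j])) <= 1:
                continue
            e = st.E20[st.rtype[i], st.rtype[j]]
            if attractive_only and e <= 0.0:
                continue
            if dist[a, b] < st.W20[st.rtype[i], st.rtype[j]]:
                out.append((i, j))
    return out


def _min_gap(st: SystemState):
    L = st.box_length
    P = st.pos
    N = st.n_beads
    d = P[:, None, :] - P[None, :, :]
    d -= L * np.round(d / L)
    dist = np.sqrt((d * d).sum(axis=2))
    contact = 0.5 * (st.sigma[:, None] + st.sigma[None, :])
    same_chain = st.chain[:, None] == st.chain[None, :]
    near = np.abs(st.resi[:, None] - st.resi[None, :]) <= 1
    mask = np.triu(np.ones((N, N), dtype=bool), 1) & ~(same_chain & near)
    # exclude bonded pairs
    for a in range(st.bond_i.size):
        mask[st.bond_i[a], st.bond_j[a]] = False
        mask[st.bond_j[a], st.bond_i[a]] = False
    gaps = np.where(mask, dist - contact, np.inf)
    idx = np.unravel_index(np.argmin(gaps), gaps.shape)
    return idx, float(gaps[idx])


def _detect_initial_hbonds(st: SystemState):
    """Greedy nearest-first assignment of H-bonds consistent with the engine's
    criteria, for prebuilt (fixture) states."""
    nh = np.nonzero(st.kind == KIND_NH)[0]
    co = np.nonzero(st.kind == KIND_CO)[0]
    L = st.box_length
    cands = []
    for i in nh:
        for j in co:
            if st.chain[i] == st.chain[j]:
                continue
            d = st.pos[i] - st.pos[j]
            d -= L * np.round(d / L)
            dist = float(np.sqrt((d * d).sum()))
            if dist < st.table.hb_width and dist > 0.5 * (st.sigma[i] + st.sigma[j]):
                cands.append((dist, int(i), int(j)))
    cands.sort()
    for dist, i, j in cands:
        if st.hb_partner[i] >= 0 or st.hb_partner[j] >= 0:
            continue
        if kernel._hb_geom_ok(i, j, st.clock, st.pos, st.vel, st.t_last, L,
                              st.aux_a, st.aux_b, st.table.hb_aux_min):
            st.hb_partner[i] = j
            st.hb_partner[j] = i
            st.hb_formed_at[i] = st.clock
            st.hb_formed_at[j] = st.clock


# --- single-event wrappers (testing / auditing) -------------------------------

@dataclass(frozen=True)
class Event:
    """One predicted discontinuity crossing."""

    time: float
    kind: str
    participants: tuple

    _KIND_NAMES = {kernel.EV_CORE: "core_collision", kernel.EV_SCWELL: "well_edge",
                   kernel.EV_HB: "hb_edge", kernel.EV_BOND: "bond_wall",
                   kernel.EV_CELL: "cell_crossing", kernel.EV_GHOST: "ghost"}


def predict_pair_event(i: int, j: int, state: SystemState):
    """Earliest future discontinuity crossing for a nonbonded pair, or None."""
    if i == j:
        raise ValueError("beads must be distinct")
    t, k = kernel._pair_candidate(
        i, j, state.clock, state.pos, state.vel, state.t_last, state.box_length,
        state.chain, state.resi, state.kind, state.rtype, state.sigma,
        state.badj_ptr, state.badj_other, state.W20, state.E20,
        state.table.hb_width, state.hb_partner)
    if k < 0:
        return None
    return Event(time=float(t), kind=Event._KIND_NAMES[k], participants=(i, j))


def execute_event(event: Event, state: SystemState):
    """Apply the impulsive rules of one pair event to ``state`` (in place).

    Mirrors the kernel's execution path: elastic bounce for cores and walls,
    energy-conserving capture/escape for well edges, directional criteria and
    single-bond bookkeeping for H-bond edges.
    """
    i, j = event.participants
    t = event.time
    for b in (i, j):
        state.pos[b] += state.vel[b] * (t - state.t_last[b])
        state.t_last[b] = t
    state.clock = max(state.clock, t)
    L = state.box_length
    r = state.pos[i] - state.pos[j]
    r -= L * np.round(r / L)
    d = float(np.sqrt((r * r).sum()))
    u = r / d
    vr = float((state.vel[i] - state.vel[j]) @ u)
    mu = 1.0 / (state.inv_mass[i] + state.inv_mass[j])
    J = 0.0
    if event.kind in ("core_collision", "bond_wall"):
        J = -2.0 * mu * vr
    elif event.kind == "well_edge":
        e = float(state.E20[state.rtype[i], state.rtype[j]])
        if vr < 0:
            J = mu * (-np.sqrt(vr * vr + 2 * e / mu) - vr)
            state.potential_energy -= e
        elif vr * vr > 2 * e / mu:
            J = mu * (np.sqrt(vr * vr - 2 * e / mu) - vr)
            state.potential_energy += e
        else:
            J = -2.0 * mu * vr
    elif event.kind == "hb_edge":
        e = state.table.hb_depth
        if state.hb_partner[i] == j:
            if vr > 0 and vr * vr > 2 * e / mu:
                J = mu * (np.sqrt(vr * vr - 2 * e / mu) - vr)
                state.potential_energy += e
                state.hb_partner[i] = -1
                state.hb_partner[j] = -1
            else:
                J = -2.0 * mu * vr
        else:
            nh = i if state.kind[i] == KIND_NH else j
            co = j if nh == i else i
            if attempt_hbond(nh, co, state, _already_at_edge=True) and vr < 0:
                J = mu * (-np.sqrt(vr * vr + 2 * e / mu) - vr)
    state.vel[i] += J * u * state.inv_mass[i]
    state.vel[j] -= J * u * state.inv_mass[j]
    state.fscal[kernel.F_PE] = state.potential_energy
    return state


def attempt_hbond(nh_bead: int, co_bead: int, state: SystemState,
                  _already_at_edge: bool = False) -> bool:
    """Directional H-bond test; on success records the bond (depth 1 eps_HB).

    True iff NH and CO are within the H-bond well width, neither is bonded,
    and all four auxiliary neighbour beads are outside ``hb_aux_min``.
    """
    if state.kind[nh_bead] != KIND_NH or state.kind[co_bead] != KIND_CO:
        raise ValueError("need an NH donor and a CO acceptor")
    if state.hb_partner[nh_bead] >= 0 or state.hb_partner[co_bead] >= 0:
        return False
    L = state.box_length
    if not _already_at_edge:
        d = state.pos[nh_bead] - state.pos[co_bead]
        d -= L * np.round(d / L)
        if float(np.sqrt((d * d).sum())) > state.table.hb_width:
            return False
    if not kernel._hb_geom_ok(nh_bead, co_bead, state.clock, state.pos, state.vel,
                              state.t_last, L, state.aux_a, state.aux_b,
                              state.table.hb_aux_min):
        return False
    state.hb_partner[nh_bead] = co_bead
    state.hb_partner[co_bead] = nh_bead
    state.hb_formed_at[nh_bead] = state.clock
    state.hb_formed_at[co_bead] = state.clock
    state.potential_energy -= state.table.hb_depth
    state.fscal[kernel.F_PE] = state.potential_energy
    return True


def ghost_collision(bead: int, state: SystemState, rng, t_star: float = 0.193):
    """Andersen-thermostat resampling of one bead from Maxwell-Boltzmann."""
    state.vel[bead] = rng.normal(size=3) * np.sqrt(t_star / state.mass[bead])
    return state


# --- trajectories -------------------------------------------------------------

@dataclass
class Snapshot:
    """One frame: wrapped positions, live H-bonds, bookkept potential energy."""

    time: float
    positions: np.ndarray
    hbonds: list                  # (donor NH bead, acceptor CO bead)
    potential_energy: float
    box_length: float
    meta: dict = field(repr=False, default=None)


@dataclass
class Trajectory:
    config: SimulationConfig
    topology: PeptideTopology
    table: ParameterTable
    snapshots: list = field(default_factory=list)
    event_counts: dict = field(default_factory=dict)
    audit_max_drift: float = 0.0

    @property
    def times(self):
        return np.array([s.time for s in self.snapshots])

    @property
    def potential_energies(self):
        return np.array([s.potential_energy for s in self.snapshots])

    def write_xyz(self, path):
        """Multi-frame XYZ, one pseudo-atom per bead, chain id in the comment."""
        labels = [b.label.split("-")[0].replace("+", "") for b in self.topology.beads]
        with open(path, "w") as fh:
            for s in self.snapshots:
                n = s.positions.shape[0]
                fh.write(f"{n}\nt= {s.time:.4f} pe= {s.potential_energy:.6f}\n")
                for c in range(n // self.topology.n_beads):
                    for b in range(self.topology.n_beads):
                        x, y, z = s.positions[c * self.topology.n_beads + b]
                        fh.write(f"{labels[b][:2]:<2s} {x:10.4f} {y:10.4f} {z:10.4f}\n")

    def write_timeseries(self, path, beta=None):
        import pandas as pd

        df = pd.DataFrame({"time_tau": self.times,
                           "potential_energy_epsHB": self.potential_energies})
        if beta is not None:
            df["beta_pct"] = beta
        df.to_csv(path, sep="\t", index=False)


def snapshot_of(state: SystemState) -> Snapshot:
    """Snapshot of the current state (wrapped positions, live H-bonds)."""
    meta = {"chain": state.chain, "resi": state.resi, "kind": state.kind,
            "rtype": state.rtype, "sequence": state.topology.sequence,
            "table": state.table, "topology": state.topology}
    return Snapshot(time=state.clock, positions=state.wrapped_positions(),
                    hbonds=state.hbonds(), potential_energy=state.potential_energy,
                    box_length=state.box_length, meta=meta)


def _kernel_args(st: SystemState):
    return (st.pos, st.vel, st.t_last, st.stamp, st.box_length,
            st.chain, st.resi, st.kind, st.rtype, st.sigma, st.inv_mass,
            st.bond_i, st.bond_j, st.bond_lo2, st.bond_hi2,
            st.badj_ptr, st.badj_bond, st.badj_other,
            st.W20, st.E20, st.table.hb_width, st.table.hb_depth,
            st.aux_a, st.aux_b, st.table.hb_aux_min, st.hb_partner,
            st.celli, st.ncell, st.cell_head, st.cell_next, st.cell_prev,
            st.ht, st.hm1, st.hm2, st.iscal, st.fscal)


def initialize_engine(state: SystemState, config: SimulationConfig):
    state.fscal[kernel.F_CLOCK] = state.clock
    state.fscal[kernel.F_PE] = state.potential_energy
    status = kernel.init_events(
        state.pos, state.vel, state.t_last, state.stamp, state.box_length,
        state.chain, state.resi, state.kind, state.rtype, state.sigma,
        state.bond_i, state.bond_j, state.bond_lo2, state.bond_hi2,
        state.badj_ptr, state.badj_bond, state.badj_other,
        state.W20, state.E20, state.table.hb_width, state.hb_partner,
        state.celli, state.ncell, state.cell_head, state.cell_next, state.cell_prev,
        state.ht, state.hm1, state.hm2,
        state.iscal, state.fscal, config.thermostat_rate, state.rng)
    if status != kernel.STATUS_OK:
        raise RuntimeError(f"engine initialization failed (status {status})")
    state._initialized = True


def advance(state: SystemState, config: SimulationConfig, t_target: float,
            max_events: int = 2 ** 62) -> int:
    """Run the event loop up to ``t_target`` (absolute, tau)."""
    if not state._initialized:
        initialize_engine(state, config)
    status = kernel.run_until(
        t_target, max_events, *_kernel_args(state),
        config.t_star, config.thermostat_rate, state.rng)
    state.clock = state.fscal[kernel.F_CLOCK]
    state.potential_energy = state.fscal[kernel.F_PE]
    if status == kernel.STATUS_TIME_REGRESSION:
        raise RuntimeError("event calendar corruption: event-time regression")
    if status == kernel.STATUS_HEAP_FULL:
        raise RuntimeError("event heap exhausted; increase capacity")
    return status


def run(config: SimulationConfig, initial_state: SystemState = None,
        table: ParameterTable = None, audit_interval: int = 10,
        max_events: int = 2 ** 62) -> Trajectory:
    """Run DMD and return a trajectory of snapshots + energy series.

    Identical (config, seed) give identical trajectories.  The bookkept
    potential energy is audited against a from-scratch geometric recompute
    every ``audit_interval`` snapshots; a drift above 1e-6 eps_HB aborts.
    """
    from .model import build_topology, default_parameter_table
    from .setup_io import SystemSpec, random_initial_configuration, init_velocities

    if table is None:
        table = initial_state.table if initial_state is not None else default_parameter_table()
    if initial_state is None:
        topo = build_topology(config.sequence)
        spec = SystemSpec(n_peptides=config.n_peptides, sequence=config.sequence,
                          box_length=config.box_length,
                          concentration=config.concentration)
        positions, L = random_initial_configuration(spec, topo, config.seed)
        vel = init_velocities(np.tile([b.mass for b in topo.beads], config.n_peptides),
                              config.t_star, config.seed + 1)
        state = make_state(topo, config.n_peptides, positions, vel, L, table,
                           seed=config.seed)
    else:
        state = initial_state

    traj = Trajectory(config=config, topology=state.topology, table=state.table)

    def take_snapshot():
        traj.snapshots.append(snapshot_of(state))

    take_snapshot()
    n_steps = int(np.ceil(config.max_time / config.snapshot_interval))
    events_used = 0
    for k in range(1, n_steps + 1):
        t_next = min(k * config.snapshot_interval, config.max_time)
        budget = max_events - events_used
        before = int(state.iscal[kernel.I_NEVENT])
        status = advance(state, config, t_next, max_events=budget)
        events_used += int(state.iscal[kernel.I_NEVENT]) - before
        take_snapshot()
        if audit_interval and (k % audit_interval == 0 or k == n_steps):
            drift = abs(state.potential_energy - state.recompute_potential_energy())
            traj.audit_max_drift = max(traj.audit_max_drift, drift)
            if drift > 1e-6:
                raise RuntimeError(f"potential-energy bookkeeping drift {drift:.3e} eps_HB")
        if status == kernel.STATUS_EVENT_BUDGET:
            break
    traj.event_counts = {
        "events": int(state.iscal[kernel.I_NEVENT]),
        "core": int(state.iscal[kernel.I_NCORE]),
        "bond_wall": int(state.iscal[kernel.I_NBOND]),
        "well_entry": int(state.iscal[kernel.I_WELLIN]),
        "well_escape": int(state.iscal[kernel.I_WELLESC]),
        "well_reflect": int(state.iscal[kernel.I_WELLREFL]),
        "hb_formed": int(state.iscal[kernel.I_HBFORM]),
        "hb_broken": int(state.iscal[kernel.I_HBBREAK]),
        "hb_attempts": int(state.iscal[kernel.I_HBATTEMPT]),
        "ghost": int(state.iscal[kernel.I_NGHOST]),
        "cell_crossings": int(state.iscal[kernel.I_NCELL]),
        "stale_discarded": int(state.iscal[kernel.I_NSTALE]),
    }
    traj.final_state = state
    return traj


def save_checkpoint(state: SystemState, path):
    """Full state + RNG as JSON text (restartable)."""
    data = {
        "clock": state.clock,
        "box_length": state.box_length,
        "n_chains": state.n_chains,
        "sequence": state.topology.sequence,
        "pos": state.pos.tolist(),
        "vel": state.vel.tolist(),
        "hb_partner": state.hb_partner.tolist(),
        "rng": int(state.rng[0]),
        "potential_energy": state.potential_energy,
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_checkpoint(path, table: ParameterTable = None) -> SystemState:
    from .model import build_topology, default_parameter_table

    with open(path) as fh:
        data = json.load(fh)
    topo = build_topology(data["sequence"])
    table = table or default_parameter_table()
    st = SystemState(topo, data["n_chains"], np.array(data["pos"]),
                     np.array(data["vel"]), data["box_length"], table)
    st.clock = data["clock"]
    st.fscal[kernel.F_CLOCK] = st.clock
    st.hb_partner[:] = np.array(data["hb_partner"], dtype=np.int32)
    st.rng[0] = np.uint64(data["rng"])
    st.potential_energy = data["potential_energy"]
    st.fscal[kernel.F_PE] = st.potential_energy
    return st
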