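"""System construction and run configuration.

Concentration bookkeeping (peptides in a cubic periodic box), random
overlap-free placement of extended chains, Maxwell-Boltzmann velocity
initialization at a reduced temperature T* = k_B T / eps_HB, and the flat
key-value run-configuration format.

Internal units: lengths in Angstrom, masses in u, energies in eps_HB, and the
reduced time unit tau = 1 A * sqrt(1 u / eps_HB).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import PeptideTopology

AVOGADRO = 6.02214076e23
# 1 A^3 = 1e-27 litre; concentration in mM = 1e3 * mol/L
_MM_PER_COUNT_PER_A3 = 1e3 / (AVOGADRO * 1e-27)


def concentration_of(n_peptides: int, box_length: float) -> float:
    """Peptide concentration (mM) of n chains in a cubic box of side L (A)."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    return n_peptides / box_length**3 * _MM_PER_COUNT_PER_A3


def box_length_for(n_peptides: int, concentration_mm: float) -> float:
    """Cubic box side (A) giving the requested concentration; exact inverse of
    :func:`concentration_of`."""
    if concentration_mm <= 0:
        raise ValueError("concentration must be positive")
    return (n_peptides * _MM_PER_COUNT_PER_A3 / concentration_mm) ** (1.0 / 3.0)


@dataclass
class SystemSpec:
    """What to build: chain count, box (or concentration), sequence, arrangement."""

    n_peptides: int
    sequence: str = "KLVFFAE"
    box_length: float = None
    concentration: float = None   # mM; exactly one of box_length/concentration
    modifications: tuple = ()
    arrangement: str = "random_gas"

    def resolved_box_length(self) -> float:
        if (self.box_length is None) == (self.concentration is None):
            raise ValueError("give exactly one of box_length or concentration")
        if self.box_length is not None:
            return float(self.box_length)
        return box_length_for(self.n_peptides, self.concentration)


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_initial_configuration(spec: SystemSpec, topology: PeptideTopology,
                                 seed: int, max_retries: int = 100_000):
    """Place chains with random positions/orientations, no core overlaps.

    Each chain is the extended template conformation, rigidly rotated and
    translated; candidate placements are rejection-sampled against all beads
    already placed (minimum-image).  Deterministic per seed.  Raises if a
    chain cannot be placed within ``max_retries`` attempts.

    Returns (positions (n_chains*n_beads, 3), box_length).
    """
    from .engine import SystemState, make_state  # deferred: engine imports model

    rng = np.random.default_rng(seed)
    L = spec.resolved_box_length()
    tpl = topology.template_coords - topology.template_coords.mean(axis=0)
    diam = np.array([b.diameter for b in topology.beads])
    extent = 2 * np.abs(tpl).max() + diam.max()
    if extent >= L:
        pass  # long chains may still fit by rotation; the sampler decides
    placed = np.empty((0, 3))
    placed_diam = np.empty((0,))
    chains = []
    for c in range(spec.n_peptides):
        ok = False
        for _ in range(max_retries):
            R = _random_rotation(rng)
            com = rng.uniform(0.0, L, size=3)
            coords = tpl @ R.T + com
            # periodic self-image overlap (chain longer than the box)
            ds = coords[:, None, :] - coords[None, :, :]
            direct = np.sqrt((ds * ds).sum(axis=2))
            ds -= L * np.round(ds / L)
            wrapped = np.sqrt((ds * ds).sum(axis=2))
            dmin_self = 0.5 * (diam[:, None] + diam[None, :])
            bad = (wrapped < dmin_self) & (direct > wrapped + 1e-9)
            if bad.any():
                continue
            if placed.shape[0]:
                d = coords[:, None, :] - placed[None, :, :]
                d -= L * np.round(d / L)
                dist = np.sqrt((d * d).sum(axis=2))
                dmin_req = 0.5 * (diam[:, None] + placed_diam[None, :])
                if np.any(dist < dmin_req):
                    continue
            placed = np.vstack([placed, coords])
            placed_diam = np.concatenate([placed_diam, diam])
            chains.append(coords)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place chain {c + 1}/{spec.n_peptides} in box {L:.1f} A "
                f"after {max_retries} attempts (density too high)")
    return np.vstack(chains), L


def init_velocities(masses: np.ndarray, t_star: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T*, zero net momentum, then rescaled so
    the instantaneous reduced temperature equals T* exactly."""
    rng = np.random.default_rng(seed)
    m = np.asarray(masses, float)
    v = rng.normal(size=(m.size, 3)) * np.sqrt(t_star / m)[:, None]
    v -= (m[:, None] * v).sum(axis=0) / m.sum()       # remove net momentum
    ke = 0.5 * (m[:, None] * v * v).sum()
    t_inst = 2.0 * ke / (3.0 * m.size)
    v *= np.sqrt(t_star / t_inst)
    return v


# --- flat key-value config files ---------------------------------------------

def write_config(path, config) -> None:
    d = asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config)
    with open(path, "w") as fh:
        for k, v in d.items():
            if v is not None:
                fh.write(f"{k} = {v}\n")


def read_config(path) -> dict:
    out = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            k, _, v = line.partition("=")
            k, v = k.strip(), v.strip()
            try:
                out[k] = int(v)
            except ValueError:
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = v
    return out


def write_provenance(path, spec: SystemSpec, seed: int) -> None:
    from . import __version__

    with open(path, "w") as fh:
        json.dump({"spec": asdict(spec), "seed": seed, "absheet": __version__},
                  fh, indent=2, default=str)
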