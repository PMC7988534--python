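"""Desk-scale self-assembly run.

Simulates 24 KLVFFAE (Abeta16-22) chains at 10 mM and T* = 0.193 — the
published state point, scaled down from 192 chains so it runs on one CPU —
and writes the trajectory, the energy/beta time series and the final state
under results/assembly/.

Run from the repository root:  python analysis/01_simulate_assembly.py [seed]
"""

import json
import sys
import time
from pathlib import Path

from absheet import analysis as an
from absheet.engine import SimulationConfig, run, save_checkpoint
from absheet.setup_io import box_length_for

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path("results/assembly")
out.mkdir(parents=True, exist_ok=True)

L = box_length_for(24, 10.0)
cfg = SimulationConfig(n_peptides=24, max_time=2400.0, box_length=L,
                       t_star=0.193, seed=seed, snapshot_interval=20.0)
print(f"24 peptides, box {L:.1f} A (10 mM), T* = {cfg.t_star}, "
      f"{cfg.max_time:.0f} tau, seed {seed}")
t0 = time.time()
traj = run(cfg)
print(f"done in {time.time() - t0:.0f} s: {traj.event_counts['events']} events "
      f"({json.dumps({k: v for k, v in traj.event_counts.items() if v})})")

traj.write_xyz(out / f"trajectory_seed{seed}.xyz")
prof = an.energy_and_beta_timeseries(traj)
prof.to_frame().to_csv(out / f"timeseries_seed{seed}.tsv", sep="\t", index=False)
save_checkpoint(traj.final_state, out / f"final_state_seed{seed}.json")

print(f"final potential energy {prof.potential_energies[-1]:.1f} eps_HB, "
      f"beta {prof.beta_percentages[-1]:.1f}%, "
      f"{len(traj.snapshots[-1].hbonds)} H-bonds")
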