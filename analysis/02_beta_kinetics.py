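"""Aggregation kinetics: beta-sheet content and potential energy vs time.

Reads the time series written by 01_simulate_assembly.py, block-averages it,
and summarizes the two-phase character of the decay (fast hydrophobic
collapse, slower beta-sheet ordering).  Writes results/beta_kinetics.tsv.

Run from the repository root:  python analysis/02_beta_kinetics.py [seed]
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from absheet.analysis import block_average

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
src = Path(f"results/assembly/timeseries_seed{seed}.tsv")
if not src.exists():
    sys.exit(f"{src} not found - run analysis/01_simulate_assembly.py first")

df = pd.read_csv(src, sep="\t")
t, pe, beta = df["time_tau"], df["potential_energy_epsHB"], df["beta_pct"]
n = len(df)

blocks = pd.DataFrame({
    "time_tau": block_average(t[1:], 10),
    "pe_epsHB": block_average(pe[1:], 10),
    "beta_pct": block_average(beta[1:], 10),
})
out = Path("results")
out.mkdir(exist_ok=True)
blocks.to_csv(out / f"beta_kinetics_seed{seed}.tsv", sep="\t", index=False)

s_first = (pe[n // 10] - pe[0]) / (t[n // 10] - t[0])
s_last = (pe.iloc[-1] - pe[n // 2]) / (t.iloc[-1] - t[n // 2])
print(f"beta: {blocks['beta_pct'].iloc[0]:.1f}% -> {blocks['beta_pct'].iloc[-1]:.1f}% "
      f"(smoothed blocks of 10 snapshots)")
print(f"potential energy: {pe.iloc[0]:.1f} -> {pe.iloc[-1]:.1f} eps_HB")
print(f"decay rate, first decile: {s_first:+.4f} eps_HB/tau; "
      f"last half: {s_last:+.4f} eps_HB/tau "
      f"({'fast-then-slow' if s_first < s_last else 'no deceleration yet'})")
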