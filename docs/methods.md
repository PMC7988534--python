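# Methods

## The model

Each residue of a peptide contributes three backbone beads — united-atom NH,
CαH and CO — plus one sidechain bead (glycine none). Beads on a chain are
held by hard-wall *bonds* (covalent: NH–CαH, CαH–CO, CαH–SC, CO–NH of the
next residue) and *pseudobonds* (NH–CO within a residue; CαH–CαH, CαH–NH and
CO–CαH across the peptide link; NH–SC and CO–SC) whose nominal lengths come
from an extended-strand template: Cα–Cα spacing 3.8 Å along the strand axis,
NH/CO displaced ±1.25 Å along the axis with an alternating ±0.8 Å pleat
offset, sidechain beads perpendicular to the backbone plane at a
residue-specific offset. Every wall allows ±2% fluctuation about nominal.
The pseudobond set fixes backbone planarity and the pleat alternation; it
does **not** fix chirality (all its distances are mirror-symmetric), so
mirror-image strands are valid states of this model — a known simplification
relative to models that pin chirality explicitly.

Nonbonded interactions are square wells. Sidechain–sidechain pairs use a
20×20 table of well widths (contact distance + 2.0 Å) and depths in ε_HB
units: hydrophobic pairs attract with depth 0.28·h_i·h_j (h is a
hydrophobicity weight, e.g. F–F = 0.227), oppositely charged pairs attract
at 0.25, like charges and everything else are hard-sphere only. This bundled
table is an explicit approximation: the published parameter set behind this
model family (210 independent widths, 19 shared depths, fit to protein
native states) is not public, and the package's correctness surface is the
event machinery and the analyses, not a byte-exact parameter set. The
versioned plain-text table format (`PAIR r1 r2 width depth`, `GEOM` records)
can hold any complete assignment.

Backbone hydrogen bonding is a directional square well of depth 1.0 ε_HB
(the energy unit; 12.47 kJ/mol) between NH and CO beads of **different
chains**, with outer width 5.0 Å. Formation is attempted when the pair
crosses the width moving inward and requires (i) both beads free (one bond
per donor and per acceptor), and (ii) the four auxiliary neighbour beads —
the CαH and preceding CO flanking the NH, the CαH and following NH flanking
the CO — to each be at least 4.5 Å from the partner bead, which enforces a
roughly linear, sheet-like approach (the ideal lattice geometry clears the
threshold at 5.0–5.15 Å; an approach along the backbone axis fails it).
Failed attempts are transparent crossings. Bound pairs escape the well only
when the radial kinetic energy exceeds the depth.

Intra-chain hydrogen bonds are disabled outright. A 7-residue strand cannot
pair with itself in β-sheet geometry, but the simplified bead geometry would
happily form i→i+3 "turn" bonds; pilot runs showed these turns sequester
every donor and acceptor into collapsed hairpins and block sheet formation
entirely. For longer chains this switch would need to be revisited.

## The event engine

Beads move ballistically between events. The calendar is a binary heap of
analytically predicted discontinuity crossings (stable quadratic roots):
hard-core collisions, sidechain well edges, hydrogen-bond well edges,
bond/pseudobond walls, cell-list crossings, and a Poisson stream of
Andersen-thermostat ghost collisions that resample single-bead velocities
from the Maxwell–Boltzmann distribution at T*. Positions are updated lazily
per bead; every event entry carries the participants' event counters and is
discarded as stale when either has moved on. Each bead keeps one aggregated
bond-wall entry (the earliest over its walls); because every wall appears in
both endpoints' aggregates, a partner deflection is always covered by the
partner's own entry, and an aggregate whose stored partner went stale is
re-predicted rather than dropped. All randomness comes from an internal
splitmix64 counter, so identical (config, seed) reproduce the event sequence
exactly.

Numerical robustness at walls: reflections are side-aware (a pair found
marginally outside a wall moving back in is a no-op, not a bounce), pairs
that graze a wall tangentially get a floor of 1e-8 Å/τ on the
post-reflection radial speed (kinetic-energy perturbation ~1e-15 ε_HB), and
a pair caught beyond its wall is projected back onto it (mass-weighted, no
energy or momentum change). Without these, a tangent graze can freeze the
calendar at a fixed clock. The bookkept potential energy (−Σ occupied well
depths − ε_HB per hydrogen bond) is audited against a from-scratch geometric
recompute during every run; the audit tolerance is 1e-6 ε_HB and measured
drift is ~1e-15.

Units: lengths in Å, masses in u, energies in ε_HB, time in
τ = 1 Å·√(u/ε_HB). The mapping of τ to nanoseconds is a convention constant
(`NS_PER_TAU` ≈ 4.9e-4 ns with a 3.3 Å / 28 u reference bead), recorded for
annotation only; nothing in the package computes with it.

## Thermostat coupling and transport

Internal walls conserve a chain's momentum, so a chain's centre-of-mass
velocity decorrelates only through ghost collisions and inter-chain
contacts. The coupling therefore sets the transport regime: at 0.1 ghost
events per bead per τ a 24-chain, 10 mM gas is diffusively frozen (measured
centre-of-mass displacement ~7 Å over 4000 τ against a 55 Å inter-chain
spacing, and essentially zero encounter events), while binding heat removal
only needs the chain's momentum turned over a few times per assembly run.
The default is 0.001 per bead per τ: near-ballistic transport with a
~1e3 τ momentum renewal time. The thermostat-temperature audit uses a
stronger coupling (0.1) purely to shorten its equilibration.

## Analysis conventions

The model has no dihedral-based secondary structure, so the observables are
declared conventions, used consistently everywhere:

* **Classified strand pair**: two chains sharing ≥ 2 hydrogen bonds.
  Orientation is the sign of the covariance of paired residue indices;
  registry offset is the median pairing offset (a+b−(n−1) for antiparallel,
  b−a for parallel; ties broken toward zero, robust to edge fraying).
  Offset 0 is in-register in both conventions; under argument swap the
  parallel offset negates and the antiparallel offset is invariant.
* **β-sheet residue**: its chain is in a classified pair and the residue is
  within one position of a residue donating or accepting one of that pair's
  bonds. This yields 0% for a monomer gas and 100% for the ideal in-register
  lattices, and is insensitive to terminus conventions.
* **Sidechain contact**: an occupied square well; for hard-sphere-only pairs
  a fallback cutoff of 1.2× contact distance.
* **Oligomer cluster**: connected component of the chain graph with H-bond
  or shared-well edges; its order parameter is the fraction of member chains
  participating in ≥ 1 classified pair. **Sheet layers** of an ordered
  cluster are the connected components of its ≥2-bond chain-level H-bond
  graph (layers stack through sidechain wells, which do not merge
  components).
* Time-series claims use block averages over 10 snapshots.

## Fixtures

The synthetic module builds ideal lattices in the four canonical
arrangements (antiparallel/parallel × in/out-of-register) with
construction-time ground truth: per-pair orientation/offset labels, bond
counts, per-residue β labels, layer counts and geometric nearest-contact
partners, all derived from the lattice arithmetic rather than by running the
analysis code. Strand spacing defaults to 5.8 Å — the spacing at which this
bead geometry satisfies the engine's hydrogen-bond criteria — rather than
the 4.9 Å fibril-diffraction value; layer spacing is 9.9 Å. Out-of-register
parallel lattices shift by whole pleat repeats (even offsets) because the
pleat has period 2. For 7-mers the lattice edge truncates the median pairing
offset of shifted parallel sheets (e.g. a 2-slot shift classifies as ±1);
the ground truth records the construction's own median, and the analysis
reproduces it exactly.

What the fixtures do *not* emulate: thermal disorder, edge fraying,
amorphous coexistence, finite-temperature registry defects. Passing the
fixture oracles shows the classification machinery is exact on clean
structures; the desk-scale dynamics runs probe the noisy case.

## Mass-spectrometry layer

Compositions and monoisotopic masses come from standard element/residue
tables (pyteomics); the proton mass convention is 1.00728 Da. The
photo-label (TFMD, trifluoromethyl-diazirine on Phe) is +C₂N₂F₃−H; carbene
chemistry is pure composition bookkeeping: peptide–peptide insertion is the
sum of chains −N₂ (one loss per formed link), water quench is −N₂+H₂O. b/y
fragments are enumerated per chain with the cross-link's partner chain
carried by exactly one side of each cleavage; double-fragmentation products
(one cleavage per chain, retaining the linked piece of each) are enumerated
on request and capped there — deeper fragmentation explodes combinatorially.
Printed literature masses for this chemistry are ~0.15–0.2 Da above the
theoretical monoisotopic values and their convention is not stated, so peak
matching uses an explicit ±0.2 Da tolerance; the m/z-relation arithmetic
itself reproduces the printed precursor neutral mass to 0.015 Da, and the
diagnostic b ion to 0.002 Da.

Site assignment ranks candidate (donor, acceptor) pairs by explained peak
count, then summed |error|; diagnostics list fragments matched by the top
candidate only. TWIMS CCS calibration fits ln Ω′ = ln A + B ln t_D by least
squares with Ω′ = Ω/(z·√(1/m_ion + 1/m_gas)), N₂ drift gas; drift times are
assumed dead-time corrected upstream.

## Problem sizes and study conditions

The published simulation is 192 peptides, 321.0 Å box (10 mM), T* = 0.193,
12 µs, three replicates — far beyond a single-CPU package test. The
package's standard desk-scale condition is 24 peptides at the same
temperature and concentration for a few thousand τ (several million
events), which is where hydrophobic collapse and the onset of inter-chain
β-sheet ordering become visible: β rises from 0 into the 3–15% range with
the characteristic lag, and the potential energy decays fast (collapse)
then slow (ordering). Acceptance-style checks run five seeds of 2400 τ and
ask for the qualitative shape in at least four; full saturation (the
analogue of the published 50%+ plateau and single four-layer sheet) needs
roughly an order of magnitude more time than a test suite budget allows and
is left to longer runs of `analysis/01_simulate_assembly.py`.

## Known limitations

* The interaction table is qualitative; registry preferences that depend on
  fine energetic balance (e.g. K16–E22 ladder strength vs F–F packing)
  should not be over-interpreted.
* Chirality is not enforced (mirror strands allowed).
* One hydrogen bond per donor/acceptor and inter-chain only.
* The Andersen thermostat at the default weak coupling leaves transport
  near-ballistic; absolute assembly timescales are therefore not mapped to
  experimental time, only the sequence of regimes is meaningful.
* Cross-link site assignment treats intensity as uninformative (peak lists
  only), and no isotope patterns are simulated.
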