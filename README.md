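# pepagg

Analysis of peptide-aggregation thermodynamics from multi-chain,
coarse-grained replica-exchange ensembles.

Short peptides aggregate — into amyloid-like fibrils, gels or amorphous
clumps — and whether they do so at a given temperature and concentration is
a central question both for peptide-drug design (where aggregation is
usually fatal) and for biomaterials (where it is the point). Equilibrium
simulations of a handful of chains in a concentration-matched periodic box,
run with temperature replica exchange, answer it by locating the
temperature at which the fully aggregated state dissociates. This package
implements the complete analysis layer for such simulations, for anyone
who has (or wants to emulate) Cα-trace snapshots of an N-chain system
sampled across a temperature ladder.

## What it computes

* **Sequence descriptors** — grand average of hydropathy
  (GRAVY = (1/n)·Σᵢ h(aaᵢ), Kyte–Doolittle scale), Henderson–Hasselbalch
  net charge at a chosen pH with configurable pKa values and terminal
  modifications, and the cubic box side l = (N/(C·N_A))^(1/3) matching an
  experimental molar concentration for N chains.
* **Oligomer identification** — two chains are associated when *any*
  Cα–Cα pair is closer than 7 Å under the minimum image; snapshots are
  partitioned into oligomers by iterative growth (equivalently, connected
  components of the association graph), giving per-snapshot fractions
  f_mᵢ of chains in m-chain oligomers.
* **Binless multi-temperature reweighting (WHAM)** — per-snapshot weights
  wᵢ(T) at any target temperature from the self-consistency equations
  exp(−f_k) = Σᵢ exp(−β_k Eᵢ)/Σ_l N_l exp(f_l − β_l Eᵢ), solved in log
  space; ensemble-averaged profiles f_m(T) = Σᵢ wᵢ(T) f_mᵢ, secondary
  -structure profiles f_s(T), and heat capacity
  C_v(T) = (⟨E²⟩_T − ⟨E⟩_T²)/(k_B T²).
* **Secondary structure from Cα geometry** — per-residue α/β/coil states
  from virtual-bond dihedrals plus a pseudo-peptide hydrogen-bond-proxy
  ladder pattern (β requires an actual paired strand, intra- or
  inter-chain; extended local geometry alone is coil).
* **Melting statistics** — the aggregate-dissociation midpoint T8m
  (logistic fit of f_N(T)), the β-content inflection Ti,β, heat-capacity
  peak temperatures, the window-convergence diagnostic σf8, and
  descriptor–melting-temperature regressions.
* **Conformational clustering & RMSF** — Ward minimum-variance clustering
  under a permutation-aware multi-chain RMSD, clusters ranked by
  cumulative wᵢ(T), medoid representatives, and per-residue Cα RMSF about
  an iteratively superposed mean chain.
* **Synthetic ensembles with exact answers** — a chain-partition model
  (contact energy ε per associated pair, entropy factor ν per block) whose
  partition function is enumerable for ≤10 chains, sampled by
  replica-exchange Monte Carlo and rendered into Cα coordinates; every
  pipeline stage can be validated against closed forms.

## Worked example

```python
from pepagg import (PeptideRecord, compute_gravy, compute_net_charge,
                    box_side_for_concentration, full_aggregate_profile,
                    midpoint_temperature, temperature_grid)
from pepagg.synthetic import (ToyModelSpec, enumerate_partition_model,
                              sample_ensemble)

rec = PeptideRecord(name="CysZ1", sequence="ARKQIV",
                    n_term="free", c_term="amide", concentration=4.210)
print(round(compute_gravy(rec), 3))                             # -0.233
print(round(compute_net_charge(rec, pH=7.0), 1))                # 3.0
print(round(box_side_for_concentration(rec.concentration, 8), 1))  # 146.7

spec = ToyModelSpec(epsilon=0.6, nu=50.0, n_sweeps=2500, seed=42)
oracle = enumerate_partition_model(spec)
print(round(oracle.midpoint(), 1))        # 287.3  (exact dissociation midpoint)

ens = sample_ensemble(spec)               # 6000 rendered snapshots, 12 rungs
prof = full_aggregate_profile(ens, temperature_grid(260, 370, 1))
print(round(midpoint_temperature(prof), 1))   # 285.8  (recovered from geometry)
print(round(prof.values[50], 3))              # 0.145  (f8 at 310 K)
```

The first block reproduces the descriptor table of the 20-peptide study
set bundled with the package (GRAVY −0.233, charge +3 at pH 7, and a
146.7 Å box realizing 4.210 mM for 8 chains). The second block builds a
synthetic 8-chain replica-exchange ensemble whose exact octamer
-dissociation midpoint is 287.3 K, then recovers 285.8 K by running the
full geometric pipeline — oligomer identification on rendered coordinates,
reweighting across the 12-rung ladder, and a logistic midpoint fit — and
shows that only 14.5% of chains remain in octamers at the 310 K
incubation temperature.

The same operations are scriptable via the `pepagg` command
(`descriptors`, `simulate`, `validate`, `convert`, `oligomers`,
`melt-profiles`, `summarize`, `cluster`); try `pepagg --help`.

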