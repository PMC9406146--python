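# Methods

This note records the models and procedures the package implements, the
parameter choices made where the design was open, and what the synthetic
validation does and does not demonstrate.

## Sequence descriptors

GRAVY is the arithmetic mean of the Kyte–Doolittle hydropathy indices over
the sequence (scale taken from Biopython's `ProtParamData`); it is
composition-only, so permuting a sequence or blocking its termini does not
change it. Net charge uses the Henderson–Hasselbalch form per ionizable
group. Because published peptide calculators differ in their pKa tables,
the set is injectable; the default is D 3.65, E 4.25, C 8.3, Y 10.07,
H 6.0, K 10.53, R 12.48, N-terminus 9.0, C-terminus 3.6. Charges quoted to
one decimal are robust to any mainstream set only when the contributing
groups are far from the working pH; the bundled regression therefore pins
charges only for peptides whose ionizable groups are fully charged at
pH 7 with blocked termini. The box side for concentration C (mM) and N
chains is l = (N/(C·N_A))^(1/3) with N_A = 6.02214076×10²³ exactly; table
comparisons round half-away-from-zero at the printed precision.

## Ensemble data model and windowing

A snapshot stores per-chain Cα coordinates (unwrapped per chain — a stored
chain never straddles the periodic boundary, keeping intra-chain geometry
directly usable), its potential energy in a declared unit (default
kcal/mol; only E/(k_B T) ratios are consumed), the ladder index it was
sampled at, a trajectory id and a step. The default ladder is the 12-rung
set 260–370 K. The analysis window keeps, per trajectory, the last
`window_frames` snapshots sub-sampled at every `stride`-th (defaults
1000 and 8), so 48 trajectories yield 6000 analysis snapshots. Files
travel as multi-model PDB (Cα only) plus a TSV metadata table and a small
YAML config; frame indices are 0-based everywhere.

## Oligomer identification

Two chains associate when any Cα–Cα minimum-image distance is strictly
below 7.0 Å. The partition of a snapshot is produced by the iterative
growth procedure (seed at the lowest unassigned chain, repeatedly scan the
remaining chains in index order for one associated with any member,
restart when the oligomer closes); this equals the connected components of
the association graph, which the tests verify by brute force with an
independent 27-image distance computation. All Cα atoms participate;
distances always take the minimum image because chains near a face can
contact a neighbor's periodic image.

## Secondary structure from Cα traces

With only Cα positions available, peptide-group interactions are proxied
by pseudo-peptide centers (midpoints of consecutive Cαs). A residue is
α when its virtual dihedral (over Cα i−1…i+2) lies in the helical band,
the Cα(i)–Cα(i+3) distance is below 6 Å, and its pseudo-peptide center
contacts the i+3 center within 6 Å (the helical hydrogen-bond pattern).
A residue is β when its dihedral is extended (|γ| ≥ 120°) *and* one of its
flanking centers pairs with a center of another strand segment (another
chain, under the minimum image, or the same chain at sequence separation
≥ 4) within 5.5 Å, in a ladder of at least two consecutive rungs.
Everything else — including an ideally extended but unpaired strand — is
statistical coil, as are residues whose dihedral is undefined (chain ends,
chains shorter than 5 residues). The dihedral sign convention is that of
`biotite.structure.dihedral`, under which a right-handed Cα helix sits
near +50°; the helical band is 30°–70°. All thresholds are named
parameters calibrated so that analytic helix and in-register sheet
fixtures classify correctly; they are stand-ins faithful to the
geometry-plus-interaction design, not values with independent
experimental provenance.

## Binless reweighting

The multi-temperature estimator solves
exp(−f_k) = Σᵢ exp(−β_k Eᵢ)/Σ_l N_l exp(f_l − β_l Eᵢ) by direct iteration
with log-sum-exp stabilization, gauge f₀ = 0, converged at
max|Δf_k| < 1e−10. Ladder rungs with no samples are excluded from the
weight denominator; a single-occupied-rung ensemble degenerates to
uniform weights at its own temperature (with a warning). Weights at any
target T are normalized to 1 (checked to 1e−12), and constant observables
reweight to themselves identically. No statistical-inefficiency
correction is applied by default — the windowing stage already
sub-samples by stride — and k_B defaults to 0.0019872041 kcal/mol/K.
Heat capacity is reported per system in the declared energy unit and is
used for peak locations only; its absolute normalization (per chain, per
mole) is deliberately left to the caller.

The tests cross-check the solver two ways: against the closed form of a
two-level system whose samples are constructed at exact Boltzmann
proportions (making the true free energies an exact fixed point), and
against an independent solver that minimizes the equivalent convex
objective with BFGS and an analytic gradient; free-energy differences
agree to 1e−6.

## Melting statistics

T8m is the midpoint of a logistic 1/(1+exp((T−Tm)/s)) fitted to the
complete-aggregate fraction by least squares, with the monotone
-interpolated 0.5 crossing as fallback and consistency check (the two
agree within 1 K on clean sigmoids). β-content never reaches 1, so its
transition is summarized by the inflection of a scaled logistic
a/(1+exp((T−Ti)/s)) + b; when that fit fails the maximum-|slope| point of
a Savitzky–Golay-smoothed profile is used, with slope ties resolved to
the middle of the tied range. Heat-capacity peaks are local maxima above
a prominence of 5% of the curve's range, tallest first. The convergence
diagnostic σf8 is the RMS deviation of a window's f8(T) from the final
window's over the ladder temperatures; a run is converged when σf8 has
stopped decreasing (final two values within 10% relative, or a
non-decreasing tail). The descriptor–melting regression is ordinary
least squares with Pearson R and residual SD on n−2 degrees of freedom.

## Clustering and RMSF

Frames are compared by all-chain Cα RMSD after optimal superposition
(Kabsch, via scipy's rotation alignment). Because all chains share one
sequence, the default metric also minimizes over chain relabelings:
assignment on chain-centroid distances (Hungarian algorithm) alternated
with re-superposition until the permutation stabilizes. Ward linkage on
the resulting distance matrix is cut at k = 5 clusters, which are ranked
by cumulative snapshot weight at the analysis temperature; each cluster
is represented by its medoid (the member minimizing mean squared distance
to the others — a coordinate-mean structure is ill-defined under
permutation symmetry), ties to the lowest frame index. When more frames
are available than the subsample bound (default 600), clustering operates
on a probability-weighted subsample with a fixed seed to bound the O(n²)
distance matrix. RMSF superposes every chain of the chosen frames onto an
iteratively re-estimated mean chain and reports the per-residue RMS
deviation; note that rigid-body refitting redistributes a localized
displacement partially into neighboring residues, so a single displaced
residue yields a peak slightly below the naive two-point value.

## The synthetic generator

The generator trades physical realism for exactness. A configuration is a
set partition of the N chains; each associated pair inside a block
contributes −ε to the energy and each block carries a
temperature-independent entropy factor ν (encoding the free-volume gain
of an independent oligomer), giving w(P,T) = ν^|P|·exp(−E(P)/k_B T). For
N ≤ 10 the 4140-or-fewer partitions are enumerated outright, providing
exact f_m(T), mean energy, C_v(T) and the dissociation midpoint (by
bisection). Defaults ε = 0.6 kcal/mol and ν = 50 put the exact midpoint
at 287 K, mid-ladder; the end-to-end validation uses ε from 0.565 to
0.73, whose exact midpoints span 270–350 K.

Sampling runs one Metropolis chain per ladder rung: single-chain
reassignment moves (move a chain into another block or split it off as a
singleton — the minimal merge/split pair) with the exact
proposal-asymmetry correction, verified against the brute-force
stationary distribution for 3 chains. Neighboring rungs attempt
configuration swaps with the standard exp(Δβ·ΔE) acceptance every 5
sweeps (the ν factor cancels in the swap ratio), and snapshots are
recorded at each exchange point after a 500-sweep burn-in, mirroring the
save-at-exchange convention of replica-exchange engines. Each recorded
partition is rendered into coordinates: blocks as parallel in-register
extended strands (4.8 Å spacing, so member chains satisfy the association
criterion transitively and interior residues satisfy the β criteria),
free chains as self-avoiding random coils, all placed by
bounding-sphere rejection so that inter-block Cα distances exceed the
7 Å cutoff plus a 1 Å margin under the minimum image. Identification
therefore recovers the generating partition on every frame, which the
tests assert.

What the generator does *not* emulate: continuum dynamics and kinetics,
realistic intra-chain flexibility, partial or transient contacts,
force-field energetics, or the real systems' β-melting-below-T8m
ordering — in this model β content is carried by every block of two or
more chains, so its inflection tracks the melting of the total associated
fraction, a few kelvin above the complete-aggregate midpoint. Passing the
end-to-end checks demonstrates the correctness of the analysis chain
(contact identification, reweighting, fitting) under known ground truth,
not the fidelity of any particular force field.

## Problem sizes

The default validation ensembles use 8 chains of 6 residues at 12
temperatures with 500–1000 snapshots per rung (6000–12000 frames per
system) — the same snapshot budget as the canonical 48-trajectory
windowing — which resolves dissociation midpoints to well under 2 K
against exact enumeration while keeping the whole suite inexpensive on a
single CPU.
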