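# Methods

## The observable and the state model

The central quantity is the cleft distance *d(t)*: the minimum over all
atom pairs between two clamp residues at the mouth of the cofactor-binding
site (Asp159 in the Rossmann-type domain, His363 in the α-helical domain
for YqhD; hydrogens are included when present, and a heavy-atoms-only flag
exists for crystal inputs).  Frames are classified

- CLOSED if *d* < 0.55 nm,
- OPEN if *d* > 1.0 nm,
- PARTIAL otherwise,

with strict inequalities, so boundary values fall in the transitional
band.  The numeric encoding CLOSED = 1, PARTIAL = 0.5, OPEN = 0 is carried
on the series for plotting.

A **switching event** is the first arrival in the terminal state opposite
to the current one; PARTIAL frames never emit events.  The waiting time of
an event at time *t* is *t − t_entry*, where *t_entry* is when the
departing terminal state was entered (series start or the previous
event).  Transit through the partial band therefore counts toward the
dwell — the time the enzyme "remains in a conformation before
switching".  The alternative convention (clock stops at the last frame
still in the departing state) is available as `exclude_transit=True`.
The raw distance series is not smoothed by default: picosecond-scale
fluctuation is part of the signal.  An optional `min_dwell_ps` debounce
relabels terminal visits shorter than the threshold as PARTIAL; it is off
by default.  The segment before the first terminal frame, and the dwell
after the last event (censored), contribute to state fractions but to no
event; the censored dwell is reported separately.

Replicas are aggregated by pooling: fractions are weighted by time-point
counts, events and waiting times are concatenated across replicas, and
replicas are never joined end-to-end, so no spurious cross-replica events
arise.

## Hydrogen bonds

A bond is called when the donor–acceptor heavy-atom distance is ≤ 0.35 nm
and the angle between the D→H and D→A vectors is < 30° (the donor-centred
convention of the GROMACS tools; the D–H···A ≥ 150° linearity convention
is a configuration switch).  Donors are N/O atoms with a bonded hydrogen
(bond inferred below 0.125 nm); acceptors come from per-residue chemistry
templates (carbonyl and carboxylate O, hydroxyl and water O, ring N
without H, phosphate O, cofactor amide O/N).  Occupancy is tallied every
10 ps at the residue-pair level — all atom-level contacts between two
residues collapse to one row, matching how such inventories are reported
— and rows below 30% presence are kept but flagged unreported.  Pairs are
undirected (either donor→acceptor orientation counts); the table row shows
the modal atom pair and its direction.  Cofactor rows are refined into
adenine / nicotinamide / dinucleotide-phosphate moiety tags from the
cofactor-side atom name, using the PDB chemical-component naming for
NAP/NDP; ring systems map to their base, riboses and phosphates to the
dinucleotide group.

Crystal structures lack hydrogens; `place_polar_hydrogens` adds them on
template donors at 0.10 nm: amide/guanidinium H in the heavy-atom plane
(anti to the existing substituents), rotatable hydroxyls by a 5° torsion
scan toward the nearest acceptor within 0.35 nm outside the donor's own
residue, waters likewise.  Placement is best-effort and idempotent;
water-mediated bridges are tagged `water` and excluded from the protein
inventories.

## Clustering

Conformations (backbone atoms, 100 ps stride by default) are compared by
mass-weighted RMSD after optimal superposition; the GROMOS neighbour-count
algorithm then repeatedly extracts the unassigned frame with the most
neighbours within the 0.13 nm cutoff as a cluster centre.  Two
conventions the original algorithm leaves open are fixed here: neighbour
counts include the frame itself, and ties break to the lowest frame
index.  Output clusters are relabelled by decreasing size.  The matrix is
held dense (the cache file stores an int32 dimension followed by the
row-major lower triangle as little-endian float32), so memory grows
quadratically in strided frames — the stride is the intended control.

## Release calling

A release event is a contiguous excursion of the protein–cofactor minimum
distance strictly above 1.0 nm lasting ≥ 1 ns (duration = last minus
first frame time of the run).  Both values are this package's choice —
release is visually obvious in distance traces, but a reproducible
detector needs a rule — set far above the bound-state contact distance
(~0.16 nm) and long enough to ignore single-frame noise; both are
configurable, and lowering either never removes an event.  The joint
report gives, per event, the cleft state at onset and the mean cofactor
R_g over the preceding window, which is where the compact
("bent-before-release") signature appears.  Whether a cofactor–Zn average
should include post-release segments is ambiguous; the series is reported
whole, and bound-state averages can be taken up to the first event.

## The synthetic generator

`synthgen` replaces the MD engine so every analysis stage can be verified
against exact ground truth.  A two-state continuous-time Markov chain
(CLOSED ⇄ OPEN, rates λ_open and λ_close per ns) is simulated in
continuous time — exponential dwells from a seeded generator — and only
then discretised at dt, so dwell statistics are exact and independent of
the frame spacing.  The distance observable is Gaussian about the state
mean, by default 0.25 nm (σ 0.08) closed and 1.30 nm (σ 0.10) open —
centred on the observed closed/open peaks and narrow enough that
noise-induced misclassification beyond the partial band stays below ~0.1%
— with a hard floor at 0.14 nm (the smallest cleft distance seen in
practice) and a 20 ps linear ramp through the partial band at each switch
(frames inside the ramp are flagged as transit).  The chain starts CLOSED,
as an equilibrated holo structure would.

The geometric embedding places two rigid 20-residue rods radiating from a
hinge; one rotates about the hinge axis, and the rotation angle is solved
per frame (Brent's method on the exact marker-pair minimum distance) so
the ASP159–HIS363 distance equals the latent distance to < 0.005 nm.
The second rod is offset 0.45 nm out of plane so only the marker tips
approach closely.  The pseudo-cofactor uses genuine NAP atom names across
its three moieties and sits ~0.18 nm above the static rod with one
planted hydrogen-bond acceptor per moiety; the Zn ion carries an exact
12-water inner shell (within 0.35 nm) plus 8 outer waters.  A scheduled
departure moves the cofactor perpendicularly out of the cleft at
1.2 nm/frame starting at the first non-transit OPEN frame at or after the
requested time — release proceeds from an opened cleft, as in the
proposed mechanism — and the realised time is recorded in the ground
truth.

The regime pair contrasts an open-biased fast regime
(λ_open = 2.4, λ_close = 0.7 ns⁻¹) with a closed-biased slow one
(λ_open = 0.4, λ_close = 0.8 ns⁻¹), five 200 ns replicas each.  The rates
are of the magnitude implied by the observed mean waits (hundreds of ps
to a few ns); reported per-direction waits include transit and censoring,
so their reciprocals are not taken literally as rates — the regimes are
meant to reproduce the *direction* of the oxidized/reduced contrast
(more open time and more switching when open-biased), not its exact
numbers.

What the generator does **not** emulate: real force-field dynamics,
solvent, correlated multi-residue motions, distance autocorrelation
within a state (noise is white), or partial-band dwell structure (the
transitional band is only a ramp).  Passing the recovery tests therefore
shows the *analysis* is correct — classification, event scanning, waiting
-time bookkeeping, release calling, geometric kernels — not that the
biological conclusions would re-emerge from new MD data.

## Numerical choices

- Units: nm and ps everywhere; conversion only at the PDB (Å) boundary.
  DCD files are written in Å (format convention) and carry no timestamps
  (uniform dt supplied on read); XTC stores nm and times but compresses
  coordinates to 0.001 nm.
- All fits and R_g are mass-weighted.  The Kabsch rotation comes from
  scipy's `align_vectors` (proper rotation guaranteed); the residual is
  recomputed directly from the transformed coordinates because the
  library's reported residual loses half its digits to cancellation near
  zero.
- Superposition requires ≥ 3 points with non-collinear spread; collinear
  sets raise rather than return an arbitrary rotation.
- Minimum distances are exact double loops (vectorised); no cell lists —
  selection sizes in this analysis never warrant them.  No periodic
  minimum-image handling: molecules are assumed whole.
- Alternate locations: only blank/'A' records are kept.  Elements missing
  from the PDB element column are inferred from atom names; masses come
  from a standard table.
- CTMC parameter-recovery checks compare the closed-state fraction
  against π_closed within three binomial standard errors taken over the
  number of observed dwells, not the number of frames: consecutive frames
  are correlated on the dwell timescale (τ = 1/(λ_open+λ_close)), so the
  frame count overstates the information content by roughly 2τ/dt.

## Open choices and limitations

- Domain boundaries (Rossmann-type resid 1–181, α-helical 182–387) are
  configuration defaults, used for interdomain tagging and domain
  metrics; published sources for this enzyme do not print exact ranges.
- For single-monomer crystal metrics the default monomer is chain D (the
  Zn-bearing one in 1OJ7), configurable.
- Whether crystal-structure H-bond counts should be computed with added
  hydrogens or heavy-atom-only criteria is not standardised; both modes
  exist and neither is asserted against a reference count.
- The test-suite problem sizes are deliberately desk-scale: gating runs
  of 200–700 ns at 10 ps sampling (tens of thousands of frames, latent
  series only), geometric embeddings of a few ns at ~300 atoms, and
  30-frame clustering matrices.  Multi-microsecond, 10⁵-atom workloads
  run through the same code paths but are the user's CPU budget.
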