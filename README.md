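# cleftdyn

Trajectory analysis of interdomain-cleft gating and cofactor release in
hinged two-domain enzymes, built around the *E. coli* oxidoreductase YqhD
(an NADP(H)-dependent, Zn²⁺-containing alcohol/aldehyde oxidoreductase,
crystal structure PDB 1OJ7).

YqhD binds its nicotinamide cofactor in a cleft between a Rossmann-type
nucleotide-binding domain and an α-helical metal-binding domain.  The
cleft opens and closes at the mouth of the binding site, and the minimum
distance between the clamp residues Asp159 and His363 is a one-dimensional
reporter of that motion: *d* < 0.55 nm is a **closed** cleft (as in the
holoenzyme crystal, *d* ≈ 0.16 nm), *d* > 1.0 nm is **open** (as in the
apoenzyme, *d* ≈ 1.25 nm), and the band in between is **partially
closed**.  How much time the enzyme spends in each state, and how long it
waits in a terminal state before switching (closed → open or back),
depends on the oxidation state of the bound cofactor and governs how
easily the cofactor is released.

`cleftdyn` implements the complete analysis chain for this kind of study,
for anyone working on domain-gating enzymes:

- **structio** — PDB / multi-model PDB / DCD / XTC I/O (nm and ps
  internally) and a small selection grammar (`chain`, `resid`, `resname`,
  `name`, `backbone`, `heavy`, `water`, `protein`, `and/or/not`);
- **geometry** — mass-weighted Kabsch superposition, RMSD series,
  per-residue RMSD, radius of gyration
  R<sub>g</sub> = √(Σᵢ mᵢ|rᵢ − r<sub>com</sub>|² / Σᵢ mᵢ),
  minimum / centre-of-mass distances, within-cutoff residue counts;
- **hbond** — geometric hydrogen-bond detection (donor–acceptor distance
  ≤ 0.35 nm and D→H∠D→A < 30°, the GROMACS convention; the D–H···A ≥ 150°
  convention is a flag), polar-hydrogen placement for crystal structures,
  and residue-pair occupancy tables with inter-monomer / interdomain /
  per-cofactor-moiety grouping;
- **cleftkin** — the three-state cleft classification (encoded 1 / 0.5 / 0),
  switching events with waiting times, replica aggregation, and distance
  histograms;
- **cluster** — GROMOS neighbour-count conformational clustering
  (0.13 nm backbone-RMSD cutoff, 100 ps stride by default);
- **release** — protein–cofactor and cofactor–Zn²⁺ minimum-distance
  series, release-event calling (sustained excursion above 1.0 nm for
  ≥ 1 ns by default), cofactor RMSD/R<sub>g</sub> conformation series and
  the Zn²⁺ water-shell census;
- **synthgen** — a synthetic stand-in for the MD engine: a two-state
  continuous-time Markov chain (exponential dwells, rates λ_open and
  λ_close per ns) drives a hinged-rod pseudo-enzyme whose marker-residue
  distance reproduces the latent cleft distance to < 0.005 nm per frame,
  with a bound pseudo-cofactor that departs on schedule, a Zn site with an
  exact water shell, and full analytic ground truth
  (π_closed = λ_close/(λ_open+λ_close), mean dwells 1/λ);
- a `cleftdyn` command-line tool (`cleft`, `hbond`, `cluster`, `release`,
  `rg-rmsd`, `simulate`, `demo`) driven by a YAML config, writing tidy
  CSV/JSON plus a reproducibility manifest.

## Worked example

Simulate the two cofactor-state regimes and analyse them end to end:

```bash
cleftdyn demo --out demo_out --seed 5
cat demo_out/regime_contrast.csv
```

```
regime,open_fraction,partial_fraction,closed_fraction,n_events,mean_wait_closed_to_open_ps,mean_wait_open_to_closed_ps
open-biased,0.7545578775455788,0.0109655701096557,0.23447655234476553,326,433.9024390243902,1375.5555555555557
closed-biased,0.39362730393627304,0.0057994200579942,0.6005732760057327,168,2092.705882352941,1368.0722891566265
```

The open-biased fast regime (λ_open = 2.4 ns⁻¹, λ_close = 0.7 ns⁻¹,
emulating oxidized-cofactor behaviour) spends 75% of time points open and
undergoes 326 switching events in 3 × 100 ns, with a mean closed→open
wait of ~0.43 ns; the closed-biased slow regime (λ_open = 0.4,
λ_close = 0.8 ns⁻¹, reduced-cofactor-like) stays mostly closed, switches
half as often, and waits ~2.1 ns before opening — the qualitative contrast
between facile and hindered cofactor release.  The demo also embeds a
gating path geometrically and calls the scheduled cofactor release:

```
start_time_ps,sustained,peak_distance_nm,scheduled_ps
2040.0,True,4.8033008840500555,2040.0
```

i.e. the release detector fires at exactly the scheduled departure frame.

The same stages run on real data:

```bash
cleftdyn cleft   --topology system.pdb --trajectory traj.xtc --out out/
cleftdyn cluster --topology system.pdb --trajectory traj.xtc --cutoff-nm 0.13 --out out/
```

From Python, crystal-structure reference metrics (with a local copy of
the 1OJ7 entry):

```python
from cleftdyn.crystal import crystal_report
crystal_report("1OJ7.pdb", monomer_chain="D")
# {'dimer_rg_nm': ..., 'monomer_rg_nm': ..., 'cleft_min_distance_nm': ...}
```

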