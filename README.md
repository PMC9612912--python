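# ligpath

A toolkit for analysing ligand binding pathways in molecular-dynamics
trajectories:

* **Binding-chain detection** — one chain per continuous ligand–protein
  association episode, using a 6 Å polar–polar association criterion, a
  10 Å all-heavy-atom dissociation criterion (hysteresis band), and a 4 Å
  two-orientation arginine–carboxyl docking criterion. Docked chains are
  split into binding (association → first docked frame) and time-reversed
  unbinding (last docked frame → dissociation) pathways; never-docked
  chains are discarded.
* **Pathway similarity analysis** — pairwise weighted-average Hausdorff
  distances between ligand reference-atom traces, hierarchical clustering
  (Ward or complete linkage) on the precomputed matrix, and per-cluster
  ligand occupancy densities written as OpenDX maps.
* **Residue contact statistics** — per-cluster fractional occurrence with
  0.2 (label) / 0.1 (display) tiers, Szymkiewicz–Simpson overlap
  coefficients within clusters vs the global pair mean, and
  fold-change comparisons between agonists.
* **Kinetics** — association rate constants `kon = N_b / Σ t_i·L_i·s_i`
  with residence-time thresholding (upper/lower bounds), bulk-time
  accounting, and free-ligand concentration from box volume and bulk-state
  occupancy.
* **Order parameters** — clamshell-closure distances ξ1/ξ2 (backbone
  center-of-mass distances), their 1-D projection ξ12, and the glycan–D2
  minimum heavy-atom distance.
* **Free energy** — 1-D histogram PMFs (0.2 Å bins, 5-block errors), 2-D
  WHAM unbiasing of harmonic umbrella windows (10-block errors),
  low-energy (≤1 kcal/mol) conformer extraction, and closure-conditioned
  PMFs.
* **Synthetic data** — a deterministic two-lobed toy receptor with a
  docking-arginine mimic, scripted-diffusion binding trajectories with
  exact ground-truth event logs (guided rails vs free diffusion, planted
  pathway templates), exact Boltzmann umbrella samples from analytic 2-D
  potentials, and a memoryless association-event generator with a planted
  kon. Every generator is a pure function of (parameters, seed).

## CLI

Stages communicate through CSV/JSON artifacts in `--outdir`; outputs embed
the toolkit version and a configuration hash, and runs are byte-for-byte
deterministic per seed.

```sh
ligpath simulate --seed 1 --outdir run        # synthetic receptor + trajectory
ligpath detect --outdir run                   # chains + pathways
ligpath cluster --n-clusters 4 --outdir run   # Hausdorff matrix, labels, densities
ligpath contacts --outdir run                 # contact profiles + OC summary
ligpath kinetics --outdir run                 # kon report + event/census tables
ligpath orderparams --outdir run              # xi1/xi2/xi12 (+ glycan-D2) series
ligpath pmf --outdir run                      # histogram PMF of xi12
ligpath pmf --windows windows.csv --outdir run  # 2-D WHAM from umbrella CSV
ligpath report --outdir run                   # run summary
```

The umbrella-window CSV has one sample per row with columns
`window_id,center1,center2,k,temperature,xi1,xi2`.

## Layout

```
src/ligpath/
  core.py         atoms, topology, trajectory, selections, units
  chains.py       chain detection, docking, pathway splitting, census
  similarity.py   Hausdorff metric, clustering, occupancy densities
  contacts.py     fractional occurrence, overlap coefficients
  kinetics.py     kon estimation, bulk time, concentrations
  orderparams.py  xi1/xi2/xi12 and glycan-D2 order parameters
  free_energy.py  histogram PMF, 2-D WHAM, block errors, conformers
  synthetic.py    ground-truth generators
  io.py           PDB/DCD via MDAnalysis, topology JSON, YAML config
  cli.py          the `ligpath` command
```
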