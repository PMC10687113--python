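# confspace

Determination and visualization of the accessible conformation space of
two-domain complexes from inter-spin-label distance distributions
(PELDOR/DEER-style data).

Experimental per-pair distance probability distributions are turned into
bounded, differentiable restraint penalties

```
T(r) = A · max(0, 1 − P(r) / (p_max · c))        (A = 10.0 Å², c = 0.75)
```

and an iterative, history-dependent protocol (250 iterations × 100
calculated / 10 selected structures by default) anneals rigid-body + linker
conformers against them. After each iteration, a Gaussian (σ = 2.5 Å,
area 1/n) is subtracted from a mutable working copy of every distribution at
each selected conformer's realized distance, progressively flattening the
already-sampled regions so the final ensemble reproduces the *full* input
distributions rather than only their modes. Conformers are then weighted by
the product of ±2.5 Å window probabilities under the original distributions
(max-normalized to a relative probability of 1), and the moving domain's
occupancy is rendered as a max-merged 3D Gaussian grid (1 Å spacing) written
as CCP4/MRC and OpenDX volumes loadable in PyMOL/ChimeraX.

## Quick start (synthetic fixture)

Everything is testable without external data — the `synth` subcommand emits
a complete runnable fixture (two pseudo-domains, a flexible linker, label
sites, forward-simulated distance distributions, and a config):

```bash
confspace synth --seed 1 -o fixture/
confspace run  -c fixture/config.yaml -o fixture/out --seed 1
confspace validate -c fixture/config.yaml -o fixture/report.json
```

`run` writes, into the output directory:

| file | content |
|---|---|
| `ensemble.pdb` | multi-model PDB, stationary domain superposed |
| `conformers.json` | machine-readable ensemble (poses, distances, weights) |
| `weights.tsv` | per-conformer window/joint/relative probabilities |
| `computed_<pair>.dat` | ensemble distance distribution per restraint |
| `density.mrc`, `density.dx` | max-merged probability volume |
| `manifest.json`, `run.log` | provenance and per-iteration convergence |

Protocol constants can be overridden on the command line
(`--iterations --calculated --selected --sigma-sub --weighting-factor
--cutoff --anneal-steps --seed`). `weight` and `density` re-run those stages
from `conformers.json` without re-sampling. `validate` runs the
restrained-vs-free and leave-one-out harnesses and reports histogram
intersection overlaps.

To view a map in PyMOL:

```
load out/ensemble.pdb
load out/density.mrc, space
isosurface surf, space, 0.5
```

## Real data

Provide a YAML config pointing at your PDB templates and distribution files
(two text columns: distance, probability density; `#`/`%` comments; unit
`angstrom` or `nanometre` per file):

```yaml
bodies:
  stationary: {pdb: e2.pdb, chain: A, rigid_ranges: [[1, 94], [109, 165]], anchor_residue: 89}
  moving:     {pdb: ub.pdb, chain: A, rigid_ranges: [[1, 71]], anchor_residue: 76}
linker: {n_residues: 5}
labels:
  - {name: S1, body: stationary, residue: 25}   # default: 7 Å along CA→CB
  - {name: M1, body: moving, residue: 48, position: [x, y, z]}  # explicit
restraints:
  - {pair: S1-M1, sites: [S1, M1], file: s1_m1.dat, unit: nanometre}
protocol: {n_iterations: 250, n_calculated: 100, n_selected: 10, rng_seed: 1}
density: {spacing: 1.0, mode: single}
output: out
```

## Layout

- `src/confspace/distributions.py` — reading, normalization, continuous
  representation, penalty terms
- `src/confspace/structure.py` — rigid bodies, pseudo-linker, label sites,
  steric score, PDB I/O
- `src/confspace/sampler.py` — annealing engine and the iterative
  Gaussian-subtraction protocol
- `src/confspace/weighting.py` — window/joint/relative probabilities
- `src/confspace/density.py` — superposition, max-merged density grid,
  MRC/DX volume I/O
- `src/confspace/synthetic.py` — ground-truth generators, forward
  simulation, validation harness
- `src/confspace/cli.py` — `confspace` command-line interface
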