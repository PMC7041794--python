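# idrens

Desk-scale analysis pipeline for the conformational ensembles of a
disordered, acidic iron-binding peptide (residues 38–59 of the magnetosome
protein Mms6) and its alanine variants, together with the companion
wet-lab-assay analytics. All inputs are generated in-package: a
coarse-grained torsional Monte Carlo sampler stands in for the original
all-atom simulations, and synthetic generators stand in for the
luminescence plate reader and the nanoplasmonic sensor.

## What's inside

| Module | Purpose |
| --- | --- |
| `idrens.sequences` | Variant registry (WT, D42A, E44A, D49A, E50A, E51A, EE50AA, E53A, R55A, D56A, MM), per-residue charges and helix propensities, FASTA round trip |
| `idrens.sampler` | Metropolis Monte Carlo sampler over Ramachandran-basin proposals with soft sterics, Debye–Hückel electrostatics and a helix bias; excluded-volume reference; counter-based (Philox) per-run seeding |
| `idrens.geometry` | Rigid ideal-geometry backbone construction (N/CA/C + side-chain bead) and dihedral extraction |
| `idrens.descriptors` | Rg, asphericity, end-to-end distance, per-residue helicity (run-of-4 rule), mean distance maps, scaling maps vs the excluded-volume reference |
| `idrens.compare` | Mutant-vs-WT metrics: local distance-map deviation, Hellinger distance of (Rg, asphericity) 2D distributions, pairwise-dissimilarity heterogeneity, cross-variant ranking |
| `idrens.assay` | Plate arithmetic (concentration/aliquot), replicate statistics, one-way ANOVA vs control, 1 Hz plasmon-trace transition windows and drift, plus both synthetic generators |
| `idrens.trajio` | Multi-model PDB (biotite) and XYZ trajectories with YAML provenance sidecars |
| `idrens.config` / `idrens.pipeline` / `idrens.cli` | YAML config, end-to-end orchestration with manifest, `idrens` command-line interface |

The sampler reproduces the published sampling design: 20 independent runs,
30×10⁶ production steps sampled every 20×10³ (1500 configurations per run,
30,000 per construct), 2×10⁶ equilibration steps, a 56 Å droplet, 298 K,
20 mM salt. The `desk` preset divides the step counts by 100 while keeping
1500 configurations per run so every count-based contract still holds at
laptop scale. The energy function is a simplified, documented stand-in —
quantitative reproduction of the original all-atom ensemble statistics is
explicitly not claimed; the per-residue helix propensities are calibrated so
the wild type shows 10–15% transient C-terminal helicity.

## CLI

```bash
idrens variants                          # registry as FASTA
idrens run-all --outdir runs/demo --seed 1 --preset desk
idrens simulate --config my.yaml         # individual stages compose the same
idrens plate --outdir runs/demo --seed 1
idrens nps --outdir runs/demo --seed 1
```

Every stage derives all randomness from the base seed; rerunning a config
reproduces its outputs byte-for-byte. `runs/<name>/manifest.json` records
the config hash, per-variant seeds, stage timings and the produced files.

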