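# switchscope

Quantitative analyses for characterizing nucleotide-binding switch
proteins (G-alpha-type GTPases) and their variants:

- **thermostability** — Boltzmann-sigmoid fitting of variable-temperature
  CD melting curves (`T_m` = V50), triplicate aggregation, and
  classification of each variant x nucleotide pair as
  nucleotide-responsive, GDP-like, GTP-like or indeterminate against
  wild-type references.
- **kinetics** — one-phase association fitting of tryptophan-fluorescence
  nucleotide-exchange traces (rising or falling), reporting the rate
  constant in reciprocal time-axis units.
- **stdnmr** — saturation-transfer-difference NMR amplification factors
  `A_STD = ((I0 - Isat)/I0) * [L]/[P]` with SNR-derived errors
  (`sigma = A_STD / SNR_diff`), normalization to a reference proton with
  quadrature error propagation, and interaction-strength binning
  (<50% weak, 50–99% weak-moderate, ~100% reference, 101–150% moderate,
  >150% strong).
- **traj** — post-processing of multi-model PDB trajectories:
  geometric H-bond detection (H···acceptor < 2.4 Å, donor-H···acceptor
  angle > 120°), inter-switch-region occupancy matrices with persistence
  thresholds, per-residue backbone RMSF, closest-residue proximity
  profiles of labeled nucleotide protons (< 6 Å radius, with a
  none-in-radius bucket so frequencies sum to 1), and replica
  aggregation as mean ± s.e.m.
- **synthetic** — seeded generators producing inputs with the exact
  statistical structure each stage assumes: sigmoidal melts, exponential
  traces, SNR-limited STD integral tables, and geometric toy
  trajectories whose H-bond occupancies and closest-residue fractions
  are realized by exact frame counting (no force field — fixtures only).

## Command line

```sh
switchscope run-all --seed 42 --out out/          # full synthetic demo
switchscope simulate --kind melt --spec spec.json --out curves.csv
switchscope melt-fit --in curves.csv --out thermal.json
switchscope kinetics-fit --in traces.csv --out kinetics.json
switchscope std-af --in std.csv --out std.json --matrix-out ratios.csv
switchscope hbond --traj r0.pdb --traj r1.pdb --out hbond.json
switchscope rmsf --traj r0.pdb --out rmsf.json
switchscope proximity --traj r0.pdb --radius 6 --out proximity.json
switchscope dossier --in thermal.json --in kinetics.json --out dossiers.json
```

CSV schemas: melting curves use
`temperature_C,signal,variant,nucleotide,replicate`; kinetic traces
`time_s,intensity,variant[,nucleotide]`; STD tables
`proton,i0,isat,snr,usable,variant,nucleotide,ligand_uM,protein_uM`.
Trajectories are MODEL/ENDMDL multi-model PDB files; proton labels and
bonds travel in a `<file>.labels.json` sidecar written alongside.

Outputs are deterministic for a fixed seed and configuration
(`run-all` is byte-identical across runs) and every report carries a
provenance block (config hash, seed, package version).

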