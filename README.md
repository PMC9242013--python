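# barrierkit

Synergistic semi-empirical QM + machine-learning prediction of DFT-quality
free-energy activation barriers for C–C bond-forming conjugate additions,
with quantitative comparison of transition-state geometries across levels
of theory.

The pipeline:

1. **qm_io** — read XYZ files and quantum-chemistry logs (a documented
   plain-text "native log" dialect plus a Gaussian-style parser behind a
   pluggable registry), merge solvent single-point energies, and assemble
   reaction manifests (CSV/JSON) pairing Michael acceptor (MA), nucleophile
   and transition state (TS) per level of theory. Units are fixed at
   ingestion: Å, Hartree, signed cm⁻¹ (negative = imaginary), elementary
   charges; atom indexing is 0-based everywhere.
2. **thermo** — quasiharmonic ideal-gas RRHO thermochemistry: Grimme damped
   free-rotor entropy interpolation (Head-Gordon damping, 100 cm⁻¹ cutoff
   default; Truhlar raising and plain RRHO selectable), molar standard-state
   correction RT ln(cRT/p°), and bimolecular barriers
   ΔG‡ = G(TS) − G(MA) − G(Nu).
3. **descriptors** — interpretable physical-organic features: Gasteiger
   (PEOE) charges, Kier–Hall electrotopological-state indices, Sterimol
   L/B1/B5, percent buried volume, Shrake–Rupley SASA, plus distance-based
   bond perception. Deterministic point sets/grids; Bondi radii from one
   constants table.
4. **featurize** — per-reaction feature tables tagged by level and subset
   (MA / TS / All, the latter including the baseline barrier), train-only
   standardization, zero-variance + collinearity pruning with a removal
   report, CSV + JSON-sidecar serialization.
5. **learn** — seven regressor families (Ridge, NNR, RFR, GBR, SVR, KRR,
   GPR with ARD Matern kernel), direct or **delta** targets (fit
   DFT − baseline, add the baseline back), greedy forward feature selection,
   grid tuning with k-fold CV, repeated-split double CV, learning curves,
   permutation importances, and structural leakage protection (selection and
   tuning cannot read non-train rows).
6. **geometry** — Kabsch superposition RMSD, stripped-substructure RMSDs
   (no-nucleophile / no-R-groups / core-only / MA-vs-TS), forming-bond
   distance deltas, sub-vdW contact detection, distribution summaries.
7. **fixtures** — deterministic synthetic reactions (enone template +
   substituent vocabulary + nitronate-like nucleophile) at two pseudo-levels
   with planted barriers, geometric noise, ground-truth sidecars, and
   synthetic feature tables with sparse planted signal for ML tests.

## CLI

```bash
# synthetic dataset (logs + XYZ + manifest + ground truth)
barrierkit fixtures make --n 50 --seed 7 --out data/

# quasiharmonic barriers at one level
barrierkit barriers compute --manifest data/manifest.csv --level SQM \
    --temp 298.15 --conc 1.0 --qh grimme --cutoff 100 --out barriers.csv

# descriptor block for one structure
barrierkit descriptors compute --xyz data/rxn0000_DFT_MA.xyz --key-atoms 0,3

# cross-level TS comparison
barrierkit geometry compare --manifest data/manifest.csv --levels SQM,DFT \
    --out rmsd.csv

# train/evaluate on a saved feature table
barrierkit learn run --features table.csv --model GPR --kernel Matern \
    --mode delta --seed 42 --double-cv 5 --report report.json
```

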