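# affinet

An E(3)-equivariant graph neural network scoring function that maps a 3D
protein–ligand complex to a predicted binding affinity (pK) as a sum of
free-energy contributions: a single trainable shift (initialized to the
training-label mean), per-ligand-atom terms, and per-ligand–protein-pair
terms. It supports a global→local transfer-learning workflow for congeneric
ligand series and a ligand-only ablation mode, plus a synthetic benchmark
generator with a known additive affinity oracle so the whole pipeline is
testable offline.

The model ingests only atomic numbers, 3D coordinates, and protein/ligand
membership. Two disconnected distance-cutoff graphs (ligand, protein) are
built per complex; message passing maintains invariant scalar features and
equivariant 3-vector directional features per atom; interatomic distances
are expanded on a Bessel radial basis with a smooth polynomial cutoff
envelope. Predictions are exactly invariant to rigid motions of the input,
and local: atoms beyond `n_passes * r_msg + r_pair` of the ligand cannot
affect the prediction.

The network runs on a small numpy reverse-mode autodiff engine
(`affinet.nnkit`) — no deep-learning framework required.

## Package layout

| module | role |
|---|---|
| `affinet.io_structures` | PDB/SDF/MOL2 parsing into `AtomicComplex`, pocket extraction, CSV manifests |
| `affinet.graphs` | cutoff graphs (brute force + KD-tree, tested identical), Bessel radial basis |
| `affinet.egnn` | equivariant message-passing encoder (scalar + directional features) |
| `affinet.readout` | shift + atomic + pair readouts, `PredictionBreakdown` |
| `affinet.training` | direct / k-fold ensemble / transfer training, stratified split, augmentation, metrics |
| `affinet.synthetic` | synthetic complexes with a known additive affinity oracle (global + local regimes) |
| `affinet.cli_app` | `affinet` CLI |
| `affinet.nnkit` | numpy autodiff engine, layers, Adam |

## CLI

```bash
# generate a synthetic labeled dataset (PDB + SDF + manifest.csv)
affinet simulate --kind global --n 100 --seed 0 --out data/global

# train / k-fold ensemble / transfer
affinet train    --manifest data/global/manifest.csv --config config.yaml --out runs/base
affinet kfold    --manifest data/global/manifest.csv --k 5 --out runs/cv
affinet transfer --base runs/base/checkpoint.npz --manifest data/local/manifest.csv --out runs/tl

# predict (per-complex JSON with atom/pair contribution breakdown) + evaluate
affinet predict  --ckpt runs/base/checkpoint.npz --manifest data/global/manifest.csv --out preds.json
affinet evaluate --pred preds.json --manifest data/global/manifest.csv --out metrics.json
```

Config YAML sections: `training` (fields of `TrainingConfig`), `model`
(fields of `ModelConfig`), and `pocket_radius` (Å; `inf` disables pocket
truncation). CLI flags override the file; every run writes a
`run_record.json` with the effective config and seed. Exit codes: 0 ok,
2 usage error, 3 invalid config / incompatible inputs.

## Notes

- Default cutoffs are 5 Å for both message passing and pair readout;
  pocket extraction defaults to 8 Å.
- Coordinate augmentation (uniform in a 0.1 Å ball, training only) is the
  regularizer of choice; rotations/translations are unnecessary because the
  architecture is exactly equivariant.
- Checkpoints are `.npz` archives with a JSON header (config hash checked
  on load; mismatched architectures are refused).
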