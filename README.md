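# pocketseg

Detection of ligand-binding pockets on protein structures by 3D semantic
segmentation.

Most structure-based drug-design workflows assume the binding site is
known; finding it is the hard part.  `pocketseg` treats pocket detection
the way computer vision treats image segmentation: the protein becomes a
36×36×36 voxel grid (2 Å resolution, 70 Å span, centered on the protein)
with 18 atomic feature channels, and a 3D U-Net — four encoder blocks, a
1×1×1 bottleneck, four decoder blocks with skip connections — predicts,
for every voxel, the probability that it belongs to a pocket.  Training
minimizes the negative smoothed Dice coefficient

    C(y, t) = -(2 Σ y·t + ε) / (Σ (y + t) + ε),    ε = 0.01,

with L2 regularization (λ = 10⁻⁵) and Adam.  Predicted densities are
thresholded at 0.5, split into face-connected components, and ranked by
summed probability; components map back to pocket-forming residues.
Evaluation uses the field's standard metrics: DCC (distance between
predicted and reference pocket centers; < 4 Å counts as correctly
located), DVO (voxel intersection-over-union of the segmentations),
success-rate curves, and detection precision/recall/F1.  Missed pockets
receive sentinel values DVO = 0 and DCC = 70√3 ≈ 121.24 Å.

The whole stack — voxel featurization, the network with backpropagation
and Adam (implemented directly on numpy), grouped cross-validation,
pocket extraction, metrics, and a synthetic-fixture generator — is
self-contained and testable on a laptop CPU.  It is aimed at method
developers and computational chemists who want a transparent, hackable
reference implementation rather than a trained production model; training
at published scale (~1.5M steps on a large cavity database) needs
accelerator hardware and is supported only as configuration.

## Worked example

```python
from pocketseg import (PocketSegmenter, ToyComplexSpec, make_toy_complex,
                       sentinel_dcc, GridSpec, dcc)

# a 400-atom pseudo-protein with one planted surface cavity + its
# reference point cloud (the representation real cavity references use)
protein, cavities, group = make_toy_complex(ToyComplexSpec(seed=7))

est = PocketSegmenter(                      # narrow desk-scale architecture
    encoder_filters=(4, 8, 16, 32), bottleneck_filters=64,
    steps=250, learning_rate=1e-4, batch_size=1, augment=False, random_state=0,
)
est.fit([protein], [cavities])
print(f"training Dice: {est.score([protein], [cavities]):.3f}")

segments = est.predict([protein])[0]
true_center = cavities[0].coords.mean(axis=0)
for rank, seg in enumerate(segments):
    print(f"pocket {rank}: {seg.n_voxels} voxels ({seg.volume:.0f} A^3), "
          f"score {seg.score:.1f}, DCC to planted cavity {dcc(seg.center, true_center):.2f} A")
print(f"sentinel DCC for the default grid: {sentinel_dcc(GridSpec()):.2f} A")
```

Output:

```
training Dice: 0.287
pocket 0: 390 voxels (3120 A^3), score 388.0, DCC to planted cavity 1.03 A
sentinel DCC for the default grid: 121.24 A
```

After 250 desk-scale steps the model already places its top-ranked pocket
1.03 Å from the planted cavity center (well below the 4 Å success
threshold), while the segmentation is still loose — Dice 0.29, a predicted
volume of 3120 ų against the cavity's 524 ų.  Location converges before
shape; longer training (the test suite's probe runs 500 steps on five
structures) tightens Dice above 0.95.

The same pipeline is available from the shell:

```bash
pocketseg make-fixtures --n 10 --seed 0 --out fixtures/
pocketseg train --manifest fixtures/manifest.tsv --checkpoint model.npz --steps 600
pocketseg predict --input fixtures/protein_000.mol2 --model model.npz --output out/
pocketseg evaluate --pred-dir preds/ --truth-dir truths/ --out report.tsv
```

`predict` writes the probability density as Gaussian `.cube` and HDF5
`.cmap` volumes for molecular viewers plus one `pocketN.mol2` per detected
pocket containing its residues.

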