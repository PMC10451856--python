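# mvifusion

Attention-guided multi-phase MRI feature fusion for predicting
**microvascular invasion (MVI)** in hepatocellular carcinoma — with a
synthetic phantom bench so the entire pipeline is testable without patient
data.

MVI is a microscopic finding (tumor emboli in endothelium-lined vascular
spaces of the peritumoral liver) that strongly predicts HCC recurrence but
is only confirmed on the resected specimen.  Its preoperative radiological
correlates — irregular tumor margins, arterial-phase peritumoral
hyperenhancement, hepatobiliary-phase peritumoral hypointensity — live in
different phases of gadoxetate-enhanced MRI (pre-contrast **PreP**, arterial
**AP**, portal **PP**, hepatobiliary **HBP**).  This package implements a
volumetric CNN that fuses the four phases through attention:

* per phase, a small LeNet5-style 3D CNN on a 16³ tumor cube, with a
  **self-attention** block (row-softmax of scaled query–key scores over the
  N = D·H·W flattened positions; residual output y = x + γ·AV, γ learnable,
  identity at γ = 0);
* across phases, a **collaborative-attention** block: each phase's queries
  attend to the other phases' keys/values, pair outputs averaged and
  residual-added — the cross-modal step that imports related information;
* per-phase 32-d features, concatenated into a |phases|·32 vector and a
  2-way softmax head, trained with the weighted multi-phase loss
  **L = Σₓ ωₓ·CEₓ** (auxiliary per-phase heads; ω normalized to sum 1),
  momentum SGD (batch 16, lr 0.004, momentum 0.9, weight decay 1e-4,
  50-epoch budget, 501-iteration cap), 5-fold cross-validation and early
  stopping.

Preprocessing mirrors the standard tumor-cube protocol: mask → bounding box
expanded by 2 voxels → cubified; global cube resampled to 16³; training-side
augmentation resamples to 32³ and cuts 16³ cubes at stride 2 (9 offsets per
axis → **729 local cubes** per tumor per phase; 168 training patients yield
729·168 + 168 = **122,640 samples per phase**).  Evaluation provides rank
AUC with stratified-bootstrap 95% CIs, Youden operating points and decision
curve analysis; interpretability provides Grad-CAM on the attention layers,
per-phase FC weight grids (32 per phase) and a quantitative
attention-localization statistic.

The networks run on a compact reverse-mode autodiff core over NumPy
(`mvifusion.nn`) — no deep-learning framework required; every op's gradient
is finite-difference tested.

The **phantom generator** plants exactly those MVI correlates with tunable
effect sizes (smooth spherical-harmonic margin perturbation, ±ring contrasts
in a 2-voxel peritumoral shell, Gaussian noise), so recovery of the planted
signal by the fusion model is a testable property.

## Worked example

```bash
python examples/03_train_fusion_model.py
```

trains a two-phase (AP+HBP) fusion model on 40 phantoms (32 train / 8 test)
with a 120-step cap and prints:

```
32 train / 8 test patients; 23360 training samples per phase
fold 0: stopped at step 120, best val loss 1.146, last val AUC 1.00
fold 1: stopped at step 120, best val loss 1.171, last val AUC 0.00
2-phase fusion ensemble test AUC: 0.800
```

23,360 = 730·32 samples per phase (729 local + 1 global per training
patient); the ensemble averages the two folds' softmax probabilities on the
8 test patients' global cubes, and the AUC measures how well the planted
AP/HBP rings separate the classes at this tiny training budget (the 4-patient
validation folds make per-fold val AUCs very coarse).  The other examples
cover phantom simulation, preprocessing arithmetic, ROC/DCA evaluation
(`04` prints AUC 0.98 with 95% CI 0.95–1.00 and a net-benefit comparison
against treat-all/treat-none) and attention interpretability (`05` prints
the per-phase weight grids and an AP Grad-CAM margin+shell mass fraction of
0.449 against a permuted null of 0.368).

## Command line

A thin CLI drives the end-to-end pipeline on a run directory:

```bash
mvifusion run-all --config config.yaml --outdir runs/demo --seed 7
# or stage by stage:
mvifusion simulate|preprocess|train|evaluate|explain --outdir runs/demo
```

The YAML config has one section per stage (`phantom`, `split`, `network`,
`train`, `evaluate`, `explain`); every field is validated with its dotted
key path and the normalized snapshot is stored in the run directory next to
`run_manifest.json`, which tracks stage completion.

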