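"""Grad-CAM saliency and phase-weight grids on a quickly trained fusion model.

Trains a short 4-phase run, then asks two interpretability questions:
which phase does the fused head weight most, and how much Grad-CAM mass
falls on the tumor margin + peritumoral shell of an MVI-positive phantom.
"""

import numpy as np
import pandas as pd

from mvifusion.interpret import (
    attention_mass_fraction,
    grad_cam,
    margin_shell_region,
    permutation_null_fraction,
    phase_mean_weights,
)
from mvifusion.nn import NetworkConfig
from mvifusion.phantom import PHASES, PhantomConfig, cohort_labels, generate_study
from mvifusion.preprocess import CubeStore, build_cube_store, build_manifest, make_split, mask_to_bbox
from mvifusion.training import TrainConfig, train_fold

cfg = PhantomConfig(n_patients=40, volume_shape=(48, 48, 48), seed=5)
labels = cohort_labels(cfg)
studies = [generate_study(cfg, i, int(l)) for i, l in enumerate(labels)]
roster = pd.DataFrame({"patient_id": [s.patient_id for s in studies], "mvi_label": labels})
split = make_split(roster, seed=5)
store = build_cube_store(studies, split)
fm = train_fold(store, build_manifest(roster, split), 0, NetworkConfig(),
                TrainConfig(max_iterations=150, eval_interval=50, early_stop_patience=6, seed=5))
model = fm.build()

weights = phase_mean_weights(model)
print("mean |FC weight| per phase segment (32 features each):")
for p, w in sorted(weights.items(), key=lambda kv: -kv[1]):
    print(f"  {p:>4}: {w:.4f}")
print("The largest grid marks the phase contributing most to the fused decision.")

study = generate_study(cfg, 999, 1)  # a fresh MVI-positive case
cs = CubeStore()
cs.add_study(study, with_local=False)
cubes = {p: cs.get_cube(study.patient_id, p, "global", (0, 0, 0))[None] for p in PHASES}
region = margin_shell_region(study.mask, mask_to_bbox(study.mask))
sal = grad_cam(model, cubes, layer="collaborative_attention", phase="AP", target_class=1)
frac = attention_mass_fraction(sal, region)
print(f"\nAP collaborative-attention Grad-CAM mass on margin+shell: {frac:.3f} "
      f"(permuted-heatmap null {permutation_null_fraction(region):.3f})")
print("Mass above the null indicates the saliency concentrates on the"
      " margin and peritumoral band rather than being spatially uniform.")
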