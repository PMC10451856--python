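"""Generate a small synthetic four-phase cohort and read back the planted signal.

Creates 8 phantom patients (half MVI-positive), writes them as NIfTI files
plus a roster CSV, and verifies that the arterial-phase peritumoral ring is
recoverable from the voxel data.
"""

import numpy as np

from mvifusion.phantom import PhantomConfig, generate_cohort, load_study, peritumoral_shell

cfg = PhantomConfig(n_patients=8, mvi_fraction=0.5, volume_shape=(48, 48, 48), seed=42)
roster = generate_cohort(cfg, "runs/example_phantom")
print(roster[["patient_id", "mvi_label"]].to_string(index=False))

positive = roster[roster["mvi_label"] == 1].iloc[0]
study = load_study(positive)
shell = peritumoral_shell(study.mask.astype(bool), cfg.ring_thickness)
background = ~(study.mask.astype(bool) | shell)
delta = study.volumes["AP"][shell].mean() - study.volumes["AP"][background].mean()
print(f"\n{study.patient_id}: AP shell minus background = {delta:.1f} "
      f"(planted ring contrast {cfg.ap_ring_contrast}, noise sd {cfg.noise_sd})")
print("The measured shell excess approximates the planted arterial ring; with"
      " noise_sd=0 it would match exactly.")
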