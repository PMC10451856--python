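"""ROC/AUC with bootstrap CI, operating point, and decision-curve analysis.

Runs on synthetic scores so it executes instantly; the same functions are
used on real model outputs by the pipeline's evaluate stage.
"""

import numpy as np

from mvifusion.evaluation import compare_models, format_report, net_benefit, roc_auc

rng = np.random.default_rng(0)
labels = np.array([1] * 14 + [0] * 28)  # the cohort-style 1:2 test composition
good = np.clip(labels * 0.55 + rng.normal(0.3, 0.18, 42), 0, 1)
weak = np.clip(labels * 0.25 + rng.normal(0.4, 0.2, 42), 0, 1)

r = roc_auc(good, labels, n_boot=2000, seed=0)
print(f"AUC {r.auc:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f}); "
      f"Youden threshold {r.threshold:.2f} -> acc {r.accuracy:.2f}, "
      f"sens {r.sensitivity:.2f}, spec {r.specificity:.2f}")

table = compare_models({"strong_model": good, "weak_model": weak}, labels, seed=0)
print("\n" + format_report(table))

dca = net_benefit(good, labels, np.arange(0.05, 0.6, 0.05))
i = 3  # p_t = 0.20
print(f"\nNet benefit at p_t={dca.thresholds[i]:.2f}: model {dca.net_benefit[i]:.3f} "
      f"vs treat-all {dca.treat_all[i]:.3f} vs treat-none 0.000")
print("A model is clinically useful at thresholds where its curve lies above"
      " both reference policies.")
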