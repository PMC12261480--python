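"""Score per-residue disorder predictions against binary labels.

We build a labeled reference, generate synthetic predictor scores
calibrated to a known ROC AUC of 0.8, and evaluate them with the pooled
metric suite (confusion counts at 0.5, F1, MCC, ROC AUC, average
precision, and the best F1 over a 0.01-step threshold grid).
"""

import numpy as np

from softdis import generate_predictions, metrics_report

rng = np.random.default_rng(21)
labels = {
    f"seq{i:02d}": (rng.random(200) < 0.3).astype(np.int8) for i in range(20)
}
# mask a few positions per sequence as unknown (-1): excluded from scoring
for lab in labels.values():
    lab[rng.choice(len(lab), size=5, replace=False)] = -1

profiles = generate_predictions(labels, auc_target=0.8, seed=21)
report = metrics_report(profiles)
print(f"profiles: {report['n_profiles']}, scored residues: {report['n_residues']}")
print(f"confusion at 0.5: tp={report['tp']} fp={report['fp']}"
      f" fn={report['fn']} tn={report['tn']}")
for name in ("f1", "mcc", "roc_auc", "pr_auc", "max_f1", "max_f1_threshold"):
    print(f"{name:17s} {report[name]:.4f}")
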