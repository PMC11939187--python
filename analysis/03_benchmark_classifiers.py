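#!/usr/bin/env python
"""Benchmark the eight classifier families under 5-fold stratified CV.

Reports per-class and macro AUC (mean +/- SD over folds), the pooled
confusion matrix at the 0.5 operating point and accuracy / precision /
recall / F1; writes results/bench.json and an overlaid ROC figure.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from serumml.bench import MODEL_NAMES, crossval_evaluate
from serumml.peaks import FeatureMatrix

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

fm = FeatureMatrix.read_csv(args.outdir / "feature_matrix.csv")
out = {}
fig, ax = plt.subplots(figsize=(5, 5))
for name in MODEL_NAMES:
    ev = crossval_evaluate(fm, name, k=5, seed=args.seed)
    out[name] = {"macro_mean_auc": ev.macro_mean_auc,
                 "macro_sd_auc": ev.macro_sd_auc,
                 "mean_auc": ev.mean_auc, "sd_auc": ev.sd_auc,
                 "confusion": ev.confusion, "metrics": ev.metrics}
    print(f"{name:14s} macro AUC {ev.macro_mean_auc:.2f} +/- {ev.macro_sd_auc:.2f}"
          f"  acc {ev.metrics['accuracy']:.3f}  f1 {ev.metrics['f1']:.3f}")
    fpr, tpr = ev.roc_points["cancer"][0]
    ax.plot(fpr, tpr, lw=1, label=f"{name} ({ev.macro_mean_auc:.2f})")

ax.plot([0, 1], [0, 1], "k--", lw=0.7)
ax.set_xlabel("false positive rate")
ax.set_ylabel("true positive rate")
ax.legend(fontsize=7)
fig.tight_layout()
fig.savefig(args.outdir / "roc_models.png", dpi=150)
(args.outdir / "bench.json").write_text(json.dumps(out, indent=1))
print("wrote bench.json, roc_models.png")
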