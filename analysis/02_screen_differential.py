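#!/usr/bin/env python
"""Volcano screening of the aligned feature matrix.

Mann-Whitney test per feature, log2 fold change of group means, calls at
p < 0.001 and |log2FC| > 1; writes the differential table, the two top-20
shortlists (largest |log2FC|; smallest p) and a volcano plot.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from serumml.peaks import FeatureMatrix
from serumml.screening import differential_test, top_k, volcano_filter

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

fm = FeatureMatrix.read_csv(args.outdir / "feature_matrix.csv")
dt = differential_test(fm)
up, down = volcano_filter(dt)
print(f"{len(up)} upregulated and {len(down)} downregulated features "
      f"(p < 0.001, |log2FC| > 1) out of {fm.n_features}")

dt.table.to_csv(args.outdir / "differential_table.csv", index=False)
top_k(dt, "abs_log2fc", 20).to_csv(args.outdir / "top20_by_fc.csv", index=False)
top_k(dt, "p", 20).to_csv(args.outdir / "top20_by_p.csv", index=False)

fig, ax = plt.subplots(figsize=(5, 4))
t = dt.table
logp = -np.log10(np.clip(t["p"], 1e-300, None))
colors = np.where(t["call"] == "up", "crimson",
                  np.where(t["call"] == "down", "royalblue", "0.6"))
ax.scatter(t["log2fc"], logp, s=10, c=colors, alpha=0.8)
ax.axvline(1, ls="--", c="0.4", lw=0.8)
ax.axvline(-1, ls="--", c="0.4", lw=0.8)
ax.axhline(3, ls="--", c="0.4", lw=0.8)
ax.set_xlabel("log2 fold change (cancer / healthy)")
ax.set_ylabel("-log10 p")
fig.tight_layout()
fig.savefig(args.outdir / "volcano.png", dpi=150)
print(f"wrote differential_table.csv, top20_by_fc.csv, top20_by_p.csv, volcano.png")
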