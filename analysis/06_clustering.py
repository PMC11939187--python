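#!/usr/bin/env python
"""Unsupervised structure checks against the clinical labels.

Restricts the matrix to the differential features (as a biologically
annotated panel would), runs bisecting K-means and BIRCH, scores both by
Rand index and AMI versus the labels, and writes a UMAP embedding plot.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from serumml import cluster
from serumml.peaks import FeatureMatrix
from serumml.screening import differential_test, volcano_filter

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

fm = FeatureMatrix.read_csv(args.outdir / "feature_matrix.csv")
dt = differential_test(fm)
up, down = volcano_filter(dt)
keep = np.concatenate([up["mz"].to_numpy(), down["mz"].to_numpy()])
cols = sorted({int(np.argmin(np.abs(fm.feature_mzs - mz))) for mz in keep})
X = fm.values[:, cols]
print(f"clustering on {len(cols)} differential features, {len(X)} samples")

rows = []
for method, assign in (
        ("bisecting_kmeans", cluster.bisecting_kmeans(X, k=2, seed=args.seed)),
        ("birch", cluster.birch_cluster(X, k=2))):
    rand, ami = cluster.concordance(assign, fm.labels)
    rows.append({"method": method, "rand": round(rand, 4), "ami": round(ami, 4)})
    print(f"{method:17s} Rand={rand:.3f}  AMI={ami:.3f}")
pd.DataFrame(rows).to_csv(args.outdir / "clustering_concordance.csv",
                          index=False)

coords = cluster.embed(X, method="umap", dims=2, seed=args.seed)
fig, ax = plt.subplots(figsize=(5, 4))
for grp, color in (("cancer", "crimson"), ("healthy", "seagreen")):
    m = np.asarray(fm.labels) == grp
    ax.scatter(coords[m, 0], coords[m, 1], s=8, c=color, label=grp, alpha=0.7)
ax.set_xlabel("UMAP 1")
ax.set_ylabel("UMAP 2")
ax.legend()
fig.tight_layout()
fig.savefig(args.outdir / "umap.png", dpi=150)
print("wrote clustering_concordance.csv, umap.png")
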