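#!/usr/bin/env python
"""Attribution consensus: Gini importances, kernel-SHAP and LIME surrogates.

Fits a random forest, computes the three global rankings, forms the top-20
majority-vote consensus, and cross-validates impurity importances across
the four tree families (intersection of top-m lists). Writes per-method
ranking CSVs and results/consensus.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from serumml import interpret
from serumml.bench import make_model
from serumml.peaks import FeatureMatrix

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=17)
ap.add_argument("--explain-samples", type=int, default=8)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

fm = FeatureMatrix.read_csv(args.outdir / "feature_matrix.csv")
names = [f"{mz:.2f}" for mz in fm.feature_mzs]
y = (np.asarray(fm.labels) == "cancer").astype(int)

rf = make_model("random_forest", seed=args.seed)
rf.fit(fm.values, y)
model_fn = lambda X: rf.predict_proba(X)[:, 1]

gini = interpret.model_importances(rf, names)
bg = interpret.draw_background(fm.values, n=200, seed=args.seed)
rng = np.random.default_rng(args.seed)
idx = rng.choice(fm.n_samples, size=args.explain_samples, replace=False)
phi, base = interpret.shap_attributions(model_fn, bg, fm.values[idx],
                                        seed=args.seed)
shap_r = interpret.shap_ranking(phi, names)
lime_r = interpret.lime_rankings(model_fn, fm.values, names, explain_idx=idx,
                                 seed=args.seed)

for r in (gini, shap_r, lime_r):
    pd.DataFrame({"feature": r.feature_names, "score": r.scores,
                  "rank": r.ranks}).sort_values("rank").to_csv(
        args.outdir / f"importance_{r.method}.csv", index=False)
    print(f"{r.method:5s} top5: {', '.join(r.top(5))}")

cons = interpret.consensus_top_k([gini, shap_r, lime_r], k=20)
inter = interpret.cross_validated_importance_intersection(fm, top_m=10,
                                                          seed=args.seed)
print(f"consensus top-20 ({sum(v >= 2 for v in cons.votes.values())} majority "
      f"features); tree-family intersection: {sorted(inter)}")
(args.outdir / "consensus.json").write_text(json.dumps({
    "selected": cons.selected, "votes": cons.votes,
    "shap_base_value": base,
    "tree_importance_intersection": sorted(inter)}, indent=1))
print("wrote importance_{gini,shap,lime}.csv, consensus.json")
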