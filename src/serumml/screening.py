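"""Differential peptide screening (volcano logic) and top-k shortlists.

Each aligned feature is tested cancer-vs-healthy with a two-sided
Mann-Whitney U test (exact null enumeration for tiny groups, tie-corrected
normal approximation otherwise) and summarised by log2 fold change of group
means with a small pseudocount guarding zero means. Volcano calls combine
p < 0.001 with |log2FC| > 1 by default; raw p-values are reported (BH-FDR is
available as an option but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .peaks import FeatureMatrix

__all__ = ["DifferentialTable", "differential_test", "volcano_filter", "top_k"]

EXACT_MAX_N = 8  # exact U-null enumeration when the smaller group is this size or less


@dataclass
class DifferentialTable:
    """Per-feature mz, log2FC (cancer over healthy), p-value and call."""

    table: pd.DataFrame  # columns: mz, log2fc, p, call

    def __len__(self) -> int:
        return len(self.table)


def differential_test(fm: FeatureMatrix, positive: str = "cancer",
                      negative: str = "healthy", fdr: bool = False,
                      p_thresh: float = 0.001, fc_thresh: float = 1.0) -> DifferentialTable:
    """Mann-Whitney screen of every feature with volcano calls attached.

    log2FC uses a pseudocount of 1e-9 of the grand mean so zero-imputed
    features stay finite. ``fdr=True`` replaces raw p with Benjamini-Hochberg
    adjusted values before calling.
    """
    y = np.asarray(fm.labels)
    pos, neg = fm.values[y == positive], fm.values[y == negative]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"both classes need >= 2 samples (got {len(pos)} {positive}, "
            f"{len(neg)} {negative})")
    grand = float(fm.values.mean())
    eps = 1e-9 * (grand if grand > 0 else 1.0)
    log2fc = np.log2((pos.mean(axis=0) + eps) / (neg.mean(axis=0) + eps))
    method = "exact" if min(len(pos), len(neg)) <= EXACT_MAX_N else "asymptotic"
    pvals = np.empty(fm.n_features)
    for j in range(fm.n_features):
        a, b = pos[:, j], neg[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0  # fully tied feature carries no evidence
            continue
        m = "asymptotic" if (method == "exact" and
                             len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)) \
            else method
        pvals[j] = mannwhitneyu(a, b, alternative="two-sided", method=m).pvalue
    if fdr:
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pvals)
        out[order] = np.clip(adj, 0, 1)
        pvals = out
    call = np.where((pvals < p_thresh) & (log2fc > fc_thresh), "up",
                    np.where((pvals < p_thresh) & (log2fc < -fc_thresh), "down", "ns"))
    return DifferentialTable(pd.DataFrame({
        "mz": fm.feature_mzs, "log2fc": log2fc, "p": pvals, "call": call}))


def volcano_filter(dt: DifferentialTable, p_thresh: float = 0.001,
                   fc_thresh: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (up, down) feature tables at the volcano thresholds."""
    t = dt.table
    up = t[(t["p"] < p_thresh) & (t["log2fc"] > fc_thresh)].reset_index(drop=True)
    down = t[(t["p"] < p_thresh) & (t["log2fc"] < -fc_thresh)].reset_index(drop=True)
    return up, down


def top_k(dt: DifferentialTable, by: str = "abs_log2fc", k: int = 20) -> pd.DataFrame:
    """Top-k shortlist by |log2FC| (descending) or p (ascending).

    Ties break deterministically by ascending m/z. If fewer than k features
    exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    t = dt.table.copy()
    if by == "abs_log2fc":
        t["_key"] = -t["log2fc"].abs()
    elif by == "p":
        t["_key"] = t["p"]
    else:
        raise ValueError(f"unknown ranking criterion {by!r}; use 'abs_log2fc' or 'p'")
    if k > len(t):
        import warnings
        warnings.warn(f"requested top {k} of only {len(t)} features; returning all")
        k = len(t)
    t = t.sort_values(["_key", "mz"], kind="mergesort").head(k)
    return t.drop(columns="_key").reset_index(drop=True)
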