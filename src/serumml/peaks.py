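"""Peak detection, greedy ppm-tolerance cross-sample alignment and the
relative-area feature matrix.

Detection follows the classic adaptive rule: local maxima at least 3% of the
spectrum's maximum intensity and at least 5 grid points wide at half
prominence; areas are trapezoid integrals between peak bases. Alignment is an
iterative greedy consensus build: the strongest unassigned signal seeds a
feature, every sample contributes at most its nearest unassigned peak within
a ppm tolerance (default 2500 ppm, generous enough to absorb +/-1500 ppm
instrumental drift), and the consensus centroid is the intensity-weighted
member mean. Matrix cells are relative areas: a sample's raw peak areas
divided by its total detected area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .preprocess import Spectrum

__all__ = ["Peak", "PeakList", "FeatureMatrix", "detect_peaks",
           "flag_matrix_region", "greedy_align", "impute_missing",
           "collapse_replicates"]


@dataclass(frozen=True)
class Peak:
    mz: float          # centroid, Da
    height: float
    area: float        # trapezoid integral between bases, intensity*Da
    width: float       # grid points at half prominence
    flagged: bool = False  # inside the matrix-cluster artifact region

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")
        if self.width < 1:
            raise ValueError("peak width must be >= 1 grid point")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass(frozen=True)
class PeakList:
    sample_id: str
    replicate: int
    group: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must have strictly increasing centroids")


@dataclass
class FeatureMatrix:
    """Rows x aligned m/z features of relative peak areas.

    ``missing`` marks cells with no detected peak (True = missing); after
    imputation the mask is retained as provenance but all values are filled.
    """

    feature_mzs: np.ndarray            # strictly increasing consensus centroids
    values: np.ndarray                 # (n_rows, n_features), relative areas
    sample_ids: list[str]
    labels: np.ndarray                 # group per row
    replicates: np.ndarray | None = None   # replicate index per row, None if collapsed
    missing: np.ndarray = None         # bool mask, same shape as values
    imputed: bool = False

    def __post_init__(self) -> None:
        self.feature_mzs = np.asarray(self.feature_mzs, float)
        self.values = np.asarray(self.values, float)
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, bool)
        if np.any(np.diff(self.feature_mzs) <= 0):
            raise ValueError("feature_mzs must be strictly increasing")
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask shapes differ")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if np.any(self.values[~self.missing] < 0):
            raise ValueError("relative areas must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values,
                          columns=[f"{mz:.2f}" for mz in self.feature_mzs])
        df.insert(0, "sample_id", self.sample_ids)
        if self.replicates is not None:
            df.insert(1, "replicate", self.replicates)
        df["group"] = self.labels
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = [c for c in ("sample_id", "replicate", "group") if c in df.columns]
        feat_cols = [c for c in df.columns if c not in meta]
        return cls(
            feature_mzs=np.array([float(c) for c in feat_cols]),
            values=df[feat_cols].to_numpy(float),
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["group"].to_numpy(str),
            replicates=df["replicate"].to_numpy(int) if "replicate" in df else None,
            imputed=True,
        )


def detect_peaks(s: Spectrum, min_height_frac: float = 0.03,
                 min_width_points: int = 5) -> PeakList:
    """Detect local maxima above an adaptive height/width gate.

    Height gate: ``min_height_frac`` of the spectrum's maximum intensity.
    Width gate: ``min_width_points`` grid points at half prominence. The
    centroid is the intensity-weighted m/z over the peak's base interval and
    the area its trapezoid integral. An all-zero spectrum yields an empty list.
    """
    y = s.intensity
    ymax = float(y.max(initial=0.0))
    if ymax <= 0:
        return PeakList(s.sample_id, s.replicate, s.group, ())
    idx, props = find_peaks(y, height=min_height_frac * ymax,
                            width=min_width_points)
    if len(idx) == 0:
        return PeakList(s.sample_id, s.replicate, s.group, ())
    _, _, left_b, right_b = peak_widths(y, idx, rel_height=1.0)
    peaks = []
    for k, i in enumerate(idx):
        lo = int(np.floor(left_b[k]))
        hi = int(np.ceil(right_b[k])) + 1
        seg_y, seg_mz = y[lo:hi], s.mz[lo:hi]
        area = float(np.trapezoid(seg_y, seg_mz))
        # centroid over the half-prominence core only: the full base interval
        # is skewed by neighbouring peak tails and baseline residue
        clo = int(np.floor(props["left_ips"][k]))
        chi = int(np.ceil(props["right_ips"][k])) + 1
        cy, cmz = y[clo:chi], s.mz[clo:chi]
        wsum = cy.sum()
        centroid = float((cy * cmz).sum() / wsum) if wsum > 0 else float(s.mz[i])
        peaks.append(Peak(mz=centroid, height=float(y[i]), area=max(area, 0.0),
                          width=float(props["widths"][k])))
    peaks.sort(key=lambda p: p.mz)
    # merge pathological duplicates sharing a centroid (keep the taller)
    dedup: list[Peak] = []
    for p in peaks:
        if dedup and p.mz <= dedup[-1].mz:
            if p.height > dedup[-1].height:
                dedup[-1] = p
        else:
            dedup.append(p)
    return PeakList(s.sample_id, s.replicate, s.group, tuple(dedup))


def flag_matrix_region(pl: PeakList, lo: float = 1500.0, hi: float = 2000.0,
                       exclude: bool = False) -> PeakList:
    """Flag (default) or drop peaks inside the matrix-cluster artifact region."""
    if lo >= hi:
        raise ValueError(f"invalid matrix region [{lo}, {hi}]: lo must be < hi")
    out = []
    for p in pl.peaks:
        in_region = lo <= p.mz <= hi
        if in_region and exclude:
            continue
        out.append(replace(p, flagged=p.flagged or in_region))
    return replace(pl, peaks=tuple(out))


def _aggregate_intensity(mzs: np.ndarray, heights: np.ndarray,
                         tol_ppm: float) -> np.ndarray:
    """For each peak, summed height of all peaks within the ppm window.

    Arrays must be sorted by m/z."""
    tol = tol_ppm * 1e-6
    lo = np.searchsorted(mzs, mzs * (1 - tol), side="left")
    hi = np.searchsorted(mzs, mzs * (1 + tol), side="right")
    csum = np.concatenate(([0.0], np.cumsum(heights)))
    return csum[hi] - csum[lo]


def greedy_align(peaklists: list[PeakList], tol_ppm: float = 2500.0) -> FeatureMatrix:
    """Iterative greedy cross-sample alignment into consensus features.

    Repeatedly seeds a new feature at the unassigned peak with the greatest
    aggregate (ppm-window-summed) intensity, gathers each row's nearest
    unassigned peak within ``tol_ppm`` of the consensus centroid, and updates
    the centroid once as the height-weighted member mean. Every peak ends up
    in exactly one feature; a feature holds at most one peak per row. Matrix
    cells are relative areas (row areas divided by the row's total detected
    area); undetected cells are flagged missing.
    """
    if not peaklists:
        raise ValueError("greedy_align requires at least one PeakList")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")

    rows = [(pl.sample_id, pl.replicate, pl.group) for pl in peaklists]
    all_mz, all_h, all_area, all_row = [], [], [], []
    for r, pl in enumerate(peaklists):
        for p in pl.peaks:
            all_mz.append(p.mz)
            all_h.append(p.height)
            all_area.append(p.area)
            all_row.append(r)
    if not all_mz:
        raise ValueError("no peaks to align")
    order = np.lexsort((all_row, all_mz))
    mz = np.asarray(all_mz)[order]
    h = np.asarray(all_h)[order]
    area = np.asarray(all_area)[order]
    rowid = np.asarray(all_row)[order]
    n = len(mz)
    assigned = np.full(n, -1, dtype=int)
    tol = tol_ppm * 1e-6

    def nearest_per_row(cand: np.ndarray, center: float) -> np.ndarray:
        """From unassigned candidate indices, keep the nearest peak per row."""
        if len(cand) == 0:
            return cand
        dev = np.abs(mz[cand] - center)
        best: dict[int, int] = {}
        for ci, d in zip(cand, dev):
            r = rowid[ci]
            if r not in best or d < abs(mz[best[r]] - center):
                best[r] = ci
        return np.array(sorted(best.values()))

    centroids: list[float] = []
    feat_members: list[np.ndarray] = []
    while True:
        un = np.flatnonzero(assigned < 0)
        if len(un) == 0:
            break
        agg = _aggregate_intensity(mz[un], h[un], tol_ppm)
        seed = un[int(np.argmax(agg))]
        center = mz[seed]
        for _ in range(2):  # gather, re-center once, re-gather
            cand = un[(mz[un] >= center * (1 - tol)) & (mz[un] <= center * (1 + tol))]
            members = nearest_per_row(cand, center)
            if len(members) == 0:
                members = np.array([seed])
            center = float(np.average(mz[members], weights=h[members]))
        assigned[members] = len(centroids)
        centroids.append(center)
        feat_members.append(members)

    feat_order = np.argsort(centroids)
    feature_mzs = np.asarray(centroids)[feat_order]
    values = np.zeros((len(rows), len(centroids)))
    missing = np.ones_like(values, bool)
    for new_f, old_f in enumerate(feat_order):
        for i in feat_members[old_f]:
            values[rowid[i], new_f] = area[i]
            missing[rowid[i], new_f] = False
    totals = np.where(missing, 0.0, values).sum(axis=1)
    totals[totals == 0] = 1.0
    values = values / totals[:, None]

    return FeatureMatrix(
        feature_mzs=feature_mzs,
        values=values,
        sample_ids=[r[0] for r in rows],
        labels=np.array([r[2] for r in rows]),
        replicates=np.array([r[1] for r in rows]),
        missing=missing,
    )


def impute_missing(fm: FeatureMatrix, mode: str = "zero") -> FeatureMatrix:
    """Fill undetected cells: ``zero`` or per-row linear ``interpolate``
    between the nearest detected features in m/z (edges fall back to 0)."""
    if mode not in ("zero", "interpolate"):
        raise ValueError(f"unknown imputation mode {mode!r}; use 'zero' or 'interpolate'")
    values = fm.values.copy()
    if mode == "zero":
        values[fm.missing] = 0.0
    else:
        for i in range(fm.n_samples):
            miss = fm.missing[i]
            if not miss.any():
                continue
            det = ~miss
            if not det.any():
                values[i] = 0.0
                continue
            values[i, miss] = np.interp(
                fm.feature_mzs[miss], fm.feature_mzs[det], values[i, det],
                left=0.0, right=0.0)
    return FeatureMatrix(feature_mzs=fm.feature_mzs, values=values,
                         sample_ids=fm.sample_ids, labels=fm.labels,
                         replicates=fm.replicates, missing=fm.missing.copy(),
                         imputed=True)


def collapse_replicates(fm: FeatureMatrix) -> FeatureMatrix:
    """Average replicate rows into one row per sample (order of first appearance)."""
    if fm.replicates is None:
        return fm
    seen: dict[str, int] = {}
    for sid in fm.sample_ids:
        seen.setdefault(sid, len(seen))
    n_s = len(seen)
    values = np.zeros((n_s, fm.n_features))
    counts = np.zeros(n_s)
    miss_all = np.ones((n_s, fm.n_features), bool)
    labels = np.empty(n_s, dtype=object)
    for i, sid in enumerate(fm.sample_ids):
        j = seen[sid]
        values[j] += fm.values[i]
        counts[j] += 1
        miss_all[j] &= fm.missing[i]
        labels[j] = fm.labels[i]
    values /= counts[:, None]
    return FeatureMatrix(feature_mzs=fm.feature_mzs, values=values,
                         sample_ids=list(seen), labels=labels.astype(str),
                         replicates=None, missing=miss_all, imputed=fm.imputed)
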