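"""Synthetic MALDI-TOF serum cohort generator with known ground truth.

Emulates the data-generating process of a case-control serum peptidome study:
two groups of samples (cancer vs healthy), triplicate spectra per sample on a
shared m/z grid over 1000-15,000 Da, Gaussian peptide peaks, smooth baseline
drift, additive trace noise, per-replicate instrumental mass drift (up to
+/-1500 ppm) and occasional matrix-cluster artifact peaks in 1500-2000 Da.
A configurable subset of peaks is planted as differential (up/down in cancer)
with controlled log2 fold change, and the generator returns a truth channel
so downstream recovery can be scored.

Design notes
------------
* Peak shape is Gaussian in m/z with a common sigma, so height and area fold
  changes coincide and the truth areas are analytic.
* Per-sample peak intensities are log-normal multiplicative draws with unit
  mean around the group mean (``intensity_cv``), so the expected group-mean
  ratio of a planted peak is exactly ``2**log2fc``. Replicates re-jitter the
  sample's intensities with a small extra log-normal factor.
* Up- and down-regulated base amplitudes are balanced so the expected total
  ion signal is identical in the two groups; row-normalised relative areas of
  null peaks then stay null instead of absorbing a global shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Spectrum

__all__ = ["SynthConfig", "GroundTruth", "generate_cohort", "paper_default_config",
           "write_cohort", "read_cohort"]

MATRIX_REGION = (1500.0, 2000.0)
DIFFERENTIAL_WINDOW = (1500.0, 6000.0)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort generator configuration. All masses in Da, intensities arbitrary units."""

    n_cancer: int = 60
    n_healthy: int = 60
    replicates_per_sample: int = 3
    mz_min: float = 1000.0
    mz_max: float = 15000.0
    grid_step: float = 1.0
    n_peaks: int = 120
    peak_width_sigma: float = 2.5
    n_up: int = 0
    n_down: int = 0
    log2fc_up: float = 2.5
    log2fc_down: float = -2.5
    intensity_cv: float = 0.15
    replicate_cv: float = 0.05
    baseline_amplitude: float = 5.0
    noise_sd: float = 0.3
    mass_jitter_ppm: float = 1500.0
    matrix_artifact_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_healthy", "replicates_per_sample", "n_peaks",
                     "n_up", "n_down"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.n_up + self.n_down > self.n_peaks:
            raise ValueError(
                f"n_up + n_down ({self.n_up + self.n_down}) exceeds n_peaks ({self.n_peaks})"
            )
        if not self.mz_min < self.mz_max:
            raise ValueError(f"mz_min ({self.mz_min}) must be < mz_max ({self.mz_max})")
        for name in ("grid_step", "peak_width_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("intensity_cv", "replicate_cv", "baseline_amplitude", "noise_sd",
                     "mass_jitter_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.matrix_artifact_rate <= 1:
            raise ValueError("matrix_artifact_rate must be a probability in [0, 1]")


@dataclass
class GroundTruth:
    """Truth channel: planted centroids, differential index sets, group means."""

    peak_mzs: np.ndarray                  # true centroid m/z per planted peak
    up_set: set[int] = field(default_factory=set)
    down_set: set[int] = field(default_factory=set)
    mean_height_cancer: np.ndarray = None
    mean_height_healthy: np.ndarray = None
    peak_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.up_set & self.down_set:
            raise ValueError("up_set and down_set must be disjoint")

    def log2fc(self) -> np.ndarray:
        """Planted log2 (cancer/healthy) mean ratio per peak."""
        return np.log2(self.mean_height_cancer / self.mean_height_healthy)


def _unit_mean_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Log-normal multiplicative factors with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _place_peaks(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-spaced centroids with mild jitter; gaps stay >> alignment tolerance."""
    lo, hi = cfg.mz_min * 1.02, cfg.mz_max * 0.98
    base = np.geomspace(lo, hi, cfg.n_peaks)
    if cfg.n_peaks > 1:
        log_gap = (np.log(hi) - np.log(lo)) / (cfg.n_peaks - 1)
        # cap the jitter at 1% in log-m/z so sparse layouts stay on the grid
        amp = min(0.15 * log_gap, 0.01)
        jitter = rng.uniform(-amp, amp, cfg.n_peaks)
        base = np.exp(np.log(base) + jitter)
    return np.sort(base)


def _pick_differential(cfg: SynthConfig, mzs: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Choose up/down peak indices, preferring the 1500-6000 Da window."""
    n_diff = cfg.n_up + cfg.n_down
    lo, hi = DIFFERENTIAL_WINDOW
    candidates = np.flatnonzero((mzs >= lo) & (mzs <= hi))
    if len(candidates) < n_diff:
        candidates = np.arange(len(mzs))
    chosen = rng.choice(candidates, size=n_diff, replace=False)
    return np.sort(chosen[: cfg.n_up]), np.sort(chosen[cfg.n_up:])


def _group_mean_heights(cfg: SynthConfig, up_idx: np.ndarray, down_idx: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Healthy/cancer expected peak heights, balanced for equal total signal."""
    n = cfg.n_peaks
    healthy = np.exp(rng.uniform(np.log(20.0), np.log(100.0), n))
    healthy[up_idx] = np.exp(rng.uniform(np.log(8.0), np.log(16.0), len(up_idx)))
    healthy[down_idx] = np.exp(rng.uniform(np.log(8.0), np.log(16.0), len(down_idx)))
    r_up, r_down = 2.0 ** cfg.log2fc_up, 2.0 ** cfg.log2fc_down
    if len(up_idx) and len(down_idx) and r_up > 1 and r_down < 1:
        # scale the down-regulated bases so expected signal lost in cancer
        # equals expected signal gained; keeps total ion current group-neutral
        gain = healthy[up_idx].sum() * (r_up - 1.0)
        loss_per_unit = (1.0 - r_down)
        healthy[down_idx] *= gain / (healthy[down_idx].sum() * loss_per_unit)
    cancer = healthy.copy()
    cancer[up_idx] = healthy[up_idx] * r_up
    cancer[down_idx] = healthy[down_idx] * r_down
    return healthy, cancer


def _render_trace(grid: np.ndarray, centroids: np.ndarray, heights: np.ndarray,
                  sigma: float) -> np.ndarray:
    y = np.zeros_like(grid)
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    half = int(np.ceil(6.0 * sigma / step))
    for mz_c, h in zip(centroids, heights):
        c = int(round((mz_c - grid[0]) / step))
        lo, hi = max(c - half, 0), min(c + half + 1, len(grid))
        if lo >= hi:
            continue
        y[lo:hi] += h * np.exp(-0.5 * ((grid[lo:hi] - mz_c) / sigma) ** 2)
    return y


def _baseline(grid: np.ndarray, amplitude: float, scale: float) -> np.ndarray:
    span = grid[-1] - grid[0]
    mid = 0.5 * (grid[0] + grid[-1])
    decay = np.exp(-(grid - grid[0]) / 2000.0)
    hump = 0.2 * (1.0 - ((grid - mid) / (0.5 * span)) ** 2)
    return amplitude * scale * (decay + np.clip(hump, 0.0, None))


def generate_cohort(cfg: SynthConfig) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth]:
    """Generate a full cohort of replicate spectra plus labels and ground truth.

    Returns
    -------
    spectra : list of Spectrum (``n_samples * replicates_per_sample`` entries,
        shared m/z grid)
    labels : DataFrame with one row per sample (``sample_id``, ``group``)
    truth : GroundTruth with planted centroids, differential sets and group means
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.arange(cfg.mz_min, cfg.mz_max + cfg.grid_step / 2, cfg.grid_step)

    centroids = _place_peaks(cfg, rng)
    up_idx, down_idx = _pick_differential(cfg, centroids, rng)
    mean_h, mean_c = _group_mean_heights(cfg, up_idx, down_idx, rng)
    truth = GroundTruth(
        peak_mzs=centroids,
        up_set=set(int(i) for i in up_idx),
        down_set=set(int(i) for i in down_idx),
        mean_height_cancer=mean_c,
        mean_height_healthy=mean_h,
        peak_sigma=cfg.peak_width_sigma,
    )

    groups = ["cancer"] * cfg.n_cancer + ["healthy"] * cfg.n_healthy
    sample_ids = [f"CC{i:03d}" for i in range(cfg.n_cancer)] + \
                 [f"HD{i:03d}" for i in range(cfg.n_healthy)]
    labels = pd.DataFrame({"sample_id": sample_ids, "group": groups})

    spectra: list[Spectrum] = []
    for sid, grp in zip(sample_ids, groups):
        mean = mean_c if grp == "cancer" else mean_h
        sample_heights = mean * _unit_mean_lognormal(rng, cfg.intensity_cv, cfg.n_peaks)
        for rep in range(cfg.replicates_per_sample):
            rep_heights = sample_heights * _unit_mean_lognormal(
                rng, cfg.replicate_cv, cfg.n_peaks)
            drift_ppm = rng.uniform(-cfg.mass_jitter_ppm, cfg.mass_jitter_ppm)
            peak_jitter = rng.normal(0.0, cfg.mass_jitter_ppm / 15.0, cfg.n_peaks)
            obs_mz = centroids * (1.0 + (drift_ppm + peak_jitter) * 1e-6)
            y = _render_trace(grid, obs_mz, rep_heights, cfg.peak_width_sigma)
            if rng.random() < cfg.matrix_artifact_rate:
                art_mz = rng.uniform(*MATRIX_REGION)
                art_h = rng.uniform(5.0, 30.0)
                y += _render_trace(grid, np.array([art_mz]), np.array([art_h]),
                                   cfg.peak_width_sigma)
            if cfg.baseline_amplitude > 0:
                y += _baseline(grid, cfg.baseline_amplitude, rng.uniform(0.8, 1.2))
            if cfg.noise_sd > 0:
                y += rng.normal(0.0, cfg.noise_sd, len(grid))
            spectra.append(Spectrum(sample_id=sid, replicate=rep, group=grp,
                                    mz=grid, intensity=y))
    return spectra, labels, truth


def paper_default_config(seed: int = 20230269) -> SynthConfig:
    """Frozen default cohort: 240 cancer vs 249 healthy, triplicates,
    19 up- and 23 down-regulated peaks at |log2FC| = 2.5.

    Mirrors the study conditions this generator emulates; the seed may be
    overridden but all structural fields are fixed.
    """
    return SynthConfig(
        n_cancer=240,
        n_healthy=249,
        replicates_per_sample=3,
        mz_min=1000.0,
        mz_max=15000.0,
        grid_step=1.0,
        n_peaks=120,
        peak_width_sigma=2.5,
        n_up=19,
        n_down=23,
        log2fc_up=2.5,
        log2fc_down=-2.5,
        intensity_cv=0.15,
        replicate_cv=0.05,
        baseline_amplitude=5.0,
        noise_sd=0.3,
        mass_jitter_ppm=1500.0,
        matrix_artifact_rate=0.05,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohort serialisation: one CSV per replicate + labels CSV + truth JSON


def write_cohort(spectra: list[Spectrum], labels: pd.DataFrame, truth: GroundTruth,
                 outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"{s.sample_id}_r{s.replicate}.csv"
        pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(
            outdir / fname, index=False)
        rows.append({"sample_id": s.sample_id, "group": s.group,
                     "replicate": s.replicate, "file": fname})
    pd.DataFrame(rows).to_csv(outdir / "labels.csv", index=False)
    truth_doc = {
        "peak_mzs": truth.peak_mzs.tolist(),
        "up_set": sorted(truth.up_set),
        "down_set": sorted(truth.down_set),
        "mean_height_cancer": truth.mean_height_cancer.tolist(),
        "mean_height_healthy": truth.mean_height_healthy.tolist(),
        "peak_sigma": truth.peak_sigma,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))


def read_cohort(indir: str | Path) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth | None]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "labels.csv")
    spectra = []
    for row in manifest.itertuples():
        df = pd.read_csv(indir / row.file)
        spectra.append(Spectrum(sample_id=row.sample_id, replicate=int(row.replicate),
                                group=row.group, mz=df["mz"].to_numpy(float),
                                intensity=df["intensity"].to_numpy(float)))
    labels = manifest[["sample_id", "group"]].drop_duplicates().reset_index(drop=True)
    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        doc = json.loads(truth_path.read_text())
        truth = GroundTruth(
            peak_mzs=np.asarray(doc["peak_mzs"], float),
            up_set=set(doc["up_set"]),
            down_set=set(doc["down_set"]),
            mean_height_cancer=np.asarray(doc["mean_height_cancer"], float),
            mean_height_healthy=np.asarray(doc["mean_height_healthy"], float),
            peak_sigma=float(doc["peak_sigma"]),
        )
    return spectra, labels, truth
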