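"""Raw MALDI-TOF spectrum cleaning.

A linear-mode serum spectrum is an intensity trace on a monotone m/z grid.
Cleaning is a fixed three-stage composition:

1. Savitzky-Golay least-squares polynomial smoothing (window 21, order 10),
   which suppresses high-frequency detector noise while preserving narrow
   peptide peak morphology;
2. a centered moving-median despiker (window 10) that removes sporadic
   single-point spikes;
3. white top-hat baseline removal (flat structuring element, 11 points):
   the trace minus its morphological opening, which strips slowly varying
   chemical/matrix baseline while keeping peaks narrower than the element.

The m/z grid is never modified; only intensities change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import grey_opening
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "PreprocessParams",
    "savgol_smooth",
    "median_despike",
    "tophat_baseline",
    "preprocess_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_mzml",
]


@dataclass(frozen=True)
class Spectrum:
    """One sample/replicate intensity trace on a strictly increasing m/z grid."""

    sample_id: str
    replicate: int
    group: str  # "cancer", "healthy" or "unknown"
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or len(mz) != len(inten):
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the three-stage cleaning pipeline."""

    savgol_window: int = 21
    savgol_polyorder: int = 10
    median_window: int = 10
    tophat_element: int = 11


def savgol_smooth(s: Spectrum, window: int = 21, polyorder: int = 10) -> Spectrum:
    """Savitzky-Golay smoothing: local least-squares polynomial fit per window.

    Edge points use the polynomial-extension (``mode="interp"``) convention so
    the trace length is unchanged.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError(f"savgol window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(
            f"savgol polyorder ({polyorder}) must be smaller than window ({window})"
        )
    if len(s.intensity) < window:
        raise ValueError("spectrum shorter than the Savitzky-Golay window")
    return s.with_intensity(
        savgol_filter(s.intensity, window_length=window, polyorder=polyorder, mode="interp")
    )


def _moving_median(y: np.ndarray, window: int) -> np.ndarray:
    # Centered window; for even sizes the extra point sits on the left and the
    # lower of the two middle order statistics is taken (left-biased tie rule).
    n = len(y)
    left = window // 2
    right = window - 1 - left
    padded = np.pad(y, (left, right), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    assert windows.shape[0] == n
    k = (window - 1) // 2  # lower median index; exact median for odd windows
    return np.sort(windows, axis=1)[:, k]


def median_despike(s: Spectrum, window: int = 10) -> Spectrum:
    """Moving-median filter removing isolated intensity spikes.

    The window is centered; even window sizes extend one extra point to the
    left and resolve the median tie toward the lower order statistic.
    """
    if window < 1:
        raise ValueError(f"median window must be >= 1, got {window}")
    if window > len(s.intensity):
        raise ValueError(
            f"median window ({window}) exceeds trace length ({len(s.intensity)})"
        )
    if window == 1:
        return s
    return s.with_intensity(_moving_median(s.intensity, window))


def tophat_baseline(s: Spectrum, element_size: int = 11) -> Spectrum:
    """White top-hat baseline correction: trace minus its morphological opening.

    Removes any structure wider than the flat structuring element (the drifting
    baseline) while retaining narrow peaks. Small negative residuals are
    clipped to zero so downstream peak areas stay non-negative.
    """
    if element_size < 1:
        raise ValueError(f"structuring element size must be >= 1, got {element_size}")
    opened = grey_opening(s.intensity, size=element_size, mode="reflect")
    return s.with_intensity(np.clip(s.intensity - opened, 0.0, None))


def preprocess_spectrum(s: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Full cleaning pipeline: Savitzky-Golay -> moving median -> white top-hat."""
    p = params or PreprocessParams()
    s = savgol_smooth(s, window=p.savgol_window, polyorder=p.savgol_polyorder)
    s = median_despike(s, window=p.median_window)
    s = tophat_baseline(s, element_size=p.tophat_element)
    return s


# ---------------------------------------------------------------------------
# I/O


def read_spectrum_csv(
    path: str | Path,
    sample_id: str | None = None,
    replicate: int = 0,
    group: str = "unknown",
) -> Spectrum:
    """Read a two-column (mz, intensity) CSV into a Spectrum."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "mz" not in cols or "intensity" not in cols:
        raise ValueError(f"{path}: expected columns 'mz' and 'intensity'")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(
        sample_id=sid,
        replicate=replicate,
        group=group,
        mz=df[cols["mz"]].to_numpy(float),
        intensity=df[cols["intensity"]].to_numpy(float),
    )


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(path, index=False)


def read_mzml(path: str | Path, group: str = "unknown") -> list[Spectrum]:
    """Read all spectra of an mzML file (requires the optional pyteomics extra)."""
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("mzML ingestion requires pyteomics (install serumml[mzml])") from exc
    out: list[Spectrum] = []
    with _mzml.MzML(str(path)) as reader:
        for i, scan in enumerate(reader):
            out.append(
                Spectrum(
                    sample_id=str(scan.get("id", f"scan{i}")),
                    replicate=i,
                    group=group,
                    mz=np.asarray(scan["m/z array"], float),
                    intensity=np.asarray(scan["intensity array"], float),
                )
            )
    return out
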