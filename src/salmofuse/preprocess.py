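"""Spectral and elemental preprocessing.

The REIMS chain turns raw peak lists into a model-ready binned block:
background subtraction, single-point lockmass recalibration against leucine
enkephalin ([M-H]- 554.2615), a relative total-ion-count noise threshold,
0.2 Da binning over m/z 100-1200 (5500 bins), and row-wise TIC
normalization. The ICP-MS chain covers internal-standard ratioing, CRM
recovery checks, element filtering against a below-LOD fraction, and the
min-max scaling used for heatmaps and low-level fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LOCKMASS_REFERENCE = 554.2615  # leucine enkephalin [M-H]-

__all__ = [
    "PeakList",
    "SpectraBlock",
    "ElementBlock",
    "MinMaxParams",
    "lockmass_correct",
    "background_subtract",
    "tic_threshold_filter",
    "bin_spectrum",
    "bin_labels",
    "tic_normalize",
    "minmax_scale",
    "apply_minmax",
    "internal_standard_normalize",
    "crm_check",
    "filter_elements",
    "reims_chain",
]


class CalibrationError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class DataQualityError(ValueError):
    pass


@dataclass
class PeakList:
    """A centroided spectrum: parallel m/z and intensity arrays plus the
    acquisition range [lo, hi)."""

    mz: np.ndarray
    intensity: np.ndarray
    lo: float = 100.0
    hi: float = 1200.0

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class SpectraBlock:
    """Samples x m/z-bin intensity matrix.

    ``data`` is a DataFrame indexed by sample ID whose columns are bin-center
    labels formatted to one decimal ("100.1" ... "1199.9"); ``edges`` holds
    the n_bins+1 uniform bin edges.
    """

    data: pd.DataFrame
    edges: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.data.shape[1] != self.edges.size - 1:
            raise ValueError("bin count does not match edges")

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]


@dataclass
class ElementBlock:
    """Samples x element concentration matrix with a below-LOD mask."""

    data: pd.DataFrame
    below_lod: pd.DataFrame | None = None

    def __post_init__(self):
        if self.below_lod is None:
            self.below_lod = pd.DataFrame(
                False, index=self.data.index, columns=self.data.columns
            )
        if self.below_lod.shape != self.data.shape:
            raise ValueError("below-LOD mask shape mismatch")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative concentrations")

    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# REIMS chain


def lockmass_correct(
    peaks: PeakList, observed_lock: float, reference: float = LOCKMASS_REFERENCE
) -> PeakList:
    """Single-point multiplicative m/z recalibration.

    Every m/z is multiplied by ``reference / observed_lock``; intensities are
    untouched. This is the standard TOF drift model and is the exact inverse
    of a uniform multiplicative drift.
    """
    if observed_lock is None or not np.isfinite(observed_lock) or observed_lock <= 0:
        raise CalibrationError(f"invalid observed lockmass {observed_lock!r}")
    factor = reference / observed_lock
    return replace(peaks, mz=peaks.mz * factor, intensity=peaks.intensity.copy())


def background_subtract(
    peaks: PeakList, background: PeakList, tolerance: float = 0.01
) -> PeakList:
    """Subtract a background spectrum peak-by-peak, clipping at zero.

    Each sample peak is matched to the nearest background peak within
    ``tolerance`` Da; unmatched background peaks are ignored.
    """
    if (peaks.lo, peaks.hi) != (background.lo, background.hi):
        raise ValueError("acquisition ranges differ between sample and background")
    out = peaks.intensity.copy()
    if len(background):
        order = np.argsort(background.mz, kind="stable")
        bmz = background.mz[order]
        bint = background.intensity[order]
        idx = np.searchsorted(bmz, peaks.mz)
        for j, m in enumerate(peaks.mz):
            best = None
            for cand in (idx[j] - 1, idx[j]):
                if 0 <= cand < bmz.size and abs(bmz[cand] - m) <= tolerance:
                    if best is None or abs(bmz[cand] - m) < abs(bmz[best] - m):
                        best = cand
            if best is not None:
                out[j] = max(0.0, out[j] - bint[best])
    return replace(peaks, mz=peaks.mz.copy(), intensity=out)


def tic_threshold_filter(peaks: PeakList, fraction: float = 1e-5) -> PeakList:
    """Drop peaks whose intensity is below ``fraction`` of the input TIC."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    tic = float(peaks.intensity.sum())
    keep = peaks.intensity >= fraction * tic
    return replace(peaks, mz=peaks.mz[keep], intensity=peaks.intensity[keep])


def bin_labels(lo: float = 100.0, hi: float = 1200.0, width: float = 0.2) -> list[str]:
    """Bin-center labels rounded to one decimal, e.g. '327.3'."""
    n = int(round((hi - lo) / width))
    return [f"{lo + (i + 0.5) * width:.1f}" for i in range(n)]


def bin_spectrum(
    peaks: PeakList, lo: float = 100.0, hi: float = 1200.0, width: float = 0.2
):
    """Sum peak intensities into uniform half-open bins [edge, edge+width).

    Returns ``(vector, labels)``. Peaks outside [lo, hi) are dropped with a
    logged count. The default axis yields exactly 5500 bins.
    """
    n = (hi - lo) / width
    n_bins = int(round(n))
    if abs(n - n_bins) > 1e-9:
        raise ValueError(f"width {width} does not divide range ({lo}, {hi})")
    in_range = (peaks.mz >= lo) & (peaks.mz < hi)
    dropped = int((~in_range).sum())
    if dropped:
        log.info("bin_spectrum: dropped %d peaks outside [%g, %g)", dropped, lo, hi)
    idx = np.floor((peaks.mz[in_range] - lo) / width).astype(int)
    # guard the rare float edge case m/z == hi - eps mapping to n_bins
    idx = np.clip(idx, 0, n_bins - 1)
    vec = np.bincount(idx, weights=peaks.intensity[in_range], minlength=n_bins)
    return vec, bin_labels(lo, hi, width)


def tic_normalize(block: SpectraBlock) -> SpectraBlock:
    """Scale each sample so its bin intensities sum to 1."""
    sums = block.data.sum(axis=1)
    bad = sums[sums <= 0]
    if len(bad):
        raise NormalizationError(
            f"all-zero spectrum for sample(s): {list(bad.index)}"
        )
    return SpectraBlock(block.data.div(sums, axis=0), block.edges.copy())


def reims_chain(
    sample: PeakList,
    background: PeakList | None = None,
    observed_lock: float | None = None,
    tic_fraction: float = 1e-5,
    lo: float = 100.0,
    hi: float = 1200.0,
    width: float = 0.2,
):
    """Full spectral parsing chain for one sample: background subtraction,
    lockmass correction, TIC threshold, binning. Returns (vector, labels)."""
    p = sample
    if background is not None:
        p = background_subtract(p, background)
    if observed_lock is not None:
        p = lockmass_correct(p, observed_lock)
    p = tic_threshold_filter(p, tic_fraction)
    return bin_spectrum(p, lo, hi, width)


# ---------------------------------------------------------------------------
# Scaling and element-block operations


@dataclass
class MinMaxParams:
    mins: pd.Series
    maxs: pd.Series


def minmax_scale(matrix: pd.DataFrame):
    """Column-wise min-max scaling to [0, 1] on the fitted data.

    Constant columns map to 0. Returns ``(scaled, MinMaxParams)``; applying
    the stored extrema to held-out data may legitimately fall outside [0,1]
    (no clipping).
    """
    matrix = pd.DataFrame(matrix)
    mins = matrix.min(axis=0)
    maxs = matrix.max(axis=0)
    return apply_minmax(matrix, MinMaxParams(mins, maxs)), MinMaxParams(mins, maxs)


def apply_minmax(matrix: pd.DataFrame, params: MinMaxParams) -> pd.DataFrame:
    matrix = pd.DataFrame(matrix)
    span = (params.maxs - params.mins).replace(0, np.nan)
    scaled = (matrix - params.mins) / span
    return scaled.fillna(0.0)


def internal_standard_normalize(
    signals: pd.DataFrame, is_signal: pd.Series
) -> pd.DataFrame:
    """Divide each sample's analyte signals by its internal-standard signal
    (Rh infusion convention). A shared sensitivity drift affecting analyte
    and internal-standard channels alike cancels exactly."""
    signals = pd.DataFrame(signals)
    is_signal = pd.Series(is_signal).reindex(signals.index)
    bad = is_signal[(is_signal.isna()) | (is_signal <= 0)]
    if len(bad):
        raise DataQualityError(
            f"non-positive internal standard for sample(s): {list(bad.index)}"
        )
    return signals.div(is_signal, axis=0)


def crm_check(
    control_results: pd.DataFrame,
    certified: pd.Series,
    bounds: tuple[float, float] = (80.0, 120.0),
) -> pd.DataFrame:
    """Certified-reference-material QC report.

    Parameters
    ----------
    control_results : repeated CRM measurements (rows) x elements.
    certified : certified concentration per element.
    bounds : acceptable mean recovery window in percent.

    Returns a per-element frame with mean_recovery_pct, rsd_pct and a
    boolean ``ok`` column.
    """
    control_results = pd.DataFrame(control_results)
    if len(control_results) < 2:
        raise ValueError("need at least two control measurements")
    certified = pd.Series(certified).reindex(control_results.columns)
    if (certified <= 0).any() or certified.isna().any():
        bad = certified[(certified.isna()) | (certified <= 0)]
        raise ValueError(f"invalid certified values for: {list(bad.index)}")
    recovery = 100.0 * control_results.div(certified, axis=1)
    mean = recovery.mean(axis=0)
    sd = recovery.std(axis=0, ddof=1)
    rsd = 100.0 * sd / mean.replace(0, np.nan)
    report = pd.DataFrame(
        {
            "mean_recovery_pct": mean,
            "rsd_pct": rsd.fillna(0.0),
            "ok": (mean >= bounds[0]) & (mean <= bounds[1]),
        }
    )
    return report


class EmptyPanelError(ValueError):
    pass


def filter_elements(
    block: ElementBlock,
    max_below_lod_fraction: float = 0.5,
    exclude: tuple[str, ...] = (),
) -> ElementBlock:
    """Drop elements whose below-LOD fraction exceeds the threshold, plus an
    explicit exclusion list (the "excessively high concentration" panel is
    supplied by the caller). Surviving element names are logged."""
    frac = block.below_lod.mean(axis=0)
    keep = [
        e
        for e in block.elements
        if frac[e] <= max_below_lod_fraction and e not in set(exclude)
    ]
    if not keep:
        raise EmptyPanelError("all elements removed by filtering")
    log.info("filter_elements: %d elements retained: %s", len(keep), keep)
    return ElementBlock(block.data[keep].copy(), block.below_lod[keep].copy())
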