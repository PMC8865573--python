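"""Transversal-wavevector extraction from far-field images.

Each far-field acquisition is reduced to a (k_min, k_median, k_max) summary:

1. gamma correction on the max-normalized image (contrast stretch), then
   binarization against a dark-level segmentation threshold;
2. a k_t histogram of the above-threshold pixels, with per-bin mass divided
   by the bin's mean pixel radius to undo the circumference spreading of
   ring-shaped patterns, and bins below a fraction of the histogram maximum
   zeroed;
3. a top-hat fit: the contiguous above-threshold run containing the global
   maximum gives the band support [k_min, k_max], and the weighted median of
   the in-support mass gives k_median.

Frames whose total intensity falls below a dark-level frame threshold are
flagged invalid and carry no wavevector values.  Summaries over a scan grid
assemble into k_t(x, z) and I(x, z) maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import FarFieldImage, RelayOptics, kt_grid, pixel_radius
from .simulate import ScanGrid

__all__ = [
    "ExtractionParams",
    "KtHistogram",
    "KtSummary",
    "KtMap",
    "IntensityMap",
    "default_params",
    "preprocess",
    "radial_histogram",
    "fit_tophat",
    "extract_kt",
    "build_maps",
    "brute_force_summary",
    "KtExtractor",
]


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the extraction algorithm.

    gamma : contrast exponent applied to the max-normalized image (1.4).
    seg_threshold : segmentation threshold in raw counts (dark level).
    hist_threshold_frac : histogram bins below this fraction of the maximum
        are zeroed (0.3).
    frame_threshold : total-frame counts below which a frame is invalid.
    bin_width : histogram bin width in 2*pi/lambda units.
    """

    gamma: float = 1.4
    seg_threshold: float = 0.0
    hist_threshold_frac: float = 0.3
    frame_threshold: float = 0.0
    bin_width: float = 0.005

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.hist_threshold_frac < 1:
            raise ValueError("hist_threshold_frac must be in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


def default_params(
    relay: RelayOptics,
    dark_mean: float = 0.0,
    dark_sd: float = 0.0,
    n_sigma: float = 5.0,
) -> ExtractionParams:
    """Thresholds derived from the camera's dark statistics.

    The segmentation threshold sits at the dark mean plus ``n_sigma`` dark
    standard deviations; the frame threshold at the expected dark total plus
    ``n_sigma`` standard deviations of the total.  With ``dark_sd = 0`` both
    reduce to the plain dark-condition means.  The segmentation threshold is
    floored at half a count — the histogram weights segmented pixels by
    count, not intensity, so sub-quantization residues must never pass.
    """
    n_px = int(np.prod(relay.image_shape))
    return ExtractionParams(
        seg_threshold=float(max(dark_mean + n_sigma * dark_sd, 0.5)),
        frame_threshold=float(n_px * dark_mean + n_sigma * np.sqrt(n_px) * dark_sd),
    )


@dataclass
class KtHistogram:
    """Radius-corrected k_t histogram of the segmented pixels."""

    bin_edges: np.ndarray
    weights: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def is_empty(self) -> bool:
        return bool(np.all(self.weights <= 0))


@dataclass(frozen=True)
class KtSummary:
    """Per-frame extraction result; invalid frames carry NaN wavevectors."""

    k_min: float
    k_median: float
    k_max: float
    frame_intensity: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not (self.k_min <= self.k_median <= self.k_max):
            raise ValueError("require k_min <= k_median <= k_max")

    @classmethod
    def invalid(cls, frame_intensity: float) -> "KtSummary":
        return cls(np.nan, np.nan, np.nan, frame_intensity, False)


@dataclass
class KtMap:
    """k_median(x, z) over a scan grid; excluded points carry NaN."""

    grid: ScanGrid
    values: np.ndarray
    k_min: np.ndarray
    k_max: np.ndarray
    excluded: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        pts = self.grid.points
        return pd.DataFrame(
            {
                "x": pts[:, 0],
                "z": pts[:, 1],
                "k_median": self.values,
                "k_min": self.k_min,
                "k_max": self.k_max,
                "excluded": self.excluded,
            }
        )


@dataclass
class IntensityMap:
    """Total collected counts I(x, z) over a scan grid."""

    grid: ScanGrid
    values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        pts = self.grid.points
        return pd.DataFrame({"x": pts[:, 0], "z": pts[:, 1], "intensity": self.values})


# ---------------------------------------------------------------------------
# algorithm stages


def preprocess(image: FarFieldImage, params: ExtractionParams) -> np.ndarray:
    """Gamma-correct and binarize a far-field image.

    Gamma is applied to the max-normalized intensity; the raw-count
    threshold is transformed consistently, so the resulting mask equals
    ``intensity > seg_threshold`` and segmentation is amplitude-invariant.
    """
    raw = image.intensity
    peak = float(raw.max())
    if peak <= 0:
        return np.zeros(raw.shape, dtype=bool)
    if np.all(raw >= 2**image.bit_depth - 1):
        warnings.warn("image is fully saturated; mask may be meaningless")
    norm = (raw / peak) ** params.gamma
    thr = (max(params.seg_threshold, 0.0) / peak) ** params.gamma
    return norm > thr


def radial_histogram(
    mask: np.ndarray,
    image: FarFieldImage,
    relay: RelayOptics,
    params: ExtractionParams,
) -> KtHistogram:
    """Circumference-corrected k_t histogram of the masked pixels.

    Each above-threshold pixel contributes unit mass at its k_t; per-bin
    mass is divided by the bin's mean pixel radius (signal arriving at a
    larger ring radius is spread over more pixels).  Bins below
    ``hist_threshold_frac`` of the histogram maximum are zeroed.
    """
    kt = kt_grid(relay)
    nr, nc = relay.image_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rr = pixel_radius(ii, jj, relay)

    k_vals = kt[mask]
    r_vals = rr[mask]
    k_top = float(kt.max())
    n_bins = max(int(np.ceil(k_top / params.bin_width)), 8)
    edges = params.bin_width * np.arange(n_bins + 1)
    if k_vals.size == 0:
        return KtHistogram(edges, np.zeros(n_bins))

    idx = np.clip(np.digitize(k_vals, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    r_sum = np.bincount(idx, weights=r_vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, r_sum / np.maximum(counts, 1), 0.0)
    weights = np.where(mean_r > 0, counts / np.maximum(mean_r, 1e-12), counts)
    # pixels at the exact optical center (R = 0) carry k_t = 0; keep their raw count
    peak = weights.max()
    if peak > 0:
        weights = np.where(weights >= params.hist_threshold_frac * peak, weights, 0.0)
    return KtHistogram(edges, weights)


def fit_tophat(hist: KtHistogram) -> tuple[float, float, float]:
    """Fit a top-hat (boxcar) to the histogram: the support is the
    contiguous above-threshold run containing the global maximum (ties
    resolved toward lower k), and k_median is the weighted median of the
    in-support mass."""
    w = np.asarray(hist.weights, dtype=float)
    if np.all(w <= 0):
        raise ValueError("empty histogram: nothing to fit")
    nz = w > 0
    # contiguous runs of nonzero bins
    edges_idx = np.flatnonzero(np.diff(np.concatenate([[0], nz.view(np.int8), [0]])))
    starts, stops = edges_idx[::2], edges_idx[1::2]
    peak_bin = int(np.argmax(w))  # argmax takes the first (lowest-k) maximum
    run = next((s, t) for s, t in zip(starts, stops) if s <= peak_bin < t)
    s, t = run
    k_min = float(hist.bin_edges[s])
    k_max = float(hist.bin_edges[t])
    centers = hist.bin_centers[s:t]
    mass = w[s:t]
    cum = np.cumsum(mass)
    k_median = float(centers[np.searchsorted(cum, 0.5 * cum[-1])])
    return k_min, k_median, k_max


def extract_kt(
    image: FarFieldImage, relay: RelayOptics, params: ExtractionParams
) -> KtSummary:
    """Full per-frame chain: segment -> radius-corrected histogram -> top-hat."""
    frame_intensity = image.total
    if frame_intensity < params.frame_threshold:
        return KtSummary.invalid(frame_intensity)
    mask = preprocess(image, params)
    if not mask.any():
        return KtSummary.invalid(frame_intensity)
    hist = radial_histogram(mask, image, relay, params)
    if hist.is_empty:
        return KtSummary.invalid(frame_intensity)
    k_min, k_median, k_max = fit_tophat(hist)
    return KtSummary(k_min, k_median, k_max, frame_intensity, True)


def build_maps(
    stack: Sequence[FarFieldImage],
    grid: ScanGrid,
    relay: RelayOptics,
    params: ExtractionParams,
) -> tuple[KtMap, IntensityMap]:
    """Per-point extraction over a scan stack, assembled into maps.

    Excluded (gray) points are exactly the frames that fail validity —
    total counts below the frame threshold or an empty histogram.
    """
    if len(stack) != grid.n_points:
        raise ValueError(
            f"stack length {len(stack)} does not match grid size {grid.n_points}"
        )
    n = grid.n_points
    vals = np.full(n, np.nan)
    kmin = np.full(n, np.nan)
    kmax = np.full(n, np.nan)
    inten = np.zeros(n)
    excl = np.zeros(n, dtype=bool)
    for p, img in enumerate(stack):
        s = extract_kt(img, relay, params)
        inten[p] = s.frame_intensity
        if s.valid:
            vals[p], kmin[p], kmax[p] = s.k_median, s.k_min, s.k_max
        else:
            excl[p] = True
    return KtMap(grid, vals, kmin, kmax, excl), IntensityMap(grid, inten)


def brute_force_summary(
    image: FarFieldImage, relay: RelayOptics, params: ExtractionParams
) -> tuple[float, float, float]:
    """Independent per-pixel oracle for noiseless images: min/max k_t over
    the above-threshold pixels and the 1/R-weighted per-pixel median.

    Deliberately avoids the histogram/top-hat path so it can cross-check it.
    """
    mask = image.intensity > max(params.seg_threshold, 0.0)
    kt = kt_grid(relay)[mask]
    nr, nc = relay.image_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rr = pixel_radius(ii, jj, relay)[mask]
    if kt.size == 0:
        raise ValueError("no pixels above threshold")
    w = 1.0 / np.maximum(rr, 1e-12)
    order = np.argsort(kt)
    cum = np.cumsum(w[order])
    k_med = float(kt[order][np.searchsorted(cum, 0.5 * cum[-1])])
    return float(kt.min()), k_med, float(kt.max())


class KtExtractor:
    """Stateless transformer turning far-field stacks into k_t summaries.

    Follows the scikit-learn estimator protocol: parameters are set in
    ``__init__``, ``fit`` validates and freezes the histogram binning, and
    ``transform`` maps a sequence of :class:`FarFieldImage` to a DataFrame
    of per-frame summaries.
    """

    def __init__(
        self,
        relay: RelayOptics | None = None,
        gamma: float = 1.4,
        seg_threshold: float = 0.0,
        hist_threshold_frac: float = 0.3,
        frame_threshold: float = 0.0,
        bin_width: float = 0.005,
    ):
        self.relay = relay
        self.gamma = gamma
        self.seg_threshold = seg_threshold
        self.hist_threshold_frac = hist_threshold_frac
        self.frame_threshold = frame_threshold
        self.bin_width = bin_width

    def get_params(self, deep: bool = True) -> dict:
        return {
            "relay": self.relay,
            "gamma": self.gamma,
            "seg_threshold": self.seg_threshold,
            "hist_threshold_frac": self.hist_threshold_frac,
            "frame_threshold": self.frame_threshold,
            "bin_width": self.bin_width,
        }

    def set_params(self, **kwargs) -> "KtExtractor":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _params(self) -> ExtractionParams:
        return ExtractionParams(
            gamma=self.gamma,
            seg_threshold=self.seg_threshold,
            hist_threshold_frac=self.hist_threshold_frac,
            frame_threshold=self.frame_threshold,
            bin_width=self.bin_width,
        )

    def fit(self, X: Sequence[FarFieldImage] | None = None, y=None) -> "KtExtractor":
        if self.relay is None:
            raise ValueError("relay must be set before fitting")
        self.params_ = self._params()
        return self

    def transform(self, X: Sequence[FarFieldImage]) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            self.fit()
        rows = [extract_kt(img, self.relay, self.params_) for img in X]
        return pd.DataFrame(
            {
                "k_min": [r.k_min for r in rows],
                "k_median": [r.k_median for r in rows],
                "k_max": [r.k_max for r in rows],
                "frame_intensity": [r.frame_intensity for r in rows],
                "valid": [r.valid for r in rows],
            }
        )

    def fit_transform(self, X: Sequence[FarFieldImage], y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
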