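"""ROI segmentation and blind source-position classification.

Each micro-aperture (slot) defines a spatial region of interest (ROI): the
grid points inside its collection lobe whose intensity reaches 50% of the
lobe maximum.  Averaging the extracted k_median over the footprint yields a
wavevector interval (mean +/- SD) per slot.  When the intervals are pairwise
disjoint ("orthogonal" segmentation), a blind excitation can be classified
by interval containment of its extracted k_median; excitations matching no
interval (or failing frame validity) fall into the "Out" class.

The confusion matrix of true vs predicted classes is scored with one-vs-rest
accuracy/precision/recall per class and the overall accuracy
OA = trace(CM) / N_R.  Two F1 variants are reported: ``f1`` follows the
source convention P*R/(P+R) literally, ``f1_standard`` the conventional
2PR/(P+R); on a perfect classifier the former is 0.5, the latter 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .extract import IntensityMap, KtMap, KtSummary
from .optics import RelayOptics, SlotSpec, TaperGeometry
from .simulate import ScanGrid, SimConfig, apply_noise, collection_efficiency, noiseless_slot_model

__all__ = [
    "RoiInterval",
    "RoiModel",
    "ConfusionMatrix",
    "ClassMetrics",
    "segment_rois",
    "classify_point",
    "run_blind_experiment",
    "confusion",
    "class_metrics",
    "RoiClassifier",
    "OUT_LABEL",
]

OUT_LABEL = "Out"


@dataclass(frozen=True)
class RoiInterval:
    """One slot's wavevector interval and spatial footprint."""

    label: str
    kt_mean: float
    kt_sd: float
    footprint: frozenset[int]  # row-major grid indices
    degenerate: bool = False  # single-point footprint (sd = 0)

    @property
    def lo(self) -> float:
        return self.kt_mean - self.kt_sd

    @property
    def hi(self) -> float:
        return self.kt_mean + self.kt_sd

    def contains(self, k: float) -> bool:
        return self.lo <= k <= self.hi


@dataclass(frozen=True)
class RoiModel:
    """Ordered ROI intervals; ``orthogonal`` iff pairwise disjoint."""

    rois: tuple[RoiInterval, ...]
    orthogonal: bool

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def __iter__(self):
        return iter(self.rois)


def _intervals_disjoint(rois: Sequence[RoiInterval]) -> bool:
    ordered = sorted(rois, key=lambda r: r.lo)
    return all(a.hi < b.lo for a, b in zip(ordered, ordered[1:]))


def segment_rois(
    ktmap: KtMap,
    imap: IntensityMap,
    slots: Sequence[SlotSpec],
    geom: TaperGeometry,
    lobe_threshold: float = 0.5,
) -> RoiModel:
    """Segment the k_t/intensity maps into per-slot ROIs.

    For each slot, candidate points are the valid grid points whose axial
    position falls within the slot's own axial footprint (half the slot
    length on either side of its center, so neighbouring lobes are not
    mixed in); the footprint keeps those whose intensity is at least
    ``lobe_threshold`` of the lobe maximum.  The interval is mean +/- SD of
    k_median over the footprint.
    """
    if ktmap.grid is not imap.grid and ktmap.grid != imap.grid:
        raise ValueError("maps must share a grid")
    grid = ktmap.grid
    pts = grid.points
    valid = ~ktmap.excluded
    rois = []
    for slot in slots:
        zc = slot.z_center(geom)
        half = slot.slot_length / 2.0
        in_lobe = valid & (np.abs(pts[:, 1] - zc) <= half)
        if not in_lobe.any():
            raise ValueError(f"empty footprint for slot {slot.id}")
        lobe_max = imap.values[in_lobe].max()
        member = in_lobe & (imap.values >= lobe_threshold * lobe_max)
        if not member.any():
            raise ValueError(f"empty footprint for slot {slot.id}")
        ks = ktmap.values[member]
        idx = frozenset(np.flatnonzero(member).tolist())
        rois.append(
            RoiInterval(
                label=slot.id,
                kt_mean=float(np.mean(ks)),
                kt_sd=float(np.std(ks)),
                footprint=idx,
                degenerate=len(idx) == 1 or float(np.std(ks)) == 0.0,
            )
        )
    return RoiModel(tuple(rois), orthogonal=_intervals_disjoint(rois))


def classify_point(summary: KtSummary, rois: RoiModel) -> str:
    """Assign a blind excitation to a slot by interval containment of its
    extracted k_median; invalid frames and out-of-interval values -> Out."""
    if not rois.orthogonal:
        raise ValueError("ROI intervals overlap: classification is ambiguous")
    if not summary.valid:
        return OUT_LABEL
    for roi in rois:
        if roi.contains(summary.k_median):
            return roi.label
    return OUT_LABEL


def true_label_for_position(
    x: float, z: float, rois: RoiModel, ktmap: KtMap
) -> str:
    """True class of a position: ROI membership of the nearest grid point
    on the segmented map (Out for excluded or unassigned points)."""
    idx = ktmap.grid.nearest_index(x, z)
    for roi in rois:
        if idx in roi.footprint:
            return roi.label
    return OUT_LABEL


def _footprint_interior(roi: RoiInterval, grid: ScanGrid) -> np.ndarray:
    """Footprint points all of whose 4-neighbours are also in the footprint
    (the footprint eroded by one grid cell)."""
    inside = []
    fp = roi.footprint
    for idx in sorted(fp):
        iz, ix = divmod(idx, grid.n_x)
        ok = True
        for dz, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jz, jx = iz + dz, ix + dx
            if 0 <= jz < grid.n_z and 0 <= jx < grid.n_x:
                if jz * grid.n_x + jx not in fp:
                    ok = False
                    break
        if ok:
            inside.append(idx)
    return np.asarray(inside, dtype=int)


def run_blind_experiment(
    n_points: int,
    rois: RoiModel,
    ktmap: KtMap,
    slots: Sequence[SlotSpec],
    geom: TaperGeometry,
    relay: RelayOptics,
    cfg: SimConfig,
    params,
    seed: int,
    interior_only: bool = False,
) -> tuple[list[str], list[str], np.ndarray]:
    """Blind detection experiment with randomly generated excitations.

    Positions are sampled uniformly over the scan-grid area (or, with
    ``interior_only``, uniformly among interiors of the ROI footprints —
    footprints eroded by one grid cell).  Per position, the true class comes
    from the segmented map and the predicted class from the full
    simulate -> extract -> classify chain.  Returns (true, predicted,
    positions); reproducible under ``seed``.
    """
    from .extract import extract_kt

    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    grid = ktmap.grid
    if interior_only:
        pools = [_footprint_interior(r, grid) for r in rois]
        pool = np.concatenate([p for p in pools if p.size])
        if pool.size == 0:
            raise ValueError("no interior footprint points to sample")
        pts = grid.points[rng.choice(pool, size=n_points)]
        # jitter within a quarter grid cell so positions are not lattice points
        pts = pts + rng.uniform(-0.25, 0.25, size=pts.shape) * grid.spacing
    else:
        x_min, x_max, z_min, z_max = grid.extent
        pts = np.column_stack(
            [
                rng.uniform(x_min, x_max, size=n_points),
                rng.uniform(z_min, z_max, size=n_points),
            ]
        )

    patterns = [
        noiseless_slot_model(s, geom, relay, cfg.source_amplitude) for s in slots
    ]
    children = np.random.SeedSequence([seed, 1]).spawn(n_points)
    truths, preds = [], []
    for p, (x, z) in enumerate(pts):
        truths.append(true_label_for_position(x, z, rois, ktmap))
        model = np.zeros(relay.image_shape, dtype=float)
        for slot, pat in zip(slots, patterns):
            eff = collection_efficiency((x, z), slot, geom, cfg)
            if eff > 1e-12:
                model += eff * pat
        img = apply_noise(model, relay, cfg, rng=np.random.default_rng(children[p]))
        preds.append(classify_point(extract_kt(img, relay, params), rois))
    return truths, preds, pts


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i, j] = #(true = labels[i] and predicted = labels[j])."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square over labels")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str],
) -> ConfusionMatrix:
    """Tally true-vs-predicted label pairs into a confusion matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest metrics and overall accuracy.

    ``f1`` uses the form P*R/(P+R); ``f1_standard`` the conventional
    2PR/(P+R).  Undefined ratios (0/0) are NaN, never silently 0.
    """

    labels: tuple[str, ...]
    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    f1_standard: np.ndarray
    overall_accuracy: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accuracy": self.accuracy,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "f1_standard": self.f1_standard,
            },
            index=list(self.labels),
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest TP/TN/FP/FN per class and overall accuracy trace/total."""
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    n = len(cm.labels)
    acc = np.empty(n)
    prec = np.empty(n)
    rec = np.empty(n)
    f1 = np.empty(n)
    f1s = np.empty(n)
    for k in range(n):
        tp = counts[k, k]
        fp = counts[:, k].sum() - tp
        fn = counts[k, :].sum() - tp
        tn = total - tp - fp - fn
        acc[k] = (tp + tn) / total
        prec[k] = _safe_div(tp, tp + fp)
        rec[k] = _safe_div(tp, tp + fn)
        f1[k] = _safe_div(prec[k] * rec[k], prec[k] + rec[k])
        f1s[k] = 2.0 * f1[k]
    oa = float(np.trace(counts) / total)
    return ClassMetrics(cm.labels, acc, prec, rec, f1, f1s, oa)


class RoiClassifier:
    """Depth classifier over wavevector intervals (scikit-learn protocol).

    ``fit`` segments the per-slot ROIs from a k_t map and an intensity map;
    ``predict`` assigns labels to extracted summaries (or raw k_median
    values) by interval containment.
    """

    def __init__(
        self,
        slots: Sequence[SlotSpec] | None = None,
        geom: TaperGeometry | None = None,
        lobe_threshold: float = 0.5,
    ):
        self.slots = slots
        self.geom = geom
        self.lobe_threshold = lobe_threshold

    def get_params(self, deep: bool = True) -> dict:
        return {
            "slots": self.slots,
            "geom": self.geom,
            "lobe_threshold": self.lobe_threshold,
        }

    def set_params(self, **kwargs) -> "RoiClassifier":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ktmap: KtMap, imap: IntensityMap) -> "RoiClassifier":
        if self.slots is None or self.geom is None:
            raise ValueError("slots and geom must be set before fitting")
        self.roi_model_ = segment_rois(
            ktmap, imap, self.slots, self.geom, self.lobe_threshold
        )
        self.classes_ = np.asarray(self.roi_model_.labels + [OUT_LABEL])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "roi_model_"):
            raise ValueError("classifier is not fitted")
        out = []
        for item in X:
            if isinstance(item, KtSummary):
                out.append(classify_point(item, self.roi_model_))
            else:
                s = KtSummary(float(item), float(item), float(item), np.inf, True)
                out.append(classify_point(s, self.roi_model_))
        return np.asarray(out)

    def score(self, X, y) -> float:
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean(pred == y))
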