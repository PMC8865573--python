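"""Versor-basis construction and far-field demultiplexing.

Site-selective acquisitions (one per slot) are background-subtracted,
clipped at zero and normalized into versors ``v_j`` — a non-negative basis
of the far-field space.  A mixed acquisition ``R_i`` (all slots collecting
simultaneously) is decomposed by the Hadamard projection

    M_ij = R_i (.) v_j          (pixelwise product)
    c_ij = sum_pixels M_ij      (overlap integral)
    m_ij = 100 * c_ij / sum_j c_ij

so each row of ``m`` gives the percentage of the detected signal assigned
to each slot, i.e. to each collection depth.  The assignment is unambiguous
when the versors have negligible pairwise overlap (orthogonality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import FarFieldImage

__all__ = [
    "VersorBasis",
    "DemuxResult",
    "build_versors",
    "orthogonality_matrix",
    "overlap_images",
    "project_coefficients",
    "percentage_matrix",
    "demux",
    "VersorDemultiplexer",
]

_NORM_KINDS = ("unit-sum", "unit-l2", "max-1")


def _as_array(img) -> np.ndarray:
    if isinstance(img, FarFieldImage):
        return np.asarray(img.intensity, dtype=float)
    return np.asarray(img, dtype=float)


@dataclass(frozen=True)
class VersorBasis:
    """Ordered, normalized, non-negative per-slot far-field patterns."""

    versors: tuple[np.ndarray, ...]
    labels: tuple[str, ...]
    background: np.ndarray | None = None
    norm_kind: str = "unit-sum"

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.versors}
        if len(shapes) != 1:
            raise ValueError("all versors must share a shape")
        for v in self.versors:
            if np.any(v < 0):
                raise ValueError("versors must be non-negative")

    @property
    def n(self) -> int:
        return len(self.versors)

    @property
    def shape(self) -> tuple[int, int]:
        return self.versors[0].shape


def _normalize(v: np.ndarray, norm_kind: str) -> np.ndarray:
    if norm_kind == "unit-sum":
        s = v.sum()
    elif norm_kind == "unit-l2":
        s = np.sqrt((v**2).sum())
    elif norm_kind == "max-1":
        s = v.max()
    else:
        raise ValueError(f"norm_kind must be one of {_NORM_KINDS}")
    if s <= 0:
        raise ValueError("cannot normalize a zero versor")
    return v / s


def build_versors(
    slot_images: Sequence,
    background=None,
    norm_kind: str = "unit-sum",
    labels: Sequence[str] | None = None,
) -> VersorBasis:
    """Background-subtract, clip at zero and normalize per-slot patterns.

    The default unit-total-intensity normalization makes each projection
    coefficient interpretable as fluorescence-weighted overlap; ``unit-l2``
    makes a mixture of the versors themselves recover its own weights
    exactly when the supports are disjoint.
    """
    if len(slot_images) < 2:
        raise ValueError("need at least two slot images to form a basis")
    bg = _as_array(background) if background is not None else None
    versors = []
    for img in slot_images:
        a = _as_array(img)
        if bg is not None:
            a = np.clip(a - bg, 0.0, None)
        if a.sum() <= 0:
            raise ValueError("slot image is everywhere below the background")
        versors.append(_normalize(a, norm_kind))
    if labels is None:
        labels = tuple(f"S{k + 1}" for k in range(len(versors)))
    return VersorBasis(tuple(versors), tuple(labels), bg, norm_kind)


def orthogonality_matrix(basis: VersorBasis) -> np.ndarray:
    """Normalized pairwise overlap scores: symmetric, unit diagonal; small
    off-diagonal entries mean the versors separate cleanly."""
    n = basis.n
    raw = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            raw[i, j] = raw[j, i] = float((basis.versors[i] * basis.versors[j]).sum())
    d = np.sqrt(np.diag(raw))
    return raw / np.outer(d, d)


def overlap_images(pattern, basis: VersorBasis) -> list[np.ndarray]:
    """Hadamard (pixelwise) products of one mixed pattern with each versor."""
    a = _as_array(pattern)
    if a.shape != basis.shape:
        raise ValueError("pattern shape does not match basis")
    return [a * v for v in basis.versors]


def project_coefficients(M: Sequence[np.ndarray]) -> np.ndarray:
    """Integrate each overlap image into a scalar coefficient."""
    return np.asarray([float(m.sum()) for m in M])


def percentage_matrix(c: np.ndarray) -> np.ndarray:
    """Row-normalize coefficients to percentages (each row sums to 100).

    A zero row has no signal to apportion and comes back as NaN."""
    c = np.atleast_2d(np.asarray(c, dtype=float))
    sums = c.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = 100.0 * c / sums
    m[np.repeat(sums <= 0, c.shape[1], axis=1)] = np.nan
    return m


@dataclass
class DemuxResult:
    """Full decomposition of a set of mixed patterns on a versor basis."""

    basis: VersorBasis
    M: list[list[np.ndarray]]  # [pattern][slot] overlap images
    c: np.ndarray  # (n_patterns, n_slots) coefficients
    m: np.ndarray  # (n_patterns, n_slots) percentages
    pattern_labels: tuple[str, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        idx = list(self.pattern_labels) or [f"R{k + 1}" for k in range(self.m.shape[0])]
        return pd.DataFrame(self.m, index=idx, columns=list(self.basis.labels))


def demux(
    patterns: Sequence,
    basis: VersorBasis,
    background=None,
    pattern_labels: Sequence[str] | None = None,
) -> DemuxResult:
    """Decompose mixed patterns on the basis: overlap images, coefficients
    and percentage rows.

    ``background`` (typically the same autofluorescence reference used for
    the versors) is subtracted from each pattern and the result clipped at
    zero before projection.
    """
    bg = _as_array(background) if background is not None else None
    M_all, c_all = [], []
    for pat in patterns:
        a = _as_array(pat)
        if bg is not None:
            a = np.clip(a - bg, 0.0, None)
        M = overlap_images(a, basis)
        M_all.append(M)
        c_all.append(project_coefficients(M))
    c = np.asarray(c_all)
    return DemuxResult(
        basis=basis,
        M=M_all,
        c=c,
        m=percentage_matrix(c),
        pattern_labels=tuple(pattern_labels or ()),
    )


class VersorDemultiplexer:
    """Demultiplexer with the scikit-learn transformer protocol.

    ``fit`` builds the versor basis from site-selective slot acquisitions;
    ``transform`` maps mixed far-field patterns to rows of per-slot signal
    percentages.  The full :class:`DemuxResult` of the last transform is
    kept in ``result_``.
    """

    def __init__(self, norm_kind: str = "unit-sum", orthogonality_limit: float = 0.05):
        self.norm_kind = norm_kind
        self.orthogonality_limit = orthogonality_limit

    def get_params(self, deep: bool = True) -> dict:
        return {
            "norm_kind": self.norm_kind,
            "orthogonality_limit": self.orthogonality_limit,
        }

    def set_params(self, **kwargs) -> "VersorDemultiplexer":
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        slot_images: Sequence,
        y=None,
        background=None,
        labels: Sequence[str] | None = None,
    ) -> "VersorDemultiplexer":
        self.basis_ = build_versors(
            slot_images, background=background, norm_kind=self.norm_kind, labels=labels
        )
        self.background_ = (
            _as_array(background) if background is not None else None
        )
        gram = orthogonality_matrix(self.basis_)
        self.orthogonality_ = gram
        off = gram[~np.eye(self.basis_.n, dtype=bool)]
        self.max_overlap_ = float(off.max()) if off.size else 0.0
        return self

    def transform(self, patterns: Sequence) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise ValueError("demultiplexer is not fitted")
        self.result_ = demux(patterns, self.basis_, background=self.background_)
        return self.result_.m

    def fit_transform(
        self, slot_images: Sequence, patterns: Sequence | None = None, **kw
    ) -> np.ndarray:
        self.fit(slot_images, **kw)
        return self.transform(patterns if patterns is not None else slot_images)
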