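"""Taper geometry and the Fourier-plane (back-focal-plane) mapping.

A tapered optical fiber (TF) narrows from its untapered core radius ``a0``
down to a sub-micrometer tip.  Light entering the taper at local radius
``a(z)`` couples to guided modes whose transversal wavevector ``k_t`` grows
with the local diameter of the waveguide.  Imaging the far field of the
distal facet through a three-lens relay places each plane-wave component at
a radial distance ``R`` from the optical axis on the camera, with

    k_t / (2*pi/lambda) = sin(arctan(f2 / (f1*f3) * R))

where ``f1``, ``f2``, ``f3`` are the relay focal lengths.  All wavevectors
in this package are expressed in units of ``2*pi/lambda`` so that values are
wavelength-free and bounded by the fiber NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "TaperGeometry",
    "SlotSpec",
    "RelayOptics",
    "FarFieldImage",
    "local_radius",
    "axial_position_for_diameter",
    "pixel_radius",
    "kt_from_radius",
    "radius_from_kt",
    "kt_band_for_section",
    "kt_grid",
]


@dataclass(frozen=True)
class TaperGeometry:
    """Geometry of a tapered fiber.

    Parameters
    ----------
    a0 : float
        Untapered core radius in micrometers.
    psi : float
        Taper half-angle in degrees (0 < psi < 90).
    L : float
        Length of the tapered section in micrometers.
    NA : float
        Numerical aperture of the fiber.
    lambda_em : float
        Emission wavelength in nanometers (metadata; k_t is kept in
        2*pi/lambda units throughout).
    EL : float
        Emission/collection length along the taper in micrometers
        (metadata describing the light-sensitive region).
    """

    a0: float = 100.0
    psi: float = 5.0
    L: float = 1250.0
    NA: float = 0.37
    lambda_em: float = 520.0
    EL: float = 1250.0

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if not 0 < self.psi < 90:
            raise ValueError("psi must be in (0, 90) degrees")
        if not 0 < self.NA < 1:
            raise ValueError("NA must be in (0, 1)")

    @property
    def tan_psi(self) -> float:
        return float(np.tan(np.deg2rad(self.psi)))


@dataclass(frozen=True)
class SlotSpec:
    """A micro-aperture (uSlot) milled through the taper's metal coating.

    ``local_diameter`` is the taper diameter at the slot center (slot
    positions are conventionally quoted as diameters); the corresponding
    local radius is half of it.
    """

    id: str
    local_diameter: float
    slot_length: float = 100.0
    slot_width: float = 20.0
    z_um: float | None = None  # explicit axial position; overrides inversion

    def __post_init__(self) -> None:
        if self.local_diameter <= 0:
            raise ValueError("local_diameter must be positive")
        if self.slot_length <= 0 or self.slot_width <= 0:
            raise ValueError("slot dimensions must be positive")

    def z_center(self, geom: TaperGeometry) -> float:
        """Axial position (um from tip) where the taper reaches the slot."""
        if self.z_um is not None:
            return self.z_um
        if self.local_diameter >= 2 * geom.a0:
            raise ValueError("slot diameter must be below the untapered diameter")
        return axial_position_for_diameter(self.local_diameter, geom)


def default_slots() -> list[SlotSpec]:
    """Three slots at taper diameters 30/50/80 um, 100x20 um^2 apertures."""
    return [
        SlotSpec("S1", 30.0),
        SlotSpec("S2", 50.0),
        SlotSpec("S3", 80.0),
    ]


@dataclass(frozen=True)
class RelayOptics:
    """The three-lens far-field relay plus camera sampling.

    ``pixel_pitch`` is the physical pixel size after binning, in
    micrometers.  ``center`` is the optical axis position (i0, j0) in pixel
    coordinates.
    """

    f1: float = 32.0
    f2: float = 250.0
    f3: float = 100.0
    pixel_pitch: float = 26.0
    image_shape: tuple[int, int] = (512, 512)
    center: tuple[float, float] = (255.5, 255.5)
    lambda_em: float = 520.0

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.f3) <= 0:
            raise ValueError("focal lengths must be positive")
        i0, j0 = self.center
        nr, nc = self.image_shape
        if not (0 <= i0 < nr and 0 <= j0 < nc):
            raise ValueError("center must lie inside image_shape")

    @property
    def lever(self) -> float:
        """f2 / (f1*f3) in 1/mm: converts R (mm) to tan(theta)."""
        return self.f2 / (self.f1 * self.f3)

    @classmethod
    def coarse(cls, n: int = 128) -> "RelayOptics":
        """Same optical field sampled on an n x n grid (heavier binning)."""
        pitch = 26.0 * (512 / n)
        c = (n - 1) / 2
        return cls(pixel_pitch=pitch, image_shape=(n, n), center=(c, c))


@dataclass
class FarFieldImage:
    """A single far-field acquisition: non-negative counts on a pixel grid."""

    intensity: np.ndarray
    pixel_pitch: float
    center: tuple[float, float]
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def total(self) -> float:
        return float(self.intensity.sum())


# ---------------------------------------------------------------------------
# mappings


def local_radius(z: float | np.ndarray, geom: TaperGeometry) -> float | np.ndarray:
    """Taper radius a(z) at axial distance ``z`` (um) from the tip.

    a(z) = min(a0, z * tan(psi)); the tip has zero radius and the profile
    saturates at the untapered radius.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be non-negative (measured from the tip)")
    out = np.minimum(geom.a0, z * geom.tan_psi)
    return float(out) if out.ndim == 0 else out


def axial_position_for_diameter(diameter: float, geom: TaperGeometry) -> float:
    """Inverse of :func:`local_radius`: z (um from tip) where the taper
    diameter equals ``diameter``."""
    if not 0 < diameter < 2 * geom.a0:
        raise ValueError("diameter must be in (0, 2*a0)")
    return (diameter / 2.0) / geom.tan_psi


def pixel_radius(
    i: float | np.ndarray, j: float | np.ndarray, relay: RelayOptics
) -> float | np.ndarray:
    """Physical distance (mm) of pixel (i, j) from the optical center."""
    i0, j0 = relay.center
    r_um = relay.pixel_pitch * np.hypot(
        np.asarray(i, dtype=float) - i0, np.asarray(j, dtype=float) - j0
    )
    out = r_um / 1000.0
    return float(out) if np.ndim(out) == 0 else out


def kt_from_radius(R: float | np.ndarray, relay: RelayOptics) -> float | np.ndarray:
    """Transversal wavevector (2*pi/lambda units) at camera radius R (mm)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be non-negative")
    out = np.sin(np.arctan(relay.lever * R))
    return float(out) if out.ndim == 0 else out


def radius_from_kt(kt: float | np.ndarray, relay: RelayOptics) -> float | np.ndarray:
    """Inverse mapping: camera radius (mm) at which ``kt`` lands."""
    kt = np.asarray(kt, dtype=float)
    if np.any((kt < 0) | (kt >= 1)):
        raise ValueError("kt must be in [0, 1) in 2*pi/lambda units")
    out = np.tan(np.arcsin(kt)) / relay.lever
    return float(out) if out.ndim == 0 else out


def kt_band_for_section(
    a_local: float, geom: TaperGeometry, band_fraction: float = 0.7
) -> tuple[float, float]:
    """Phenomenological wavevector band collected at local taper radius
    ``a_local`` (um).

    The upper edge scales linearly with the local radius and reaches the
    fiber NA in the untapered limit: k_hi = NA * a_local / a0.  The lower
    edge is ``band_fraction * k_hi``.  This is a declared approximation of
    the mode-theoretic relation between collection radius and transversal
    wavevector (monotone, NA-capped), not an eigenmode computation.

    The default ``band_fraction`` of 0.7 keeps the bands of the standard
    30/50/80 um slots pairwise disjoint (a ring covering [0.5, 1]*k_hi
    would overlap its neighbour whenever adjacent diameter ratios exceed
    0.5, breaking the non-overlapping-interval premise the demultiplexing
    method rests on).
    """
    if not 0 < a_local <= geom.a0:
        raise ValueError("a_local must be in (0, a0]")
    if not 0 < band_fraction < 1:
        raise ValueError("band_fraction must be in (0, 1)")
    k_hi = geom.NA * (a_local / geom.a0)
    return band_fraction * k_hi, k_hi


def kt_grid(relay: RelayOptics) -> np.ndarray:
    """Per-pixel k_t map (2*pi/lambda units) for the relay's image grid."""
    nr, nc = relay.image_shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    return kt_from_radius(pixel_radius(ii, jj, relay), relay)
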