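"""Synthetic far-field data generator.

Emulates the statistical structure of far-field acquisitions from a tapered
fiber submerged in fluorescent solution (or implanted in tissue): ring-shaped
(annular) far-field patterns whose radius encodes the taper diameter at the
collection site, per-slot collection-efficiency lobes in the [x, z] scan
plane, scattering blur, Poisson photon noise, camera dark noise, and an
optional autofluorescence background.

The noiseless model intensity of an annulus is proportional to 1/R on the
pixels whose mapped k_t lies in the band, so that the radius-corrected
histogram used by the extraction stage is flat (top-hat) over the band.

All randomness flows through a single seed in :class:`SimConfig`; identical
seed and configuration produce bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import (
    FarFieldImage,
    RelayOptics,
    SlotSpec,
    TaperGeometry,
    kt_band_for_section,
    kt_grid,
    pixel_radius,
)

__all__ = [
    "ScanGrid",
    "SimConfig",
    "make_grid",
    "grid_preset",
    "collection_efficiency",
    "render_annulus",
    "render_slot_pattern",
    "render_mixture",
    "simulate_scan_stack",
    "make_background",
    "noiseless_slot_model",
    "apply_noise",
    "DEPTH_PRESETS",
]


@dataclass(frozen=True)
class ScanGrid:
    """Row-major grid of excitation points in the [x, z] plane (um).

    ``z`` runs along the taper axis (0 at the tip), ``x`` off-axis.
    Points are ordered row-major: for each z row, all x columns.
    """

    n_x: int
    n_z: int
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_z < 1:
            raise ValueError("grid counts must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_points(self) -> int:
        return self.n_x * self.n_z

    @property
    def points(self) -> np.ndarray:
        """(N, 2) array of (x, z) positions, row-major in z then x."""
        x0, z0 = self.origin
        xs = x0 + self.spacing * np.arange(self.n_x)
        zs = z0 + self.spacing * np.arange(self.n_z)
        zz, xx = np.meshgrid(zs, xs, indexing="ij")
        return np.column_stack([xx.ravel(), zz.ravel()])

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, z_min, z_max) of the point lattice."""
        x0, z0 = self.origin
        return (
            x0,
            x0 + self.spacing * (self.n_x - 1),
            z0,
            z0 + self.spacing * (self.n_z - 1),
        )

    def nearest_index(self, x: float, z: float) -> int:
        """Row-major index of the grid point nearest to (x, z)."""
        x0, z0 = self.origin
        ix = int(np.clip(round((x - x0) / self.spacing), 0, self.n_x - 1))
        iz = int(np.clip(round((z - z0) / self.spacing), 0, self.n_z - 1))
        return iz * self.n_x + ix


def make_grid(
    n_x: int, n_z: int, spacing: float, origin: tuple[float, float] = (0.0, 0.0)
) -> ScanGrid:
    """Build a row-major scan grid of ``n_x * n_z`` points."""
    return ScanGrid(n_x=n_x, n_z=n_z, spacing=spacing, origin=origin)


# Presets mirroring the three characterization grids: a sparse bare-fiber
# grid (25 x 8 at 50 um => 200 points), a denser slotted-fiber grid
# (41 x 5 at 20 um => 205 points; the long side runs along z) and a
# close-up grid (26 x 11 at 10 um => 286 points).
_GRID_PRESETS = {
    "bare_tf": dict(n_x=8, n_z=25, spacing=50.0, origin=(10.0, 0.0)),
    "slotted_tf": dict(n_x=5, n_z=41, spacing=20.0, origin=(10.0, 0.0)),
    "slot_closeup": dict(n_x=11, n_z=26, spacing=10.0, origin=(10.0, 100.0)),
}


def grid_preset(name: str) -> ScanGrid:
    try:
        kw = _GRID_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown grid preset {name!r}; available: {sorted(_GRID_PRESETS)}"
        ) from None
    return ScanGrid(**kw)


@dataclass(frozen=True)
class SimConfig:
    """Noise and collection parameters of the synthetic generator.

    dark_mean, dark_sd : camera dark level and noise, in counts.
    poisson_scale : photons (counts) per unit of model intensity.
    blur_sigma : Gaussian blur of the far-field pattern, in pixels; a
        phenomenological proxy for tissue scattering.
    lobe_extent : out-of-axis decay length of the collection lobe (um).
    edge_width : axial smoothing width of the slot footprint edges (um).
    source_amplitude : peak model amplitude (counts) of a scan-point source.
    versor_amplitude : amplitude used for versor-quality acquisitions.
    background : optional autofluorescence pattern added before noise.
    seed : base seed for all randomness.
    """

    dark_mean: float = 100.0
    dark_sd: float = 10.0
    poisson_scale: float = 1.0
    blur_sigma: float = 1.0
    lobe_extent: float = 200.0
    edge_width: float = 5.0
    source_amplitude: float = 2000.0
    versor_amplitude: float = 20000.0
    background: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_mean < 0 or self.dark_sd < 0:
            raise ValueError("dark noise parameters must be non-negative")
        if self.lobe_extent <= 0:
            raise ValueError("lobe_extent must be positive")

    def noiseless(self) -> "SimConfig":
        """Copy with all noise sources and blur switched off."""
        return replace(
            self, dark_mean=0.0, dark_sd=0.0, poisson_scale=0.0, blur_sigma=0.0
        )

    def clear_solution(self) -> "SimConfig":
        """Copy without scattering blur: acquisitions in non-scattering
        fluorescent solution (versor calibration), camera noise kept."""
        return replace(self, blur_sigma=0.0)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# collection model


def collection_efficiency(
    source: tuple[float, float],
    slot: SlotSpec,
    geom: TaperGeometry,
    cfg: SimConfig,
) -> float:
    """Relative efficiency with which a source at (x, z) couples into a slot.

    Separable kernel: a smoothed axial top-hat over the slot's axial
    footprint times an exponential decay exp(-|x|/lobe_extent) off-axis.
    Peak value 1 for a source centered on the slot at zero off-axis offset.
    """
    from scipy.special import erf

    x, z = source
    zc = slot.z_center(geom)
    half = slot.slot_length / 2.0
    w = max(cfg.edge_width, 1e-9)
    # smoothed top-hat: convolution of a box with a Gaussian edge
    axial = 0.5 * (
        erf((z - (zc - half)) / (np.sqrt(2) * w))
        - erf((z - (zc + half)) / (np.sqrt(2) * w))
    )
    lateral = np.exp(-abs(x) / cfg.lobe_extent)
    return float(np.clip(axial, 0.0, 1.0) * lateral)


# ---------------------------------------------------------------------------
# rendering

_KT_CACHE: dict[RelayOptics, np.ndarray] = {}
_R_CACHE: dict[RelayOptics, np.ndarray] = {}


def _cached_kt(relay: RelayOptics) -> np.ndarray:
    if relay not in _KT_CACHE:
        _KT_CACHE[relay] = kt_grid(relay)
    return _KT_CACHE[relay]


def _cached_radius(relay: RelayOptics) -> np.ndarray:
    if relay not in _R_CACHE:
        nr, nc = relay.image_shape
        ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        _R_CACHE[relay] = pixel_radius(ii, jj, relay)
    return _R_CACHE[relay]


def annulus_model(
    k_lo: float, k_hi: float, amplitude: float, relay: RelayOptics
) -> np.ndarray:
    """Noiseless annulus: amplitude * (R_inner / R) on the band, 0 elsewhere.

    The 1/R profile makes the circumference-corrected k_t histogram flat
    over [k_lo, k_hi].  Amplitude is the value at the inner edge.
    """
    if not 0 <= k_lo < k_hi <= 1:
        raise ValueError("need 0 <= k_lo < k_hi <= 1")
    kt = _cached_kt(relay)
    rr = _cached_radius(relay)
    band = (kt >= k_lo) & (kt <= k_hi)
    model = np.zeros(relay.image_shape, dtype=float)
    if amplitude != 0 and band.any():
        r_inner = rr[band].min()
        with np.errstate(divide="ignore"):
            model[band] = amplitude * r_inner / np.maximum(rr[band], 1e-12)
    return model


def noiseless_slot_model(
    slot: SlotSpec,
    geom: TaperGeometry,
    relay: RelayOptics,
    amplitude: float = 1.0,
    band_fraction: float = 0.7,
) -> np.ndarray:
    """Noiseless far-field model of one slot's annular pattern."""
    a_local = slot.local_diameter / 2.0
    k_lo, k_hi = kt_band_for_section(a_local, geom, band_fraction)
    return annulus_model(k_lo, k_hi, amplitude, relay)


def apply_noise(
    model: np.ndarray,
    relay: RelayOptics,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> FarFieldImage:
    """Shared noise pipeline: blur -> Poisson -> dark -> quantize -> clip.

    With ``poisson_scale == 0`` the (blurred) model passes through
    deterministically and only the dark offset/noise is added.
    """
    if rng is None:
        rng = cfg.rng()
    out = np.asarray(model, dtype=float)
    if cfg.background is not None:
        out = out + cfg.background
    if cfg.blur_sigma > 0:
        out = gaussian_filter(out, sigma=cfg.blur_sigma)
    if cfg.poisson_scale > 0:
        out = rng.poisson(out * cfg.poisson_scale).astype(float) / cfg.poisson_scale
    if cfg.dark_mean > 0 or cfg.dark_sd > 0:
        out = out + rng.normal(cfg.dark_mean, cfg.dark_sd, size=out.shape)
        out = np.rint(out)
    out = np.clip(out, 0.0, 2**16 - 1)
    return FarFieldImage(
        intensity=out,
        pixel_pitch=relay.pixel_pitch,
        center=relay.center,
        bit_depth=16,
        meta=dict(meta or {}),
    )


def render_annulus(
    k_lo: float,
    k_hi: float,
    amplitude: float,
    relay: RelayOptics,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> FarFieldImage:
    """Render a single annular far-field pattern through the noise pipeline."""
    model = annulus_model(k_lo, k_hi, amplitude, relay)
    return apply_noise(
        model, relay, cfg, rng, meta={"k_lo": k_lo, "k_hi": k_hi, "amplitude": amplitude}
    )


def render_slot_pattern(
    slot: SlotSpec,
    geom: TaperGeometry,
    relay: RelayOptics,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    amplitude: float | None = None,
) -> FarFieldImage:
    """Render the versor-quality far-field pattern of a single slot."""
    amp = cfg.versor_amplitude if amplitude is None else amplitude
    model = noiseless_slot_model(slot, geom, relay, amp)
    return apply_noise(model, relay, cfg, rng, meta={"slot": slot.id, "amplitude": amp})


# Depth presets for simulated brain insertion: deeper implants activate more
# slots (the shallowest slot S1 enters the tissue first).
DEPTH_PRESETS = {
    "d1": (1.0, 0.0, 0.0),
    "d2": (1.0, 1.0, 0.0),
    "d3": (1.0, 1.0, 1.0),
}


def render_mixture(
    weights: Sequence[float],
    slots: Sequence[SlotSpec],
    geom: TaperGeometry,
    relay: RelayOptics,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    amplitude: float | None = None,
) -> FarFieldImage:
    """Render a weighted superposition of per-slot patterns (simultaneous
    collection through several slots), then the shared noise pipeline."""
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(slots):
        raise ValueError("one weight per slot required")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0):
        raise ValueError("at least one weight must be positive")
    amp = cfg.versor_amplitude if amplitude is None else amplitude
    model = np.zeros(relay.image_shape, dtype=float)
    for w, slot in zip(weights, slots):
        if w > 0:
            model += w * noiseless_slot_model(slot, geom, relay, amp)
    return apply_noise(
        model, relay, cfg, rng, meta={"weights": weights.tolist(), "amplitude": amp}
    )


def _taper_segments(geom: TaperGeometry, segment_um: float = 50.0) -> list[SlotSpec]:
    """Discretize a bare (slotless) taper into axial segments, each treated
    as a micro-slot, so continuous k_t(x, z) maps can be simulated."""
    segs = []
    z = segment_um / 2.0
    k = 0
    while z < geom.EL:
        d = 2.0 * min(geom.a0, z * geom.tan_psi)
        if d > 1.0:  # skip the sub-micrometer apex
            segs.append(
                SlotSpec(f"seg{k}", local_diameter=d, slot_length=segment_um, z_um=z)
            )
            k += 1
        z += segment_um
    return segs


def simulate_scan_stack(
    grid: ScanGrid,
    geom: TaperGeometry,
    relay: RelayOptics,
    cfg: SimConfig,
    slots: Sequence[SlotSpec] | None = None,
) -> list[FarFieldImage]:
    """One far-field image per grid point, in grid (row-major) order.

    Each point source couples through every slot with its collection
    efficiency as amplitude; ``slots=None`` simulates a bare taper by
    discretizing the collection length into axial segments.  Frame
    randomness is drawn from independent child streams of ``cfg.seed`` so
    the stack is reproducible regardless of chunking.
    """
    if slots is None:
        slots = _taper_segments(geom)
    slots = list(slots)
    # noiseless per-slot patterns are position-independent; cache them
    patterns = [
        noiseless_slot_model(s, geom, relay, cfg.source_amplitude) for s in slots
    ]
    children = np.random.SeedSequence(cfg.seed).spawn(grid.n_points)
    stack: list[FarFieldImage] = []
    for p, (x, z) in enumerate(grid.points):
        effs = [collection_efficiency((x, z), s, geom, cfg) for s in slots]
        model = np.zeros(relay.image_shape, dtype=float)
        for eff, pat in zip(effs, patterns):
            if eff > 1e-12:
                model += eff * pat
        img = apply_noise(
            model,
            relay,
            cfg,
            rng=np.random.default_rng(children[p]),
            meta={
                "x": float(x),
                "z": float(z),
                "index": p,
                "noiseless_total": float(model.sum()),
                "efficiencies": {s.id: float(e) for s, e in zip(slots, effs)},
            },
        )
        stack.append(img)
    return stack


def make_background(
    relay: RelayOptics, amplitude: float = 200.0, sigma_k: float = 0.15
) -> np.ndarray:
    """Smooth autofluorescence-like background: a broad radial Gaussian in
    k-space, mimicking light generated inside the patch cord and taper."""
    kt = _cached_kt(relay)
    return amplitude * np.exp(-0.5 * (kt / sigma_k) ** 2)
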