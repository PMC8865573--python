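"""Shared fixtures: a coarse-sampled optical relay and one simulated
slotted-fiber characterization run reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ktdemux as kd
from ktdemux.classify import segment_rois
from ktdemux.extract import build_maps, default_params

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

SEED = 11


@pytest.fixture(scope="session")
def geom() -> kd.TaperGeometry:
    return kd.TaperGeometry()


@pytest.fixture(scope="session")
def relay() -> kd.RelayOptics:
    # same optical field as the 512x512 camera, sampled 128x128 for speed
    return kd.RelayOptics.coarse(128)


@pytest.fixture(scope="session")
def slots() -> list[kd.SlotSpec]:
    return kd.default_slots()


@pytest.fixture(scope="session")
def simcfg() -> kd.SimConfig:
    return kd.SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def params(relay, simcfg):
    return default_params(relay, simcfg.dark_mean, simcfg.dark_sd)


@pytest.fixture(scope="session")
def char_grid() -> kd.ScanGrid:
    return kd.grid_preset("slotted_tf")


@pytest.fixture(scope="session")
def char_stack(char_grid, geom, relay, simcfg, slots):
    """Default-noise characterization scan over the slotted-fiber grid."""
    return kd.simulate_scan_stack(char_grid, geom, relay, simcfg, slots)


@pytest.fixture(scope="session")
def char_maps(char_stack, char_grid, relay, params):
    return build_maps(char_stack, char_grid, relay, params)


@pytest.fixture(scope="session")
def rois(char_maps, slots, geom):
    ktmap, imap = char_maps
    return segment_rois(ktmap, imap, slots, geom)


@pytest.fixture(scope="session")
def uniform_basis(relay):
    """Three disjoint equal-area uniform versors on the slot bands.

    Supports are trimmed to a common pixel count so every versor has unit
    total mass and equal L2 mass — the regime where the Hadamard projection
    recovers mixture weights exactly.
    """
    from ktdemux.demux import build_versors
    from ktdemux.simulate import _cached_kt

    kt = _cached_kt(relay)
    geom = kd.TaperGeometry()
    bands = [
        kd.kt_band_for_section(s.local_diameter / 2.0, geom)
        for s in kd.default_slots()
    ]
    masks = [(kt >= lo) & (kt <= hi) for lo, hi in bands]
    n_min = min(int(m.sum()) for m in masks)
    supports = []
    for m in masks:
        idx = np.flatnonzero(m.ravel())[:n_min]
        mm = np.zeros(kt.size, dtype=bool)
        mm[idx] = True
        supports.append(mm.reshape(kt.shape).astype(float))
    return build_versors(supports, norm_kind="unit-sum"), supports
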