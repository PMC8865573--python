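"""Versor construction and Hadamard-projection demultiplexing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ktdemux as kd
from ktdemux.demux import (
    VersorDemultiplexer,
    build_versors,
    demux,
    orthogonality_matrix,
    overlap_images,
    percentage_matrix,
    project_coefficients,
)
from ktdemux.simulate import apply_noise, make_background, noiseless_slot_model


class TestBuildVersors:
    def test_delta_versor_has_unit_mass(self):
        a = np.zeros((8, 8))
        a[2, 3] = 7.0
        basis = build_versors([a, np.eye(8)], norm_kind="unit-sum")
        assert basis.versors[0].sum() == pytest.approx(1.0)
        assert basis.versors[0][2, 3] == pytest.approx(1.0)

    def test_background_subtraction_identity(self, relay):
        cfg = kd.SimConfig(seed=0).noiseless()
        ann = kd.render_annulus(0.1, 0.2, 100.0, relay, cfg).intensity
        bg = np.full(relay.image_shape, 30.0)
        basis = build_versors([ann + bg, bg + 1.0], background=bg)
        assert np.allclose(basis.versors[0], ann / ann.sum())

    def test_simulated_slot_versor_radii_increase(self, geom, relay, slots):
        imgs = [noiseless_slot_model(s, geom, relay, 100.0) for s in slots]
        basis = build_versors(imgs, labels=[s.id for s in slots])
        from ktdemux.simulate import _cached_kt

        kt = _cached_kt(relay)
        outer = [kt[v > 0].max() for v in basis.versors]
        assert outer[0] < outer[1] < outer[2]

    def test_zero_versor_rejected(self):
        bg = np.full((4, 4), 10.0)
        with pytest.raises(ValueError):
            build_versors([bg * 0.5, bg * 2], background=bg)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            build_versors([np.ones((4, 4))])


class TestOrthogonality:
    def test_disjoint_supports_score_zero(self, uniform_basis):
        basis, _ = uniform_basis
        gram = orthogonality_matrix(basis)
        assert np.allclose(np.diag(gram), 1.0)
        off = gram[~np.eye(basis.n, dtype=bool)]
        assert np.all(off == 0.0)

    def test_identical_versors_score_one(self):
        v = np.random.default_rng(0).uniform(0, 1, (6, 6))
        basis = build_versors([v, v.copy()])
        assert orthogonality_matrix(basis)[0, 1] == pytest.approx(1.0)

    def test_simulated_default_slots_nearly_orthogonal(self, geom, relay, slots):
        """Versor acquisitions in clear solution: max off-diagonal < 0.05."""
        cfg = kd.SimConfig(seed=5).clear_solution()
        bg = make_background(relay)
        rng = cfg.rng()
        imgs = [
            apply_noise(
                noiseless_slot_model(s, geom, relay, cfg.versor_amplitude) + bg,
                relay, cfg, rng=rng,
            )
            for s in slots
        ]
        bg_img = apply_noise(bg, relay, cfg, rng=rng)
        vd = VersorDemultiplexer().fit(imgs, background=bg_img)
        assert vd.max_overlap_ < 0.05


class TestProjection:
    def test_disjoint_pattern_gives_zero_overlap(self, uniform_basis):
        basis, supports = uniform_basis
        elsewhere = np.ones(basis.shape) - sum(s > 0 for s in supports)
        M = overlap_images(elsewhere, basis)
        assert all(m.sum() == 0.0 for m in M)

    def test_uniform_versor_overlap_proportional_to_pattern(self):
        v_unif = np.ones((6, 6))
        basis = build_versors([v_unif, np.eye(6)], norm_kind="max-1")
        pat = np.random.default_rng(1).uniform(0, 5, (6, 6))
        M = overlap_images(pat, basis)
        assert np.allclose(M[0], pat)

    def test_coefficients_are_total_mass(self):
        M = [np.zeros((5, 5)), np.full((5, 5), 2.0) * (np.arange(25).reshape(5, 5) < 10)]
        c = project_coefficients(M)
        assert c[0] == 0.0 and c[1] == 20.0

    def test_percentage_rows(self):
        m = percentage_matrix(np.array([[5.0, 0.0, 0.0]]))
        assert np.allclose(m, [[100.0, 0.0, 0.0]])
        z = percentage_matrix(np.array([[0.0, 0.0]]))
        assert np.isnan(z).all()

    @given(
        c=st.lists(
            st.lists(st.floats(0.0, 1e6), min_size=3, max_size=3),
            min_size=1,
            max_size=5,
        )
    )
    def test_rows_sum_to_100_whenever_defined(self, c):
        m = percentage_matrix(np.asarray(c))
        sums = np.nansum(m, axis=1)
        for row, s in zip(m, sums):
            if not np.isnan(row).any():
                assert s == pytest.approx(100.0, abs=1e-6)


class TestDemux:
    def test_versors_project_to_identity(self, uniform_basis):
        basis, _ = uniform_basis
        res = demux(list(basis.versors), basis)
        assert np.allclose(res.m, 100.0 * np.eye(basis.n), atol=1e-9)

    def test_exact_weight_recovery_noiseless(self, uniform_basis):
        basis, _ = uniform_basis
        W = np.array([[0.3, 0.7, 0.0], [0.2, 0.3, 0.5]])
        mixtures = [
            sum(w * v for w, v in zip(row, basis.versors)) for row in W
        ]
        res = demux(mixtures, basis)
        expect = 100.0 * W / W.sum(axis=1, keepdims=True)
        assert np.max(np.abs(res.m - expect)) < 1e-9

    def test_scale_invariance(self, uniform_basis):
        basis, _ = uniform_basis
        pat = 0.4 * basis.versors[0] + 0.6 * basis.versors[2]
        m1 = demux([pat], basis).m
        m2 = demux([173.0 * pat], basis).m
        assert np.allclose(m1, m2, atol=1e-9)

    def test_basis_permutation_permutes_columns(self, uniform_basis):
        basis, _ = uniform_basis
        from ktdemux.demux import VersorBasis

        perm = [2, 0, 1]
        permuted = VersorBasis(
            tuple(basis.versors[i] for i in perm),
            tuple(basis.labels[i] for i in perm),
            norm_kind=basis.norm_kind,
        )
        pat = 0.2 * basis.versors[0] + 0.8 * basis.versors[1]
        m1 = demux([pat], basis).m[0]
        m2 = demux([pat], permuted).m[0]
        assert np.allclose(m1[perm], m2, atol=1e-9)

    def test_crosstalk_bounded_by_overlap_score(self, geom, relay, slots):
        """Single-slot input leaks at most 100*s/(1+s) into other rows."""
        imgs = [noiseless_slot_model(s, geom, relay, 1000.0) for s in slots]
        basis = build_versors(imgs)
        gram = orthogonality_matrix(basis)
        res = demux([imgs[0]], basis)
        for j in (1, 2):
            s = gram[0, j]
            assert res.m[0, j] <= 100.0 * s / (1.0 + s) + 1e-9

    def test_depth_series_activates_growing_slot_sets(self, geom, relay, slots):
        """Deeper simulated implants spread signal over more apertures."""
        from dataclasses import replace

        from ktdemux.simulate import DEPTH_PRESETS, render_mixture

        cfg = kd.SimConfig(seed=5)
        vc = cfg.clear_solution()
        bg = make_background(relay)
        rng = vc.rng()
        imgs = [
            apply_noise(
                noiseless_slot_model(s, geom, relay, vc.versor_amplitude) + bg,
                relay, vc, rng=rng,
            )
            for s in slots
        ]
        bg_img = apply_noise(bg, relay, vc, rng=rng)
        vd = VersorDemultiplexer().fit(imgs, background=bg_img)
        cfg_bg = replace(cfg, background=bg)
        mixed = [
            render_mixture(DEPTH_PRESETS[d], slots, geom, relay, cfg_bg, rng=rng)
            for d in ("d1", "d2", "d3")
        ]
        m = vd.transform(mixed)
        # shallow implant: S1 dominant; mid: S3 negligible; deep: all active
        assert m[0, 0] > 90.0
        assert m[1, 2] < 5.0
        assert np.all(m[2] > 10.0)
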