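import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from wcetex.config import PipelineConfig
from wcetex.glcm_features import (
    DIRECTION_ORDER,
    DIRECTIONS,
    CooccurrenceMatrix,
    QuantizedPlane,
    cooccurrence_matrix,
    descriptor_tensor,
    haralick_features,
    quantize_plane,
)
from wcetex.image_io import HSVFrame
from wcetex.synthetic_data import fixture_plane
from wcetex.wavelet_synthesis import decompose, synthesize_focus_image


def brute_force_cooccurrence(levels, mask, n_levels, direction, distance, symmetric):
    """Exhaustive ordered pair enumeration by an explicit double loop."""
    dr, dc = DIRECTIONS[direction]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    return counts / counts.sum()


def direct_haralick(p, idm_form="standard", entropy_sign="negative"):
    """Scalar-loop evaluation of the four descriptor formulas."""
    ng = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    g = np.arange(ng)
    mux, muy = float(g @ px), float(g @ py)
    sx = float(np.sqrt(((g - mux) ** 2) @ px))
    sy = float(np.sqrt(((g - muy) ** 2) @ py))
    f1 = f2num = f3 = f4 = 0.0
    for i in range(ng):
        for j in range(ng):
            f1 += p[i, j] ** 2
            f2num += i * j * p[i, j]
            if idm_form == "standard":
                f3 += p[i, j] / (1 + (i - j) ** 2)
            elif j != i + 1:
                f3 += p[i, j] / (1 + (i - j))
            if p[i, j] > 0:
                f4 += p[i, j] * np.log2(p[i, j])
    f2 = 0.0 if sx * sy == 0 else (f2num - mux * muy) / (sx * sy)
    if entropy_sign == "negative":
        f4 = -f4
    return np.array([f1, f2, f3, f4])


class TestQuantize:
    def test_constant_plane_maps_to_level_zero(self):
        q = quantize_plane(np.full((8, 8), 2.5), np.ones((8, 8), bool), 32)
        assert (q.levels == 0).all()

    def test_ramp_matches_floor_oracle(self):
        ramp = np.tile(np.linspace(0.0, 1.0, 64), (8, 1))
        q = quantize_plane(ramp, np.ones((8, 64), bool), 32)
        oracle = np.floor(31 * ramp).astype(int)
        oracle[ramp == 1.0] = 31
        np.testing.assert_array_equal(q.levels, oracle)

    def test_masked_pixels_hold_sentinel(self, rng):
        mask = rng.random((8, 8)) > 0.5
        q = quantize_plane(rng.normal(size=(8, 8)), mask, 8)
        assert (q.levels[~mask] == -1).all()
        assert q.levels[mask].min() >= 0 and q.levels[mask].max() <= 7

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            quantize_plane(np.zeros((8, 8)), np.zeros((8, 8), bool), 32)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        plane=hnp.arrays(
            np.float64,
            (6, 6),
            elements=st.floats(-100, 100, allow_nan=False),
        ),
        n_levels=st.integers(2, 64),
    )
    def test_levels_always_in_range(self, plane, n_levels):
        """Property: every unmasked level lies in [0, n_levels - 1]."""
        q = quantize_plane(plane, np.ones((6, 6), bool), n_levels)
        assert q.levels.min() >= 0
        assert q.levels.max() <= n_levels - 1

    def test_range_dispersion_uses_full_scale(self, rng):
        """Min-max dispersion: both extreme levels are hit."""
        q = quantize_plane(rng.normal(size=(64, 64)), np.ones((64, 64), bool), 32)
        assert q.levels.min() == 0 and q.levels.max() == 31


class TestCooccurrence:
    def test_constant_2x2_single_entry(self):
        q = QuantizedPlane(np.full((2, 2), 5), 32, np.ones((2, 2), bool))
        c = cooccurrence_matrix(q, 0, 1, symmetric=False)
        assert c.p[5, 5] == 1.0
        assert c.p.sum() == 1.0
        assert c.pair_count == 2

    def test_fixture_plane_matches_brute_force(self):
        levels = fixture_plane("glcm4x4")
        mask = np.ones((4, 4), bool)
        q = QuantizedPlane(levels, 4, mask)
        for symmetric in (False, True):
            for ang in DIRECTION_ORDER:
                c = cooccurrence_matrix(q, ang, 1, symmetric=symmetric)
                oracle = brute_force_cooccurrence(levels, mask, 4, ang, 1, symmetric)
                np.testing.assert_array_equal(c.p, oracle)

    def test_random_masked_planes_match_brute_force(self, rng):
        """Exact agreement with exhaustive pair enumeration, 50 masked planes."""
        for _ in range(50):
            h, w = rng.integers(3, 9, size=2)
            levels = rng.integers(0, 5, size=(h, w))
            mask = rng.random((h, w)) > 0.3
            q = QuantizedPlane(np.where(mask, levels, -1), 5, mask)
            ang = int(rng.choice(DIRECTION_ORDER))
            sym = bool(rng.random() > 0.5)
            try:
                c = cooccurrence_matrix(q, ang, 1, symmetric=sym)
            except ValueError:
                # mask admits no pair at this displacement; oracle agrees
                dr, dc = DIRECTIONS[ang]
                pairs = 0
                for r in range(h):
                    for cc in range(w):
                        r2, c2 = r + dr, cc + dc
                        if 0 <= r2 < h and 0 <= c2 < w and mask[r, cc] and mask[r2, c2]:
                            pairs += 1
                assert pairs == 0
                continue
            oracle = brute_force_cooccurrence(levels, mask, 5, ang, 1, sym)
            np.testing.assert_array_equal(c.p, oracle)

    def test_normalization(self, rng):
        q = quantize_plane(rng.normal(size=(16, 16)), np.ones((16, 16), bool), 8)
        for ang in DIRECTION_ORDER:
            c = cooccurrence_matrix(q, ang)
            assert abs(c.p.sum() - 1.0) < 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        levels=hnp.arrays(np.int64, (5, 7), elements=st.integers(0, 3)),
        ang=st.sampled_from(DIRECTION_ORDER),
        sym=st.booleans(),
    )
    def test_probability_mass_property(self, levels, ang, sym):
        """Property: the matrix is a probability distribution regardless of
        plane content, direction or accumulation mode."""
        q = QuantizedPlane(levels, 4, np.ones((5, 7), bool))
        c = cooccurrence_matrix(q, ang, 1, symmetric=sym)
        assert abs(c.p.sum() - 1.0) < 1e-9
        assert (c.p >= 0).all()

    def test_symmetric_matrix_is_symmetric(self, rng):
        q = quantize_plane(rng.normal(size=(12, 12)), np.ones((12, 12), bool), 6)
        c = cooccurrence_matrix(q, 45, symmetric=True)
        np.testing.assert_array_equal(c.p, c.p.T)

    def test_no_valid_pairs_raises(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[3, 3] = True  # no neighbouring unmasked pair at d=1
        q = QuantizedPlane(np.where(mask, 0, -1), 4, mask)
        with pytest.raises(ValueError, match="no valid pairs"):
            cooccurrence_matrix(q, 0, 1)


class TestHaralick:
    def test_single_entry_matrix(self):
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        c = CooccurrenceMatrix(p, 0, 1, 1, True)
        for idm in ("standard", "as_printed"):
            hv = haralick_features(c, idm_form=idm)
            assert hv.f1 == 1.0
            assert hv.f2 == 0.0  # degenerate marginals
            assert hv.f3 == 1.0
            assert hv.f4 == 0.0

    def test_uniform_matrix_closed_form(self):
        ng = 4
        p = np.full((ng, ng), 1.0 / ng**2)
        hv = haralick_features(CooccurrenceMatrix(p, 0, 1, 1, True))
        assert np.isclose(hv.f1, 1.0 / ng**2)
        assert np.isclose(hv.f4, np.log2(ng**2))

    def test_fixture_matrix_matches_direct_summation(self):
        levels = fixture_plane("glcm4x4")
        q = QuantizedPlane(levels, 4, np.ones((4, 4), bool))
        c = cooccurrence_matrix(q, 0, 1, symmetric=False)
        for idm in ("standard", "as_printed"):
            for sign in ("negative", "as_printed"):
                hv = haralick_features(c, idm_form=idm, entropy_sign=sign)
                np.testing.assert_allclose(hv.as_array(), direct_haralick(c.p, idm, sign))

    def test_random_matrices_match_direct_summation(self, rng):
        for _ in range(20):
            raw = rng.random((6, 6)) * (rng.random((6, 6)) > 0.3)
            if raw.sum() == 0:
                continue
            p = raw / raw.sum()
            c = CooccurrenceMatrix(p, 0, 1, 1, False)
            hv = haralick_features(c)
            np.testing.assert_allclose(hv.as_array(), direct_haralick(p), rtol=1e-12)

    def test_f1_f4_invariant_to_level_relabeling(self, rng):
        raw = rng.random((8, 8))
        p = raw / raw.sum()
        perm = rng.permutation(8)
        pp = p[np.ix_(perm, perm)]
        a = haralick_features(CooccurrenceMatrix(p, 0, 1, 1, False))
        b = haralick_features(CooccurrenceMatrix(pp, 0, 1, 1, False))
        assert np.isclose(a.f1, b.f1)
        assert np.isclose(a.f4, b.f4)

    def test_f2_invariant_to_affine_level_shift(self, rng):
        """Embedding the matrix further down the diagonal shifts both
        marginals equally and leaves the correlation unchanged."""
        raw = rng.random((5, 5))
        p = raw / raw.sum()
        shifted = np.zeros((9, 9))
        shifted[4:, 4:] = p
        a = haralick_features(CooccurrenceMatrix(p, 0, 1, 1, False))
        b = haralick_features(CooccurrenceMatrix(shifted, 0, 1, 1, False))
        assert np.isclose(a.f2, b.f2)


class TestDescriptorTensor:
    def test_shape_and_finiteness(self, small_frame, default_cfg):
        from wcetex.pipeline import frame_tensor

        t = frame_tensor(small_frame, default_cfg)
        assert t.shape == (4, 4, 3, 2)
        assert np.isfinite(t).all()

    def test_constant_frame_equals_constant_image_descriptors(self):
        channels = np.full((3, 32, 32), 0.5)
        frame = HSVFrame(channels=channels, mask=np.ones((32, 32), bool))
        t = descriptor_tensor(frame)
        # each cell must equal the constant-image Haralick vector (F1=1, F2=0,
        # F3=1, F4=0): the zero detail reconstruction quantizes to level 0
        expected = np.array([1.0, 0.0, 1.0, 0.0])
        for ai in range(4):
            for ci in range(3):
                for fj in range(2):
                    np.testing.assert_allclose(t[:, ai, ci, fj], expected)

    def test_matches_manual_stage_composition(self, hsv_frame, default_cfg):
        t = descriptor_tensor(hsv_frame, default_cfg)
        for ci in range(3):
            sb = decompose(
                hsv_frame.channels[ci], default_cfg.wavelet, default_cfg.transform_variant
            )
            for fj in (1, 2):
                syn = synthesize_focus_image(sb, fj)
                q = quantize_plane(syn, hsv_frame.mask, default_cfg.n_levels)
                for ai, ang in enumerate(DIRECTION_ORDER):
                    c = cooccurrence_matrix(q, ang, default_cfg.distance, default_cfg.symmetric)
                    hv = haralick_features(c, default_cfg.idm_form, default_cfg.entropy_sign)
                    np.testing.assert_array_equal(t[:, ai, ci, fj - 1], hv.as_array())

    def test_rotation_permutes_direction_axis_identity_mode(self, rng):
        """A 90-degree frame rotation swaps the 0- and 90-degree matrices;
        exact when the wavelet stage is bypassed."""
        cfg = PipelineConfig(transform_variant="identity", symmetric=True)
        ch = rng.random((3, 16, 16))
        frame = HSVFrame(channels=ch, mask=np.ones((16, 16), bool))
        rot = HSVFrame(
            channels=np.rot90(ch, k=1, axes=(1, 2)).copy(), mask=np.ones((16, 16), bool)
        )
        t = descriptor_tensor(frame, cfg)
        tr = descriptor_tensor(rot, cfg)
        a0, a90 = DIRECTION_ORDER.index(0), DIRECTION_ORDER.index(90)
        np.testing.assert_allclose(t[:, a0], tr[:, a90], atol=1e-12)
        np.testing.assert_allclose(t[:, a90], tr[:, a0], atol=1e-12)
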