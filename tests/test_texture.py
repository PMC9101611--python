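import math

import numpy as np
import pytest

from lesiontex.preprocess import normalize_and_quantize
from lesiontex.texture import (
    CooccurrenceMatrix,
    Direction,
    TextureConfig,
    compute_glcm,
    compute_indices,
    compute_rlm,
    feature_vector,
    glcm_difference_entropy,
    glcm_entropy,
    long_run_emphasis,
    offsets_for_distance,
)
from oracles import (
    naive_difference_entropy,
    naive_entropy,
    naive_glcm,
    naive_long_run_emphasis,
    naive_rlm,
)

DIRECTIONS = list(Direction)


class TestCooccurrence:
    def test_two_column_example(self, quantized_factory):
        # [[1,2],[1,2]] at offset (0,1): only (1,2) pairs
        q = quantized_factory([[1, 2], [1, 2]], ng=2)
        m = compute_glcm(q, (0, 1))
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(m.p, expected)
        assert glcm_entropy(m) == pytest.approx(math.log(2))
        assert glcm_difference_entropy(m) == pytest.approx(0.0)

    def test_constant_input_single_cell(self, quantized_factory):
        q = quantized_factory(np.full((6, 6), 3), ng=4)
        m = compute_glcm(q, (1, 1))
        assert m.p[2, 2] == 1.0
        assert glcm_entropy(m) == 0.0
        assert glcm_difference_entropy(m) == pytest.approx(0.0)

    def test_mixed_pairs_difference_entropy(self):
        # hand-built matrix: q(0)=q(1)=0.5 -> log 2
        p = np.array([[0.25, 0.25], [0.25, 0.25]])
        m = CooccurrenceMatrix(p, offset=(0, 1), ng=2, pair_count=8)
        assert glcm_difference_entropy(m) == pytest.approx(math.log(2))

    def test_uniform_matrix_entropy_is_maximal(self):
        ng = 8
        m = CooccurrenceMatrix(
            np.full((ng, ng), 1 / ng**2), offset=(0, 1), ng=ng, pair_count=ng * ng
        )
        assert glcm_entropy(m) == pytest.approx(math.log(ng**2))

    def test_normalization_and_symmetry_invariants(self, rng, quantized_factory):
        q = quantized_factory(rng.integers(1, 9, (16, 16)), ng=8)
        for offset in [(0, 3), (2, 0), (3, 3), (2, -2)]:
            m = compute_glcm(q, offset)
            assert m.p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(m.p, m.p.T)
            m_neg = compute_glcm(q, (-offset[0], -offset[1]))
            np.testing.assert_allclose(m.p, m_neg.p)

    def test_invalid_offsets(self, quantized_factory):
        q = quantized_factory(np.ones((4, 4), int), ng=2)
        with pytest.raises(ValueError):
            compute_glcm(q, (0, 0))
        with pytest.raises(ValueError):
            compute_glcm(q, (4, 0))

    def test_unnormalized_matrix_rejected(self):
        m = CooccurrenceMatrix(np.full((2, 2), 0.3), offset=(0, 1), ng=2, pair_count=4)
        with pytest.raises(ValueError, match="not normalized"):
            glcm_entropy(m)


class TestRunLength:
    def test_single_row_run_decomposition(self, quantized_factory):
        q = quantized_factory([[1, 1, 2, 2, 2, 1]], ng=2)
        rlm = compute_rlm(q, "horizontal")
        assert rlm.r[0, 1] == 1  # level 1, length 2
        assert rlm.r[1, 2] == 1  # level 2, length 3
        assert rlm.r[0, 0] == 1  # level 1, length 1
        assert rlm.total_runs == 3
        assert long_run_emphasis(rlm) == pytest.approx(14 / 3)

    def test_checkerboard_attains_lower_bound(self, quantized_factory):
        n = 8
        board = 1 + (np.add.outer(np.arange(n), np.arange(n)) % 2)
        q = quantized_factory(board, ng=2)
        for d in ("horizontal", "vertical"):
            rlm = compute_rlm(q, d)
            assert long_run_emphasis(rlm) == 1.0
            assert rlm.total_runs == n * n

    def test_constant_square_single_runs(self, quantized_factory):
        w = 12
        q = quantized_factory(np.full((w, w), 2), ng=3)
        rlm = compute_rlm(q, "horizontal")
        assert rlm.r[1, w - 1] == w  # w runs of length w
        assert long_run_emphasis(rlm) == w * w

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_pixel_count_conservation(self, rng, quantized_factory, direction):
        q = quantized_factory(rng.integers(1, 5, (13, 13)), ng=4)
        rlm = compute_rlm(q, direction)
        k = np.arange(1, rlm.nr + 1)
        assert (k * rlm.r.sum(axis=0)).sum() == 13 * 13

    def test_empty_matrix_rejected(self, quantized_factory):
        from lesiontex.texture import RunLengthMatrix

        empty = RunLengthMatrix(np.zeros((2, 4), int), Direction.HORIZONTAL, ng=2, nr=4)
        with pytest.raises(ValueError):
            long_run_emphasis(empty)


class TestOracleEquivalence:
    """Vectorized builders against brute-force enumeration."""

    def test_matrices_and_features_match_bruteforce(self, quantized_factory):
        rng = np.random.default_rng(12345)
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1), (0, 3), (2, -2)]
        for _ in range(30):
            side = int(rng.integers(8, 33))
            ng = int(rng.choice([4, 8, 16]))
            q = quantized_factory(rng.integers(1, ng + 1, (side, side)), ng=ng)
            off = offsets[int(rng.integers(len(offsets)))]
            m = compute_glcm(q, off)
            ref_p = naive_glcm(q.levels, ng, off)
            np.testing.assert_array_equal(m.p, ref_p)
            assert glcm_entropy(m) == pytest.approx(naive_entropy(ref_p), abs=1e-10)
            assert glcm_difference_entropy(m) == pytest.approx(
                naive_difference_entropy(ref_p), abs=1e-10
            )
            d = DIRECTIONS[int(rng.integers(4))]
            rlm = compute_rlm(q, d)
            ref_r = naive_rlm(q.levels, ng, d.value)
            np.testing.assert_array_equal(rlm.r, ref_r)
            assert long_run_emphasis(rlm) == pytest.approx(
                naive_long_run_emphasis(ref_r), abs=1e-10
            )


class TestFeatureVector:
    def test_constant_roi_closed_forms(self):
        q = normalize_and_quantize(np.full((32, 32), 120, np.uint8), ng=64)
        fv = feature_vector(q)
        assert fv.entropy == 0.0
        assert fv.difentrp == 0.0
        assert fv.ti == 0.0 and fv.bi == 0.0
        # horizontal direction: one maximal run per row of the full width
        assert fv.per_direction["horizontal"]["lngremph"] == 32 * 32

    def test_aggregate_is_mean_of_directions(self, rng, quantized_factory):
        q = quantized_factory(rng.integers(1, 9, (32, 32)), ng=8)
        fv = feature_vector(q, TextureConfig(distance=5))
        per = fv.per_direction
        for name, agg in (("entropy", fv.entropy), ("difentrp", fv.difentrp),
                          ("lngremph", fv.lngremph)):
            assert agg == pytest.approx(np.mean([per[d.value][name] for d in DIRECTIONS]))

    def test_entropy_matches_independent_offset_computation(self, rng, quantized_factory):
        q = quantized_factory(rng.integers(1, 5, (32, 32)), ng=4)
        fv = feature_vector(q, TextureConfig(distance=5))
        ref = np.mean(
            [naive_entropy(naive_glcm(q.levels, 4, off))
             for off in offsets_for_distance(5).values()]
        )
        assert fv.entropy == pytest.approx(ref, abs=1e-10)

    def test_index_identities(self, rng, quantized_factory):
        for _ in range(5):
            q = quantized_factory(rng.integers(1, 17, (24, 24)), ng=16)
            fv = feature_vector(q)
            assert fv.ti * fv.lngremph == pytest.approx(fv.entropy, abs=1e-12)
            assert fv.bi * fv.lngremph == pytest.approx(fv.difentrp, abs=1e-12)

    def test_rotation_consistency(self, rng, quantized_factory):
        q = quantized_factory(rng.integers(1, 9, (20, 20)), ng=8)
        q_rot = quantized_factory(np.rot90(q.levels), ng=8)
        fv, fv_rot = feature_vector(q), feature_vector(q_rot)
        swap = {"horizontal": "vertical", "vertical": "horizontal",
                "diag45": "diag135", "diag135": "diag45"}
        for d, d2 in swap.items():
            for name in ("entropy", "difentrp", "lngremph"):
                assert fv.per_direction[d][name] == pytest.approx(
                    fv_rot.per_direction[d2][name], abs=1e-12
                )
        assert fv.entropy == pytest.approx(fv_rot.entropy, abs=1e-12)
        assert fv.lngremph == pytest.approx(fv_rot.lngremph, abs=1e-12)

    def test_log_base_rescales_entropies(self, rng, quantized_factory):
        q = quantized_factory(rng.integers(1, 9, (16, 16)), ng=8)
        nat = feature_vector(q, TextureConfig(distance=3))
        b10 = feature_vector(q, TextureConfig(distance=3, log_base=10))
        assert b10.entropy == pytest.approx(nat.entropy / math.log(10))
        assert b10.difentrp == pytest.approx(nat.difentrp / math.log(10))
        assert b10.lngremph == nat.lngremph  # run lengths unaffected

    def test_feature_bounds(self, rng, quantized_factory):
        ng = 8
        q = quantized_factory(rng.integers(1, ng + 1, (16, 16)), ng=ng)
        fv = feature_vector(q, TextureConfig(distance=2))
        assert 0 <= fv.entropy <= math.log(ng**2)
        assert 0 <= fv.difentrp <= math.log(ng)
        assert 1 <= fv.lngremph <= 16 * 16

    def test_compute_indices_contract(self):
        assert compute_indices(2.0, 0.9, 4.0) == (0.5, 0.225)
        assert compute_indices(0.0, 0.0, 7.0) == (0.0, 0.0)
        with pytest.raises(ValueError):
            compute_indices(1.0, 1.0, 0.0)


def test_structure_response_monotone_in_correlation_length():
    """Smoother random fields -> longer runs and lower entropy."""
    from lesiontex.synthetic_data import GeneratorParams, generate_roi

    lre_means, ent_means = [], []
    for corr in (0.0, 1.0, 2.5, 5.0):
        lre, ent = [], []
        for seed in range(5):
            params = GeneratorParams(side=96, correlation_length=corr,
                                     noise_sd=2.0, seed=seed)
            fv = feature_vector(normalize_and_quantize(generate_roi(params)))
            lre.append(fv.lngremph)
            ent.append(fv.entropy)
        lre_means.append(np.mean(lre))
        ent_means.append(np.mean(ent))
    assert all(a < b for a, b in zip(lre_means, lre_means[1:]))
    assert all(a > b for a, b in zip(ent_means, ent_means[1:]))


class TestSkimageCrossCheck:
    """The GLCM builder against scikit-image's graycomatrix."""

    def test_four_direction_matrices_match_graycomatrix(self, rng, quantized_factory):
        from skimage.feature import graycomatrix

        d = 3
        levels = rng.integers(1, 9, (20, 20))
        q = quantized_factory(levels, ng=8)
        mine = {name: compute_glcm(q, off).p
                for name, off in offsets_for_distance(d).items()}
        img = (levels - 1).astype(np.uint8)
        # skimage offsets are (round(d sin a), round(d cos a)): the axial
        # directions use distance d, the diagonals d*sqrt(2) (grid steps)
        axial = graycomatrix(img, [d], [0, np.pi / 2], levels=8,
                             symmetric=True, normed=True)
        diag = graycomatrix(img, [d * np.sqrt(2)], [np.pi / 4, 3 * np.pi / 4],
                            levels=8, symmetric=True, normed=True)
        pairs = [
            (Direction.HORIZONTAL, axial[:, :, 0, 0]),
            (Direction.VERTICAL, axial[:, :, 0, 1]),
            (Direction.DIAG45, diag[:, :, 0, 0]),
            (Direction.DIAG135, diag[:, :, 0, 1]),
        ]
        matched = 0
        for direction, p_sk in pairs:
            for p_mine in mine.values():
                if np.allclose(p_mine, p_sk, atol=1e-12):
                    matched += 1
                    break
        assert matched == 4


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_quantized


@given(arrays(np.int64, (10, 10), elements=st.integers(min_value=1, max_value=6)))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_run_decomposition_conserves_pixels_property(levels):
    """Along every direction the maximal runs tile the image exactly."""
    q = make_quantized(levels, ng=6)
    for d in Direction:
        rlm = compute_rlm(q, d)
        k = np.arange(1, rlm.nr + 1)
        assert int((k * rlm.r.sum(axis=0)).sum()) == levels.size
        assert long_run_emphasis(rlm) >= 1.0


@given(
    arrays(np.int64, (12, 12), elements=st.integers(min_value=1, max_value=5)),
    st.sampled_from([(0, 1), (1, 0), (2, 2), (1, -3)]),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_glcm_is_probability_distribution_property(levels, offset):
    """Any input yields a symmetric matrix summing to one."""
    m = compute_glcm(make_quantized(levels, ng=5), offset)
    assert abs(m.p.sum() - 1.0) < 1e-12
    assert np.all(m.p >= 0)
    np.testing.assert_allclose(m.p, m.p.T)
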