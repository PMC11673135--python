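"""Similarity and quality metrics: analytic identities, loop oracles, printed cells."""

import math

import numpy as np
import pytest

from regstack import (
    RigidTransform,
    brenner_gradient,
    correlation_coefficient,
    energy_of_gradient,
    entropy,
    gray_level,
    joint_histogram,
    metric_report,
    mmd,
    mse,
    mutual_information,
    registration_accuracy,
    rmse,
    standard_deviation,
)


@pytest.fixture
def random_pair(rng):
    a = rng.integers(0, 256, (64, 64)).astype(float)
    b = rng.integers(0, 256, (64, 64)).astype(float)
    return a, b


class TestMseRmse:
    def test_identical_zero(self, random_pair):
        a, _ = random_pair
        assert mse(a, a, RigidTransform()) == 0.0

    def test_constant_difference_closed_form(self):
        assert mse(np.zeros((8, 8)), np.full((8, 8), 2.0)) == 4.0
        assert rmse(np.full((8, 8), 5.0), np.full((8, 8), 2.0)) == 3.0

    def test_loop_oracle(self, random_pair):
        a, b = random_pair
        total = 0.0
        for r in range(64):
            for c in range(64):
                total += (a[r, c] - b[r, c]) ** 2
        assert mse(a, b) == pytest.approx(total / 64 / 64)

    def test_rmse_squared_equals_mse_exactly(self, random_pair):
        a, b = random_pair
        assert rmse(a, b) ** 2 == pytest.approx(mse(a, b), rel=1e-14)

    def test_warped_mse_matches_explicit_warp(self, smooth_image):
        from regstack import apply_rigid_transform

        t = RigidTransform(4.5, -3.25, 6.0)
        explicit = float(np.mean((smooth_image - apply_rigid_transform(smooth_image, t)) ** 2))
        assert mse(smooth_image, smooth_image, t) == pytest.approx(explicit, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestCorrelation:
    def test_self_correlation_is_one(self, random_pair):
        a, _ = random_pair
        assert correlation_coefficient(a, a) == pytest.approx(1.0)

    def test_negated_affine_is_minus_one(self, random_pair):
        a, _ = random_pair
        assert correlation_coefficient(a, -a + 300.0) == pytest.approx(-1.0)

    def test_textbook_formula_oracle(self, random_pair):
        a, b = random_pair
        am, bm = a.mean(), b.mean()
        num = float(np.sum((a - am) * (b - bm)))
        den = math.sqrt(float(np.sum((a - am) ** 2)) * float(np.sum((b - bm) ** 2)))
        assert correlation_coefficient(a, b) == pytest.approx(num / den)

    def test_affine_invariance_and_sign_flip(self, random_pair):
        a, b = random_pair
        cc = correlation_coefficient(a, b)
        assert correlation_coefficient(2.5 * a + 10, b) == pytest.approx(cc)
        assert correlation_coefficient(-a, b) == pytest.approx(-cc)

    def test_constant_image_rejected(self, random_pair):
        a, _ = random_pair
        with pytest.raises(ValueError):
            correlation_coefficient(a, np.full_like(a, 9.0))


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        # k equiprobable levels: MI(a, a) = H(a) = log2(k)
        levels = np.repeat([0.0, 85.0, 170.0, 255.0], 16)
        a = rng.permutation(levels).reshape(8, 8)
        assert mutual_information(a, a) == pytest.approx(2.0)
        assert mutual_information(a, a) == pytest.approx(entropy(a))

    def test_self_information_identity_random(self, random_pair):
        a, _ = random_pair
        assert mutual_information(a, a) == pytest.approx(entropy(a), rel=1e-12)

    def test_independence_gives_zero(self, rng):
        a = np.full((8, 8), 100.0)  # constant carries no information
        b = rng.integers(0, 256, (8, 8)).astype(float)
        assert mutual_information(b, a) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_joint_table(self):
        # counts {(0,0): 2, (255,255): 2} over 4 pixels -> 1 bit
        a = np.array([[0.0, 0.0], [255.0, 255.0]])
        assert mutual_information(a, a, bins=2) == pytest.approx(1.0)

    def test_symmetric_and_nonnegative(self, random_pair):
        a, b = random_pair
        mab = mutual_information(a, b, bins=32)
        assert mab == pytest.approx(mutual_information(b, a, bins=32))
        assert mab >= 0.0

    def test_joint_histogram_marginals(self, random_pair):
        a, b = random_pair
        h = joint_histogram(a, b, bins=64)
        assert h.sum() == a.size
        marg = h.sum(axis=1)
        own = np.bincount(
            np.clip(np.rint(a.ravel() / (255 / 63)), 0, 63).astype(int), minlength=64
        )
        assert np.array_equal(marg, own)


# (true params, estimated params, printed accuracy %) — all 16 published cells
PRINTED_ACCURACY_CELLS = [
    ((20, 20, 0.5), (19.025, 19.600, 0.505), 97.375),
    ((20, 20, 0.5), (20.009, 19.966, 0.500), 99.928),
    ((30, 25, -5), (29.415, 24.541, -5.170), 97.605),
    ((30, 25, -5), (30.055, 24.990, -5.000), 99.925),
    ((50, -50, 10), (49.990, -50.689, 10.180), 98.934),
    ((50, -50, 10), (50.027, -49.955, 10.004), 99.939),
    ((10, 10, -15), (9.599, 10.059, -15.032), 98.396),
    ((10, 10, -15), (9.959, 10.089, -15.000), 99.566),
    ((5, 5, 0.2), (5.016, 5.239, 0.201), 98.133),
    ((5, 5, 0.2), (5.008, 5.002, 0.200), 99.933),
    ((50, 45, -10), (50.606, 44.898, -10.160), 98.987),
    ((50, 45, -10), (49.891, 45.013, -10.000), 99.918),
    ((25, -20, 5), (24.596, -20.193, 5.120), 98.340),
    ((25, -20, 5), (25.059, -20.090, 5.000), 99.771),
    ((-80, 60, 15), (-79.299, 60.703, 15.120), 99.051),
    ((-80, 60, 15), (-79.878, 60.025, 15.000), 99.935),
]


class TestRegistrationAccuracy:
    def test_perfect_recovery_is_100(self):
        t = RigidTransform(20, 20, 0.5)
        assert registration_accuracy(t, t) == 100.0

    @pytest.mark.parametrize("true,est,expected", PRINTED_ACCURACY_CELLS)
    def test_published_accuracy_cells(self, true, est, expected):
        # agreement at the printed precision: the published displacements are
        # themselves rounded to 3 decimals, so the accuracy recomputed from
        # them can differ from the published cell by one unit in the last place
        acc = registration_accuracy(RigidTransform(*true), RigidTransform(*est))
        assert round(abs(acc - expected), 4) <= 0.001

    def test_zero_true_parameter_raises(self):
        with pytest.raises(ValueError):
            registration_accuracy(RigidTransform(10, 0, 5), RigidTransform(10, 1, 5))

    def test_zero_policy_absolute_fallback(self):
        acc = registration_accuracy(
            RigidTransform(10, 0, 5),
            RigidTransform(10, 0.03, 5),
            zero_policy="absolute",
        )
        assert acc == pytest.approx(100 - 100 / 3 * 0.03)


class TestSingleImageMetrics:
    def test_gray_level_is_mean(self, rng):
        assert gray_level(np.full((4, 4), 37.0)) == 37.0
        half = np.concatenate([np.zeros((4, 8)), np.full((4, 8), 100.0)])
        assert gray_level(half) == 50.0
        img = rng.uniform(0, 255, (16, 16))
        assert gray_level(img) == pytest.approx(sum(map(sum, img)) / 256)

    def test_standard_deviation_population(self, rng):
        assert standard_deviation(np.full((6, 6), 9.0)) == 0.0
        two_level = np.concatenate([np.zeros((4, 8)), np.full((4, 8), 2.0)])
        assert standard_deviation(two_level) == 1.0
        img = rng.uniform(0, 255, (16, 16))
        mu = img.mean()
        assert standard_deviation(img) == pytest.approx(
            math.sqrt(sum((v - mu) ** 2 for v in img.ravel()) / img.size)
        )

    def test_entropy_cases(self, rng):
        assert entropy(np.full((8, 8), 50.0)) == 0.0
        uniform = np.tile(np.arange(256, dtype=float), 4).reshape(32, 32)
        assert entropy(uniform) == pytest.approx(8.0)
        # probabilities (1/2, 1/4, 1/8, 1/8) -> 1.75 bits
        values = [0.0] * 8 + [85.0] * 4 + [170.0] * 2 + [255.0] * 2
        img = rng.permutation(np.array(values)).reshape(4, 4)
        assert entropy(img) == pytest.approx(1.75)

    def test_eog_cases(self, rng):
        assert energy_of_gradient(np.full((5, 5), 3.0)) == 0.0
        ramp = np.tile(np.arange(7, dtype=float), (5, 1))  # unit steps along columns
        assert energy_of_gradient(ramp) == 5 * 6  # (n-1) unit-squared terms per row
        img = rng.uniform(0, 255, (10, 10))
        total = 0.0
        for r in range(10):
            for c in range(10):
                if r + 1 < 10:
                    total += (img[r + 1, c] - img[r, c]) ** 2
                if c + 1 < 10:
                    total += (img[r, c + 1] - img[r, c]) ** 2
        assert energy_of_gradient(img) == pytest.approx(total)

    def test_brenner_cases(self, rng):
        assert brenner_gradient(np.full((5, 5), 3.0)) == 0.0
        ramp = np.tile(np.arange(6, dtype=float)[:, None], (1, 4))  # unit row steps
        assert brenner_gradient(ramp) == 4 * (6 - 2) * 4  # each valid term (2)^2
        img = rng.uniform(0, 255, (10, 10))
        total = sum(
            (img[r + 2, c] - img[r, c]) ** 2 for r in range(8) for c in range(10)
        )
        assert brenner_gradient(img) == pytest.approx(total)

    def test_mmd_cases(self, rng):
        assert mmd(np.full((5, 5), 3.0)) == 0.0
        one_axis = np.tile(np.arange(6, dtype=float), (5, 1))  # varies along cols only
        assert mmd(one_axis) == 0.0
        img = rng.uniform(0, 255, (10, 10))
        total = sum(
            abs(img[r, c] - img[r + 1, c]) * abs(img[r, c] - img[r, c + 1])
            for r in range(9)
            for c in range(9)
        )
        assert mmd(img) == pytest.approx(total)

    def test_gradient_metrics_translation_invariant_for_interior(self, smooth_image):
        from regstack import apply_rigid_transform

        shifted = apply_rigid_transform(smooth_image, RigidTransform(5, 3, 0))
        crop = (slice(20, 100), slice(20, 100))
        ref_crop = smooth_image[slice(17, 97), slice(15, 95)]
        assert energy_of_gradient(shifted[crop]) == pytest.approx(
            energy_of_gradient(ref_crop), rel=1e-9
        )


def test_metric_report_layout(rng):
    imgs = {"direct": rng.uniform(0, 255, (16, 16)), "reg": rng.uniform(0, 255, (16, 16))}
    rep = metric_report(imgs)
    assert list(rep.columns) == ["image", "metric", "value"]
    assert len(rep) == 10
    assert set(rep["metric"]) == {"eog", "brenner", "gray_level", "sd", "entropy"}
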