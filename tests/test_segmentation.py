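"""Colour conversion, clustering, PCA projection and index arithmetic."""

import numpy as np
import pytest

from cytodiff.errors import (
    DegenerateInputError,
    DomainError,
    FormatError,
    UndefinedIndexError,
)
from cytodiff.segmentation import (
    ClassMasks,
    apoptotic_index,
    initial_cluster,
    pca_project,
    postprocess,
    rgb_to_lab,
)


def lab_reference(rgb8):
    """Independent sRGB → XYZ (D65) → L*a*b* conversion from the standard
    formulas, used as a second colorimetry implementation."""
    c = np.asarray(rgb8, float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.412390799265959, 0.357584339383878, 0.180480788401834],
            [0.212639005871510, 0.715168678767756, 0.072192315360734],
            [0.019330818715592, 0.119194779794626, 0.950532152249661],
        ]
    )
    xyz = M @ lin
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    L = 116 * f[1] - 16
    return np.array([L, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])


class TestRgbToLab:
    def test_reference_white(self):
        lab = rgb_to_lab(np.full((1, 1, 3), 255, np.uint8))[0, 0]
        assert lab[0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab[1]) < 0.01 and abs(lab[2]) < 0.01

    def test_black(self):
        lab = rgb_to_lab(np.zeros((1, 1, 3), np.uint8))[0, 0]
        assert lab[0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "rgb", [(119, 119, 119), (200, 30, 40), (10, 60, 200), (150, 90, 30)]
    )
    def test_against_independent_formulas(self, rgb):
        img = np.array(rgb, np.uint8).reshape(1, 1, 3)
        # atol 0.05 covers the slightly different D65 white-point constants
        # used by the two implementations (~0.05 ΔE, far below visibility)
        np.testing.assert_allclose(
            rgb_to_lab(img)[0, 0], lab_reference(rgb), atol=0.05
        )

    def test_wrong_channel_count(self):
        with pytest.raises(FormatError):
            rgb_to_lab(np.zeros((4, 4), np.uint8))


class TestInitialCluster:
    def test_three_solid_colors_recovered_exactly(self):
        img = np.zeros((30, 30, 3), np.uint8)
        img[:10] = (245, 245, 245)  # background
        img[10:20] = (40, 60, 160)  # blue
        img[20:] = (140, 80, 30)  # brown
        masks = initial_cluster(rgb_to_lab(img), seed=0)
        assert masks.white[:10].all() and not masks.white[10:].any()
        assert masks.blue[10:20].all() and masks.blue.sum() == 300
        assert masks.brown[20:].all() and masks.brown.sum() == 300

    def test_constant_image_degenerate(self):
        img = np.full((8, 8, 3), 120, np.uint8)
        with pytest.raises(DegenerateInputError):
            initial_cluster(rgb_to_lab(img), seed=0)

    def test_deterministic_given_seed(self, small_tile):
        _, img, _ = small_tile
        lab = rgb_to_lab(img)
        a = initial_cluster(lab, seed=5)
        b = initial_cluster(lab, seed=5)
        assert (a.white == b.white).all()
        assert (a.blue == b.blue).all()
        assert (a.brown == b.brown).all()

    def test_masks_partition(self, small_tile):
        _, img, _ = small_tile
        masks = initial_cluster(rgb_to_lab(img), seed=0)
        total = masks.white.astype(int) + masks.blue.astype(int) + masks.brown.astype(int)
        assert (total == 1).all()


class TestPcaProject:
    def test_rank_one_image_has_two_zero_eigenvalues(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 1, (16, 16, 1))
        lab = np.concatenate([base * 50, base * 10, base * -20], axis=2)
        proj = pca_project(lab)
        assert proj.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert proj.eigenvalues[2] == pytest.approx(0.0, abs=1e-10)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pca_project(np.full((5, 5, 3), 7.0))

    def test_decorrelation_and_variance_conservation(self):
        rng = np.random.default_rng(1)
        lab = rng.normal(0, 1, (40, 40, 3)) @ np.array(
            [[2.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 0.5]]
        )
        proj = pca_project(lab)
        X = proj.pixels.reshape(-1, 3)
        cov = np.cov(X.T)
        off = np.abs(cov - np.diag(np.diag(cov))).max()
        assert off <= 1e-8 * np.trace(cov)
        src = lab.reshape(-1, 3)
        assert np.trace(cov) == pytest.approx(np.var(src, axis=0, ddof=1).sum())
        assert np.all(np.diff(proj.eigenvalues) <= 1e-12)
        # orthonormal rotation
        np.testing.assert_allclose(
            proj.eigenvectors.T @ proj.eigenvectors, np.eye(3), atol=1e-12
        )

    def test_channel2_oriented_brown_above_blue(self, default_tile):
        _, img, _ = default_tile
        lab = rgb_to_lab(img)
        masks = initial_cluster(lab, seed=0)
        proj = pca_project(lab, masks)
        ch2 = proj.pixels[..., 1]
        assert ch2[masks.brown].mean() > ch2[masks.blue].mean()


class TestPostprocess:
    def test_fills_small_hole(self):
        mask = np.zeros((20, 20), bool)
        mask[2:18, 2:18] = True
        mask[9:11, 9:11] = False  # 4-px hole
        out = postprocess(mask, min_hole_px=10, min_object_px=10)
        assert out[9:11, 9:11].all()

    def test_removes_small_speck(self):
        mask = np.zeros((20, 20), bool)
        mask[5, 5:7] = True
        out = postprocess(mask, min_hole_px=10, min_object_px=10)
        assert not out.any()

    def test_idempotent(self, default_tile):
        _, img, truth = default_tile
        noisy = truth.brown.copy()
        rng = np.random.default_rng(0)
        flips = rng.integers(0, noisy.size, 300)
        noisy.reshape(-1)[flips] ^= True
        once = postprocess(noisy)
        twice = postprocess(once)
        assert (once == twice).all()

    def test_empty_mask_passthrough(self):
        out = postprocess(np.zeros((5, 5), bool))
        assert not out.any()


class TestApoptoticIndex:
    def _masks(self, brown, white, shape=(10, 10)):
        b = np.zeros(shape, bool)
        w = np.zeros(shape, bool)
        b.reshape(-1)[:brown] = True
        w.reshape(-1)[brown : brown + white] = True
        blue = ~(b | w)
        return ClassMasks(white=w, blue=blue, brown=b)

    def test_all_brown(self):
        masks = ClassMasks(
            white=np.zeros((5, 5), bool),
            blue=np.zeros((5, 5), bool),
            brown=np.ones((5, 5), bool),
        )
        assert apoptotic_index(masks).index == pytest.approx(100.0)

    def test_no_brown(self):
        assert apoptotic_index(self._masks(0, 30)).index == 0.0

    def test_tissue_convention_arithmetic(self):
        res = apoptotic_index(self._masks(10, 50))
        assert res.index == pytest.approx(20.0)
        assert (res.br_count, res.w_count, res.area) == (10, 50, 100)

    def test_area_convention(self):
        assert apoptotic_index(self._masks(10, 50), "area").index == pytest.approx(10.0)

    def test_no_tissue_undefined(self):
        masks = ClassMasks(
            white=np.ones((4, 4), bool),
            blue=np.zeros((4, 4), bool),
            brown=np.zeros((4, 4), bool),
        )
        with pytest.raises(UndefinedIndexError):
            apoptotic_index(masks)
        with pytest.raises(DomainError):
            apoptotic_index(self._masks(1, 1), "percent-of-what")

    def test_masks_must_partition(self):
        with pytest.raises(FormatError):
            ClassMasks(
                white=np.ones((3, 3), bool),
                blue=np.ones((3, 3), bool),
                brown=np.zeros((3, 3), bool),
            )
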