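"""Projection, segmentation, mitochondrial masking and per-cell medians."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from magicquant import (
    MaskConfig,
    ProjectedImage,
    ZStack,
    mito_mask,
    quantify_cell,
    segment_background,
    segment_cells,
    summarize_population,
    zsum_project,
)
from magicquant.image_quant import BORDER, NO_MITO, CellRecord


def _projected(gfp2d, mch2d):
    return ProjectedImage(gfp_sum=np.asarray(gfp2d), mcherry_sum=np.asarray(mch2d))


class TestProjection:
    def test_single_plane_identity(self):
        g = np.arange(12, dtype=np.uint16).reshape(1, 3, 4)
        proj = zsum_project(ZStack(gfp=g, mcherry=g))
        assert np.array_equal(proj.gfp_sum, g[0])

    def test_three_planes_of_ones(self):
        # oracle: direct summation
        ones = np.ones((3, 2, 2), dtype=np.uint16)
        proj = zsum_project(ZStack(gfp=ones, mcherry=ones))
        assert (proj.gfp_sum == 3).all()
        assert (proj.mcherry_sum == 3).all()

    def test_all_zero(self):
        z = np.zeros((4, 5, 5), dtype=np.uint16)
        assert (zsum_project(ZStack(gfp=z, mcherry=z)).gfp_sum == 0).all()

    def test_no_uint16_overflow(self):
        g = np.full((8, 2, 2), 60_000, dtype=np.uint16)
        proj = zsum_project(ZStack(gfp=g, mcherry=g))
        assert (proj.gfp_sum == 8 * 60_000).all()

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ZStack(gfp=np.zeros((2, 3, 3)), mcherry=np.zeros((2, 4, 4)))


class TestBackgroundSegmentation:
    def test_constant_image_all_background_with_warning(self):
        proj = _projected(np.full((20, 20), 5.0), np.full((20, 20), 5.0))
        with pytest.warns(UserWarning, match="constant"):
            fg = segment_background(proj)
        assert not fg.any()

    def test_two_bright_blobs_match_otsu_oracle(self):
        # blobs cover ~17% of the field: the p90 foreground-seed rule
        # assumes cells occupy more than ~10% of pixels
        img = np.zeros((60, 60))
        img[8:23, 8:23] = 100.0
        img[32:52, 32:52] = 100.0
        rng = np.random.default_rng(0)
        noisy = img + rng.normal(0, 1, img.shape)
        proj = _projected(noisy / 2, noisy / 2)
        fg = segment_background(proj)
        oracle = noisy > threshold_otsu(noisy)
        # agreement up to a 1-px boundary band
        disagree = fg ^ oracle
        boundary = ndi.binary_dilation(oracle) ^ ndi.binary_erosion(oracle)
        assert not (disagree & ~boundary).any()
        _, n = ndi.label(fg)
        assert n == 2


class TestCellSegmentation:
    def test_one_isolated_blob_one_label(self):
        img = np.zeros((40, 40))
        img[12:28, 12:28] = 50.0
        proj = _projected(img, img)
        labels = segment_cells(proj, img > 0, MaskConfig(cell_radius_px=8))
        assert labels.max() == 1

    def test_two_separated_blobs_two_labels(self):
        # oracle: connected-component labelling
        img = np.zeros((60, 60))
        img[5:20, 5:20] = 50.0
        img[35:55, 35:55] = 50.0
        proj = _projected(img, img)
        labels = segment_cells(proj, img > 0, MaskConfig(cell_radius_px=7))
        _, n_cc = ndi.label(img > 0)
        assert labels.max() == n_cc == 2

    def test_touching_blobs_split_with_centroids_in_distinct_labels(self):
        yy, xx = np.mgrid[0:50, 0:80]
        c1, c2 = (25, 25), (25, 52)
        blob = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= 14**2) | (
            (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= 14**2
        )
        img = blob * 50.0
        labels = segment_cells(_projected(img, img), blob, MaskConfig(cell_radius_px=12))
        assert labels.max() == 2
        assert labels[c1] != labels[c2] != 0

    def test_empty_foreground_empty_labels(self):
        proj = _projected(np.zeros((10, 10)), np.zeros((10, 10)))
        assert segment_cells(proj, np.zeros((10, 10), bool)).max() == 0

    def test_label_conservation(self, small_scene):
        proj = zsum_project(small_scene.zstack)
        fg = segment_background(proj)
        labels = segment_cells(proj, fg, MaskConfig(cell_radius_px=8))
        assert ((labels > 0) == fg).all()  # every fg pixel in exactly one cell
        areas = np.bincount(labels.ravel())[1:]
        assert areas.sum() == fg.sum()
        assert (np.unique(labels) == np.arange(labels.max() + 1)).all()  # contiguous


class TestMitoMask:
    def test_uniform_positive_all_in_mask(self):
        mask, no_mito = mito_mask(np.full(50, 7.0))
        assert mask.all() and not no_mito

    def test_integer_ramp_five_percent_of_max(self):
        # oracle: enumerate pixels against 0.05 * 100
        values = np.arange(101.0)
        mask, no_mito = mito_mask(values)
        assert not no_mito
        assert mask.sum() == 96
        assert values[mask].min() == 5.0

    def test_all_zero_no_mito(self):
        mask, no_mito = mito_mask(np.zeros(10))
        assert no_mito and not mask.any()

    @given(
        st.lists(st.floats(0.0, 1e6), min_size=1, max_size=60),
        st.integers(-10, 10),
    )
    def test_gain_invariance_exact(self, values, log2_gain):
        """Multiplying the channel by any positive gain leaves the mask
        unchanged; power-of-two gains make the float comparison exact."""
        values = np.asarray(values)
        gain = float(2.0**log2_gain)
        m1, f1 = mito_mask(values)
        m2, f2 = mito_mask(values * gain)
        assert f1 == f2
        assert np.array_equal(m1, m2)


class TestQuantifyCell:
    def _setup(self, gfp_vals, mch_vals):
        n = len(gfp_vals)
        labels = np.zeros((3, n), dtype=np.int32)
        labels[1, :] = 1
        gfp = np.zeros((3, n))
        mch = np.zeros((3, n))
        gfp[1, :] = gfp_vals
        mch[1, :] = mch_vals
        return _projected(gfp, mch), labels

    def test_median_is_sort_middle(self):
        # oracle: sort {1,2,3,4,100} -> 3
        proj, labels = self._setup([1, 2, 3, 4, 100], [10] * 5)
        cfg = MaskConfig(min_cell_area_px=1, exclude_border=False)
        rec = quantify_cell(proj, labels, 1, cfg)
        assert rec.spgfp_median == 3.0

    def test_proportional_channels_give_ratio_c(self):
        mch = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        proj, labels = self._setup(2.5 * mch, mch)
        cfg = MaskConfig(min_cell_area_px=1, exclude_border=False)
        rec = quantify_cell(proj, labels, 1, cfg)
        assert rec.spgfp_over_mcherry == pytest.approx(2.5)

    def test_single_pixel_mask(self):
        proj, labels = self._setup([7.0], [3.0])
        cfg = MaskConfig(min_cell_area_px=1, exclude_border=False)
        assert quantify_cell(proj, labels, 1, cfg).spgfp_median == 7.0

    def test_zero_mcherry_flags_no_mito(self):
        proj, labels = self._setup([5.0, 5.0], [0.0, 0.0])
        cfg = MaskConfig(min_cell_area_px=1, exclude_border=False)
        rec = quantify_cell(proj, labels, 1, cfg)
        assert NO_MITO in rec.qc_flags
        assert rec.spgfp_median is None

    def test_border_flagging(self):
        proj, labels = self._setup([5.0, 5.0], [1.0, 1.0])
        labels[0, 0] = 1  # touch the top border
        rec = quantify_cell(proj, labels, 1, MaskConfig(min_cell_area_px=1))
        assert BORDER in rec.qc_flags

    def test_missing_cell_id_rejected(self):
        proj, labels = self._setup([1.0], [1.0])
        with pytest.raises(ValueError, match="not present"):
            quantify_cell(proj, labels, 99)

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=3, max_size=21).filter(
            lambda v: len(v) % 2 == 1
        ),
        st.floats(0.1, 5.0),
        st.floats(0.0, 100.0),
    )
    def test_median_monotone_invariance(self, values, slope, offset):
        """Strictly increasing transforms commute with the median (odd n)."""
        v = np.asarray(values)
        med = np.median(v)
        assert np.median(slope * v + offset) == pytest.approx(slope * med + offset)


class TestPopulationSummary:
    def _rec(self, cid, spgfp, ratio=1.0, flags=()):
        return CellRecord(cid, 100, 30, spgfp, spgfp / ratio, ratio, frozenset(flags))

    def test_single_record(self):
        s = summarize_population([self._rec(1, 5.0)], "c")
        assert s.mean_spgfp == 5.0 and s.n_cells == 1

    def test_mean_of_two(self):
        s = summarize_population([self._rec(1, 2.0), self._rec(2, 4.0)], "c")
        assert s.mean_spgfp == 3.0

    def test_normalization(self):
        # oracle: 25 / 10 = 2.5
        s = summarize_population([self._rec(1, 25.0)], "c", reference_mean=10.0)
        assert s.normalized_spgfp == 2.5

    def test_flagged_cells_excluded_and_empty_errors(self):
        flagged = self._rec(1, 9.0, flags=[NO_MITO])
        s = summarize_population([flagged, self._rec(2, 4.0)], "c")
        assert s.n_cells == 1 and s.mean_spgfp == 4.0
        with pytest.raises(ValueError, match="NO_MITO"):
            summarize_population([flagged], "c")


class TestEndToEndRecovery:
    def test_noisy_recovery_r_above_095(self):
        """Pearson r > 0.95 between generator truth and estimates, >=50 cells."""
        from magicquant import ImagingParams, generate_scene, quantify_image

        scene = generate_scene(
            ImagingParams(image_shape=(12, 300, 300), cell_count=60, noise_sd=2.0, seed=21)
        )
        records, labels, _ = quantify_image(scene.zstack)
        by_id = {r.cell_id: r for r in records}
        truth, est = [], []
        nz = scene.zstack.n_planes
        for k, v in scene.per_cell_true_spgfp.items():
            mito_k = scene.mito_truth & (scene.cell_truth == k)
            lab = int(np.bincount(labels[mito_k]).argmax())
            rec = by_id.get(lab)
            if lab > 0 and rec is not None and rec.spgfp_median is not None:
                truth.append(v * nz)
                est.append(rec.spgfp_median)
        assert len(truth) >= 50
        assert np.corrcoef(truth, est)[0, 1] > 0.95
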