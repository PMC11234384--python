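"""Background correction, punctum detection and mask generation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from mcsquant.core import Image, Mask, PunctaField
from mcsquant.segmentation import (
    PunctaParams,
    count_nuclei,
    detect_puncta,
    make_organelle_mask,
    max_z_project,
    subtract_background,
)
from mcsquant.simulate import SceneSpec, render_channel


def _img(data, px=77.7, corrected=False):
    return Image(np.asarray(data, float), pixel_size_nm=px, background_corrected=corrected)


class TestSubtractBackground:
    def test_uniform_image_goes_to_zero(self):
        img = _img(np.full((10, 10), 10.0))
        bg = Mask(np.eye(10, dtype=bool))
        out = subtract_background(img, bg)
        assert np.all(out.data == 0)
        assert out.background_corrected

    def test_spot_minus_background(self):
        data = np.full((10, 10), 20.0)
        data[5, 5] = 100.0
        bg = np.zeros((10, 10), bool)
        bg[0] = True
        out = subtract_background(_img(data), Mask(bg))
        assert out.data[5, 5] == pytest.approx(80.0)

    def test_empty_bg_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subtract_background(_img(np.ones((5, 5))), Mask(np.zeros((5, 5), bool)))

    def test_overlapping_cell_mask_rejected(self):
        bg = np.zeros((5, 5), bool)
        bg[0, 0] = True
        cell = np.ones((5, 5), bool)
        with pytest.raises(ValueError, match="overlaps"):
            subtract_background(_img(np.ones((5, 5))), Mask(bg), Mask(cell))

    def test_idempotent_when_bg_region_is_zero(self):
        data = np.full((10, 10), 7.0)
        bg = np.zeros((10, 10), bool)
        bg[:2] = True
        once = subtract_background(_img(data), Mask(bg))
        twice = subtract_background(once, Mask(bg))
        assert np.array_equal(once.data, twice.data)


class TestDetectPuncta:
    def test_blank_image_gives_empty_field(self, spec):
        img = _img(np.zeros(spec.shape), corrected=True)
        assert len(detect_puncta(img)) == 0

    def test_single_spot_centroid_within_half_pixel(self, spec):
        pt = np.array([[80.3, 151.7]]) * spec.pixel_size_nm
        img = render_channel(pt, spec, amplitudes=200.0, noise=True, seed=3)
        field = detect_puncta(
            img.with_data(img.data, background_corrected=True),
            PunctaParams(sigma_nm=spec.psf_sigma_nm),
        )
        assert len(field) == 1
        err = np.hypot(*(field.centroids_nm[0] - pt[0])) / spec.pixel_size_nm
        assert err < 0.5

    def test_hundred_spots_recall_and_precision(self, spec):
        rng = np.random.default_rng(5)
        # enforce 6 px separation between true spots
        pts = []
        while len(pts) < 100:
            cand = rng.uniform(20, 235, size=2)
            if all(np.hypot(*(cand - p)) >= 6 for p in pts):
                pts.append(cand)
        pts = np.array(pts) * spec.pixel_size_nm
        img = render_channel(pts, spec, amplitudes=200.0, noise=True, seed=6)
        field = detect_puncta(
            img.with_data(img.data, background_corrected=True),
            PunctaParams(sigma_nm=spec.psf_sigma_nm),
        )
        tree = cKDTree(pts)
        d, _ = tree.query(field.centroids_nm)
        matched = (d < 2 * spec.pixel_size_nm).sum()
        precision = matched / len(field)
        recall = matched / len(pts)
        assert precision >= 0.98
        assert recall >= 0.98

    @pytest.mark.parametrize("f_coloc", [0.0, 0.3, 0.8])
    def test_f1_on_generator_scenes(self, masks, f_coloc, spec):
        from mcsquant.simulate import place_puncta

        cell, mito = masks
        t = place_puncta(cell, mito, n_ref=150, n_partner=150, f_coloc=f_coloc,
                         f_mito=0.25, seed=int(f_coloc * 10) + 1)
        img = render_channel(t.ref_points, spec, amplitudes=200.0, noise=True, seed=8)
        field = detect_puncta(
            img.with_data(img.data, background_corrected=True),
            PunctaParams(sigma_nm=spec.psf_sigma_nm),
        )
        tree = cKDTree(t.ref_points)
        d, _ = tree.query(field.centroids_nm)
        tp = (d < 2 * spec.pixel_size_nm).sum()
        precision = tp / len(field)
        recall = tp / len(t.ref_points)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95

    def test_translation_equivariance(self, spec):
        pts = np.array([[100, 100], [140, 90], [80, 160]]) * spec.pixel_size_nm
        img = render_channel(pts, spec, noise=False)
        shifted = np.roll(img.data, (5, 3), axis=(0, 1))
        params = PunctaParams(sigma_nm=spec.psf_sigma_nm)
        f0 = detect_puncta(img.with_data(img.data, background_corrected=True), params)
        f1 = detect_puncta(img.with_data(shifted, background_corrected=True), params)
        a = np.sort(f0.centroids_nm, axis=0)
        b = np.sort(f1.centroids_nm - np.array([3, 5]) * spec.pixel_size_nm, axis=0)
        assert np.allclose(a, b, atol=0.1 * spec.pixel_size_nm)

    def test_requires_background_correction(self, spec):
        with pytest.raises(ValueError, match="background"):
            detect_puncta(_img(np.zeros(spec.shape)))


class TestOrganelleMask:
    def test_blank_gives_empty_mask(self, spec):
        img = _img(np.zeros(spec.shape), corrected=True)
        assert make_organelle_mask(img).is_empty()

    def test_jaccard_against_generator_truth(self, masks, spec):
        cell, mito = masks
        pts = np.column_stack(np.nonzero(mito.data))[:, ::-1] * spec.pixel_size_nm
        img = render_channel(pts, spec, amplitudes=50.0, noise=True, seed=9)
        est = make_organelle_mask(
            img.with_data(img.data, background_corrected=True), cell_mask=cell
        )
        inter = (est.data & mito.data).sum()
        union = (est.data | mito.data).sum()
        assert inter / union >= 0.7

    def test_deterministic(self, spec):
        rng = np.random.default_rng(2)
        img = _img(rng.random(spec.shape) * 10, corrected=True)
        a = make_organelle_mask(img)
        b = make_organelle_mask(img)
        assert np.array_equal(a.data, b.data)


class TestCountNuclei:
    def test_blank_gives_zero(self):
        n, _ = count_nuclei(_img(np.zeros((64, 64))))
        assert n == 0

    def test_ten_disjoint_nuclei(self):
        from mcsquant.simulate import make_pla_scene

        _, dapi, truth = make_pla_scene(n_cells=10, spots_per_cell_mean=0, seed=12)
        n, _ = count_nuclei(dapi)
        assert n == truth.n_cells == 10

    def test_touching_nuclei_may_merge(self):
        # two discs closer than one diameter: connected-component counting
        # sees one object -- the documented limitation
        from skimage import draw

        data = np.zeros((64, 64))
        for cx in (28, 36):
            rr, cc = draw.disk((32, cx), 6, shape=data.shape)
            data[rr, cc] = 500
        n, _ = count_nuclei(_img(data))
        assert n == 1


class TestMaxZProject:
    def test_single_plane_identity(self):
        img = Image(np.arange(12.0).reshape(1, 3, 4), pixel_size_nm=1)
        assert np.array_equal(max_z_project(img).data, img.data[0])

    def test_pixelwise_maximum(self):
        stack = Image(np.array([[[3.0]], [[7.0]], [[5.0]]]), pixel_size_nm=1)
        assert max_z_project(stack).data[0, 0] == 7.0

    def test_spot_plane_wins_over_zero_plane(self):
        spot = np.zeros((4, 4))
        spot[2, 2] = 9
        stack = Image(np.stack([np.zeros((4, 4)), spot]), pixel_size_nm=1)
        assert np.array_equal(max_z_project(stack).data, spot)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            max_z_project(Image(np.empty((0, 4, 4)), pixel_size_nm=1))
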