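"""Wavelet segmentation, colocalization, and endocytosis checks."""

import numpy as np
import pytest
from scipy import ndimage

from polyquant.imaging import (
    StructureMask,
    classify_endocytosed,
    colocalize,
    structure_metrics,
    wavelet_segment,
)
from polyquant.synthetic import simulate_two_channel_image


def gaussian_spot(shape, center, amplitude, sigma):
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return amplitude * np.exp(
        -((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2)
    )


def mask_from_labels(labels, pixel_size_nm=100.0, image=None):
    """Build a StructureMask from a hand-constructed label image."""
    import pandas as pd

    labels = np.asarray(labels, dtype=np.int32)
    image = np.ones_like(labels, dtype=float) if image is None else image
    ids = np.unique(labels[labels > 0])
    rows = []
    for i, sid in enumerate(ids, start=1):
        sel = labels == sid
        rr, cc = np.nonzero(sel)
        rows.append(
            {
                "structure_id": i,
                "n_pixels": int(sel.sum()),
                "area_um2": float(sel.sum() * (pixel_size_nm / 1000.0) ** 2),
                "total_intensity": float(image[sel].sum()),
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
            }
        )
    relabeled = np.zeros_like(labels)
    for i, sid in enumerate(ids, start=1):
        relabeled[labels == sid] = i
    return StructureMask(
        label_image=relabeled,
        table=pd.DataFrame(
            rows,
            columns=[
                "structure_id", "n_pixels", "area_um2", "total_intensity",
                "centroid_row", "centroid_col",
            ],
        ),
        pixel_size_nm=pixel_size_nm,
    )


class TestWaveletSegment:
    def test_constant_image_empty_mask(self):
        mask = wavelet_segment(np.full((64, 64), 100.0))
        assert mask.n_structures == 0

    def test_single_spot_detected_with_peak(self):
        rng = np.random.default_rng(1)
        lam = 10.0 + gaussian_spot((128, 128), (64, 64), 10 * np.sqrt(10), 1.5)
        img = rng.poisson(lam)
        mask = wavelet_segment(img)
        assert mask.n_structures == 1
        assert mask.label_image[64, 64] == 1

    def test_two_separated_spots(self):
        rng = np.random.default_rng(2)
        sigma = 1.5
        lam = (
            10.0
            + gaussian_spot((128, 128), (40, 40), 30, sigma)
            + gaussian_spot((128, 128), (40 + int(10 * sigma), 40), 30, sigma)
        )
        mask = wavelet_segment(rng.poisson(lam))
        assert mask.n_structures == 2
        cents = mask.table[["centroid_row", "centroid_col"]].to_numpy()
        true = np.array([[40, 40], [55, 40]])
        d = np.linalg.norm(cents[:, None] - true[None], axis=2)
        assert np.all(d.min(axis=0) <= 1.0)

    def test_threshold_monotonicity(self):
        pair = simulate_two_channel_image(shape=(256, 256), n_puncta_a=30, seed=3)
        counts = [
            wavelet_segment(pair.channel_a, threshold_k=k).n_structures
            for k in (2.0, 3.0, 4.0, 6.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_intensity_summed_from_original_exactly(self):
        pair = simulate_two_channel_image(shape=(256, 256), n_puncta_a=20, seed=4)
        mask = wavelet_segment(pair.channel_a)
        total = float(pair.channel_a[mask.label_image > 0].sum())
        assert mask.table["total_intensity"].sum() == pytest.approx(total, abs=1e-9)

    def test_min_size_filter(self):
        rng = np.random.default_rng(5)
        lam = 10.0 + gaussian_spot((128, 128), (64, 64), 30, 1.5)
        img = rng.poisson(lam)
        big = wavelet_segment(img, min_size_px=4).n_structures
        huge = wavelet_segment(img, min_size_px=500).n_structures
        assert big >= 1 and huge == 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            wavelet_segment(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            wavelet_segment(np.full((8, 8), -1.0))


class TestStructureMetrics:
    def test_mean_and_sum(self):
        labels = np.zeros((100, 100), dtype=int)
        labels[10:13, 10:13] = 1
        labels[50:53, 50:53] = 2
        image = np.zeros((100, 100))
        image[10:13, 10:13] = 100 / 9
        image[50:53, 50:53] = 300 / 9
        m = structure_metrics(mask_from_labels(labels, image=image))
        assert m["mean_intensity_per_cluster"] == pytest.approx(200.0)
        assert m["summed_intensity"] == pytest.approx(400.0)

    def test_density_per_um2(self):
        labels = np.zeros((100, 100), dtype=int)
        for i in range(10):
            labels[i * 10 : i * 10 + 2, 0:2] = i + 1
        m = structure_metrics(mask_from_labels(labels, pixel_size_nm=100.0))
        assert m["clusters_per_um2"] == pytest.approx(10 / 100.0)

    def test_percent_area(self):
        labels = np.zeros((200, 500), dtype=int)
        labels[:10, :500] = 1  # 5,000 of 100,000 pixels
        m = structure_metrics(mask_from_labels(labels))
        assert m["percent_area"] == pytest.approx(5.0)

    def test_empty_mask_zeros(self):
        m = structure_metrics(mask_from_labels(np.zeros((32, 32), dtype=int)))
        assert m["n_structures"] == 0 and m["summed_intensity"] == 0.0


class TestColocalize:
    def test_identical_masks_full_colocalization(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[5:9, 5:9] = 1
        labels[30:34, 40:44] = 2
        mask = mask_from_labels(labels)
        assert colocalize(mask, mask).fraction_a_coloc == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((64, 64), dtype=int)
        b = np.zeros((64, 64), dtype=int)
        a[5:9, 5:9] = 1
        b[40:44, 40:44] = 1
        res = colocalize(mask_from_labels(a), mask_from_labels(b))
        assert res.fraction_a_coloc == 0.0

    def test_constructed_three_of_ten(self):
        a = np.zeros((200, 200), dtype=int)
        b = np.zeros((200, 200), dtype=int)
        for i in range(10):
            a[i * 20 + 2 : i * 20 + 6, 10:14] = i + 1
        for i in range(3):  # overlap exactly three A structures by one pixel
            b[i * 20 + 5, 13] = i + 1
        b[190:194, 150:154] = 4
        res = colocalize(mask_from_labels(a), mask_from_labels(b))
        assert res.fraction_a_coloc == pytest.approx(0.30)
        assert res.n_coloc == 3

    def test_apposition_counts_near_centroids(self):
        a = np.zeros((64, 64), dtype=int)
        b = np.zeros((64, 64), dtype=int)
        a[10:13, 10:13] = 1
        b[10:13, 14:17] = 1  # no shared pixel, centroids 4 px apart -> still out
        res = colocalize(mask_from_labels(a), mask_from_labels(b), mode="apposition")
        assert res.fraction_a_coloc == 0.0
        b2 = np.zeros((64, 64), dtype=int)
        b2[10:13, 12:15] = 1  # centroid distance 2 px
        res2 = colocalize(mask_from_labels(a), mask_from_labels(b2), mode="apposition")
        assert res2.fraction_a_coloc == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            colocalize(
                mask_from_labels(np.zeros((8, 8), dtype=int)),
                mask_from_labels(np.zeros((9, 9), dtype=int)),
            )

    @pytest.mark.parametrize("fraction", [0.0, 0.3, 0.7, 1.0])
    def test_recovers_generator_overlap_fraction(self, fraction):
        pair = simulate_two_channel_image(overlap_fraction=fraction, seed=6)
        ma = wavelet_segment(pair.channel_a, pixel_size_nm=pair.pixel_size_nm)
        mb = wavelet_segment(pair.channel_b, pixel_size_nm=pair.pixel_size_nm)
        res = colocalize(ma, mb)
        assert abs(res.fraction_a_coloc - fraction) <= 0.05


class TestEndocytosis:
    def test_all_surface(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[5:9, 5:9] = 1
        labels[30:34, 40:44] = 2
        mask = mask_from_labels(labels)
        res = classify_endocytosed(mask, mask)
        assert res.fraction_internal == 0.0
        assert res.n_surface + res.n_internal == res.n_total_green

    def test_empty_red_all_internal(self):
        g = np.zeros((64, 64), dtype=int)
        g[5:9, 5:9] = 1
        res = classify_endocytosed(
            mask_from_labels(g), mask_from_labels(np.zeros((64, 64), dtype=int))
        )
        assert res.fraction_internal == 1.0

    def test_two_of_twenty_internal(self):
        g = np.zeros((300, 300), dtype=int)
        r = np.zeros((300, 300), dtype=int)
        for i in range(20):
            row, col = 10 + (i // 5) * 40, 10 + (i % 5) * 40
            g[row : row + 3, col : col + 3] = i + 1
            if i < 18:
                r[row + 1, col + 1] = i + 1
        res = classify_endocytosed(mask_from_labels(g), mask_from_labels(r))
        assert res.fraction_internal == pytest.approx(0.10)

    def test_no_green_flagged_undefined(self):
        empty = mask_from_labels(np.zeros((16, 16), dtype=int))
        res = classify_endocytosed(empty, empty)
        assert res.undefined and np.isnan(res.fraction_internal)


def test_eight_connectivity():
    img = np.full((32, 32), 0.0)
    img[10, 10] = img[11, 11] = img[12, 12] = img[13, 13] = 500.0
    mask = wavelet_segment(img, min_size_px=4, threshold_k=1.0)
    # diagonal chain forms a single 8-connected structure ...
    assert mask.n_structures == 1
    # ... that a 4-connected labeling would fragment
    _, n4 = ndimage.label(img > 0)
    assert n4 == 4
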