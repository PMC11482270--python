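"""Minimum thresholding, droplet segmentation/measurement, binning, ratios."""

import numpy as np
import pandas as pd
import pytest

from liverscope.exceptions import (
    FormatError,
    ThresholdingError,
    UndefinedRatioError,
)
from liverscope.histomorphometry import (
    CalibratedImage,
    assign_bins,
    colorize_droplets,
    compare_group_medians,
    droplet_pipeline,
    measure_droplets,
    minimum_autothreshold,
    segment_droplets,
    size_distribution,
    stain_area_ratio,
    to_grayscale,
)
from liverscope.synthetic import simulate_section_image


def reference_minimum_threshold(hist, max_iter=10000):
    """Independent step-by-step coding of the Minimum algorithm: iterated
    3-point running-mean smoothing (edge values reflected) until bimodal,
    threshold at the between-peak minimum."""
    h = [float(v) for v in hist]

    def maxima(a):
        out, direction = [], 1
        for i in range(len(a) - 1):
            if direction > 0 and a[i + 1] < a[i]:
                out.append(i)
                direction = -1
            elif direction < 0 and a[i + 1] > a[i]:
                direction = 1
        return out

    for _ in range(max_iter + 1):
        m = maxima(h)
        if len(m) == 2:
            lo, hi = m
            best = min(range(lo, hi + 1), key=lambda i: (h[i], i))
            return best
        smoothed = []
        for i in range(len(h)):
            left = h[i - 1] if i > 0 else h[0]
            right = h[i + 1] if i < len(h) - 1 else h[-1]
            smoothed.append((left + h[i] + right) / 3.0)
        h = smoothed
    raise RuntimeError("not bimodal")


class TestGrayscale:
    def test_channel_mean_arithmetic(self):
        px = np.array([[[255, 255, 255], [30, 60, 90]]], dtype=np.uint8)
        gray = to_grayscale(CalibratedImage(px))
        assert gray.pixels[0, 0] == 255
        assert gray.pixels[0, 1] == 60

    def test_gray_input_is_identity(self):
        px = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        out = to_grayscale(CalibratedImage(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_bad_shape_is_format_error(self):
        with pytest.raises(FormatError):
            to_grayscale(CalibratedImage(np.zeros((2, 2, 4), dtype=np.uint8)))


class TestMinimumThreshold:
    def test_two_delta_peaks_threshold_between(self):
        hist = np.zeros(256, dtype=int)
        hist[10], hist[20] = 5, 7
        t = minimum_autothreshold(hist)
        assert 10 < t < 20

    def test_single_level_fails(self):
        hist = np.zeros(256, dtype=int)
        hist[100] = 50
        with pytest.raises(ThresholdingError):
            minimum_autothreshold(hist)

    def test_matches_independent_reference_implementation(self):
        from scipy.stats import norm
        levels = np.arange(256)
        for mus, sds, ws in [((80, 190), (12, 18), (4000, 6000)),
                             ((60, 170), (20, 25), (9000, 3000)),
                             ((100, 220), (8, 10), (500, 800))]:
            hist = np.rint(
                ws[0] * norm.pdf(levels, mus[0], sds[0])
                + ws[1] * norm.pdf(levels, mus[1], sds[1])
            ).astype(int)
            assert minimum_autothreshold(hist) == reference_minimum_threshold(hist)

    def test_close_to_skimage_threshold_minimum(self):
        # library cross-check: same valley up to its extra initial smoothing
        import skimage.filters
        from scipy.stats import norm
        levels = np.arange(256)
        hist = np.rint(
            4000 * norm.pdf(levels, 80, 12) + 6000 * norm.pdf(levels, 190, 18)
        ).astype(int)
        mine = minimum_autothreshold(hist)
        theirs = skimage.filters.threshold_minimum(
            hist=(hist.astype(float), levels.astype(float))
        )
        assert abs(mine - theirs) <= 3

    @pytest.mark.parametrize("factor", [2, 7, 100])
    def test_count_scale_invariance(self, factor):
        img, _ = simulate_section_image(seed=11)
        hist = np.bincount(img.pixels.ravel(), minlength=256)
        assert minimum_autothreshold(hist) == minimum_autothreshold(hist * factor)


class TestSegmentationAndMeasurement:
    def _disk_image(self, centers, radii, fg=240, bg=120, shape=(128, 128)):
        img = np.full(shape, bg, dtype=np.uint8)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        for (cy, cx), r in zip(centers, radii):
            img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r**2] = fg
        return CalibratedImage(img)

    def test_planted_disks_counted(self):
        img = self._disk_image([(30, 30), (30, 90), (90, 60)], [8, 10, 12])
        labels, thr = segment_droplets(img)
        assert 120 < thr < 240
        assert labels.max() == 3

    def test_uniform_image_fails_threshold(self):
        img = CalibratedImage(np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(ThresholdingError):
            segment_droplets(img)

    def test_exclusion_mask_removes_disk(self):
        img = self._disk_image([(30, 30), (90, 90)], [8, 8])
        mask = np.zeros((128, 128), dtype=bool)
        mask[80:100, 80:100] = True
        img.exclusion_mask = mask
        labels, _ = segment_droplets(img)
        records = measure_droplets(labels)
        assert len(records) == 1
        assert records.iloc[0]["centroid_row"] == pytest.approx(30, abs=1)

    def test_area_boundary_29_and_30_pixels(self):
        # 29 px -> 17.4 µm² excluded; 30 px -> 18.0 µm² retained
        labels = np.zeros((20, 40), dtype=int)
        labels[1:2, 1:30] = 1   # 29 pixels
        labels[10:11, 1:31] = 2  # 30 pixels
        records = measure_droplets(labels, pixel_area=0.6, min_area_um2=18.0)
        assert records["droplet_id"].tolist() == [2]
        assert records.iloc[0]["area_um2"] == pytest.approx(18.0)

    def test_disk_area_close_to_continuous(self):
        img = self._disk_image([(64, 64)], [20], shape=(128, 128))
        labels, _ = segment_droplets(img)
        records = measure_droplets(labels)
        assert records.iloc[0]["area_px"] == pytest.approx(np.pi * 400, rel=0.03)

    def test_min_area_monotonicity(self):
        img, _ = simulate_section_image(seed=5)
        labels, _ = segment_droplets(img)
        counts, medians = [], []
        for cutoff in [18.0, 60.0, 150.0]:
            rec = measure_droplets(labels, pixel_area=0.6, min_area_um2=cutoff)
            counts.append(len(rec))
            medians.append(rec["area_um2"].median())
        assert counts == sorted(counts, reverse=True)
        assert medians == sorted(medians)


class TestBinningAndSummary:
    def _records(self, areas):
        return pd.DataFrame({
            "droplet_id": range(1, len(areas) + 1),
            "area_px": [int(a / 0.6) for a in areas],
            "area_um2": areas,
            "centroid_row": 0.0,
            "centroid_col": 0.0,
        })

    def test_half_open_bin_edges(self):
        rec = assign_bins(self._records([199.99, 200.0]))
        assert rec.iloc[0]["bin_label"] == ">=18-<200"
        assert rec.iloc[1]["bin_label"] == ">=200-<400"

    def test_single_droplet_summary(self):
        s = size_distribution(self._records([250.0]))
        assert s.frequencies[">=200-<400"] == pytest.approx(1.0)
        assert s.median_um2 == pytest.approx(250.0)
        assert s.n_droplets == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_frequencies_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        areas = rng.uniform(18, 3000, size=rng.integers(2, 50)).tolist()
        s = size_distribution(self._records(areas))
        assert s.frequencies.sum() == pytest.approx(1.0)
        assert s.median_um2 >= 18.0

    def test_empty_records_warn_and_zero(self):
        s = size_distribution(self._records([]))
        assert s.n_droplets == 0
        assert (s.frequencies == 0).all()

    def test_colorize_distinct_bins_and_determinism(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0:3, 0:3] = 1
        labels[6:9, 6:9] = 2
        rec = assign_bins(self._records([50.0, 500.0]))
        rgb1, legend = colorize_droplets(labels, rec)
        rgb2, _ = colorize_droplets(labels, rec)
        np.testing.assert_array_equal(rgb1, rgb2)
        c1 = tuple(rgb1[1, 1])
        c2 = tuple(rgb1[7, 7])
        assert c1 != c2
        assert tuple(rgb1[5, 5]) == (0, 0, 0)
        assert len(legend) == 2

    def test_excluded_droplet_stays_background(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[0:2, 0:2] = 1
        rgb, _ = colorize_droplets(labels, assign_bins(self._records([])))
        assert (rgb == 0).all()


class TestGroupComparison:
    def _summary(self, median):
        from liverscope.histomorphometry import DropletSizeSummary
        freq = pd.Series({">=18-<200": 0.5, ">=200-<400": 0.5})
        return DropletSizeSummary(freq, median, 10)

    def test_identical_medians_p_one(self):
        summaries = {f"a{i}": self._summary(m) for i, m in enumerate([100, 110, 120] * 2)}
        groups = {f"a{i}": ("veh" if i < 3 else "trt") for i in range(6)}
        stats = compare_group_medians(summaries, groups)
        assert stats["median"].loc["median_um2", "p"] == pytest.approx(1.0)

    def test_matches_shared_t_oracle(self):
        import scipy.stats
        summaries = {f"a{i}": self._summary(m)
                     for i, m in enumerate([100, 110, 120, 60, 70, 80])}
        groups = {f"a{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        stats = compare_group_medians(summaries, groups)
        t_ref, p_ref = scipy.stats.ttest_ind([100, 110, 120], [60, 70, 80])
        assert stats["median"].loc["median_um2", "t"] == pytest.approx(float(t_ref))
        assert stats["median"].loc["median_um2", "p"] == pytest.approx(float(p_ref))

    def test_unit_change_leaves_t_p_unchanged(self):
        m1 = {f"a{i}": self._summary(m) for i, m in enumerate([100, 110, 120, 60, 70, 80])}
        m2 = {f"a{i}": self._summary(m * 1e-6)
              for i, m in enumerate([100, 110, 120, 60, 70, 80])}
        groups = {f"a{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        s1 = compare_group_medians(m1, groups)["median"]
        s2 = compare_group_medians(m2, groups)["median"]
        assert s1.loc["median_um2", "t"] == pytest.approx(s2.loc["median_um2", "t"])
        assert s1.loc["median_um2", "p"] == pytest.approx(s2.loc["median_um2", "p"])


class TestStainAreaRatio:
    def test_half_bright_image_has_fifty_percent_otsu_area(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:, 32:] = 200
        nuclei = CalibratedImage(img)
        signal = CalibratedImage(img)
        signal_pct, nuclei_pct, ratio = stain_area_ratio(signal, nuclei)
        assert nuclei_pct == pytest.approx(50.0)
        assert ratio == pytest.approx(signal_pct / nuclei_pct)

    def test_blank_signal_gives_zero_ratio(self):
        blank = CalibratedImage(np.zeros((16, 16), dtype=np.uint8))
        nuc_px = np.zeros((16, 16), dtype=np.uint8)
        nuc_px[:8] = 255
        sig_pct, _, ratio = stain_area_ratio(blank, CalibratedImage(nuc_px))
        assert sig_pct == 0.0 and ratio == 0.0

    def test_blank_nuclei_is_undefined(self):
        nuc = CalibratedImage(np.zeros((8, 8), dtype=np.uint8))
        sig_px = np.zeros((8, 8), dtype=np.uint8)
        sig_px[:4] = 255
        with pytest.raises(UndefinedRatioError):
            stain_area_ratio(CalibratedImage(sig_px), nuc)

    def test_dimension_mismatch(self):
        with pytest.raises(FormatError):
            stain_area_ratio(
                CalibratedImage(np.zeros((8, 8), dtype=np.uint8)),
                CalibratedImage(np.zeros((8, 9), dtype=np.uint8)),
            )


class TestTilingInvariance:
    def test_disjoint_tiles_pool_to_identical_summary(self):
        img, truth = simulate_section_image(seed=21, width=200, height=200, noise_sd=0)
        labels, _ = segment_droplets(img)
        whole = measure_droplets(labels)
        # split at a row that cuts no droplet
        rows = sorted(d["center_row"] for d in truth.planted_disks)
        radii = {d["center_row"]: d["radius_px"] for d in truth.planted_disks}
        cut = 100
        assert all(abs(d["center_row"] - cut) > d["radius_px"] + 2
                   for d in truth.planted_disks), "fixture must not cut droplets"
        top = CalibratedImage(img.pixels[:cut], pixel_area=img.pixel_area)
        bottom = CalibratedImage(img.pixels[cut:], pixel_area=img.pixel_area)
        parts = []
        for tile in (top, bottom):
            lab, _ = segment_droplets(tile)
            parts.append(measure_droplets(lab))
        pooled = pd.concat(parts, ignore_index=True)
        assert sorted(pooled["area_px"]) == sorted(whole["area_px"])
        s1 = size_distribution(whole)
        s2 = size_distribution(pooled)
        pd.testing.assert_series_equal(s1.frequencies, s2.frequencies)
        assert s1.median_um2 == pytest.approx(s2.median_um2)
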