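"""Segmentation, geometry, dispersion and sarcomere-length estimation."""

import numpy as np
import pandas as pd
import pytest

from conftest import mean_jaccard
from ehtkit import morphometry as mo
from ehtkit import synthetic as sy


class TestSegmentNuclei:
    def test_round_trip_count(self, small_image, analyzed_image):
        _, channels, _, gt = small_image
        nuclei = mo.segment_nuclei(channels[0], 0.1)
        assert nuclei.max() == int(gt.loc[gt.parameter == "n_cells", "value"].iloc[0])

    def test_blank_channel_warns_zero(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            labels = mo.segment_nuclei(np.zeros((64, 64)), 0.1)
        assert labels.max() == 0

    def test_exact_minimum_area_retained(self):
        img = np.zeros((64, 64))
        img[10:30, 10:35] = 100.0  # 500 px = 5.0 um^2 at 0.1 um/px
        labels = mo.segment_nuclei(img, 0.1)
        assert labels.max() == 1
        img2 = np.zeros((64, 64))
        img2[10:30, 10:34] = 100.0  # 480 px = 4.8 um^2, below the bound
        assert mo.segment_nuclei(img2, 0.1).max() == 0


class TestWatershedCells:
    def test_two_cells_split_on_membrane(self):
        p = sy.ImageParams(canvas_size=(384, 384), n_cells=2, orientation_sd=0.0,
                           myocyte_fraction=1.0, rng_seed=3)
        channels, labels, _ = sy.generate_tissue_image(p)
        nuclei = mo.segment_nuclei(channels[0], 0.1)
        seg = mo.watershed_cells(channels[1], nuclei, pixel_size=0.1)
        assert len(np.unique(seg)) - 1 == 2

    def test_single_seed_covers_foreground(self):
        p = sy.ImageParams(canvas_size=(256, 256), n_cells=1, rng_seed=4)
        channels, labels, _ = sy.generate_tissue_image(p)
        nuclei = mo.segment_nuclei(channels[0], 0.1)
        seg = mo.watershed_cells(channels[1], nuclei, pixel_size=0.1)
        assert seg.max() == 1
        # the single segment covers (at least) the rendered cell interior
        inner = labels == 1
        assert (seg[inner] == 1).mean() > 0.95

    def test_partition_and_seed_uniqueness(self, small_image, analyzed_image):
        _, channels, labels, _ = small_image
        _, _, seg, _, _ = analyzed_image
        nuclei = mo.segment_nuclei(channels[0], 0.1)
        for cid in np.unique(seg[seg > 0]):
            seeds = np.unique(nuclei[(seg == cid) & (nuclei > 0)])
            assert seeds.size == 1

    def test_jaccard_against_truth(self, small_image, analyzed_image):
        _, _, labels, _ = small_image
        _, _, seg, _, _ = analyzed_image
        assert mean_jaccard(labels, seg) >= 0.9

    def test_no_seeds_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            mo.watershed_cells(np.zeros((32, 32)), np.zeros((32, 32), dtype=np.int32))


class TestSegmentActinin:
    def test_threshold_is_mode_plus_sd(self):
        rng = np.random.default_rng(0)
        img = np.full((100, 100), 10.0)
        img[:20, :] = rng.uniform(30, 60, (20, 100))
        mask, thr = mo.segment_actinin(img)
        # brute-force oracle: histogram mode + whole-image SD
        counts, edges = np.histogram(img, bins=int(np.ceil(img.max() - img.min())),
                                     range=(img.min(), img.min() + np.ceil(img.max() - img.min())))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert thr == pytest.approx(mode + img.std(), rel=1e-12)
        np.testing.assert_array_equal(mask, img > thr)

    def test_constant_image_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, _ = mo.segment_actinin(np.full((32, 32), 7.0))
        assert not mask.any()

    def test_mask_stripe_period_matches_truth(self):
        p = sy.ImageParams(canvas_size=(512, 512), orientation_sd=0.0, orientation_mean=0.0,
                           myocyte_fraction=1.0, sarcomere_period=2.0, blur_sd=0.0, rng_seed=2)
        channels, labels, gt = sy.generate_tissue_image(p)
        mask, _ = mo.segment_actinin(channels[2])
        rec = gt.attrs["cells"].iloc[0]
        row = int(round(rec.center_row))
        c0 = int(round(rec.center_col - rec.length_um / 0.1 / 2)) + 5
        prof = mask[row, c0 : c0 + 100].astype(float)
        # distance between successive mask-stripe onsets equals the period
        onsets = np.flatnonzero(np.diff(prof) > 0)
        gaps = np.diff(onsets)
        assert np.median(gaps) * 0.1 == pytest.approx(2.0, abs=0.1)


class TestFilterMyocytes:
    def _cells(self, rows):
        return pd.DataFrame(rows, columns=["actinin_area_fraction", "nucleus_area_um2"]).assign(
            cell_id=lambda d: np.arange(1, len(d) + 1)
        )

    def test_rule_application(self):
        cells = self._cells([(0.10, 6.0), (0.05, 10.0), (0.08, 4.0)])
        kept, counts = mo.filter_myocytes(cells)
        assert counts == {"n_total": 3, "n_retained": 1}
        assert kept["cell_id"].tolist() == [1]

    def test_inclusive_bounds(self):
        kept, _ = mo.filter_myocytes(self._cells([(0.07, 5.0)]))
        assert len(kept) == 1

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(1)
        cells = self._cells(list(zip(rng.uniform(0, 0.2, 200), rng.uniform(0, 10, 200))))
        prev = len(cells) + 1
        for frac in [0.0, 0.05, 0.07, 0.1, 0.2]:
            n = mo.filter_myocytes(cells, min_actinin_fraction=frac)[1]["n_retained"]
            assert n <= prev
            prev = n
        prev = len(cells) + 1
        for area in [0.0, 2.0, 5.0, 8.0]:
            n = mo.filter_myocytes(cells, min_nucleus_area=area)[1]["n_retained"]
            assert n <= prev
            prev = n

    def test_realized_myocyte_fraction(self, small_image, analyzed_image):
        _, _, _, gt = small_image
        cells, section, _, _, _ = analyzed_image
        true_frac = float(gt.loc[gt.parameter == "myocyte_fraction_realized", "value"].iloc[0])
        n = section.n_cells_total
        binom_sd = np.sqrt(true_frac * (1 - true_frac) / n)
        assert section.n_cells_retained / n == pytest.approx(true_frac, abs=3 * binom_sd + 1.0 / n)


class TestCellMorphology:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((60, 160), dtype=bool)
        mask[20:30, 30:130] = True  # 10 x 100 px
        res = mo.cell_morphology(mask, 0.1)
        assert res["area_um2"] == pytest.approx(10.0)
        assert res["length_um"] == pytest.approx(10.0, abs=0.05)
        assert res["width_um"] == pytest.approx(1.0, abs=0.05)
        assert res["orientation_deg"] == pytest.approx(0.0, abs=0.5)

    def test_rotated_rectangle_orientation(self):
        # rotate the pixel set by 30 degrees about its center
        rows, cols = np.mgrid[0:10, 0:100]
        pts = np.stack([rows.ravel() - 4.5, cols.ravel() - 49.5], axis=1).astype(float)
        th = np.deg2rad(30.0)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        rotated = pts @ rot.T
        res = mo.cell_morphology(rotated + 200.0, 0.1)
        assert res["orientation_deg"] == pytest.approx(30.0, abs=0.5)
        assert res["length_um"] == pytest.approx(10.0, abs=0.2)

    def test_circle_flagged_isotropic(self):
        rr, cc = np.mgrid[-30:31, -30:31]
        mask = rr**2 + cc**2 <= 30**2
        res = mo.cell_morphology(mask, 0.1)
        assert res["isotropic"]
        assert res["length_um"] == pytest.approx(res["width_um"], rel=0.02)

    def test_collinear_pixels_zero_width(self):
        pts = np.stack([np.zeros(10), np.arange(10.0)], axis=1)
        res = mo.cell_morphology(pts, 0.1)
        assert res["width_um"] == pytest.approx(0.1, abs=0.1)

    def test_rotation_equivariance_on_tissue(self, small_image):
        _, _, labels, gt = small_image
        cells = gt.attrs["cells"]
        for _, rec in cells.iloc[:8].iterrows():
            m = labels == rec.cell_id
            r1 = mo.cell_morphology(m, 0.1)
            r2 = mo.cell_morphology(np.rot90(m), 0.1)
            d = (r2["orientation_deg"] - r1["orientation_deg"]) % 180.0
            assert min(d, 180.0 - d) == pytest.approx(90.0, abs=1.0)
            assert r2["area_um2"] == pytest.approx(r1["area_um2"])
            assert r2["length_um"] == pytest.approx(r1["length_um"], rel=0.02)


class TestNeighborGraph:
    def test_chain_first_and_second_degree(self):
        lab = np.zeros((4, 40), dtype=np.int32)
        for k in range(4):
            lab[:, k * 10 : (k + 1) * 10] = k + 1  # chain A-B-C-D
        g = mo.neighbor_graph(lab)
        assert set(g.neighbors(2)) == {1, 3}
        assert mo.second_degree_neighbors(g, 2) == {4}

    def test_isolated_cell(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[2:6, 2:6] = 1
        lab[12:16, 12:16] = 2  # diagonal gap: not 4-connected
        g = mo.neighbor_graph(lab)
        assert set(g.neighbors(1)) == set()

    def test_matches_brute_force_boundary_scan(self):
        # random space-filling tessellation, exhaustively scanned in python
        rng = np.random.default_rng(4)
        seeds = np.zeros((64, 64), dtype=np.int32)
        pts = rng.integers(0, 64, size=(12, 2))
        for k, (r, c) in enumerate(pts, start=1):
            seeds[r, c] = k
        from skimage.segmentation import expand_labels

        seg = expand_labels(seeds, distance=100)
        g = mo.neighbor_graph(seg)
        edges = set()
        h, w = seg.shape
        for r in range(h):
            for c in range(w):
                for dr, dc in ((0, 1), (1, 0)):
                    if r + dr < h and c + dc < w:
                        a, b = seg[r, c], seg[r + dr, c + dc]
                        if a and b and a != b:
                            edges.add(frozenset((int(a), int(b))))
        assert {frozenset(e) for e in g.edges} == edges


class TestDispersion:
    def test_identical_orientations_zero(self):
        assert mo.axial_dispersion([37.0] * 8) == 0.0

    def test_axial_wrap(self):
        # 0 and 170 are 10 degrees apart axially, not 170
        d = mo.axial_dispersion([0.0, 170.0])
        assert d == pytest.approx(np.std([5.0, -5.0], ddof=1))

    def test_matches_wrap_assignment_oracle(self):
        # brute-force oracle: minimal plain sample SD over all 180-degree
        # wrap assignments of the angles
        rng = np.random.default_rng(2)
        angles = (45.0 + rng.normal(0, 15.0, 9)) % 180.0
        best = np.inf
        for bits in range(2 ** len(angles)):
            shift = 180.0 * np.array([(bits >> k) & 1 for k in range(len(angles))])
            best = min(best, float(np.std(angles - shift, ddof=1)))
        assert mo.axial_dispersion(angles) == pytest.approx(best, rel=0.05)

    def test_field_recovery_within_15_percent(self):
        p = sy.ImageParams(canvas_size=(1792, 1792), orientation_sd=10.0, rng_seed=3)
        _, labels, gt = sy.generate_tissue_image(p)
        cells_gt = gt.attrs["cells"]
        assert len(cells_gt) >= 200
        g = mo.neighbor_graph(labels, max_gap=25)
        disp = mo.local_dispersion(cells_gt[["cell_id", "orientation_deg"]], g)
        assert np.nanmean(disp) == pytest.approx(10.0, rel=0.15)

    def test_small_sets_missing(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[:5] = 1
        lab[5:] = 2
        g = mo.neighbor_graph(lab)
        table = pd.DataFrame({"cell_id": [1, 2], "orientation_deg": [10.0, 20.0]})
        disp = mo.local_dispersion(table, g, min_set_size=3)
        assert disp.isna().all()


class TestSarcomereLength:
    @pytest.mark.parametrize("period", [1.87, 2.19])
    def test_round_trip(self, period):
        p = sy.ImageParams(canvas_size=(768, 768), sarcomere_period=period,
                           myocyte_fraction=1.0, orientation_sd=8.0, rng_seed=5)
        channels, labels, gt = sy.generate_tissue_image(p)
        cells, section, seg = mo.analyze_tissue(channels, pixel_size=0.1)
        vals = cells.loc[cells.is_myocyte, "sarcomere_length_um"].dropna()
        assert len(vals) >= 5
        assert vals.mean() == pytest.approx(period, abs=0.05)

    def test_unstriped_cell_missing(self):
        p = sy.ImageParams(canvas_size=(256, 256), n_cells=1, myocyte_fraction=1.0, rng_seed=6)
        channels, labels, gt = sy.generate_tissue_image(p)
        rec = gt.attrs["cells"].iloc[0]
        flat = np.full(channels[2].shape, 40.0)  # uniform actinin, no striation
        flat[labels == 0] = 10.0
        res = mo.sarcomere_length(flat, rec, labels == 1, pixel_size=0.1)
        assert np.isnan(res["sarcomere_length_um"])
        assert res["reason"] == "no striation"

    def test_short_cell_missing_with_reason(self):
        rec = dict(orientation_deg=0.0, length_um=4.0, width_um=2.0)
        res = mo.sarcomere_length(np.zeros((64, 64)), rec, np.zeros((64, 64), bool),
                                  pixel_size=0.1)
        assert np.isnan(res["sarcomere_length_um"])
        assert "shorter" in res["reason"]


class TestCrossSection:
    def test_fraction_arithmetic(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:4] = True
        sec = mo.cross_section_stats(mask, pixel_size=0.1)
        assert sec.actinin_fraction == pytest.approx(0.40)
        empty = mo.cross_section_stats(np.zeros((10, 10), bool), pixel_size=0.1)
        assert empty.actinin_fraction == 0.0

    def test_matches_pixel_count_oracle_unblurred(self):
        p = sy.ImageParams(canvas_size=(512, 512), blur_sd=0.0, myocyte_fraction=1.0,
                           rng_seed=7)
        channels, _, _ = sy.generate_tissue_image(p)
        mask, thr = mo.segment_actinin(channels[2])
        sec = mo.cross_section_stats(mask, pixel_size=0.1)
        # oracle: direct pixel count above the same statistical threshold
        img = channels[2]
        counts, edges = np.histogram(img, bins=int(np.ceil(img.max() - img.min())) or 1,
                                     range=(img.min(), img.min() + max(np.ceil(img.max() - img.min()), 1)))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        oracle = float((img > mode + img.std()).mean())
        assert sec.actinin_fraction == pytest.approx(oracle, abs=0.02)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            mo.cross_section_stats(np.zeros((4, 4), bool), 0.0)
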