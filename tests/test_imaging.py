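import numpy as np
import pytest

from netscope.imaging import (
    FieldQuantification,
    FieldShapeError,
    FluorescenceField,
    ThresholdConfig,
    binarize_channel,
    coloc_area,
    coloc_mask,
    count_cells,
    count_neutrophils,
    quantify_field,
    summarize_individual,
)


def brute_force_otsu(image):
    """Exhaustive threshold sweep maximizing between-class variance."""
    vals = np.unique(image)
    best_t, best_var = vals[0], -1.0
    for t in vals[:-1]:
        lo = image[image <= t]
        hi = image[image > t]
        w0, w1 = lo.size / image.size, hi.size / image.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestBinarizeChannel:
    def test_constant_zero_image(self):
        mask = binarize_channel(np.zeros((4, 4)), 10)
        assert not mask.any()

    def test_strict_comparison(self):
        img = np.array([[5, 20], [20, 5]])
        mask = binarize_channel(img, 10)
        assert mask.tolist() == [[False, True], [True, False]]
        # exactly at the threshold stays out
        assert not binarize_channel(np.full((2, 2), 10), 10).any()

    def test_otsu_recovers_painted_blob(self, rng):
        img = np.full((64, 64), 10.0)
        img[20:40, 10:30] = 200.0
        img += rng.normal(0, 2, img.shape)
        mask = binarize_channel(img, "otsu")
        expected = np.zeros((64, 64), dtype=bool)
        expected[20:40, 10:30] = True
        assert (mask == expected).all()

    def test_otsu_matches_brute_force_sweep(self, rng):
        from netscope.imaging import resolve_threshold

        img = rng.integers(0, 50, (32, 32)).astype(float)
        img[:10] += 150
        t = resolve_threshold(img, "otsu")
        # both thresholds must split identically on this bimodal image
        assert (img > t).sum() == (img > brute_force_otsu(img)).sum()

    def test_otsu_on_constant_image_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            mask = binarize_channel(np.full((8, 8), 7.0), "otsu")
        assert not mask.any()
        assert "constant" in caplog.text


class TestColocMask:
    def test_disjoint_masks_empty(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[:5], b[5:] = True, True
        assert not coloc_mask(a, b, 0).any()

    def test_identical_masks_idempotent(self, rng):
        m = rng.random((20, 20)) > 0.5
        assert (coloc_mask(m, m, 0) == m).all()

    def test_overlapping_rectangles_brute_force(self):
        a = np.zeros((30, 30), dtype=bool)
        b = np.zeros((30, 30), dtype=bool)
        a[5:15, 5:15] = True
        b[5:15, 10:20] = True  # offset 5 px -> 10x5 overlap
        inter = coloc_mask(a, b, 0)
        brute = sum(
            a[i, j] and b[i, j] for i in range(30) for j in range(30)
        )
        assert inter.sum() == brute == 50

    def test_symmetry(self, rng):
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        assert (coloc_mask(a, b, 3) == coloc_mask(b, a, 3)).all()

    def test_min_area_filter(self):
        a = np.zeros((10, 10), dtype=bool)
        a[0, 0] = True  # 1-px object
        a[5:8, 5:8] = True  # 9-px object
        out = coloc_mask(a, a, 5)
        assert out.sum() == 9

    def test_shape_mismatch(self):
        with pytest.raises(FieldShapeError):
            coloc_mask(np.zeros((2, 2), bool), np.zeros((3, 3), bool), 0)


class TestColocArea:
    def test_empty(self):
        assert coloc_area(np.zeros((5, 5), bool)) == 0

    def test_pixel_count(self, rng):
        m = rng.random((50, 50)) > 0.7
        assert coloc_area(m) == int(m.sum())

    def test_pixel_size_conversion(self):
        m = np.zeros((10, 10), bool)
        m.flat[:50] = True
        assert coloc_area(m, pixel_size_um=0.5) == pytest.approx(12.5)


def paint_disk(img, r, c, radius, value=200.0):
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = value


class TestCountCells:
    def test_blank_channel(self):
        count, labels = count_cells(np.zeros((32, 32)), ThresholdConfig(dapi_threshold=10))
        assert count == 0 and labels.max() == 0

    def test_five_disjoint_disks(self):
        img = np.full((100, 100), 5.0)
        for r, c in [(15, 15), (15, 80), (50, 50), (85, 20), (85, 85)]:
            paint_disk(img, r, c, 6)
        count, _ = count_cells(img, ThresholdConfig(dapi_threshold=100))
        assert count == 5

    def test_min_area_filters_specks(self):
        img = np.full((50, 50), 5.0)
        paint_disk(img, 25, 25, 6)
        img[2, 2] = 200.0  # single hot pixel
        cfg = ThresholdConfig(dapi_threshold=100, min_nucleus_area_px=30)
        count, _ = count_cells(img, cfg)
        assert count == 1


class TestCountNeutrophils:
    def test_no_mpo_signal(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:10, 5:10] = 1
        assert count_neutrophils(labels, np.zeros((20, 20), bool), ThresholdConfig()) == 0

    def test_one_of_three_with_cytoplasm_ring(self):
        size = 120
        dapi = np.full((size, size), 5.0)
        mpo = np.full((size, size), 5.0)
        centers = [(20, 20), (60, 60), (100, 30)]
        for r, c in centers:
            paint_disk(dapi, r, c, 6)
        # ring around the second nucleus only
        paint_disk(mpo, 60, 60, 10)
        yy, xx = np.ogrid[:size, :size]
        mpo[(yy - 60) ** 2 + (xx - 60) ** 2 <= 6**2] = 5.0
        cfg = ThresholdConfig(
            dapi_threshold=100, neutrophil_overlap_fraction=0.1, nucleus_dilation_radius_px=4
        )
        _, labels = count_cells(dapi, cfg)
        assert count_neutrophils(labels, mpo > 100, cfg) == 1


class TestQuantifyField:
    def test_blank_field(self):
        z = np.zeros((64, 64))
        field = FluorescenceField(dapi=z, mpo=z, cith3=z)
        q = quantify_field(field, ThresholdConfig(
            dapi_threshold=10, mpo_threshold=10, cith3_threshold=10))
        assert (q.coloc_area, q.cell_count, q.neutrophil_count) == (0, 0, 0)
        assert q.nets_area_per_cell == 0 and q.nets_area_per_neutrophil == 0

    def test_arithmetic_on_ground_truth(self):
        """50-px coloc region, 10 nuclei, 4 neutrophils -> 5.0 and 12.5."""
        size = 220
        dapi = np.full((size, size), 5.0)
        mpo = np.full((size, size), 5.0)
        cith3 = np.full((size, size), 5.0)
        centers = [(30 + 40 * (i // 4), 30 + 50 * (i % 4)) for i in range(10)]
        for r, c in centers:
            paint_disk(dapi, r, c, 6)
        for r, c in centers[:4]:  # cytoplasm rings -> neutrophils
            paint_disk(mpo, r, c, 10)
            yy, xx = np.ogrid[:size, :size]
            mpo[(yy - r) ** 2 + (xx - c) ** 2 <= 6**2] = 5.0
        mpo[200:205, 100:110] = 200.0  # 50-px double-positive patch
        cith3[200:205, 100:110] = 200.0
        cfg = ThresholdConfig(
            dapi_threshold=100, mpo_threshold=100, cith3_threshold=100,
            neutrophil_overlap_fraction=0.1, nucleus_dilation_radius_px=4,
        )
        q = quantify_field(FluorescenceField(dapi=dapi, mpo=mpo, cith3=cith3), cfg)
        assert q.cell_count == 10
        assert q.neutrophil_count == 4
        assert q.coloc_area == 50
        assert q.nets_area_per_cell == pytest.approx(5.0)
        assert q.nets_area_per_neutrophil == pytest.approx(12.5)

    def test_negative_control_no_red(self, rng):
        """MPO+ cells but no Cit-H3 -> zero colocalization."""
        from netscope.simulate import ImageSceneSpec, generate_field

        field, _ = generate_field(
            ImageSceneSpec(n_cells=8, n_neutrophils=8, n_nets_filaments=0, seed=7)
        )
        # manual thresholds: Otsu is undefined on a signal-free red channel
        q = quantify_field(
            field,
            ThresholdConfig(mpo_threshold=100, cith3_threshold=100, dapi_threshold=100),
        )
        assert q.coloc_area == 0
        assert q.nets_area_per_cell == 0

    def test_zero_cells_with_signal_warns(self, caplog):
        z = np.zeros((32, 32))
        hot = np.full((32, 32), 5.0)
        hot[10:20, 10:20] = 200.0
        field = FluorescenceField(dapi=z, mpo=hot, cith3=hot)
        cfg = ThresholdConfig(dapi_threshold=10, mpo_threshold=100, cith3_threshold=100)
        with caplog.at_level("WARNING"):
            q = quantify_field(field, cfg)
        assert q.coloc_area == 100
        assert q.nets_area_per_cell == 0
        assert "no cells" in caplog.text

    def test_no_neutrophils_flags_missing(self):
        size = 64
        dapi = np.full((size, size), 5.0)
        paint_disk(dapi, 20, 20, 6)
        hot = np.full((size, size), 5.0)
        hot[40:50, 40:50] = 200.0
        field = FluorescenceField(dapi=dapi, mpo=hot, cith3=hot)
        cfg = ThresholdConfig(dapi_threshold=100, mpo_threshold=100, cith3_threshold=100)
        q = quantify_field(field, cfg)
        assert q.neutrophil_count == 0 and q.coloc_area > 0
        assert q.nets_area_per_neutrophil is None

    def test_threshold_monotonicity(self, rng):
        from netscope.simulate import ImageSceneSpec, generate_field

        field, _ = generate_field(ImageSceneSpec(seed=11))
        areas = []
        for t in (50, 100, 150, 190):
            cfg = ThresholdConfig(mpo_threshold=t, cith3_threshold=t, dapi_threshold="otsu")
            areas.append(quantify_field(field, cfg).coloc_area)
        assert areas == sorted(areas, reverse=True)

    def test_shape_mismatch(self):
        with pytest.raises(FieldShapeError):
            FluorescenceField(
                dapi=np.zeros((4, 4)), mpo=np.zeros((4, 4)), cith3=np.zeros((5, 5))
            )


class TestSummarizeIndividual:
    def mk(self, per_cell, per_neu=None, subject="A"):
        return FieldQuantification(
            subject_id=subject, field_id="f", coloc_area=0.0, cell_count=1,
            neutrophil_count=1, nets_area_per_cell=per_cell,
            nets_area_per_neutrophil=per_neu,
        )

    def test_mean_over_six_fields(self):
        fields = [self.mk(v) for v in (2, 4, 6, 0, 0, 0)]
        assert summarize_individual(fields).mean_nets_area_per_cell == pytest.approx(2.0)

    def test_single_field_identity(self):
        s = summarize_individual([self.mk(3.5, 7.0)])
        assert s.mean_nets_area_per_cell == 3.5
        assert s.mean_nets_area_per_neutrophil == 7.0
        assert s.n_fields == 1

    def test_missing_per_neutrophil_excluded(self):
        fields = [self.mk(1, 4.0), self.mk(1, None), self.mk(1, 8.0)]
        assert summarize_individual(fields).mean_nets_area_per_neutrophil == pytest.approx(6.0)

    def test_empty_collection(self):
        with pytest.raises(ValueError):
            summarize_individual([])

    def test_mixed_subjects(self):
        with pytest.raises(ValueError, match="mixed"):
            summarize_individual([self.mk(1, subject="A"), self.mk(1, subject="B")])

    def test_consistency_with_brute_force(self, rng):
        """Summary equals an independent per-field recomputation on the same masks."""
        from netscope.simulate import ImageSceneSpec, generate_field

        quants = []
        brute_means = []
        for i in range(3):
            field, _ = generate_field(
                ImageSceneSpec(n_cells=12, n_neutrophils=5, seed=100 + i),
                subject_id="S", field_id=f"f{i}",
            )
            cfg = ThresholdConfig()
            q = quantify_field(field, cfg)
            quants.append(q)
            # independent recomputation from raw masks
            mpo = binarize_channel(field.mpo, cfg.mpo_threshold)
            red = binarize_channel(field.cith3, cfg.cith3_threshold)
            n_cells, _ = count_cells(field.dapi, cfg)
            area = int((mpo & red).sum())
            brute_means.append(area / n_cells)
        s = summarize_individual(quants)
        assert s.mean_nets_area_per_cell == pytest.approx(np.mean(brute_means))
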