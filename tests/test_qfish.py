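"""Segmentation, signal integration, TCR/NTCR/RTL arithmetic."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from adrenotelo.phantom import (
    SlidePhantomConfig,
    match_to_truth,
    simulate_cellblock,
    simulate_qfish_slide,
    simulate_slide_pair,
)
from adrenotelo.pipeline import quantify_pair
from adrenotelo.qfish import (
    CellBlockReference,
    NucleusMeasurement,
    QFISHImage,
    cellblock_reference,
    compute_rtl,
    compute_tcr,
    estimate_absolute_length_kbp,
    estimate_background,
    measure_nuclei,
    normalize_ntcr,
    segment_nuclei,
)

NF = SlidePhantomConfig(
    shape=(220, 200),
    nuclei_per_zone={"ZF": 30},
    poisson_noise=False,
    read_noise_sd=0.0,
    cellblock_shape=(120, 200),
    cellblock_nuclei=50,
)


def _measurement(nid=1, tel=100.0, cen=50.0):
    return NucleusMeasurement(
        nucleus_id=nid, centroid=(0.0, 0.0), area_px=40, tel_signal=tel,
        cen_signal=cen, tcr=tel / cen,
    )


class TestSegmentation:
    def test_disjoint_nuclei_found_with_accurate_centroids(self):
        img, truth = simulate_qfish_slide(NF, 1)
        labels = segment_nuclei(img.dapi)
        n = labels.max()
        assert n == len(truth.nuclei) == 30
        import skimage.measure

        centroids = np.array(
            [p.centroid for p in skimage.measure.regionprops(labels)]
        )
        ids = match_to_truth(truth, centroids, max_distance_px=1.0)
        assert (ids >= 0).all()

    def test_blank_and_constant_planes_give_zero_labels(self):
        assert segment_nuclei(np.zeros((50, 50))).max() == 0
        assert segment_nuclei(np.full((50, 50), 7.0)).max() == 0

    def test_watershed_splits_touching_pairs(self):
        cfg = replace(NF, nuclei_per_zone={}, touching_pairs=10)
        img, truth = simulate_qfish_slide(cfg, 6)
        assert len(truth.nuclei) == 20
        labels = segment_nuclei(img.dapi)
        assert labels.max() == 20


class TestBackground:
    def test_constant_plane(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:10, 5:10] = 1
        assert estimate_background(np.full((20, 20), 7.0), labels) == 7.0

    def test_noise_free_phantom_background_is_exact(self):
        cfg = replace(NF, gain_cy3=3.0)
        img, truth = simulate_qfish_slide(cfg, 2)
        bg = estimate_background(img.cy3, truth.labels, truth.lipofuscin_mask)
        assert bg == pytest.approx(3.0 * cfg.bg_cy3)

    def test_all_foreground_errors(self):
        labels = np.ones((10, 10), dtype=int)
        with pytest.raises(ValueError, match="background"):
            estimate_background(np.zeros((10, 10)), labels)


class TestMeasurement:
    def test_noise_free_signals_match_truth_within_half_percent(self):
        cfg = replace(NF, gain_cy3=1.7)
        img, truth = simulate_qfish_slide(cfg, 3)
        meas, qc = measure_nuclei(
            truth.labels, img.cy3, img.fitc, 1.7 * cfg.bg_cy3, cfg.bg_fitc
        )
        assert qc["measured"] == len(truth.nuclei)
        by_id = truth.nuclei.set_index("nucleus_id")
        for m in meas:
            assert m.tel_signal == pytest.approx(
                1.7 * by_id.loc[m.nucleus_id, "tel_au"], rel=0.005
            )
            assert m.cen_signal == pytest.approx(
                by_id.loc[m.nucleus_id, "cen_au"], rel=0.005
            )

    def test_fully_masked_nucleus_dropped_and_counted(self):
        img, truth = simulate_qfish_slide(NF, 4)
        lip = truth.labels == truth.nuclei.nucleus_id.iloc[0]
        meas, qc = measure_nuclei(
            truth.labels, img.cy3, img.fitc, NF.bg_cy3, NF.bg_fitc, lipofuscin_mask=lip
        )
        assert qc["dropped_fully_masked"] == 1
        assert len(meas) == len(truth.nuclei) - 1

    def test_zero_telomere_plane_gives_zero_tcrs(self):
        img, truth = simulate_qfish_slide(NF, 5)
        meas, _ = measure_nuclei(
            truth.labels, np.zeros_like(img.cy3), img.fitc, 0.0, NF.bg_fitc
        )
        assert all(m.tel_signal == 0.0 and m.tcr == 0.0 for m in meas)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            measure_nuclei(np.zeros((5, 5), int), np.zeros((6, 6)), np.zeros((5, 5)), 0, 0)


class TestTCR:
    @pytest.mark.parametrize(("tel", "cen", "tcr"), [(100, 50, 2.0), (0, 50, 0.0)])
    def test_ratio(self, tel, cen, tcr):
        assert compute_tcr(tel, cen) == tcr

    def test_zero_centromere_errors(self):
        with pytest.raises(ValueError):
            compute_tcr(50, 0)


class TestCellBlockReference:
    def test_mean_of_constant_tcrs(self):
        ref = cellblock_reference([_measurement(i, 40, 50) for i in range(50)], "s")
        assert ref.mean_tcr == pytest.approx(0.8)
        assert ref.n_nuclei == 50

    def test_minimum_nuclei_enforced(self):
        with pytest.raises(ValueError, match="49"):
            cellblock_reference([_measurement(i) for i in range(49)], "slide-x")

    def test_noise_free_block_mean_reflects_channel_gains(self):
        cfg = replace(NF, gain_cy3=2.0, gain_fitc=0.5, cen_gsd=1.0)
        img, truth = simulate_cellblock(cfg, 6)
        meas, _ = measure_nuclei(
            truth.labels, img.cy3, img.fitc, 2.0 * cfg.bg_cy3, 0.5 * cfg.bg_fitc
        )
        ref = cellblock_reference(meas, "s")
        expected = (8.64 * cfg.kbp_to_au / cfg.cen_median_au) * (2.0 / 0.5)
        assert ref.mean_tcr == pytest.approx(expected, rel=0.005)


class TestNormalize:
    REF = CellBlockReference(slide_id="s1", mean_tcr=0.6, n_nuclei=50)

    def test_ratio_examples(self):
        assert normalize_ntcr(1.2, self.REF) == pytest.approx(2.0)
        assert normalize_ntcr(0.6, self.REF) == pytest.approx(1.0)

    def test_slide_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            normalize_ntcr(1.0, self.REF, slide_id="s2")

    def test_whole_slide_gain_cancels_in_ntcr(self):
        """The cell-block rationale: gain shifts TCR but never NTCR."""
        base = replace(NF, nuclei_per_zone={"ZF": 15, "ZR": 10})
        out = {}
        for g in (1.0, 3.0):
            sim = simulate_slide_pair(replace(base, gain_cy3=g), 8, slide_id="s")
            df, _, _ = quantify_pair(sim.tissue, sim.cellblock)
            out[g] = df.set_index("nucleus_id")[["tcr", "ntcr"]]
        a, b = out[3.0].align(out[1.0], join="inner")
        assert len(a) > 0
        assert np.allclose(a.ntcr, b.ntcr, rtol=0.01)
        assert np.allclose(a.tcr, 3.0 * b.tcr, rtol=1e-6)


class TestRTL:
    def test_mean_of_constant_values(self):
        rtl = compute_rtl("p", "zr", [0.5] * 110)
        assert rtl.rtl == 0.5 and len(rtl.ntcr_values) == 110

    def test_minimum_cell_count_enforced(self):
        with pytest.raises(ValueError, match="short by 1"):
            compute_rtl("p", "zr", [0.5] * 109)

    def test_subsampling_is_seeded_and_bounded(self):
        rng = np.random.default_rng(10)
        values = rng.lognormal(0, 0.2, 500)
        a = compute_rtl("p", "zr", values, seed=1)
        b = compute_rtl("p", "zr", values, seed=1)
        c = compute_rtl("p", "zr", values, seed=2)
        assert a.ntcr_values == b.ntcr_values
        assert len(a.ntcr_values) == 120
        bound = 2 * np.std(values) / np.sqrt(110)
        assert abs(a.rtl - c.rtl) < 2 * bound

    def test_rtl_is_exact_mean_of_retained_values(self):
        rng = np.random.default_rng(11)
        rtl = compute_rtl("p", "zg", rng.lognormal(0, 0.2, 115), seed=0)
        assert rtl.rtl == np.mean(rtl.ntcr_values)


class TestAbsoluteLength:
    @pytest.mark.parametrize(("ntcr", "kbp"), [(1.0, 8.64), (0.5, 4.32), (2.0, 17.28)])
    def test_anchor_scaling(self, ntcr, kbp):
        assert estimate_absolute_length_kbp(ntcr) == pytest.approx(kbp)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            estimate_absolute_length_kbp(0.0)


class TestQFISHImageValidation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            QFISHImage(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 5)))

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            QFISHImage(np.full((4, 4), -1.0), np.zeros((4, 4)), np.zeros((4, 4)))
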