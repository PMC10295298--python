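"""Sensitivity analysis: injection, TSC/TPPC/ROC curves and the MDL."""
import numpy as np
import pytest

import excitescan as ex
from excitescan.core import DetectionMap, SpectralLibrary, SpectralStack
from excitescan.detectors import mf_build
from excitescan.sensitivity import (
    TSAConfig,
    default_config,
    estimate_mdl,
    inject_target,
    roc_curve,
    run_roc,
    run_tppc,
    run_tsa,
    run_tsc,
)


def _two_member_library():
    spectra = np.array([[1.0, 0.5, 0.1, 0.05],
                        [0.05, 0.2, 0.6, 1.0]])
    return SpectralLibrary(["bg", "target"], spectra,
                           np.arange(4.0) * 10 + 400)


def _zero_stack(shape=(8, 8), bands=4):
    return SpectralStack(np.zeros((bands,) + shape),
                         np.arange(float(bands)) * 10 + 400, corrected=True)


def _center_roi(shape=(8, 8), n=3):
    roi = np.zeros(shape, dtype=bool)
    roi[:n, :n] = True
    return roi


class TestInjection:
    def test_zero_injection_is_identity(self, rng):
        stack = SpectralStack(rng.random((4, 6, 6)), np.arange(4.0) + 1,
                              corrected=True)
        out = inject_target(stack, _center_roi((6, 6)), rng.random(4), 0.0)
        assert np.array_equal(out.data, stack.data)

    def test_pure_target_in_roi_of_zero_stack(self):
        r = np.array([0.1, 0.4, 0.8, 1.0])
        roi = _center_roi()
        out = inject_target(_zero_stack(), roi, r, 7.0)
        assert np.allclose(out.data[:, roi], 7.0 * r[:, None])
        assert np.all(out.data[:, ~roi] == 0)

    def test_difference_matches_per_pixel_oracle(self, rng):
        stack = SpectralStack(rng.random((5, 7, 7)) * 10,
                              np.arange(5.0) + 1, corrected=True)
        roi = rng.random((7, 7)) > 0.5
        r = rng.random(5)
        out = inject_target(stack, roi, r, 3.0)
        diff = out.data - stack.data
        for i in range(7):
            for j in range(7):
                expected = 3.0 * r if roi[i, j] else np.zeros(5)
                assert np.allclose(diff[:, i, j], expected, atol=1e-12)

    def test_negative_scalar_rejected(self):
        with pytest.raises(ValueError):
            inject_target(_zero_stack(), _center_roi(), np.ones(4), -1.0)


class TestTSC:
    def test_lu_on_zero_background_recovers_a_exactly(self):
        lib = _two_member_library()
        config = TSAConfig(roi=_center_roi(), target="target", detector="LU",
                           a_grid=np.arange(6.0))
        tsc = run_tsc(_zero_stack(), config, lib)
        assert np.allclose(tsc.mean, np.arange(6.0), atol=1e-9)
        assert tsc.slope == pytest.approx(1.0, abs=1e-9)
        assert tsc.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_sam_angle_decreases_toward_zero(self):
        lib = _two_member_library()
        bg = np.tile(lib.spectrum("bg")[:, None, None] * 10, (1, 8, 8))
        stack = SpectralStack(bg, lib.wavelengths, corrected=True)
        config = TSAConfig(roi=_center_roi(), target="target",
                           detector="SAM", a_grid=np.arange(0.0, 31.0, 5.0))
        tsc = run_tsc(stack, config, lib)
        assert np.all(np.diff(tsc.mean) < 0)

    def test_mf_slope_equals_q_dot_r(self):
        lib = _two_member_library()
        bg = np.tile(lib.spectrum("bg")[:, None, None] * 4, (1, 8, 8))
        stack = SpectralStack(bg, lib.wavelengths, corrected=True)
        config = TSAConfig(roi=_center_roi(), target="target", detector="MF",
                           a_grid=np.arange(8.0))
        tsc = run_tsc(stack, config, lib)
        q = mf_build(lib, "target").filter_vector
        assert tsc.slope == pytest.approx(float(q @ lib.spectrum("target")),
                                          abs=1e-9)
        assert tsc.r_squared == pytest.approx(1.0, abs=1e-12)


class TestTPPC:
    def test_step_at_threshold_on_zero_background(self):
        lib = _two_member_library()
        roi = np.ones((10, 10), dtype=bool)  # 100 pixels
        stack = SpectralStack(np.zeros((4, 10, 10)),
                              np.arange(4.0) * 10 + 400, corrected=True)
        config = TSAConfig(roi=roi, target="target", detector="LU",
                           a_grid=np.arange(0.0, 31.0), tppc_threshold=15.0)
        tppc = run_tppc(stack, config, lib)
        counts = dict(zip(tppc.a, tppc.counts))
        assert all(counts[a] == 0 for a in range(0, 16))
        assert all(counts[a] == 100 for a in range(16, 31))

    def test_no_false_positives_on_noiseless_background(self):
        # an exactly modeled non-target background unmixes to zero target
        scene = ex.tiny_scene(seed=0, n_frames=1)
        stacks, truth = ex.render_scene(scene)
        config = TSAConfig(roi=_center_roi((16, 16)), target="Cal-520",
                           detector="LU", a_grid=np.array([0.0, 1.0]),
                           tppc_threshold=15.0)
        # remove the Ca2+ signal to make it a pure non-target background
        data = stacks[0].data - np.einsum(
            "b,rc->brc", truth.library.spectrum("Cal-520"),
            truth.abundance_maps["Cal-520"][0])
        bg = SpectralStack(data, scene.wavelengths, corrected=True)
        tppc = run_tppc(bg, config, truth.library)
        assert tppc.counts[0] == 0

    def test_counts_match_bruteforce_enumeration(self, rng):
        lib = _two_member_library()
        data = rng.random((4, 9, 9)) * 8
        stack = SpectralStack(data, lib.wavelengths, corrected=True)
        roi = rng.random((9, 9)) > 0.7
        config = TSAConfig(roi=roi, target="target", detector="MF",
                           a_grid=np.arange(0.0, 6.0), tppc_threshold=2.0)
        tppc = run_tppc(stack, config, lib)
        op = mf_build(lib, "target")
        for a, count in zip(tppc.a, tppc.counts):
            injected = inject_target(stack, roi, lib.spectrum("target"), a)
            vals = np.einsum("b,brc->rc", op.filter_vector, injected.data)
            assert count == int((vals > 2.0).sum())


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        lib = _two_member_library()
        roi = _center_roi()
        config = TSAConfig(roi=roi, target="target", detector="LU",
                           roc_scale=5.0,
                           threshold_grid=np.arange(0.0, 51.0))
        _, auc = run_roc(_zero_stack(), config, lib)
        assert auc == 1.0

    def test_roi_independent_noise_gives_chance_level(self):
        roi = _center_roi((20, 20), 10)
        aucs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            dmap = DetectionMap(g.random((20, 20)), "t", "abundance", "MF")
            aucs.append(roc_curve(dmap, roi,
                                  np.linspace(0, 1, 50)).auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se + 1e-9

    def test_matches_confusion_matrix_oracle(self, rng):
        values = rng.random((8, 8)) * 10
        roi = rng.random((8, 8)) > 0.5
        thresholds = np.linspace(0, 10, 10)
        dmap = DetectionMap(values, "t", "abundance", "LU")
        roc = roc_curve(dmap, roi, thresholds)
        # brute-force confusion counting per threshold
        pts = set()
        for t in thresholds:
            tp = fp = 0
            for i in range(8):
                for j in range(8):
                    if values[i, j] > t:
                        if roi[i, j]:
                            tp += 1
                        else:
                            fp += 1
            pts.add((fp / (~roi).sum(), tp / roi.sum()))
        pts |= {(0.0, 0.0), (1.0, 1.0)}
        got = set(zip(roc.fpr.round(12), roc.tpr.round(12)))
        assert got == {(round(f, 12), round(t, 12)) for f, t in pts}

    def test_degenerate_roi_rejected(self):
        lib = _two_member_library()
        full = np.ones((8, 8), dtype=bool)
        for roi in (np.zeros((8, 8), dtype=bool), full):
            config = TSAConfig(roi=roi, target="target", detector="LU")
            with pytest.raises(ValueError):
                run_roc(_zero_stack(), config, lib)

    def test_auc_invariant_under_monotone_transform(self, rng):
        values = rng.random((12, 12)) * 5
        roi = rng.random((12, 12)) > 0.6
        thresholds = np.linspace(0, 5, 25)
        base = roc_curve(DetectionMap(values, "t", "abundance", "LU"),
                         roi, thresholds)
        warped = roc_curve(DetectionMap(np.exp(values), "t", "abundance",
                                        "LU"), roi, np.exp(thresholds))
        assert np.array_equal(base.fpr, warped.fpr)
        assert np.array_equal(base.tpr, warped.tpr)
        assert base.auc == warped.auc


class TestMDL:
    def test_first_grid_value_above_noiseless_maximum(self):
        lib = _two_member_library()
        # background whose LU target output tops out at 12.3
        data = np.zeros((4, 8, 8))
        data[:, 4, 4] = 12.3 * lib.spectrum("target")
        stack = SpectralStack(data, lib.wavelengths, corrected=True)
        config = TSAConfig(roi=_center_roi(), target="target", detector="LU",
                           threshold_grid=np.arange(0.0, 51.0))
        assert estimate_mdl(stack, config, lib) == 13.0

    def test_all_zero_output_gives_smallest_positive_threshold(self):
        lib = _two_member_library()
        config = TSAConfig(roi=_center_roi(), target="target", detector="LU",
                           threshold_grid=np.arange(0.0, 51.0))
        assert estimate_mdl(_zero_stack(), config, lib) == 1.0

    def test_matches_quantile_oracle_with_tolerance(self, rng):
        lib = _two_member_library()
        data = (lib.spectrum("bg")[:, None, None]
                * (rng.random((16, 16)) * 20)[None])
        data = data + rng.normal(0, 0.3, data.shape).clip(0)
        stack = SpectralStack(data, lib.wavelengths, corrected=True)
        grid = np.linspace(0.0, 30.0, 121)
        config = TSAConfig(roi=_center_roi((16, 16)), target="target",
                           detector="MF", threshold_grid=grid,
                           fp_tolerance=0.001)
        got = estimate_mdl(stack, config, lib)
        op = mf_build(lib, "target")
        vals = np.einsum("b,brc->rc", op.filter_vector, data).ravel()
        candidates = [t for t in grid if t > 0
                      and (vals > t).mean() <= 0.001]
        assert got == pytest.approx(min(candidates))


class TestFullAnalysis:
    def test_run_tsa_consistent_with_parts(self, control_tsa):
        scene, stack, truth, library, roi = control_tsa
        config = default_config(roi, "Cal-520", "MF")
        result = run_tsa(stack, config, library)
        tsc = run_tsc(stack, config, library)
        tppc = run_tppc(stack, config, library)
        roc, auc = run_roc(stack, config, library)
        assert np.allclose(result.tsc.mean, tsc.mean)
        assert np.array_equal(result.tppc.counts, tppc.counts)
        assert result.auc == auc
        assert 0.0 <= result.auc <= 1.0
        assert np.all((result.roc.fpr >= 0) & (result.roc.fpr <= 1))

    def test_sam_config_defaults_use_radian_scales(self):
        cfg = default_config(_center_roi(), "Cal-520", "SAM")
        assert cfg.tppc_threshold == 0.98
        assert cfg.threshold_grid.max() == pytest.approx(1.8)
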