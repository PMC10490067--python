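"""Edge detection, segmentation, and the 50%-significance selection rule."""

import numpy as np
import pytest

from nutriwin.detect import (
    AgeWindow,
    SobelWindowDetector,
    binarize_map,
    merge_equivalent_windows,
    segment_windows,
    select_window_nutrients,
    sobel_edge_profile,
)
from nutriwin.scan import PValueMap, ScanConfig, build_pvalue_map
from nutriwin.synthetic import GeneratorConfig, generate_cohort


def make_map(p2, sign=None, age_mid=None, nutrients=None):
    p2 = np.asarray(p2, float)
    nw_, nn = p2.shape
    if sign is None:
        sign = np.where(np.isnan(p2), 0.0, 1.0)
    if age_mid is None:
        age_mid = np.linspace(10, 50, nw_)
    if nutrients is None:
        nutrients = [f"n{j}" for j in range(nn)]
    return PValueMap(p2=p2, sign=np.asarray(sign, float),
                     beta2=np.where(np.asarray(sign, float) == 0, np.nan,
                                    np.asarray(sign, float)),
                     age_mid=np.asarray(age_mid, float),
                     age_min=np.asarray(age_mid, float) - 2,
                     age_max=np.asarray(age_mid, float) + 2,
                     nutrients=list(nutrients), config=ScanConfig())


def sobel_by_hand(m):
    """Literal 3x3 convolution with replicate padding."""
    kernel = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], float)
    padded = np.pad(np.asarray(m, float), 1, mode="edge")
    out = np.zeros_like(np.asarray(m, float))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            patch = padded[i:i + 3, j:j + 3]
            out[i, j] = (patch * kernel).sum()
    return np.abs(out).sum(axis=1)


class TestBinarize:
    @pytest.mark.parametrize("p,sign,mode,expected", [
        (0.049, 1, "positive_only", 1),
        (0.051, 1, "positive_only", 0),
        (0.049, -1, "positive_only", 0),
        (0.049, -1, "signed", -1),
        (np.nan, 0, "positive_only", 0),
        (np.nan, 0, "signed", 0),
    ])
    def test_threshold_and_sign_gate(self, p, sign, mode, expected):
        pmap = make_map([[p] * 4] * 3, sign=[[sign] * 4] * 3)
        b = binarize_map(pmap, alpha=0.05, mode=mode)
        assert b[0, 0] == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            binarize_map(make_map(np.full((3, 2), 0.5)), mode="sideways")


class TestSobelProfile:
    def test_matches_hand_convolution_on_block_map(self):
        # nutrients 0-1 significant in windows 0-4, nutrients 2-3 in 5-9
        m = np.zeros((10, 4))
        m[:5, :2] = 1
        m[5:, 2:] = 1
        profile = sobel_edge_profile(m)
        np.testing.assert_allclose(profile.strength, sobel_by_hand(m))
        assert profile.strength.argmax() in (4, 5)

    @pytest.mark.parametrize("fill", [0.0, 1.0])
    def test_constant_map_has_zero_strength(self, fill):
        m = np.full((10, 4), fill)
        np.testing.assert_array_equal(sobel_edge_profile(m).strength, 0.0)

    def test_matches_hand_convolution_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = rng.integers(0, 2, (12, 5))
            np.testing.assert_allclose(sobel_edge_profile(m).strength,
                                       sobel_by_hand(m))

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="3 windows"):
            sobel_edge_profile(np.zeros((2, 4)))

    def test_smoothing_preserves_length_and_suppresses_speckle(self):
        rng = np.random.default_rng(1)
        m = (rng.random((60, 6)) < 0.05).astype(float)  # isolated speckle
        raw = sobel_edge_profile(m).strength
        smoothed = sobel_edge_profile(m, smooth=25).strength
        assert smoothed.shape == raw.shape
        assert smoothed.max() < raw.max()


class TestSegmentation:
    def test_constant_profile_gives_single_window(self):
        pmap = make_map(np.full((30, 4), 0.5))
        profile = sobel_edge_profile(binarize_map(pmap))
        windows = segment_windows(profile, pmap)
        assert len(windows) == 1
        assert windows[0].start_month <= 10
        assert windows[0].end_month >= 50

    def test_clean_block_edge_found(self):
        p2 = np.full((40, 4), 0.5)
        p2[:20, :2] = 0.001
        p2[20:, 2:] = 0.001
        pmap = make_map(p2, age_mid=np.linspace(8, 47, 40))
        profile = sobel_edge_profile(binarize_map(pmap))
        windows = segment_windows(profile, pmap, min_gap=5)
        boundaries = [w.end_month for w in windows[:-1]]
        # edge lies between age_mid[19] and [20] ~ 27-28 months
        assert any(abs(b - 27) <= 2 for b in boundaries)

    def test_forced_k_gives_k_plus_one_windows(self, default_synthetic):
        table, _ = default_synthetic
        pmap = build_pvalue_map(table)
        det = SobelWindowDetector(k_boundaries=2).fit(pmap, table)
        assert len(det.windows_) == 3

    def test_windows_abut_and_partition(self, default_synthetic):
        table, _ = default_synthetic
        pmap = build_pvalue_map(table)
        det = SobelWindowDetector().fit(pmap, table)
        ws = det.windows_
        for prev, nxt in zip(ws, ws[1:]):
            assert nxt.start_month == prev.end_month + 1
        assert sum(w.n_children for w in ws) == table.n


class TestSelectionRule:
    def test_fraction_at_threshold_selects(self):
        # nutrient significant-positive in exactly 2 of 4 windows
        p2 = np.array([[0.01], [0.01], [0.5], [0.5]])
        pmap = make_map(p2, age_mid=[10, 20, 30, 40])
        w = AgeWindow(8, 42)
        select_window_nutrients(pmap, [w])
        (name, sign, frac), = w.selected_nutrients
        assert (name, sign, frac) == ("n0", 1, 0.5)

    def test_below_threshold_not_selected(self):
        p2 = np.array([[0.01], [0.5], [0.5], [0.5]])
        pmap = make_map(p2, age_mid=[10, 20, 30, 40])
        w = AgeWindow(8, 42)
        select_window_nutrients(pmap, [w])
        assert w.selected_nutrients == []

    def test_never_significant_absent_everywhere(self):
        p2 = np.full((6, 3), 0.9)
        pmap = make_map(p2, age_mid=np.linspace(10, 50, 6))
        windows = [AgeWindow(8, 30), AgeWindow(31, 52)]
        select_window_nutrients(pmap, windows)
        assert all(w.selected_nutrients == [] for w in windows)

    def test_degenerate_fits_excluded_from_denominator(self):
        # 2 valid fits (1 significant) + 2 degenerate: fraction = 1/2
        p2 = np.array([[0.01], [0.5], [np.nan], [np.nan]])
        sign = np.array([[1.0], [1.0], [0.0], [0.0]])
        pmap = make_map(p2, sign=sign, age_mid=[10, 20, 30, 40])
        w = AgeWindow(8, 42)
        select_window_nutrients(pmap, [w])
        assert w.selected_nutrients[0][2] == pytest.approx(0.5)

    def test_negative_association_needs_signed_mode(self):
        p2 = np.full((4, 1), 0.01)
        sign = np.full((4, 1), -1.0)
        pmap = make_map(p2, sign=sign, age_mid=[10, 20, 30, 40])
        w_pos = AgeWindow(8, 42)
        select_window_nutrients(pmap, [w_pos], mode="positive_only")
        assert w_pos.selected_nutrients == []
        w_sgn = AgeWindow(8, 42)
        select_window_nutrients(pmap, [w_sgn], mode="signed")
        assert w_sgn.selected_nutrients[0][1] == -1


class TestMerging:
    def test_empty_selections_collapse_to_single_window(self):
        p2 = np.full((30, 4), 0.8)
        pmap = make_map(p2)
        windows = [AgeWindow(10, 25), AgeWindow(26, 40), AgeWindow(41, 50)]
        merged = merge_equivalent_windows(pmap, windows)
        assert len(merged) == 1

    def test_distinct_selections_not_merged(self):
        p2 = np.full((40, 2), 0.8)
        p2[:20, 0] = 0.001
        p2[20:, 1] = 0.001
        pmap = make_map(p2, age_mid=np.linspace(10, 49, 40))
        windows = [AgeWindow(10, 29), AgeWindow(30, 49)]
        merged = merge_equivalent_windows(pmap, windows)
        assert len(merged) == 2


class TestRecovery:
    def test_planted_boundaries_recovered(self):
        """Default generator, a few seeds: detected boundary within 2
        months of each planted one (20 and 30)."""
        errors = []
        for seed in (0, 1, 2, 3, 4, 5):
            table, truth = generate_cohort(GeneratorConfig(seed=seed))
            pmap = build_pvalue_map(table)
            det = SobelWindowDetector().fit(pmap, table)
            for b in truth.boundaries:
                errors.append(min(abs(d - b) for d in det.boundaries_))
        assert np.median(errors) <= 2

    def test_strong_signal_sets_recovered(self):
        """With two planted nutrients per window (less cross-nutrient
        contamination of the GLM residual), the 50% rule recovers the
        planted sets essentially perfectly."""
        from nutriwin.synthetic import EffectSpec, selection_scores
        effects = tuple(
            [EffectSpec(n, (1,), 0.015) for n in ("Copper", "Iron")]
            + [EffectSpec(n, (2,), 0.015)
               for n in ("Gangliosides", "Sphingomyelin")]
            + [EffectSpec(n, (3,), 0.015)
               for n in ("Alpha tocopherol", "PFA 22:5")])
        recalls, precisions = [], []
        for seed in (1, 2, 3):
            table, truth = generate_cohort(
                GeneratorConfig(effects=effects, seed=seed))
            pmap = build_pvalue_map(table)
            det = SobelWindowDetector().fit(pmap, table)
            scores = selection_scores(truth, det.windows_)
            recalls += list(scores["recall"])
            precisions += list(scores["precision"].dropna())
        assert np.median(recalls) >= 0.8
        assert np.median(precisions) >= 0.8

    def test_null_cohort_collapses_to_single_window(self, null_config):
        singles = 0
        for seed in range(5):
            table, _ = generate_cohort(null_config, seed=700 + seed)
            pmap = build_pvalue_map(table, ScanConfig(stride=25))
            det = SobelWindowDetector().fit(pmap, table)
            singles += len(det.windows_) == 1
        assert singles >= 3
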