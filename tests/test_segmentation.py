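"""Tests for multipoint linear fitting and steep/gradual curve segmentation."""

import numpy as np
import pytest

import focusqc as fq
from focusqc.exceptions import CurveError, SegmentationError

from naive_refs import brute_force_segment


class TestFitWindowLine:
    def test_collinear_points(self):
        c = fq.FocusCurve(values=[0, 1, 2, 3, 4])
        line = fq.fit_window_line(c, 1, 3)
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(-1.0)
        assert line.rss == pytest.approx(0.0, abs=1e-14)
        assert line.window == (1, 3)

    def test_closed_form_ols(self):
        c = fq.FocusCurve(values=[0, 1, 0, 0, 0])
        line = fq.fit_window_line(c, 1, 3)
        assert line.slope == pytest.approx(0.0, abs=1e-14)
        assert line.intercept == pytest.approx(1.0 / 3.0)
        assert line.rss == pytest.approx(2.0 / 3.0)

    def test_constant_window(self):
        c = fq.FocusCurve(values=[5, 5, 5, 5, 5, 5])
        line = fq.fit_window_line(c, 2, 4)
        assert line.slope == pytest.approx(0.0, abs=1e-14)
        assert line.rss == pytest.approx(0.0, abs=1e-14)

    def test_window_out_of_range(self):
        c = fq.FocusCurve(values=[0, 1, 2, 1, 0])
        with pytest.raises(CurveError):
            fq.fit_window_line(c, 4, 3)
        with pytest.raises(SegmentationError):
            fq.fit_window_line(c, 1, 2)

    def test_line_is_callable(self):
        c = fq.FocusCurve(values=[0, 1, 2, 3, 4])
        line = fq.fit_window_line(c, 1, 3)
        assert line(4.0) == pytest.approx(3.0)


class TestSteepLine:
    def test_tent_left(self, tent_curve):
        line = fq.find_steep_line(tent_curve, "left", 3)
        assert line.window == (4, 6)
        assert line.slope == pytest.approx(1.0)

    def test_tent_right_mirrors(self, tent_curve):
        line = fq.find_steep_line(tent_curve, "right", 3)
        assert line.window == (6, 8)
        assert line.slope == pytest.approx(-1.0)

    def test_linear_flank_tie_prefers_peak(self):
        # strictly linear rise: every left window has the same slope
        c = fq.FocusCurve(values=[0, 1, 2, 3, 4, 5, 6, 3, 1, 0.5, 0.2])
        line = fq.find_steep_line(c, "left", 3)
        assert line.window == (5, 7)  # nearest the peak at k = 7

    def test_too_few_points(self):
        c = fq.FocusCurve(values=[3, 2, 1, 0.5, 0.2, 0.1, 0.05])  # peak at k=1
        with pytest.raises(SegmentationError, match="flank"):
            fq.find_steep_line(c, "left", 3)


class TestGradualLine:
    def test_tent_left_rss(self, tent_curve):
        line = fq.find_gradual_line(tent_curve, "left", 3, "rss")
        assert line.window == (1, 3)  # only window disjoint from steep (4,6)
        assert line.slope == pytest.approx(0.0, abs=1e-14)
        assert line.rss == pytest.approx(0.0, abs=1e-14)

    def test_reference_left_rss(self, reference_curve):
        line = fq.find_gradual_line(reference_curve, "left", 3, "rss")
        assert line.window == (1, 3)
        assert line.slope == pytest.approx(0.01)
        assert line.intercept == pytest.approx(0.09)

    def test_criteria_disagree_on_collinear_sloped_window(self):
        # window (1,3) is perfectly collinear but sloped (RSS = 0 spuriously
        # wins under the rss criterion); window (2,4) is flattest by |slope|
        c = fq.FocusCurve(
            values=[0.10, 0.20, 0.30, 0.10, 0.11, 0.10, 0.5, 1.0, 0.5, 0.1, 0.1, 0.1, 0.1]
        )
        by_rss = fq.find_gradual_line(c, "left", 3, "rss")
        assert by_rss.window == (1, 3)
        assert by_rss.rss == pytest.approx(0.0, abs=1e-14)
        by_slope = fq.find_gradual_line(c, "left", 3, "slope")
        assert by_slope.window == (2, 4)
        assert by_slope.slope == pytest.approx(-0.05)

    def test_gradual_ties_prefer_outermost(self, tent_curve):
        # widen the tent tails so several zero-rss windows exist
        c = fq.FocusCurve(values=[0] * 7 + [1, 2, 1] + [0] * 7)
        line = fq.find_gradual_line(c, "left", 3, "rss")
        assert line.window == (1, 3)
        line_r = fq.find_gradual_line(c, "right", 3, "rss")
        assert line_r.window == (15, 17)

    def test_no_disjoint_window(self):
        c = fq.FocusCurve(values=[0, 0.1, 0.5, 0.8, 1.0, 0.8, 0.5, 0.1, 0])
        with pytest.raises(SegmentationError, match="disjoint"):
            fq.find_gradual_line(c, "left", 3)


class TestSegmentCurve:
    def test_tent_exact_corners(self, tent_curve):
        seg = fq.segment_curve(tent_curve, m=3)
        assert seg.klcp == pytest.approx(4.0, abs=1e-12)
        assert seg.krcp == pytest.approx(8.0, abs=1e-12)
        assert seg.kmax == 6
        assert seg.f_lcp == pytest.approx(0.0, abs=1e-12)

    def test_reference_curve_cutoffs(self, reference_curve):
        seg = fq.segment_curve(reference_curve, m=3, criterion="rss")
        assert seg.klcp == pytest.approx(0.89 / 0.29, abs=1e-9)
        assert seg.krcp == pytest.approx(12 - 0.89 / 0.29, abs=1e-9)
        assert seg.f_lcp == pytest.approx(
            fq.interpolate_curve(reference_curve, seg.klcp)
        )

    def test_region_sets_cover_curve(self, reference_curve):
        seg = fq.segment_curve(reference_curve, m=3)
        assert list(seg.left_gradual_region) == [1, 2, 3]
        assert list(seg.left_steep_region) == [4, 5, 6]
        assert list(seg.right_steep_region) == [6, 7, 8]
        assert list(seg.right_gradual_region) == [9, 10, 11]
        union = (
            set(seg.left_gradual_region)
            | set(seg.left_steep_region)
            | set(seg.right_steep_region)
            | set(seg.right_gradual_region)
        )
        assert union == set(range(1, seg.n + 1))

    def test_curve_too_short_for_m(self):
        c = fq.FocusCurve(values=[0, 0.1, 0.5, 1.0, 0.5, 0.1, 0])
        with pytest.raises(SegmentationError, match="N >="):
            fq.segment_curve(c, m=3)

    def test_multi_peak_curve_fails_cleanly(self):
        c = fq.FocusCurve(
            values=[0.1, 0.2, 0.3, 0.6, 1.0, 0.6, 0.3, 0.2, 0.9, 0.2, 0.1]
        )
        with pytest.raises(SegmentationError):
            fq.segment_curve(c, m=3)

    @pytest.mark.parametrize("seed", range(25))
    def test_brute_force_oracle_agreement(self, seed):
        """An independent exhaustive enumeration of all window pairs (own OLS
        via np.polyfit) selects the same windows and cutoffs."""
        c = fq.generate_unimodal_curve(seed, m=3, noise=0.01)
        seg = fq.segment_curve(c, m=3, criterion="rss")
        lw, lg, klcp, rw, rg, krcp = brute_force_segment(c.values, 3, "rss")
        assert seg.left_steep_line.window == lw
        assert seg.left_gradual_line.window == lg
        assert seg.right_steep_line.window == rw
        assert seg.right_gradual_line.window == rg
        assert seg.klcp == pytest.approx(klcp, abs=1e-8)
        assert seg.krcp == pytest.approx(krcp, abs=1e-8)

    @pytest.mark.parametrize("criterion", ["rss", "slope"])
    @pytest.mark.parametrize("seed", range(20))
    def test_mirror_symmetry(self, seed, criterion):
        """Segmenting the reversed curve mirrors the cutoffs."""
        c = fq.generate_unimodal_curve(seed, m=3, noise=0.01)
        seg = fq.segment_curve(c, m=3, criterion=criterion)
        rev = fq.FocusCurve(values=c.values[::-1].copy())
        segr = fq.segment_curve(rev, m=3, criterion=criterion)
        n = c.n
        assert segr.klcp == pytest.approx(n + 1 - seg.krcp, abs=1e-9)
        assert segr.krcp == pytest.approx(n + 1 - seg.klcp, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_affine_invariance(self, seed):
        """Cutoffs and selected windows are unchanged under F -> aF + b."""
        c = fq.generate_unimodal_curve(seed, m=3, noise=0.01)
        seg = fq.segment_curve(c, m=3)
        c2 = fq.FocusCurve(values=4.25 * c.values + 17.0)
        seg2 = fq.segment_curve(c2, m=3)
        assert seg2.klcp == pytest.approx(seg.klcp, abs=1e-9)
        assert seg2.krcp == pytest.approx(seg.krcp, abs=1e-9)
        assert seg2.left_steep_line.window == seg.left_steep_line.window
        assert seg2.left_gradual_line.window == seg.left_gradual_line.window
        assert seg2.right_steep_line.window == seg.right_steep_line.window
        assert seg2.right_gradual_line.window == seg.right_gradual_line.window

    @pytest.mark.parametrize("half_width,tail", [(2, 4), (3, 5), (4, 6), (2, 6)])
    def test_piecewise_linear_tents_recover_corners(self, half_width, tail):
        """On piecewise-linear single-peak curves with flat tails the cutoffs
        equal the true corner abscissas exactly."""
        c = fq.generate_fixture_curve("tent", half_width=half_width, tail=tail)
        seg = fq.segment_curve(c, m=3)
        assert seg.klcp == pytest.approx(tail, abs=1e-10)
        assert seg.krcp == pytest.approx(c.n + 1 - tail, abs=1e-10)

    def test_invariant_ordering_holds(self, reference_curve):
        seg = fq.segment_curve(reference_curve, m=3)
        assert 1 < seg.klcp < seg.kmax < seg.krcp < seg.n

    def test_report_dict_serializable(self, reference_curve):
        import json

        seg = fq.segment_curve(reference_curve, m=3)
        text = json.dumps(seg.to_dict())
        assert '"klcp"' in text and '"left_steep_line"' in text
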