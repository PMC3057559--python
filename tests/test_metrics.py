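"""Facial-metric formulas, polygon geometry, and test–retest reliability."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sasangface as sf
from sasangface import metrics as fm
from sasangface.landmarks import LandmarkSet
from conftest import random_simple_polygon


class TestPolygonGeometry:
    def test_square_perimeter_area_ratio(self, make_landmarks):
        # degenerate 4-point cycle: P5 and P2 coincide, remaining vertices a square
        lm = make_landmarks({
            "P3": (0.0, 0.0),
            "P5": (0.0, 89.0),
            "P2": (0.0, 89.0),
            "P6": (89.0, 89.0),
            "P4": (89.0, 0.0),
        })
        assert fm.par(lm) == pytest.approx(4.0 / 89.0, rel=1e-12)

    def test_regular_pentagon_closed_form(self, make_landmarks):
        R = 50.0
        verts = [
            (R * math.cos(2 * math.pi * k / 5), R * math.sin(2 * math.pi * k / 5))
            for k in range(5)
        ]
        lm = make_landmarks(dict(zip(("P3", "P5", "P2", "P6", "P4"), verts)))
        expected = 4.0 * math.sin(math.pi / 5) / (R * math.sin(2 * math.pi / 5))
        assert fm.par(lm) == pytest.approx(expected, rel=1e-12)

    def test_par_scaling_law(self, template):
        doubled = LandmarkSet(
            "x2", {k: (2 * x, 2 * y) for k, (x, y) in template.points.items()}
        )
        assert fm.par(doubled) == pytest.approx(fm.par(template) / 2, rel=1e-12)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([(0, 0), (1, 1), (1, 0), (0, 1)], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            fm.polygon_perimeter_area(bowtie)

    def test_zero_area_rejected(self):
        collinear = np.array([(0, 0), (1, 1), (2, 2)], dtype=float)
        with pytest.raises(ValueError, match="zero area"):
            fm.polygon_perimeter_area(collinear)

    def test_shoelace_matches_shapely_oracle(self):
        from shapely.geometry import Polygon

        rng = np.random.default_rng(42)
        for _ in range(200):
            v = random_simple_polygon(rng)
            _, area = fm.polygon_perimeter_area(v)
            assert area == pytest.approx(Polygon(v).area, rel=1e-9)


class TestMetricFormulas:
    def test_whr(self, make_landmarks):
        lm = make_landmarks({
            "P3": (-70.0, 15.0), "P4": (70.0, 15.0),
            "P7": (0.0, -20.0), "P8": (0.0, 47.0),
        })
        assert fm.whr(lm) == pytest.approx(140.0 / 67.0, rel=1e-12)

    def test_whr_zero_cheek_width(self, make_landmarks):
        lm = make_landmarks({"P3": (0.0, 15.0), "P4": (0.0, 15.0)})
        assert fm.whr(lm) == 0.0

    def test_whr_zero_height_error(self, make_landmarks):
        lm = make_landmarks({"P7": (0.0, 5.0), "P8": (0.0, 5.0)})
        with pytest.raises(ValueError, match="P7"):
            fm.whr(lm)

    def test_cjwr(self, make_landmarks):
        lm = make_landmarks({
            "P3": (-70.0, 15.0), "P4": (70.0, 15.0),
            "P5": (-62.0, 70.0), "P6": (62.0, 70.0),
        })
        assert fm.cjwr(lm) == pytest.approx(140.0 / 124.0, rel=1e-12)

    def test_cjwr_equal_widths_is_one(self, make_landmarks):
        lm = make_landmarks({
            "P3": (-60.0, 15.0), "P4": (60.0, 15.0),
            "P5": (-60.0, 70.0), "P6": (60.0, 70.0),
        })
        assert fm.cjwr(lm) == pytest.approx(1.0)

    def test_eye_size(self, make_landmarks):
        lm = make_landmarks({
            "P9": (-47.5, 0.0), "P10": (47.5, 0.0),
            "P11": (-15.0, 0.0), "P12": (15.0, 0.0),
        })
        assert fm.eye_size(lm) == pytest.approx(32.5, rel=1e-12)

    def test_eye_size_equal_spans_is_zero(self, make_landmarks):
        lm = make_landmarks({
            "P9": (-15.0, 0.0), "P10": (15.0, 0.0),
            "P11": (-15.0, 0.0), "P12": (15.0, 0.0),
        })
        assert fm.eye_size(lm) == pytest.approx(0.0)

    def test_eye_size_negative_warns_but_returns(self, make_landmarks):
        lm = make_landmarks({
            "P9": (-10.0, 0.0), "P10": (10.0, 0.0),
            "P11": (-20.0, 0.0), "P12": (20.0, 0.0),
        })
        with pytest.warns(UserWarning, match="negative eye size"):
            assert fm.eye_size(lm) == pytest.approx(-10.0)

    def test_lf_fh(self, make_landmarks):
        lm = make_landmarks({"P2": (0.0, 110.0), "P1": (0.0, -70.0)})
        assert fm.lf_fh(lm) == pytest.approx(110.0 / 180.0, rel=1e-12)

    def test_lf_fh_pupils_on_chin_line(self, make_landmarks):
        lm = make_landmarks({"P13": (-31.0, 100.0), "P14": (31.0, 100.0),
                             "P2": (0.0, 100.0)})
        assert fm.lf_fh(lm) == pytest.approx(0.0)

    def test_fw_lfh(self, make_landmarks):
        lm = make_landmarks({
            "P3": (-70.0, 15.0), "P4": (70.0, 15.0), "P2": (0.0, 115.0),
        })
        assert fm.fw_lfh(lm) == pytest.approx(140.0 / 115.0, rel=1e-12)

    def test_eh_mean_unequal_offsets(self, make_landmarks):
        offsets = {"P9p": 10, "P10p": 20, "P11p": 10, "P12p": 20, "P13p": 10, "P14p": 20}
        over = {}
        base = sf.template_landmarks().points
        for name, off in offsets.items():
            x, y = base[name.rstrip("p")]
            over[name] = (x, y - off)
        lm = make_landmarks(over)
        assert fm.eh_mean(lm) == pytest.approx(15.0, rel=1e-12)

    def test_eh_mean_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        pts = {p: tuple(rng.uniform(-50, 50, 2)) for p in sf.landmarks.POINT_NAMES}
        lm = LandmarkSet("r", pts)
        manual = np.mean([
            math.dist(pts[f"P{i}"], pts[f"P{i}p"]) for i in range(9, 15)
        ])
        assert fm.eh_mean(lm) == pytest.approx(manual, rel=1e-12)

    def test_metric_vector_aggregates_components(self, template):
        mv = sf.metric_vector(template)
        assert mv.PAR == pytest.approx(fm.par(template))
        assert mv.WHR == pytest.approx(fm.whr(template))
        assert mv.CJWR == pytest.approx(fm.cjwr(template))
        assert mv.eye_size == pytest.approx(fm.eye_size(template))
        assert mv.LF_FH == pytest.approx(fm.lf_fh(template))
        assert mv.FW_LFH == pytest.approx(fm.fw_lfh(template))
        assert mv.EH_mean == pytest.approx(fm.eh_mean(template))


class TestInvariants:
    @given(
        s=st.floats(min_value=0.1, max_value=10.0),
        dx=st.floats(min_value=-100, max_value=100),
        dy=st.floats(min_value=-100, max_value=100),
    )
    def test_similarity_scaling_laws(self, s, dx, dy):
        template = sf.template_landmarks()
        moved = LandmarkSet(
            "t",
            {k: (s * x + dx, s * y + dy) for k, (x, y) in template.points.items()},
        )
        base, new = sf.metric_vector(template), sf.metric_vector(moved)
        # dimensionless ratios invariant under scaling + translation
        for name in ("WHR", "CJWR", "LF_FH", "FW_LFH"):
            assert getattr(new, name) == pytest.approx(getattr(base, name), rel=1e-9)
        # mm-valued metrics scale as s, PAR as 1/s
        assert new.eye_size == pytest.approx(s * base.eye_size, rel=1e-9)
        assert new.EH_mean == pytest.approx(s * base.EH_mean, rel=1e-9)
        assert new.PAR == pytest.approx(base.PAR / s, rel=1e-9)

    def test_ratio_identity_for_vertical_midline(self, template):
        # with P1 directly above P2, FW/LFH · LF/FH = cheek width / face height
        mv = sf.metric_vector(template)
        expected = template.distance("P3", "P4") / template.distance("P1", "P2")
        assert mv.FW_LFH * mv.LF_FH == pytest.approx(expected, rel=1e-12)


class TestReliability:
    def test_identical_repeats_zero_cv(self, template):
        mv = sf.metric_vector(template)
        table = sf.reliability_cv({"s": [mv, mv]})
        assert (table["cv_max"] == 0).all()

    def test_two_point_cv_formula(self, template):
        # repeats 10 and 10.1: CV = 100·sd/mean with sample SD
        base = sf.metric_vector(template)
        kwargs = base.as_dict()
        mv1 = sf.MetricVector(**{**kwargs, "eye_size": 10.0})
        mv2 = sf.MetricVector(**{**kwargs, "eye_size": 10.1})
        table = sf.reliability_cv({"s": [mv1, mv2]})
        expected = 100.0 * np.std([10.0, 10.1], ddof=1) / 10.05
        assert table.loc["eye_size", "cv_max"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.7036, abs=1e-3)

    def test_requires_two_repeats(self, template):
        with pytest.raises(ValueError, match="at least 2"):
            sf.reliability_cv({"s": [sf.metric_vector(template)]})

    def test_jitter_study_reproduces_published_band(self, template):
        # 0.8 mm landmark jitter, 15 subjects x 2 repeats: per-metric mean CV
        # falls inside the published test-retest band 0.4-5.53%
        rng = np.random.default_rng(7)
        repeated = {}
        for s in range(15):
            repeated[f"s{s}"] = [
                sf.metric_vector(LandmarkSet(
                    f"s{s}",
                    {k: (x + rng.normal(0, 0.8), y + rng.normal(0, 0.8))
                     for k, (x, y) in template.points.items()},
                ))
                for _ in range(2)
            ]
        table = sf.reliability_cv(repeated)
        assert (table["cv_mean"] >= 0.4).all()
        assert (table["cv_mean"] <= 5.53).all()
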