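"""Angle profiles and morphometric parameters against analytic oracles."""

import numpy as np
import pytest

from spermshape import (PopulationSpec, ShapeParams, anchored_profile,
                        angle_profile, compare_xy, detect_hook_apex,
                        generate_population, generate_shape, morph_stats)
from spermshape.geometry import Outline, resample_closed
from spermshape.morphometry import AngleProfile, NoLandmarkError
from spermshape.synthetic import NucleusRecord


class TestAngleProfile:
    @pytest.mark.parametrize("f", [0.02, 0.05, 0.10, 0.25])
    def test_circle_inscribed_angle_closed_form(self, circle_outline, f):
        """On a circle, the window angle equals 180 - 180*f for any
        window fraction f (inscribed-angle theorem)."""
        prof = angle_profile(circle_outline, window_fraction=f)
        expected = 180.0 - 180.0 * f
        assert np.all(np.abs(prof.angles - expected) < 0.5)

    def test_square_mid_edge_and_corner(self, square_outline):
        prof = angle_profile(square_outline, window_fraction=0.05,
                             n_index=100)
        # index 0 is a corner of the unit square (perimeter starts there);
        # mid-edge indices are 1/8 of the perimeter later
        assert abs(prof.angles[0] - 90.0) < 1.0
        assert abs(prof.angles[12] - 180.0) < 1.0    # 12.5% ~ mid-edge

    def test_reflex_region_exceeds_180(self):
        # an L-shaped (concave) hexagon has one reflex corner
        verts = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]],
                         float)
        prof = angle_profile(Outline(resample_closed(verts, 600)),
                             window_fraction=0.02, n_index=300)
        assert prof.angles.max() > 200.0
        assert prof.angles.min() < 120.0

    def test_window_too_wide_rejected(self, circle_outline):
        with pytest.raises(ValueError):
            angle_profile(circle_outline, window_fraction=0.5)

    def test_similarity_invariance(self, wt_outline):
        """Rotation, translation and uniform scaling leave the profile
        unchanged."""
        base = anchored_profile(wt_outline)[0].angles
        moved = wt_outline.transformed(scale=2.5, angle=1.1,
                                       shift=(13.0, -4.0))
        np.testing.assert_allclose(anchored_profile(moved)[0].angles, base,
                                   atol=0.6)

    def test_orientation_canonicalized(self, wt_outline):
        reversed_outline = Outline(wt_outline.vertices[::-1].copy())
        a = anchored_profile(wt_outline)[0].angles
        b = anchored_profile(reversed_outline)[0].angles
        # reversal flips traversal direction; the canonical CCW profile of
        # the reversed outline is the mirrored profile of the original
        assert min(np.max(np.abs(a - b)),
                   np.max(np.abs(a - np.roll(b[::-1], 1)))) < 1.0

    def test_total_turning_is_360(self, wt_outline):
        v = wt_outline.vertices
        d = np.diff(np.vstack([v, v[:2]]), axis=0)
        headings = np.arctan2(d[:, 1], d[:, 0])
        turns = np.diff(headings)
        turns = (turns + np.pi) % (2 * np.pi) - np.pi
        assert abs(np.degrees(turns.sum()) - 360.0) < 1e-6


class TestHookApex:
    def test_min_index_and_rotation(self):
        angles = np.full(100, 170.0)
        angles[37] = 40.0
        prof = AngleProfile(angles, 0.05)
        apex = detect_hook_apex(prof)
        assert apex == 37
        assert prof.rotated(apex).angles[0] == 40.0

    def test_tie_breaks_to_first(self):
        angles = np.full(50, 170.0)
        angles[[10, 30]] = 40.0
        assert detect_hook_apex(AngleProfile(angles, 0.05)) == 10

    def test_circle_has_no_landmark(self, circle_outline):
        with pytest.raises(NoLandmarkError):
            detect_hook_apex(angle_profile(circle_outline))

    def test_apex_near_planted_tip(self):
        """The detected apex lies within 3 profile indices of the
        generator's planted hook-tip coordinate."""
        for seed in (1, 2, 3):
            outline, tip = generate_shape(ShapeParams(), seed=seed,
                                          return_landmarks=True)
            _, frac = anchored_profile(outline)
            coarse = resample_closed(outline.vertices, 100)
            apex_xy = coarse[int(round(frac * 100)) % 100]
            tip_idx = np.argmin(np.linalg.norm(coarse - tip, axis=1))
            apex_idx = int(round(frac * 100)) % 100
            gap = min(abs(apex_idx - tip_idx), 100 - abs(apex_idx - tip_idx))
            assert gap <= 3, (apex_xy, tip)


class TestMorphStats:
    def test_circle_identity(self, circle_outline):
        ms = morph_stats(circle_outline)
        assert abs(ms.circularity - 1.0) < 0.005
        assert abs(ms.regularity - 1.0) < 0.005

    def test_square(self, square_outline):
        ms = morph_stats(square_outline)
        assert abs(ms.circularity - np.pi / 4) < 0.01

    def test_two_to_one_ellipse(self, ellipse_outline):
        ms = morph_stats(ellipse_outline)
        assert abs(ms.length / ms.width - 2.0) < 0.04
        assert abs(ms.regularity - 1.0) < 0.02

    def test_circularity_bounded_on_battery(self, circle_outline,
                                            square_outline, ellipse_outline,
                                            wt_outline):
        for o in (circle_outline, square_outline, ellipse_outline,
                  wt_outline):
            ms = morph_stats(o)
            assert 0 < ms.circularity <= 1.0
            assert ms.width <= ms.length + 1e-9

    def test_self_intersecting_rejected(self):
        bowtie = Outline(resample_closed(
            np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]]), 60))
        with pytest.raises(ValueError):
            morph_stats(bowtie)


def _records_from_draws(rng, n, y_shift=0.0):
    """Records with parameter-level stats, skipping outline building (the
    statistical machinery is what is under test here)."""
    records = []
    for i in range(n):
        sex = "X" if i % 2 == 0 else "Y"
        base = {p: rng.normal(0, 1) for p in
                ("area", "perimeter", "length", "width", "min_angle",
                 "circularity", "regularity")}
        if sex == "Y":
            base["circularity"] += y_shift
        records.append(NucleusRecord(cell_id=str(i), genotype="YQDEL",
                                     sex=sex, params=ShapeParams(),
                                     stats=base))
    return records


class TestCompareXY:
    def test_null_flag_rate_nominal(self):
        """Identically distributed X and Y: the Bonferroni-corrected flag
        rate stays near the nominal alpha."""
        rng = np.random.default_rng(0)
        flagged = 0
        tests = 0
        for _ in range(100):
            report = compare_xy(_records_from_draws(rng, 1000))
            flagged += int(report.significant.sum())
            tests += len(report)
        # family-wise alpha 0.01 across 7 parameters per replicate
        assert flagged <= 5

    def test_planted_effect_power(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            report = compare_xy(_records_from_draws(rng, 1000, y_shift=1.0))
            row = report[report.parameter == "circularity"]
            hits += bool(row.significant.iloc[0])
        assert hits >= 38

    def test_constant_samples_handled(self):
        records = []
        for i in range(20):
            records.append(NucleusRecord(
                cell_id=str(i), genotype="WT", sex="X" if i % 2 else "Y",
                params=ShapeParams(),
                stats={p: 1.0 for p in ("area", "perimeter", "length",
                                        "width", "min_angle", "circularity",
                                        "regularity")}))
        report = compare_xy(records)
        assert (report.p == 1.0).all()

    def test_missing_class_rejected(self):
        records = _records_from_draws(np.random.default_rng(2), 10)
        only_x = [r for r in records if r.sex == "X"]
        with pytest.raises(ValueError):
            compare_xy(only_x)
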