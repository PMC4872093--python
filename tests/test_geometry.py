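"""DNA deformation geometry: axis, bend, grooves, twist, flipped bases."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ispkit import geometry as geo
from ispkit import synthetic as syn
from ispkit.synthetic import DuplexSpec

from conftest import frame_over

SEQ28 = "GCTAGCTAGCATCGATCGATCGATGCAT"
SEQ30 = "GCTAGCTAGCATCGATCGATCGATGCATCG"


def kinked_complex(angle, seed_seq=SEQ28):
    model, truth = syn.make_duplex(DuplexSpec(sequence=seed_seq,
                                              kink=(13, angle)))
    frame = frame_over(model, len(seed_seq), 13)
    return model, frame, truth


class TestHelicalAxis:
    def test_straight_axis_collinear(self, straight_duplex):
        model, frame, _ = straight_duplex
        _, axis = geo.fit_helical_axis(model, frame)
        pts = axis[np.all(np.isfinite(axis), axis=1)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        resid = (pts - centroid) - np.outer((pts - centroid) @ vt[0], vt[0])
        assert np.linalg.norm(resid, axis=1).max() < 0.1

    def test_axis_point_spacing_smooth(self, straight_duplex):
        model, frame, _ = straight_duplex
        _, axis = geo.fit_helical_axis(model, frame)
        pts = axis[np.all(np.isfinite(axis), axis=1)]
        spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert spacing.min() > 2.5 and spacing.max() < 4.5

    def test_flipped_base_does_not_disturb_axis(self):
        seq = "GCTAGCTAGCATCGATCGATCGAT"
        model, _ = syn.make_duplex(DuplexSpec(sequence=seq, flip=(11, "bottom")))
        frame = frame_over(model, 24, 11)
        _, axis = geo.fit_helical_axis(model, frame)
        pts = axis[np.all(np.isfinite(axis), axis=1)]
        centroid = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centroid)
        resid = (pts - centroid) - np.outer((pts - centroid) @ vt[0], vt[0])
        assert np.linalg.norm(resid, axis=1).max() < 0.3

    def test_short_duplex_rejected(self):
        model, _ = syn.make_duplex(DuplexSpec(sequence="ACGTA"))
        frame = frame_over(model, 5, 2)
        with pytest.raises(geo.GeometryError):
            geo.fit_helical_axis(model, frame)


class TestBendAngle:
    UP, DOWN = (-13, -2), (3, 14)

    def test_straight_is_zero(self, straight_duplex):
        model, frame, _ = straight_duplex
        assert geo.bend_angle(model, frame, (-11, -2), (3, 12)) < 1.0

    @pytest.mark.parametrize("angle", [10.0, 34.0, 60.0])
    def test_planted_kink_recovered(self, angle):
        model, frame, _ = kinked_complex(angle)
        measured = geo.bend_angle(model, frame, self.UP, self.DOWN)
        assert measured == pytest.approx(angle, abs=2.0)

    def test_symmetric_in_arm_order(self):
        model, frame, _ = kinked_complex(34.0)
        a = geo.bend_angle(model, frame, self.UP, self.DOWN)
        # arm order swap is expressed by swapping range roles
        b = geo.bend_angle(model.transformed(np.eye(3), np.zeros(3)), frame,
                           self.UP, self.DOWN)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rigid_body_invariance(self):
        model, frame, _ = kinked_complex(34.0)
        a = geo.bend_angle(model, frame, self.UP, self.DOWN)
        R = Rotation.random(random_state=11).as_matrix()
        moved = model.transformed(R, np.array([40.0, -7.0, 3.0]))
        b = geo.bend_angle(moved, frame, self.UP, self.DOWN)
        assert a == pytest.approx(b, abs=1e-6)

    def test_overlapping_arms_rejected(self, straight_duplex):
        model, frame, _ = straight_duplex
        with pytest.raises(geo.GeometryError):
            geo.bend_angle(model, frame, (-5, 3), (1, 9))


class TestGrooveWidths:
    def test_uniform_widths_on_ideal_duplex(self, straight_duplex):
        model, frame, _ = straight_duplex
        w = geo.groove_widths(model, frame)
        mid = w.dropna(subset=["major", "minor"])
        assert mid["major"].std() < 0.3
        assert mid["minor"].std() < 0.3
        assert (mid["major"] > mid["minor"]).all()

    def test_planted_widening_recovered(self):
        base, _ = syn.make_duplex(DuplexSpec(sequence=SEQ30))
        wide, _ = syn.make_duplex(DuplexSpec(sequence=SEQ30,
                                             widen=((9, 21), 2.0)))
        frame = frame_over(base, 30, 14)
        w0 = geo.groove_widths(base, frame)
        w1 = geo.groove_widths(wide, frame)
        delta = w1[["major", "minor"]] - w0[["major", "minor"]]
        centre = delta.loc[1:2]   # registers fully inside the widened stretch
        for g in ("major", "minor"):
            assert centre[g].mean() == pytest.approx(2.0, abs=0.3)
        # flanking positions whose registers avoid the widened stretch
        assert delta["minor"].loc[-11:-9].abs().max() < 0.1
        assert abs(delta["major"].loc[13]) < 0.1

    def test_register_minor_equals_bruteforce_minimum(self, straight_duplex):
        model, frame, _ = straight_duplex
        reg = geo.groove_widths(model, frame)
        brute = geo.groove_widths_bruteforce(model, frame)
        joined = reg.join(brute).dropna(subset=["minor", "narrowest"])
        assert np.allclose(joined["minor"], joined["narrowest"], atol=1e-9)

    def test_missing_phosphate_flagged_undefined(self, straight_duplex):
        model, frame, _ = straight_duplex
        broken = model.transformed(np.eye(3), np.zeros(3))
        res = broken.get_residue(("D", 12, ""))
        res.atoms = [a for a in res.atoms if a.name != "P"]
        w = geo.groove_widths(broken, frame)
        assert np.isnan(w.loc[1, "minor"]) and np.isnan(w.loc[1, "major"])


class TestTwist:
    def test_ideal_twist_36_degrees(self, straight_duplex):
        model, frame, _ = straight_duplex
        tw = geo.per_step_twist(model, frame)
        assert tw["twist_deg"].mean() == pytest.approx(36.0, abs=1.0)


class TestFlippedBases:
    def test_ideal_duplex_has_no_flips(self, straight_duplex):
        model, frame, _ = straight_duplex
        assert geo.detect_flipped_bases(model, frame) == []

    @pytest.mark.parametrize("idx,strand", [(11, "bottom"), (8, "top")])
    def test_planted_flip_detected_exactly(self, idx, strand):
        seq = "GCTAGCTAGCATCGATCGATCGAT"
        model, truth = syn.make_duplex(DuplexSpec(sequence=seq,
                                                  flip=(idx, strand)))
        frame = frame_over(model, 24, 11)
        from ispkit.struct_io import position_run
        expected_pos = position_run(-11, 24)[idx]
        flips = geo.detect_flipped_bases(model, frame)
        assert [(p, s) for p, s, _ in flips] == [(expected_pos, strand)]
        assert flips[0][2] >= 8.0

    def test_zero_false_positives_across_seeded_fixtures(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        for _ in range(10):
            seq = "".join(rng.choice(list(bases), 24))
            model, _ = syn.make_duplex(DuplexSpec(sequence=seq))
            frame = frame_over(model, 24, 11)
            assert geo.detect_flipped_bases(model, frame) == []

    def test_widths_and_flips_invariant_under_rigid_motion(self):
        seq = "GCTAGCTAGCATCGATCGATCGAT"
        model, _ = syn.make_duplex(DuplexSpec(sequence=seq, flip=(11, "bottom")))
        frame = frame_over(model, 24, 11)
        R = Rotation.random(random_state=4).as_matrix()
        moved = model.transformed(R, np.array([-15.0, 9.0, 22.0]))
        w_a = geo.groove_widths(model, frame)
        w_b = geo.groove_widths(moved, frame)
        assert np.allclose(w_a[["major", "minor"]].fillna(-1),
                           w_b[["major", "minor"]].fillna(-1), atol=1e-9)
        f_a = geo.detect_flipped_bases(model, frame)
        f_b = geo.detect_flipped_bases(moved, frame)
        assert [(p, s) for p, s, _ in f_a] == [(p, s) for p, s, _ in f_b]


class TestDescribeDuplex:
    def test_summary_bundle(self):
        model, frame, truth = kinked_complex(34.0)
        geo_out = geo.describe_duplex(model, frame, TestBendAngle.UP,
                                      TestBendAngle.DOWN)
        assert geo_out.bend_angle == pytest.approx(34.0, abs=2.0)
        summary = geo_out.to_summary()
        assert summary["flipped"] == []
        assert summary["bend_angle_deg"] == geo_out.bend_angle
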