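import numpy as np
import pytest

import bundledissect as bd
from bundledissect.core import ReferenceSpace, ScalarVolume, Tractogram
from bundledissect.decompose import (assign_parcels, decompose, distal_segment,
                                     tract_scalar_stats)


class TestDistalSegment:
    def test_straight_line_exact_cut(self):
        """50 mm line along +y ending at (10,60,0): distal 20 mm runs from
        (10,40,0) to (10,60,0)."""
        y = np.linspace(10, 60, 26)  # 2 mm vertex spacing
        s = np.stack([np.full_like(y, 10.0), y, np.zeros_like(y)], axis=1)
        seg = distal_segment(s, length=20.0)
        assert np.allclose(seg[0], [10, 40, 0])
        assert np.allclose(seg[-1], [10, 60, 0])
        assert np.linalg.norm(np.diff(seg, axis=0), axis=1).sum() == pytest.approx(20.0)

    def test_interpolated_cut_point(self):
        s = np.array([[0, 0, 0], [0, 30, 0], [0, 47, 0]], float)
        seg = distal_segment(s, length=20.0)
        assert np.allclose(seg[0], [0, 27, 0])

    def test_short_streamline_returned_whole(self):
        s = np.array([[0, 20, 0], [0, 26, 0], [0, 32, 0]], float)
        seg = distal_segment(s, length=20.0)
        assert np.allclose(seg, s)

    def test_zero_length_is_the_endpoint(self):
        s = np.array([[0, 0, -20], [0, 40, 0]], float)
        seg = distal_segment(s, length=0.0)
        assert seg.shape == (1, 3) and np.allclose(seg[0], [0, 40, 0])

    def test_orientation_independent(self):
        s = np.array([[0, 0, -20], [0, 20, 0], [0, 50, 10]], float)
        a = distal_segment(s, length=15.0)
        b = distal_segment(s[::-1], length=15.0)
        assert np.allclose(a, b)


class TestAssignParcels:
    def test_terminal_inside_slab(self, labels):
        # straight approach ending in the right superiorfrontal tile (y=58)
        s = np.array([[9.0, 20.0, 40.0], [9.0, 58.0, 40.0]])
        assert assign_parcels(s, labels) == {"rh-superiorfrontal"}

    def test_grazing_two_adjacent_tiles(self, labels):
        # distal segment running *along* the thin coronal plane across the
        # superiorfrontal/rostralmiddlefrontal border -> multi-membership
        s = np.array([[9.0, 30.0, 40.0], [9.0, 58.0, 40.0], [20.0, 58.0, 40.0]])
        assert assign_parcels(s, labels) == {"rh-superiorfrontal",
                                             "rh-rostralmiddlefrontal"}

    def test_background_only(self, labels):
        s = np.array([[9.0, 25.0, 10.0], [9.0, 40.0, 10.0]])
        assert assign_parcels(s, labels) == set()

    def test_temporal_label_not_counted_as_prefrontal(self, labels):
        s = np.array([[45.0, -40.0, -17.0], [45.0, -20.0, -17.0]])
        assert assign_parcels(s, labels) == set()


class TestDecompose:
    def test_counts_match_ground_truth_exactly(self, subject, selected):
        """With disjoint parcels and clean approaches the per-parcel counts
        equal the generator's class counts."""
        import collections
        gt = subject.ground_truth
        right_classes = [c for c, r in zip(gt.classes, selected.records)
                         if r["side"] == "right"]
        expected = collections.Counter(c.split("-", 1)[1] for c in right_classes)
        rep, parcel_sets = decompose(selected.right, subject.labels, "right")
        assert rep.n_total == len(right_classes)
        # allow the rare jittered terminal that slips off its slab
        for parcel, cnt in expected.items():
            assert abs(rep.counts[parcel] - cnt) <= max(2, 0.02 * cnt)
        # every frontal streamline sits in >= 1 sub-bundle
        assert sum(1 for ps in parcel_sets if ps) == rep.n_frontal
        assert sum(rep.counts.values()) >= rep.n_frontal

    def test_brute_force_equivalence(self, subject, selected):
        """decompose ≡ independent per-streamline re-evaluation."""
        rep, parcel_sets = decompose(selected.right, subject.labels, "right")
        labels = subject.labels
        for s, ps in zip(selected.right.streamlines, parcel_sets):
            # oracle: dense sampling of the last 20 mm walked vertex-wise
            p = bd.subdivide_polyline(np.asarray(s), 0.1)
            if p[0, 1] > p[-1, 1]:
                p = p[::-1]
            d_from_end = np.concatenate(
                [[0], np.cumsum(np.linalg.norm(np.diff(p[::-1], axis=0), axis=1))])
            distal = p[::-1][d_from_end <= 20.0 + 1e-9][::-1]
            idx = np.rint(labels.space.world_to_voxel(distal)).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(labels.space.shape)), axis=1)
            hit = {labels.names[int(v)] for v in np.unique(labels.grid[tuple(idx[ok].T)])
                   if v != 0 and "temporal" not in labels.names[int(v)]}
            assert hit == ps

    def test_empty_bundle_gives_empty_report(self, subject, spec):
        rep, sets = decompose(Tractogram([], spec.space), subject.labels, "right")
        assert rep.n_total == 0 and rep.n_frontal == 0 and rep.percent_of_full == 0.0

    def test_all_in_one_parcel(self, labels, spec):
        sls = [np.array([[9.0, 20.0, 40.0], [9.0 + dx, 58.0, 40.0]])
               for dx in (0.0, 0.5, 1.0)]
        rep, _ = decompose(Tractogram(sls, spec.space), labels, "right")
        assert rep.percent_of_frontal["superiorfrontal"] == 100.0
        assert sum(v for k, v in rep.percent_of_frontal.items()
                   if k != "superiorfrontal") == 0.0


class TestScalarStats:
    def test_constant_field(self):
        space = ReferenceSpace(np.eye(4), (4, 4, 4))
        fa = ScalarVolume(np.full((4, 4, 4), 0.354), space)
        region = np.zeros((4, 4, 4), bool)
        region[1:3, 1:3, 1:3] = True
        out = tract_scalar_stats(region, {"fa": fa})
        assert out["fa"] == pytest.approx(0.354)

    def test_hand_average(self):
        space = ReferenceSpace(np.eye(4), (2, 1, 1))
        ax = ScalarVolume(np.array([900.0, 940.0]).reshape(2, 1, 1), space,
                          units="um^2/s")
        region = np.ones((2, 1, 1), bool)
        assert tract_scalar_stats(region, {"axial": ax})["axial"] == pytest.approx(920.0)

    def test_empty_region_flags_nan(self):
        space = ReferenceSpace(np.eye(4), (2, 2, 2))
        fa = ScalarVolume(np.zeros((2, 2, 2)), space)
        out = tract_scalar_stats(np.zeros((2, 2, 2), bool), {"fa": fa})
        assert np.isnan(out["fa"])

    def test_shape_mismatch_raises(self):
        space = ReferenceSpace(np.eye(4), (2, 2, 2))
        fa = ScalarVolume(np.zeros((2, 2, 2)), space)
        with pytest.raises(ValueError):
            tract_scalar_stats(np.ones((3, 3, 3), bool), {"fa": fa})

    def test_per_mille_report_units(self):
        rep = bd.SubBundleReport(
            hemisphere="right", n_total=10, n_frontal=10,
            counts={"superiorfrontal": 10},
            percent_of_frontal={"superiorfrontal": 100.0},
            percent_of_full=100.0,
            scalar_means={"fa": {"superiorfrontal": 0.354},
                          "axial": {"superiorfrontal": 920.0}})
        frame = rep.to_frame(per_mille=True)
        assert frame.loc[0, "fa"] == pytest.approx(354.0)
        assert frame.loc[0, "axial"] == pytest.approx(920.0)  # ADCs unscaled
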