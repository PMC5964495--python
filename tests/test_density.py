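import numpy as np
import pytest

import bundledissect as bd
from bundledissect.core import ReferenceSpace, Tractogram
from bundledissect.density import (group_average, relative_map, render_density,
                                   subdivide_polyline, threshold_indicator)


@pytest.fixture
def unit_space():
    return ReferenceSpace(np.eye(4), (12, 12, 12))


def total_length(t):
    return sum(np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in t)


class TestRenderDensity:
    def test_mass_conservation_random_tractograms(self, unit_space):
        """Central splatting oracle: grid sum equals total in-grid length."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            sls = [np.cumsum(rng.normal(scale=0.5, size=(n, 3)), axis=0) + 5.5
                   for n in rng.integers(2, 30, size=8)]
            t = Tractogram(sls, unit_space)
            d = render_density(t, unit_space)
            in_grid = total_length(t) - d.dropped_length
            assert abs(d.grid.sum() - in_grid) <= 1e-6 * total_length(t)

    def test_hand_computed_trilinear_weights(self, unit_space):
        """A 3 mm segment along a voxel-center line splits mass along its
        own axis only, matching hand-computed trilinear weights."""
        line = np.array([[5.0, 4.0, 5.0], [5.0, 7.0, 5.0]])
        d = render_density(Tractogram([line], unit_space), unit_space, step=1.0)
        assert abs(d.grid.sum() - 3.0) < 1e-12
        # midpoints at y=4.5,5.5,6.5 -> voxels (5,4..7,5) share the mass
        assert d.grid[5, 4, 5] == pytest.approx(0.5)
        assert d.grid[5, 5, 5] == pytest.approx(1.0)
        assert d.grid[5, 6, 5] == pytest.approx(1.0)
        assert d.grid[5, 7, 5] == pytest.approx(0.5)
        assert np.count_nonzero(d.grid) == 4

    def test_linearity_under_duplication(self, unit_space):
        rng = np.random.default_rng(4)
        sls = [np.cumsum(rng.normal(scale=0.4, size=(9, 3)), axis=0) + 6 for _ in range(5)]
        d1 = render_density(Tractogram(sls, unit_space), unit_space)
        d2 = render_density(Tractogram(sls + sls, unit_space), unit_space)
        assert np.allclose(d2.grid, 2 * d1.grid)

    def test_empty_tractogram(self, unit_space):
        d = render_density(Tractogram([], unit_space), unit_space)
        assert not d.grid.any()

    def test_out_of_grid_mass_is_accounted(self, unit_space):
        line = np.array([[5.0, -30.0, 5.0], [5.0, 5.0, 5.0]])
        d = render_density(Tractogram([line], unit_space), unit_space)
        assert d.dropped_length > 0
        assert abs(d.grid.sum() + d.dropped_length - 35.0) < 1e-9


class TestIndicatorsAndGroups:
    def test_threshold_boundary_inclusive(self, unit_space):
        d = bd.DensityMap(np.zeros((2, 2, 2)), None)
        d.grid = np.array([0.5, 1.0, 2.3]).reshape(3, 1, 1)
        assert list(threshold_indicator(d, 1.0).ravel()) == [False, True, True]
        assert threshold_indicator(d, 0.0).sum() == 3  # support at tau=0
        assert not threshold_indicator(d, 99.0).any()

    def test_group_average_values(self):
        a = np.zeros((3, 3, 3), bool)
        a[1, 1, 1] = True
        g = group_average([a, a, a])
        assert g.grid[1, 1, 1] == 100.0 and g.grid.sum() == 100.0
        b = np.zeros_like(a)
        g2 = group_average([a, b, b, b])
        assert g2.grid[1, 1, 1] == 25.0
        # probabilities live on the lattice {0, 100/n, ..., 100}
        assert set(np.unique(g2.grid)) <= {0.0, 25.0, 50.0, 75.0, 100.0}

    def test_group_average_errors(self):
        with pytest.raises(ValueError):
            group_average([])
        with pytest.raises(ValueError):
            group_average([np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool)])


class TestRelativeMap:
    def test_sub_equals_full_gives_100(self, unit_space):
        rng = np.random.default_rng(5)
        sls = [np.cumsum(rng.normal(scale=0.4, size=(8, 3)), axis=0) + 6 for _ in range(4)]
        t = Tractogram(sls, unit_space)
        rel = relative_map(t, t, unit_space)
        full = bd.passage_counts(t, unit_space)
        assert np.all(rel[full > 0] == 100.0)
        assert np.all(rel[full == 0] == 0.0)

    def test_disjoint_partition_sums_to_100(self, unit_space):
        rng = np.random.default_rng(6)
        sls = [np.cumsum(rng.normal(scale=0.4, size=(8, 3)), axis=0) + 6 for _ in range(6)]
        t = Tractogram(sls, unit_space)
        parts = [t.subset([0, 1]), t.subset([2, 3]), t.subset([4, 5])]
        total = sum(relative_map(p, t, unit_space) for p in parts)
        full = bd.passage_counts(t, unit_space)
        assert np.allclose(total[full > 0], 100.0)

    def test_trunk_share_matches_dominant_proportions(self, subject, selected, spec):
        """At the bundle bottleneck each dominant sub-bundle's relative map
        sits near its share of the bundle (the ~30% trunk signature)."""
        gt = subject.ground_truth
        right_idx = [i for i, c in enumerate(gt.classes) if c.startswith("rh-")
                     and "temporal" not in c]
        t_right = subject.tractogram.subset(right_idx)
        classes = [gt.classes[i] for i in right_idx]
        vox = np.rint(spec.space.world_to_voxel([6, -12, -8])).astype(int)
        for parcel, frac in (("superiorfrontal", 0.38),
                             ("rostralmiddlefrontal", 0.35),
                             ("lateralorbitofrontal", 0.24)):
            sub_t = t_right.subset([i for i, c in enumerate(classes)
                                    if c == f"rh-{parcel}"])
            rel = relative_map(sub_t, t_right, spec.space)
            assert rel[tuple(vox)] == pytest.approx(100 * frac, abs=8.0)


def test_subdivide_preserves_geometry():
    rng = np.random.default_rng(7)
    p = np.cumsum(rng.normal(size=(20, 3)), axis=0)
    q = subdivide_polyline(p, 0.3)
    assert np.allclose(np.linalg.norm(np.diff(p, axis=0), axis=1).sum(),
                       np.linalg.norm(np.diff(q, axis=0), axis=1).sum())
    assert np.max(np.linalg.norm(np.diff(q, axis=0), axis=1)) <= 0.3 + 1e-12
    # original vertices survive
    assert all(np.min(np.linalg.norm(q - v, axis=1)) < 1e-12 for v in p)
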