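import numpy as np
import pytest
from scipy import stats

import bundledissect as bd
from bundledissect.core import ReferenceSpace
from bundledissect.synthetic import (_smooth_noise, make_bundle,
                                     make_phantom_parcellation, make_subject,
                                     make_synthetic_dwi, tensor_field_from_tractogram)
from bundledissect.tensor import TensorVolume


class TestParcellation:
    def test_eight_prefrontal_parcels_per_hemisphere(self, labels):
        for prefix in ("rh-", "lh-"):
            pre = {v for v in labels.names.values()
                   if v.startswith(prefix) and "temporal" not in v}
            assert len(pre) == 8

    def test_prefrontal_voxels_strictly_frontal(self, labels, spec):
        cx, cy, cz = spec.space.voxel_centers()
        pre_ids = [k for k, v in labels.names.items() if "temporal" not in v]
        pre = np.isin(labels.grid, pre_ids)
        assert np.all(cy[pre] > 18)

    def test_hemisphere_label_sides_opposite(self, labels, spec):
        cx, _, _ = spec.space.voxel_centers()
        for k, name in labels.names.items():
            vox = labels.grid == k
            if name.startswith("rh-"):
                assert np.all(cx[vox] > 0)
            else:
                assert np.all(cx[vox] < 0)

    def test_temporal_territory_location(self, labels, spec):
        _, cy, cz = spec.space.voxel_centers()
        temp = np.isin(labels.grid,
                       [k for k, v in labels.names.items() if "temporal" in v])
        assert np.all(cy[temp] < 0) and np.all(cz[temp] < -8)

    def test_too_small_grid_rejected(self):
        tiny = ReferenceSpace(np.eye(4), (5, 5, 5))
        with pytest.raises(ValueError, match="too small"):
            make_phantom_parcellation(bd.PhantomSpec(space=tiny))


class TestMakeBundle:
    def test_prefrontal_bundle_passes_selection_and_assignment(self, spec, labels):
        rng = np.random.default_rng(2)
        sls, classes, _ = make_bundle("superiorfrontal", 10, spec, "right", rng)
        assert classes == ["rh-superiorfrontal"] * 10
        for s in sls:
            assert bd.visits_sphere(s, (6, -12, -8), 3.0)
            assert bd.connects_frontal_basal(s)
            assert bd.hemisphere_side(s) == "right"
            assert "rh-superiorfrontal" in bd.assign_parcels(s, labels)

    def test_commissural_fails_only_hemisphere(self, spec):
        rng = np.random.default_rng(3)
        sls, _, _ = make_bundle("commissural", 5, spec, "right", rng)
        for s in sls:
            assert bd.visits_sphere(s, (6, -12, -8), 3.0)
            assert bd.connects_frontal_basal(s)
            assert bd.hemisphere_side(s) is None

    def test_temporal_never_frontal(self, spec):
        rng = np.random.default_rng(4)
        sls, _, _ = make_bundle("temporal", 5, spec, "left", rng)
        for s in sls:
            assert bd.visits_sphere(s, (-6, -12, -8), 3.0)
            assert not bd.connects_frontal_basal(s)
            assert np.all(s[:, 1] < 18)

    def test_unknown_class_rejected(self, spec):
        with pytest.raises(ValueError):
            make_bundle("cerebellum", 1, spec, "right")


class TestJitterStatistics:
    def test_marginal_displacement_is_chi3(self):
        """Correlated jitter keeps the per-point marginal at N(0, sd²) per
        axis, so displacement norms follow a chi-3 distribution."""
        rng = np.random.default_rng(5)
        sd = 0.5
        noise = np.vstack([_smooth_noise(200, rng, sd, 3.0)[[60, 140]]
                           for _ in range(400)])  # well-separated samples
        r = np.linalg.norm(noise, axis=1)
        ks = stats.kstest(r / sd, stats.chi(3).cdf)
        assert ks.pvalue > 1e-4
        # analytic tail: P(r > 3 mm) at sd=0.5 is ~2e-8, so no point may fail
        assert (r > 3.0).sum() == 0

    def test_sphere_rule_failure_fraction_matches_tail(self, labels):
        """With jitter sd 0.5 every generated streamline still passes the
        3 mm sphere test (brute force), consistent with the chi-3 tail."""
        spec = bd.PhantomSpec(jitter_sd=0.5, seed=9)
        rng = np.random.default_rng(9)
        sls, _, _ = make_bundle("rostralmiddlefrontal", 300, spec, "right", rng)
        fails = sum(not bd.visits_sphere(s, (6, -12, -8), 3.0) for s in sls)
        assert fails == 0


class TestCohort:
    def test_same_seed_bit_identical(self, spec):
        a = make_subject(spec, seed=123)
        b = make_subject(spec, seed=123)
        assert len(a.tractogram) == len(b.tractogram)
        assert all(np.array_equal(x, y) for x, y in
                   zip(a.tractogram.streamlines, b.tractogram.streamlines))
        assert np.array_equal(a.tensor.data, b.tensor.data)

    def test_subjects_differ_but_share_targets(self, spec):
        cohort = bd.make_cohort(spec, 3)
        assert len({len(s.tractogram) for s in cohort}) >= 1
        assert not np.array_equal(cohort[0].tractogram.streamlines[0],
                                  cohort[1].tractogram.streamlines[0])
        assert all(s.ground_truth.proportions == cohort[0].ground_truth.proportions
                   for s in cohort)

    def test_class_counts_multinomial_with_fixed_seed(self, spec):
        """Realized counts equal an independent multinomial draw with the
        same generator state."""
        from bundledissect.synthetic import _class_probabilities
        import collections
        sub = make_subject(spec, seed=77)
        kinds, probs = _class_probabilities(spec)
        # the right hemisphere's counts are the generator's first draw
        expected = np.random.default_rng(77).multinomial(
            spec.n_streamlines // 2, probs)
        realized = collections.Counter(
            c for c in sub.ground_truth.classes
            if c.startswith("rh-") or c == "commissural")
        for kind, cnt in zip(kinds, expected):
            if kind == "commissural":
                continue  # commissural tags carry no hemisphere prefix
            assert realized["rh-" + kind] == cnt

    def test_proportions_converge(self):
        """Law of large numbers: realized prefrontal proportions approach
        the spec proportions within 3 standard errors."""
        spec = bd.PhantomSpec(n_streamlines=10_000, seed=21)
        sub = make_subject(spec, seed=21)
        import collections
        counts = collections.Counter(
            c.split("-", 1)[1] for c in sub.ground_truth.classes
            if "temporal" not in c and c != "commissural")
        n = sum(counts.values())
        for parcel, frac in sub.ground_truth.proportions.items():
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(counts[parcel] / n - frac) <= 3 * se + 1e-12

    def test_fa_inside_saturated_trunk_hits_configured_band(self, subject, spec):
        _, _, mass = tensor_field_from_tractogram(
            subject.tractogram, spec.space, saturation=spec.scalar_saturation)
        core = mass >= 10 * spec.scalar_saturation
        fa = subject.scalars["fa"].grid[core]
        assert 0.30 <= fa.mean() <= 0.40


class TestSyntheticDWI:
    def _iso_tensor(self, md=766.7):
        space = ReferenceSpace(np.eye(4), (2, 2, 2))
        return TensorVolume.from_matrices(
            np.broadcast_to(md * np.eye(3), (2, 2, 2, 3, 3)).copy(), space)

    def test_isotropic_signal_closed_form(self):
        bvals, bvecs = bd.default_gradients(n_dirs=10, shells=(1000.0,))
        sig = make_synthetic_dwi(self._iso_tensor(), bvals, bvecs, s0=1000.0)
        dw = sig[..., bvals > 0] / 1000.0
        assert np.allclose(dw, np.exp(-0.7667), atol=1e-10)

    def test_b0_equals_s0_at_infinite_snr(self):
        bvals, bvecs = bd.default_gradients(n_dirs=6)
        sig = make_synthetic_dwi(self._iso_tensor(), bvals, bvecs, s0=777.0)
        assert np.all(sig[..., bvals == 0] == 777.0)

    def test_stick_tensor_minimal_along_fiber(self):
        space = ReferenceSpace(np.eye(4), (1, 1, 1))
        D = np.diag([100.0, 1500.0, 100.0])  # fiber along +y
        tv = TensorVolume.from_matrices(D[None, None, None].copy(), space)
        n = 58
        bvals, bvecs = bd.default_gradients(n_dirs=n, shells=(1000.0,))
        bvecs = bvecs.copy()
        bvecs[2] = [0.0, 1.0, 0.0]  # ensure +y among directions
        sig = make_synthetic_dwi(tv, bvals, bvecs).ravel()
        dw = sig[bvals > 0]
        assert np.argmin(dw) == 0  # the +y direction

    def test_non_positive_definite_rejected(self):
        space = ReferenceSpace(np.eye(4), (2, 1, 1))
        m = np.broadcast_to(700 * np.eye(3), (2, 1, 1, 3, 3)).copy()
        m[1, 0, 0] = np.diag([-5.0, 700.0, 700.0])
        tv = TensorVolume.from_matrices(m, space)
        bvals, bvecs = bd.default_gradients(n_dirs=6)
        with pytest.raises(ValueError, match=r"\(1, 0, 0\)"):
            make_synthetic_dwi(tv, bvals, bvecs)

    def test_rician_noise_seeded(self):
        bvals, bvecs = bd.default_gradients(n_dirs=6)
        a = make_synthetic_dwi(self._iso_tensor(), bvals, bvecs, snr=20.0, seed=3)
        b = make_synthetic_dwi(self._iso_tensor(), bvals, bvecs, snr=20.0, seed=3)
        c = make_synthetic_dwi(self._iso_tensor(), bvals, bvecs, snr=20.0, seed=4)
        assert np.array_equal(a, b) and not np.array_equal(a, c)
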