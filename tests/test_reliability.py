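import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from herniaquant.io_core import LabeledVolume, ValidationError
from herniaquant.reliability import (
    aggregate_reports,
    cohen_kappa_masks,
    hausdorff_distance,
    landmark_representative_point,
    mean_surface_distance,
    reliability_report,
)
from herniaquant.synthetic_data import perturb_labels


def brute_force_msd(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_force_hd(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _vol_with_labels(labels):
    return LabeledVolume(
        np.zeros(labels.shape, dtype=np.float32),
        labels.astype(np.int16),
        np.diag([1.0, 1.0, 1.0, 1.0]),
    )


class TestDistances:
    def test_identical_sets_zero(self, rng):
        pts = rng.normal(size=(30, 3))
        assert mean_surface_distance(pts, pts) == 0.0
        assert hausdorff_distance(pts, pts) == 0.0

    def test_parallel_contours(self):
        x = np.linspace(0, 100, 400)
        a = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        b = a + [0.0, 2.0, 0.0]
        assert mean_surface_distance(a, b) == pytest.approx(2.0)
        assert hausdorff_distance(a, b) == pytest.approx(2.0)

    def test_outlier_dominates_hd_not_msd(self, rng):
        a = rng.normal(size=(50, 3))
        b = np.vstack([a, [[90.0, 0.0, 0.0]]])
        hd = hausdorff_distance(a, b)
        assert hd == pytest.approx(np.linalg.norm(a - [90, 0, 0], axis=1).min(), rel=1e-9)
        assert hd > 80.0
        assert mean_surface_distance(a, b) < 2.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(-50, 50, size=(40, 3))
            b = rng.uniform(-50, 50, size=(35, 3))
            assert mean_surface_distance(a, b) == pytest.approx(brute_force_msd(a, b), abs=1e-9)
            assert hausdorff_distance(a, b) == pytest.approx(brute_force_hd(a, b), abs=1e-9)

    @given(
        a=arrays(np.float64, (7, 3), elements=st.floats(-100, 100)),
        b=arrays(np.float64, (9, 3), elements=st.floats(-100, 100)),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_ordering(self, a, b):
        msd = mean_surface_distance(a, b)
        hd = hausdorff_distance(a, b)
        assert msd == pytest.approx(mean_surface_distance(b, a), abs=1e-12)
        assert hd == pytest.approx(hausdorff_distance(b, a), abs=1e-12)
        assert msd <= hd + 1e-12

    def test_empty_set_raises(self):
        with pytest.raises(ValidationError):
            mean_surface_distance(np.empty((0, 3)), np.zeros((3, 3)))
        with pytest.raises(ValidationError):
            hausdorff_distance(np.zeros((3, 3)), np.empty((0, 3)))


class TestRepresentativePoints:
    def test_pubic_symphysis_most_superior(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[5, 5, 10:13] = 14  # z in {10, 11, 12}
        point = landmark_representative_point(_vol_with_labels(labels), "pubic_symphysis")
        assert point[2] == 12.0

    def test_xiphoid_centroid(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        coords = [(3, 4, 5), (6, 4, 5), (3, 8, 5), (6, 8, 5), (4, 6, 9)]
        for c in coords:
            labels[c] = 10
        point = landmark_representative_point(_vol_with_labels(labels), "xiphoid")
        assert np.allclose(point, np.mean(coords, axis=0))

    def test_asis_tie_broken_deterministically(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        labels[4, 10, 3] = 12
        labels[8, 10, 3] = 12  # tie on y; higher x wins after z tie
        vol = _vol_with_labels(labels)
        p1 = landmark_representative_point(vol, "left_asis")
        p2 = landmark_representative_point(vol, "left_asis")
        assert np.array_equal(p1, p2)
        assert p1[0] == 8.0

    def test_umbilicus_centermost(self):
        labels = np.zeros((20, 20, 20), dtype=np.int16)
        for x in (2, 4, 6, 8, 10):
            labels[x, 5, 5] = 11
        point = landmark_representative_point(_vol_with_labels(labels), "umbilicus")
        assert point[0] == 6.0  # labeled voxel nearest the centroid

    def test_unknown_name_raises(self, default_phantom):
        vol, _ = default_phantom
        with pytest.raises(ValidationError, match="unknown"):
            landmark_representative_point(vol, "patella")


class TestKappa:
    def test_perfect_agreement(self):
        m = np.zeros((10, 10, 10), bool)
        m[3:6, 3:6, 3:6] = True
        assert cohen_kappa_masks(m, m) == pytest.approx(1.0)

    def test_disjoint_half_and_half(self):
        region = np.ones((10, 10, 1), bool)
        a = np.zeros_like(region)
        b = np.zeros_like(region)
        a[:5] = True
        b[5:] = True
        assert cohen_kappa_masks(a, b, region=region) == pytest.approx(-1.0)

    def test_hand_computed_table(self):
        # a=40 both, b=10 A-only, c=10 B-only, d=40 neither -> kappa = 0.6
        a = np.zeros((10, 10, 1), bool)
        b = np.zeros((10, 10, 1), bool)
        flat_a = np.r_[np.ones(40), np.ones(10), np.zeros(10), np.zeros(40)].astype(bool)
        flat_b = np.r_[np.ones(40), np.zeros(10), np.ones(10), np.zeros(40)].astype(bool)
        a[...] = flat_a.reshape(10, 10, 1)
        b[...] = flat_b.reshape(10, 10, 1)
        region = np.ones_like(a)
        assert cohen_kappa_masks(a, b, region=region) == pytest.approx(0.6)

    def test_degenerate_marginals_undefined(self):
        region = np.ones((4, 4, 1), bool)
        full = np.ones_like(region)
        assert cohen_kappa_masks(full, full, region=region) is None

    def test_complement_invariance(self):
        rng = np.random.default_rng(0)
        region = np.ones((8, 8, 4), bool)
        a = rng.random((8, 8, 4)) > 0.6
        b = rng.random((8, 8, 4)) > 0.5
        k1 = cohen_kappa_masks(a, b, region=region)
        k2 = cohen_kappa_masks(~a, ~b, region=region)
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_region_must_contain_masks(self):
        a = np.ones((4, 4, 1), bool)
        region = np.zeros_like(a)
        region[0, 0, 0] = True
        with pytest.raises(ValidationError):
            cohen_kappa_masks(a, a, region=region)


class TestReliabilityReport:
    def test_self_comparison(self, default_phantom):
        vol, _ = default_phantom
        rep = reliability_report(vol, vol)
        assert all(v == 0.0 for v in rep.msd_mm.values())
        assert all(v == 0.0 for v in rep.hd_mm.values())
        assert all(v == 0.0 for v in rep.landmark_ed_mm.values())
        assert rep.hernia_kappa == pytest.approx(1.0)

    def test_missing_structure_marked_absent(self, default_phantom):
        vol, _ = default_phantom
        stripped = LabeledVolume(
            vol.intensity, np.where(vol.labels == 3, 0, vol.labels), vol.affine
        )
        rep = reliability_report(vol, stripped)
        assert rep.msd_mm["posterior_wall"] is None
        assert rep.msd_mm["axial_outer"] is not None

    def test_msd_le_hd_on_perturbed_pair(self, default_phantom):
        vol, _ = default_phantom
        pert = perturb_labels(vol, 2.0, 3.0, seed=9)
        rep = reliability_report(vol, pert)
        for name, msd in rep.msd_mm.items():
            if msd is not None:
                assert msd <= rep.hd_mm[name]

    def test_batch_aggregation(self, default_phantom):
        vol, _ = default_phantom
        reports = [
            reliability_report(vol, perturb_labels(vol, 1.0, 1.0, seed=s))
            for s in range(3)
        ]
        agg = aggregate_reports(reports)
        entry = agg["msd_mm"]["axial_outer"]
        assert set(entry) == {"mean", "sd", "n"}
        assert entry["n"] == 3
        assert agg["hernia_kappa"]["mean"] <= 1.0

    def test_geometry_mismatch_rejected(self, default_phantom):
        vol, _ = default_phantom
        other = LabeledVolume(
            vol.intensity[:-1], vol.labels[:-1], vol.affine
        )
        with pytest.raises(ValidationError):
            reliability_report(vol, other)
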