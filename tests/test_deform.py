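"""Deformation: rescaling, void filling, overlaps, rib refit, vessels."""

import numpy as np
import pytest
from scipy.ndimage import binary_closing, binary_fill_holes, label as cc_label

from statphantom import deform as D
from statphantom import grid as g
from statphantom import materials as mat
from statphantom import series as ser
from statphantom import vessels as ves


def sphere_phantom(radius_vox=12, n=64):
    idx = np.arange(n) - n / 2 + 0.5
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    labels = ((x**2 + y**2 + z**2) <= radius_vox**2).astype(np.uint16)
    return g.LabeledVolume(labels, spacing=(0.2, 0.2, 0.2),
                           organ_map={1: ("ball", mat.MUSCLE)})


class TestRescaleOrgan:
    def test_identity_short_circuit(self):
        ph = sphere_phantom()
        out, vol = D.rescale_organ(ph, {1}, 1.0, (6.4, 6.4, 6.4))
        assert np.array_equal(out.labels, ph.labels)
        assert vol == g.volume_of(ph, {1})

    def test_double_volume_within_one_percent(self):
        ph = sphere_phantom()
        v0 = g.volume_of(ph, {1})
        out, vol = D.rescale_organ(ph, {1}, 2 ** (1 / 3), (6.4, 6.4, 6.4))
        assert vol == pytest.approx(2 * v0, rel=0.01)
        assert g.volume_of(out, {1}) == vol

    def test_centroid_stays_fixed(self):
        ph = sphere_phantom()
        c0 = g.centroid_of(ph, {1})
        out, _ = D.rescale_organ(ph, {1}, 1.15, c0)
        c1 = g.centroid_of(out, {1})
        assert np.linalg.norm(np.subtract(c1, c0)) <= np.linalg.norm(ph.spacing)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            D.rescale_organ(sphere_phantom(), {1}, 0.0, (0, 0, 0))


class TestFillVoids:
    def test_deflation_leaves_no_holes_and_mass_bookkeeping(self, materials):
        ph = sphere_phantom()
        ph.organ_map[1] = ("lung-like", mat.LUNG_TISSUE)
        ph.organ_map[g.L_RESIDUAL] = ("residual tissue", mat.RESIDUAL)
        before = ph.labels == 1
        out, _ = D.rescale_organ(ph, {1}, 0.8, (6.4, 6.4, 6.4))
        after = out.labels == 1
        filled = D.fill_voids(out, before, after)
        assert not ((before | after) & (filled.labels == 0)).any()
        dv = (before.sum() - after.sum()) * ph.voxel_volume
        m0 = g.mass_of(ph, {1}, materials)
        m1 = g.mass_of(filled, {1, g.L_RESIDUAL}, materials)
        gain = dv * (materials.density_of(mat.RESIDUAL)
                     - materials.density_of(mat.LUNG_TISSUE))
        assert m1 - m0 == pytest.approx(gain, rel=1e-9)

    def test_no_deflation_is_identity(self):
        ph = sphere_phantom()
        mask = ph.labels == 1
        out = D.fill_voids(ph, mask, mask)
        assert np.array_equal(out.labels, ph.labels)


class TestResolveOverlaps:
    @staticmethod
    def conflict_fixture():
        labels = np.zeros((8, 8, 8), dtype=np.uint16)
        labels[1:4, 1:4, 1:4] = g.L_RLUNG
        labels[4:7, 1:4, 1:4] = g.L_HEART
        ph = g.LabeledVolume(labels, organ_map={
            g.L_RLUNG: ("right lung tissue", mat.LUNG_TISSUE),
            g.L_HEART: ("heart", mat.HEART_TISSUE)})
        conflict = np.zeros_like(labels, dtype=bool)
        conflict[4, 1, 1] = conflict[4, 2, 2] = True
        return ph, {g.L_RLUNG: conflict}

    def test_no_conflicts_is_identity(self):
        ph, _ = self.conflict_fixture()
        out = D.resolve_overlaps(ph, D.DeformationPolicy(), None)
        assert np.array_equal(out.labels, ph.labels)

    def test_lung_wins_transfers_both_voxels(self, materials):
        ph, conflicts = self.conflict_fixture()
        heart_v0 = g.volume_of(ph, {g.L_HEART})
        out = D.resolve_overlaps(ph, D.DeformationPolicy(overlap_mode=D.LUNG_WINS),
                                 conflicts)
        assert (out.labels[conflicts[g.L_RLUNG]] == g.L_RLUNG).all()
        assert g.volume_of(out, {g.L_HEART}) == pytest.approx(
            heart_v0 - 2 * ph.voxel_volume)

    def test_organ_wins_keeps_heart(self):
        ph, conflicts = self.conflict_fixture()
        out = D.resolve_overlaps(ph, D.DeformationPolicy(overlap_mode=D.ORGAN_WINS),
                                 conflicts)
        assert (out.labels[conflicts[g.L_RLUNG]] == g.L_HEART).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="overlap mode"):
            D.DeformationPolicy(overlap_mode="both_win")


def _enclosed(cage):
    """Interior of the open banded barrel: bridge the inter-rib gaps in z,
    then take the per-slice convex hull (robust to small arc breaks where
    the cage is clipped at the body surface)."""
    from skimage.morphology import convex_hull_image

    closed = binary_closing(cage, structure=np.ones((1, 1, 5), bool))
    out = np.zeros_like(cage)
    for k in range(cage.shape[2]):
        if closed[:, :, k].any():
            out[:, :, k] = convex_hull_image(closed[:, :, k])
    return out


class TestRefitRibcage:
    def test_identity_at_unit_scale(self, coarse_template):
        out = D.refit_ribcage(coarse_template, 1.0)
        assert np.array_equal(out.labels, coarse_template.labels)

    def test_scale_grows_enclosed_volume_and_preserves_thickness(self, coarse_template):
        cage0 = coarse_template.labels == g.L_RIBS
        out = D.refit_ribcage(coarse_template, 1.1)
        cage1 = out.labels == g.L_RIBS
        v0 = _enclosed(cage0).sum()
        v1 = _enclosed(cage1).sum()
        assert v1 / v0 == pytest.approx(1.1**3, rel=0.10)
        # the new, larger cage still encloses at least as much of the lung
        lung = np.isin(coarse_template.labels, list(g.LUNG_LABELS))
        out0 = int((lung & ~_enclosed(cage0)).sum())
        out1 = int((lung & ~_enclosed(cage1)).sum())
        assert out1 <= out0
        t0 = D.shell_thickness_cm(cage0, coarse_template.spacing)
        t1 = D.shell_thickness_cm(cage1, coarse_template.spacing)
        assert abs(t1 - t0) <= max(coarse_template.spacing)

    def test_missing_ribs_rejected(self):
        ph = sphere_phantom()
        with pytest.raises(ValueError, match="rib"):
            D.refit_ribcage(ph, 1.1)


class TestAdjustVessels:
    def test_factor_one_is_identity(self, coarse_template):
        out = D.adjust_vessels(coarse_template, 1.0)
        assert np.array_equal(out.labels, coarse_template.labels)

    @pytest.mark.parametrize("factor", [1.5, 0.5])
    def test_volume_factor_achieved_within_two_percent(self, coarse_template, factor):
        out = D.adjust_vessels(coarse_template, factor)
        for v_label in g.VESSEL_LABELS:
            n0 = int((coarse_template.labels == v_label).sum())
            n1 = int((out.labels == v_label).sum())
            assert n1 == pytest.approx(factor * n0, rel=0.02)

    def test_pruning_preserves_main_trunk(self, coarse_template):
        c_r = g.centroid_of(coarse_template, g.RIGHT_LOBE_LABELS)
        c_l = g.centroid_of(coarse_template, g.LEFT_LOBE_LABELS)
        mid = 0.5 * (np.asarray(c_r) + np.asarray(c_l))
        out = D.adjust_vessels(coarse_template, 0.5)
        for v_label in g.VESSEL_LABELS:
            orig = coarse_template.labels == v_label
            hil = ves.hilum_voxel(out.labels == v_label, mid,
                                  coarse_template.spacing, coarse_template.origin)
            comp, n_comp = cc_label(out.labels == v_label,
                                    structure=np.ones((3, 3, 3)))
            sizes = np.bincount(comp.ravel())[1:]
            assert comp[hil] == int(np.argmax(sizes)) + 1
            assert orig[hil]  # hilum voxel was part of the original tree

    def test_unreachable_target_rejected(self, coarse_template):
        with pytest.raises(ValueError, match="exceeds"):
            D.adjust_vessels(coarse_template, 50.0)


class TestBuildStatisticalPhantom:
    def test_reference_spec_reproduces_template(self, coarse_template, materials):
        spec = ser.spec_for_mass(ser.REFERENCE_TOTAL_MASS_G, ser.MassDistribution())
        out, prov = D.build_statistical_phantom(coarse_template, spec,
                                                D.DeformationPolicy(), materials)
        diff = (out.labels != coarse_template.labels).mean()
        assert diff < 0.01  # identical up to re-binarization noise
        assert prov.achieved_mass_g == pytest.approx(1208.37, rel=0.01)

    def test_modes_agree_without_conflicts(self, coarse_template, materials):
        spec = ser.spec_for_mass(1100.0, ser.MassDistribution())
        a, pa = D.build_statistical_phantom(
            coarse_template, spec, D.DeformationPolicy(overlap_mode=D.LUNG_WINS), materials)
        b, pb = D.build_statistical_phantom(
            coarse_template, spec, D.DeformationPolicy(overlap_mode=D.ORGAN_WINS), materials)
        assert pa.conflict_voxels_heart == 0 and pa.conflict_voxels_liver == 0
        assert np.array_equal(a.labels, b.labels)

    def test_largest_lung_modes_differ_only_in_conflicts(self, coarse_template, materials):
        dist = ser.MassDistribution()
        spec = ser.spec_for_mass(dist.mean_g + 3 * dist.sd_g, dist)
        a, pa = D.build_statistical_phantom(
            coarse_template, spec, D.DeformationPolicy(overlap_mode=D.LUNG_WINS), materials)
        b, _ = D.build_statistical_phantom(
            coarse_template, spec, D.DeformationPolicy(overlap_mode=D.ORGAN_WINS), materials)
        diff = a.labels != b.labels
        assert pa.conflict_voxels_heart + pa.conflict_voxels_liver > 0
        assert diff.sum() == pa.conflict_voxels_heart + pa.conflict_voxels_liver
        heart_liver = np.isin(coarse_template.labels, [g.L_HEART, g.L_LIVER])
        assert (diff <= heart_liver).all()

    def test_series_convergence_and_conservation(self, coarse_template, materials):
        specs = ser.plan_series(ser.MassDistribution(n=12, seed=21))
        diag = np.linalg.norm(coarse_template.spacing)
        body0 = int((coarse_template.labels != 0).sum())
        counts = []
        for spec in specs:
            out, prov = D.build_statistical_phantom(coarse_template, spec,
                                                    D.DeformationPolicy(), materials)
            assert int((out.labels != 0).sum()) == body0
            assert abs(prov.achieved_volume_cm3 - spec.target_volume_cm3) \
                <= 0.01 * spec.target_volume_cm3
            for labels, ref in ((g.RIGHT_LOBE_LABELS, g.centroid_of(coarse_template, g.RIGHT_LOBE_LABELS)),
                                (g.LEFT_LOBE_LABELS, g.centroid_of(coarse_template, g.LEFT_LOBE_LABELS))):
                drift = np.linalg.norm(np.subtract(g.centroid_of(out, labels), ref))
                assert drift <= diag
            counts.append(int(np.isin(out.labels, list(g.LUNG_LABELS)).sum()))
        order = np.argsort([s.target_mass_g for s in specs])
        sorted_counts = np.asarray(counts)[order]
        assert np.all(np.diff(sorted_counts) >= 0)
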