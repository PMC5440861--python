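"""Photon transport: source models, attenuation physics, scoring, errors."""

import numpy as np
import pytest
from scipy import stats as sps

from statphantom import grid as g
from statphantom import materials as mat
from statphantom.transport import (BeamConfig, DoseResult, N_BATCHES, dose_map,
                                   sample_primary, transport, _kahn_compton)

from conftest import water_block

BOX = ((0.0, 0.0, 0.0), (30.0, 20.0, 40.0))


class TestSamplePrimary:
    def test_ap_is_exactly_forward(self):
        rng = np.random.default_rng(0)
        beam = BeamConfig("AP", 1.0, 10)
        for _ in range(50):
            pos, d = sample_primary(beam, BOX, rng)
            assert tuple(d) == (0.0, 1.0, 0.0)
            assert pos[1] < 0.0

    @pytest.mark.parametrize("geometry,axis,sign", [
        ("PA", 1, -1.0), ("LLAT", 0, -1.0), ("RLAT", 0, 1.0)])
    def test_parallel_beam_directions(self, geometry, axis, sign):
        rng = np.random.default_rng(1)
        pos, d = sample_primary(BeamConfig(geometry, 1.0, 10), BOX, rng)
        expected = np.zeros(3)
        expected[axis] = sign
        assert np.allclose(d, expected)

    def test_iso_directions_are_isotropic(self):
        rng = np.random.default_rng(2)
        beam = BeamConfig("ISO", 1.0, 10)
        dirs = np.array([sample_primary(beam, BOX, rng)[1] for _ in range(100_000)])
        # each component has variance 1/3; the mean should be ~N(0, 1/(3n))
        sigma = np.sqrt(1.0 / (3 * len(dirs)))
        assert np.all(np.abs(dirs.mean(axis=0)) < 3 * sigma)

    def test_rot_is_normal_to_z_with_uniform_azimuth(self):
        rng = np.random.default_rng(3)
        beam = BeamConfig("ROT", 1.0, 10)
        dirs = np.array([sample_primary(beam, BOX, rng)[1] for _ in range(100_000)])
        assert np.all(dirs[:, 2] == 0.0)
        phi = np.arctan2(dirs[:, 1], dirs[:, 0])
        counts, _ = np.histogram(phi, bins=16, range=(-np.pi, np.pi))
        chi2 = ((counts - len(dirs) / 16) ** 2 / (len(dirs) / 16)).sum()
        assert chi2 < sps.chi2.ppf(0.99, df=15)

    def test_invalid_beam_configs_rejected(self):
        with pytest.raises(ValueError):
            BeamConfig("SLANT", 1.0, 10)
        with pytest.raises(ValueError):
            BeamConfig("AP", 25.0, 10)
        with pytest.raises(ValueError):
            BeamConfig("AP", 1.0, 0)


class TestTransportPhysics:
    def test_slab_attenuation_matches_beer_lambert(self, materials):
        ph = water_block((40, 100, 40), (0.25, 0.25, 0.25))
        beam = BeamConfig("AP", 0.1, 40_000, seed=3, margin_cm=0.0)
        res = transport(ph, materials, beam, record_first_flight=beam.histories)
        mu, _ = mat.lookup_mu(materials, mat.MUSCLE, 0.1)
        mu_lin = mu * materials.density_of(mat.MUSCLE)
        ff = res.first_flight_cm
        for depth in (2.0, 5.0, 10.0):
            surviving = float(np.mean(ff > depth))
            expected = np.exp(-mu_lin * depth)
            se = np.sqrt(expected * (1 - expected) / ff.size)
            assert abs(surviving - expected) < 3 * se

    def test_thin_sheet_first_collision_kerma(self, materials):
        # one thin soft-tissue sheet normal to the beam: dose/fluence equals
        # E * mu_en/rho * (uncollided average) up to a sub-percent scatter term
        ph = water_block((4, 1, 4), (0.25, 0.04, 0.25))
        beam = BeamConfig("AP", 0.1, 100_000, seed=4, margin_cm=0.0)
        res = transport(ph, materials, beam)
        mu, muen = mat.lookup_mu(materials, mat.MUSCLE, 0.1)
        rho = materials.density_of(mat.MUSCLE)
        t = 0.04
        uncollided_avg = (1 - np.exp(-mu * rho * t)) / (mu * rho * t)
        expected = 0.1 * muen * uncollided_avg * mat.MEV_PER_G_TO_PGY
        got = res.dose_per_fluence({2})
        tol = max(3 * res.relative_error({2}), 0.015)
        assert got == pytest.approx(expected, rel=tol)

    def test_same_seed_reproduces_identical_results(self, coarse_template, materials):
        beam = BeamConfig("AP", 0.3, 20_000, seed=11)
        a = transport(coarse_template, materials, beam)
        b = transport(coarse_template, materials, beam)
        assert np.array_equal(a.label_batch_mev, b.label_batch_mev)
        assert a.total_edep_mev == b.total_edep_mev

    def test_ladf_invariant_under_beam_margin(self, coarse_template, materials):
        a = transport(coarse_template, materials,
                      BeamConfig("AP", 1.0, 150_000, seed=5, margin_cm=5.0))
        b = transport(coarse_template, materials,
                      BeamConfig("AP", 1.0, 150_000, seed=6, margin_cm=10.0))
        tol = 3 * np.hypot(a.lung_rel_err, b.lung_rel_err)
        assert a.lung_ladf == pytest.approx(b.lung_ladf, rel=tol)

    def test_energy_conservation_bound(self, coarse_template, materials):
        beam = BeamConfig("AP", 1.0, 20_000, seed=7)
        res = transport(coarse_template, materials, beam)
        assert res.total_edep_mev <= beam.histories * beam.energy_mev

    def test_ap_exceeds_lateral_at_low_energy(self, coarse_template, materials):
        for e in (0.02, 0.1):
            ap = transport(coarse_template, materials,
                           BeamConfig("AP", e, 100_000, seed=8))
            lat = transport(coarse_template, materials,
                            BeamConfig("LLAT", e, 100_000, seed=8))
            assert ap.lung_ladf > lat.lung_ladf

    def test_ladf_decreases_with_chest_wall_thickness(self, materials):
        from statphantom.template import TemplateConfig, build_template
        from conftest import COARSE_SPACING
        beams = BeamConfig("AP", 0.02, 200_000, seed=9)
        doses = []
        for wall in (2.0, 3.5):
            cfg = TemplateConfig(spacing=COARSE_SPACING, chest_wall_cm=wall)
            doses.append(transport(build_template(cfg), materials, beams).lung_ladf)
        assert doses[1] < doses[0]

    def test_batch_errors_consistent_with_seed_scatter(self, coarse_template, materials):
        values, errors = [], []
        for seed in range(10):
            res = transport(coarse_template, materials,
                            BeamConfig("AP", 0.3, 10_000, seed=100 + seed))
            values.append(res.lung_ladf)
            errors.append(res.lung_rel_err)
        values = np.asarray(values)
        sigma = np.mean(errors) * values.mean()
        stat = (len(values) - 1) * values.var(ddof=1) / sigma**2
        lo = sps.chi2.ppf(0.005, df=9)
        hi = sps.chi2.ppf(0.995, df=9)
        assert lo < stat < hi

    def test_kahn_sampler_matches_klein_nishina_mean(self):
        import numba

        @numba.njit(cache=False)
        def draw(k, n, seed):
            np.random.seed(seed)
            out = np.empty(n)
            for i in range(n):
                out[i] = 1.0 / _kahn_compton(k)
            return out

        for e_mev in (0.1, 0.5, 2.0, 8.0):
            k = e_mev / 0.51099895
            sample = draw(k, 100_000, 42)
            r = np.linspace(1.0 / (1.0 + 2.0 * k), 1.0, 4001)  # E'/E
            cos = 1.0 - (1.0 / r - 1.0) / k
            pdf = r + 1.0 / r - (1.0 - cos**2)   # KN density in r, unnormalized
            pdf /= np.trapezoid(pdf, r)
            mean = np.trapezoid(r * pdf, r)
            se = sample.std() / np.sqrt(sample.size)
            assert abs(sample.mean() - mean) < 4 * se


class TestDoseMap:
    def test_mass_weighted_sum_conserves_energy(self, coarse_template, materials):
        beam = BeamConfig("AP", 0.3, 20_000, seed=12)
        res = transport(coarse_template, materials, beam, score_map=True)
        assert res.edep_map_mev.sum() == pytest.approx(res.total_edep_mev, rel=1e-9)
        pct = dose_map(res, coarse_template, materials)
        assert pct.max() == pytest.approx(100.0)
        assert pct.min() >= 0.0

    def test_rebinned_map_shape(self, coarse_template, materials):
        res = transport(coarse_template, materials,
                        BeamConfig("AP", 0.3, 5_000, seed=13), score_map=True)
        pct = dose_map(res, coarse_template, materials, rebin=(2, 2, 1))
        assert pct.shape == (coarse_template.shape[0] // 2,
                             coarse_template.shape[1] // 2,
                             coarse_template.shape[2])

    def test_all_zero_map_stays_zero(self, coarse_template, materials):
        res = DoseResult(
            energy_mev=1.0, geometry="AP", histories=1, beam_area_cm2=1.0,
            label_edep_mev=np.zeros(12), label_batch_mev=np.zeros((12, N_BATCHES)),
            label_mass_g=np.ones(12), total_edep_mev=0.0,
            edep_map_mev=np.zeros(coarse_template.shape))
        pct = dose_map(res, coarse_template, materials)
        assert not pct.any()

    def test_map_missing_errors(self, coarse_template, materials):
        res = transport(coarse_template, materials,
                        BeamConfig("AP", 0.3, 1_000, seed=14))
        with pytest.raises(ValueError, match="without map"):
            dose_map(res, coarse_template, materials)


def test_zero_lung_mass_rejected(materials):
    labels = np.ones((4, 4, 4), dtype=np.uint16) * 2
    ph = g.LabeledVolume(labels, organ_map={2: ("water", mat.MUSCLE)})
    with pytest.raises(ValueError, match="lung"):
        transport(ph, materials, BeamConfig("AP", 1.0, 10))
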