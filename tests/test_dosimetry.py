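import math

import numpy as np
import pytest

from particokinetics import (
    AgglomerateSpec,
    ExposureSetup,
    Medium,
    ParticleSpec,
    SizeDistribution,
    SolverSettings,
    administered_totals,
    build_problem,
    delivered_dose,
    dose_auc,
    simulate_polydisperse,
    solve_transport,
)

FAST = SolverSettings(n_cells=150)


class TestExposureSetup:
    def test_volume_height_area_consistency_enforced(self):
        with pytest.raises(ValueError):
            ExposureSetup(
                concentration=1.0,
                basis="mass",
                duration=100.0,
                media_height=1e-3,
                deposition_area=1e-4,
                media_volume=5e-7,  # inconsistent with height*area = 1e-7
            )

    def test_geometry_derived_from_any_two(self):
        exp = ExposureSetup(
            concentration=1.0,
            basis="mass",
            duration=100.0,
            media_volume=3e-6,
            media_height=3.1e-3,
        )
        assert exp.area == pytest.approx(3e-6 / 3.1e-3)

    def test_rejects_unknown_basis_and_bare_volume(self):
        with pytest.raises(ValueError):
            ExposureSetup(concentration=1.0, basis="moles", duration=1.0,
                          media_volume=1e-6)
        with pytest.raises(ValueError):
            ExposureSetup(concentration=1.0, basis="mass", duration=1.0,
                          media_volume=1e-6)


class TestAdministeredTotals:
    def test_microscopy_counting_region_total(self, counting_exposure_kwargs):
        """3.7e8/mL x 0.31 cm x 3.717e-5 cm^2 = 4.26e3 particles."""
        exposure = ExposureSetup(**counting_exposure_kwargs)
        particle = ParticleSpec(24e-9, 1050.0)
        totals = administered_totals(exposure, particle)
        assert totals.number == pytest.approx(4.2634e3, rel=1e-4)

    def test_mass_concentration_to_particle_number(self):
        """10 ug/mL of 100 nm polystyrene is 1.82e10 particles/mL."""
        exposure = ExposureSetup(
            concentration=1e-2,  # 10 ug/mL in kg/m^3
            basis="mass",
            duration=3600.0,
            media_volume=1e-6,  # 1 mL
            media_height=3.1e-3,
        )
        particle = ParticleSpec(100e-9, 1050.0)
        totals = administered_totals(exposure, particle)
        assert totals.number == pytest.approx(1.819e10, rel=1e-3)

    def test_number_mass_round_trip(self):
        particle = ParticleSpec(210e-9, 1050.0)
        exposure_n = ExposureSetup(
            concentration=5e14, basis="number", duration=1.0,
            media_height=2e-3, deposition_area=1e-4,
        )
        totals_n = administered_totals(exposure_n, particle)
        exposure_m = ExposureSetup(
            concentration=totals_n.mass / exposure_n.volume, basis="mass",
            duration=1.0, media_height=2e-3, deposition_area=1e-4,
        )
        totals_m = administered_totals(exposure_m, particle)
        assert totals_m.number == pytest.approx(totals_n.number, rel=1e-12)

    def test_agglomerate_counts_solid_mass_and_monomer_surface(self):
        mono = ParticleSpec(34.8e-9, 5200.0)
        agg = AgglomerateSpec(mono, 993.7e-9, fractal_dimension=2.3)
        exposure = ExposureSetup(
            concentration=2e-3, basis="mass", duration=1.0,
            media_height=1.06e-3, deposition_area=1e-4,
        )
        totals = administered_totals(exposure, agg)
        m_agg = agg.particle_count * 5200.0 * math.pi * (34.8e-9) ** 3 / 6
        assert totals.number == pytest.approx(totals.mass / m_agg, rel=1e-12)
        assert totals.surface_area == pytest.approx(
            totals.number * agg.particle_count * math.pi * (34.8e-9) ** 2, rel=1e-12
        )


class TestDeliveredDose:
    def test_counting_fixture_particle_count(self, culture_medium,
                                             counting_exposure_kwargs):
        """24 nm beads: ~181 of the 4263 particles arrive within 500 s."""
        exposure = ExposureSetup(**counting_exposure_kwargs)
        particle = ParticleSpec(24e-9, 1050.0)
        problem = build_problem(particle, culture_medium, exposure.height, 500.0)
        sol = solve_transport(problem)
        tc = delivered_dose(sol, exposure, particle)
        delivered_count = tc.number_per_area[-1] * tc.totals.area
        assert delivered_count == pytest.approx(181, rel=0.02)

    def test_metrics_are_exact_scalar_multiples(self, culture_medium):
        particle = ParticleSpec(100e-9, 1050.0)
        exposure = ExposureSetup(
            concentration=1e-2, basis="mass", duration=3600.0,
            media_height=3.1e-3, deposition_area=9.68e-4,
        )
        problem = build_problem(particle, culture_medium, 3.1e-3, 3600.0)
        sol = solve_transport(problem, settings=FAST)
        tc = delivered_dose(sol, exposure, particle)
        f = tc.fraction_delivered
        np.testing.assert_allclose(
            tc.mass_per_area, tc.totals.mass_per_area * f, rtol=1e-12
        )
        np.testing.assert_allclose(
            tc.number_per_area, tc.totals.number_per_area * f, rtol=1e-12
        )
        np.testing.assert_allclose(
            tc.surface_area_per_area, tc.totals.surface_area_per_area * f, rtol=1e-12
        )
        # linearity in administered concentration
        double = ExposureSetup(
            concentration=2e-2, basis="mass", duration=3600.0,
            media_height=3.1e-3, deposition_area=9.68e-4,
        )
        tc2 = delivered_dose(sol, double, particle)
        np.testing.assert_allclose(tc2.mass_per_area, 2 * tc.mass_per_area, rtol=1e-12)

    def test_geometry_mismatch_rejected(self, culture_medium):
        particle = ParticleSpec(100e-9, 1050.0)
        problem = build_problem(particle, culture_medium, 3.1e-3, 3600.0)
        sol = solve_transport(problem, settings=FAST)
        other = ExposureSetup(
            concentration=1e-2, basis="mass", duration=3600.0,
            media_height=2e-3, deposition_area=1e-4,
        )
        with pytest.raises(ValueError):
            delivered_dose(sol, other, particle)


class TestDoseAuc:
    def _course(self, times, fraction, total_mass_per_area=1.0):
        from particokinetics.dosimetry import AdministeredTotals, DoseTimeCourse

        totals = AdministeredTotals(number=1.0, mass=1.0, surface_area=1.0, area=1.0)
        f = np.asarray(fraction, float)
        return DoseTimeCourse(
            times=np.asarray(times, float),
            fraction_delivered=f,
            number_per_area=f,
            surface_area_per_area=f,
            mass_per_area=total_mass_per_area * f,
            auc={},
            totals=totals,
        )

    def test_constant_dose_rectangle(self):
        """Dose M held for T hours integrates to M*T metric-hours."""
        tc = self._course([0.0, 7200.0], [1.0, 1.0], total_mass_per_area=5.0)
        assert dose_auc(tc, "mass") == pytest.approx(10.0)

    def test_linear_delivery_triangle(self):
        tc = self._course([0.0, 7200.0], [0.0, 1.0], total_mass_per_area=5.0)
        assert dose_auc(tc, "mass") == pytest.approx(5.0)

    def test_rejects_single_point_and_unknown_metric(self):
        tc = self._course([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            dose_auc(tc, "volume")
        short = self._course([0.0], [0.0])
        with pytest.raises(ValueError):
            dose_auc(short, "mass")


class TestSizeDistribution:
    def test_fractions_renormalized_with_warning(self):
        with pytest.warns(UserWarning):
            dist = SizeDistribution(((1e-7, 0.5), (2e-7, 0.6)))
        assert dist.number_fractions.sum() == pytest.approx(1.0)

    def test_invalid_classes_rejected(self):
        with pytest.raises(ValueError):
            SizeDistribution(())
        with pytest.raises(ValueError):
            SizeDistribution(((1e-7, 0.5), (1e-7, 0.5)))
        with pytest.raises(ValueError):
            SizeDistribution(((-1e-7, 1.0),))
        with pytest.raises(ValueError):
            SizeDistribution(((1e-7, -0.2), (2e-7, 1.2)))

    def test_csv_round_trip(self, tmp_path):
        dist = SizeDistribution(((600e-9, 0.25), (990e-9, 0.5), (1500e-9, 0.25)))
        path = tmp_path / "dist.csv"
        dist.to_csv(path)
        back = SizeDistribution.from_csv(path)
        np.testing.assert_allclose(back.diameters, dist.diameters, rtol=1e-12)
        np.testing.assert_allclose(
            back.number_fractions, dist.number_fractions, rtol=1e-12
        )

    def test_csv_schema_enforced(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("size,frac\n100,1.0\n")
        with pytest.raises(ValueError):
            SizeDistribution.from_csv(bad)


class TestPolydisperse:
    def _exposure(self, height=1.06e-3, duration=3600.0):
        return ExposureSetup(
            concentration=2e-3, basis="mass", duration=duration,
            media_height=height, deposition_area=1e-4,
        )

    def test_single_class_matches_monodisperse_pipeline(self, culture_medium):
        mono = ParticleSpec(34.8e-9, 5200.0)
        dist = SizeDistribution(((993.7e-9, 1.0),))
        exposure = self._exposure()
        result = simulate_polydisperse(
            dist, mono, culture_medium, exposure,
            fractal_dimension=2.3, settings=FAST,
        )
        agg = AgglomerateSpec(mono, 993.7e-9, fractal_dimension=2.3)
        problem = build_problem(agg, culture_medium, exposure.height, exposure.duration)
        sol = solve_transport(
            problem, output_times=result.timecourse.times, settings=FAST
        )
        direct = delivered_dose(sol, exposure, agg)
        np.testing.assert_allclose(
            result.timecourse.mass_per_area, direct.mass_per_area, rtol=1e-9
        )

    def test_two_equal_mass_classes_average_their_fractions(self, culture_medium):
        """With equal class masses the mixture fraction is (f1+f2)/2."""
        mono = ParticleSpec(34.8e-9, 5200.0)
        d1, d2 = 600e-9, 1200e-9
        df = 2.3
        # number fractions chosen so nu_i * d_i^DF are equal
        w1 = (d2 / d1) ** df
        nu1 = w1 / (1 + w1)
        dist = SizeDistribution(((d1, nu1), (d2, 1 - nu1)))
        exposure = self._exposure()
        result = simulate_polydisperse(
            dist, mono, culture_medium, exposure,
            fractal_dimension=df, settings=FAST,
        )
        np.testing.assert_allclose(result.mass_fractions, [0.5, 0.5], rtol=1e-9)
        f1 = result.class_solutions[0].fraction_delivered
        f2 = result.class_solutions[1].fraction_delivered
        np.testing.assert_allclose(
            result.timecourse.fraction_delivered, (f1 + f2) / 2, rtol=1e-12
        )

    def test_five_class_mixture_equals_external_sum(self, culture_medium):
        """Combined mass course equals per-class solves summed outside."""
        mono = ParticleSpec(34.8e-9, 5200.0)
        classes = ((500e-9, 0.1), (750e-9, 0.2), (1000e-9, 0.4),
                   (1250e-9, 0.2), (1500e-9, 0.1))
        dist = SizeDistribution(classes)
        exposure = self._exposure()
        times = np.linspace(0.0, exposure.duration, 41)
        result = simulate_polydisperse(
            dist, mono, culture_medium, exposure,
            fractal_dimension=2.3, output_times=times, settings=FAST,
        )
        # brute force: independent pipeline per class, summed by solid mass
        masses = np.array(
            [
                AgglomerateSpec(mono, d, fractal_dimension=2.3).solid_mass * nu
                for d, nu in classes
            ]
        )
        weights = masses / masses.sum()
        total_mass_per_area = (
            exposure.concentration * exposure.volume / exposure.area
        )
        expected = np.zeros_like(times)
        for (d, _nu), w in zip(classes, weights):
            agg = AgglomerateSpec(mono, d, fractal_dimension=2.3)
            problem = build_problem(
                agg, culture_medium, exposure.height, exposure.duration
            )
            sol = solve_transport(problem, output_times=times, settings=FAST)
            expected += w * sol.fraction_delivered * total_mass_per_area
        np.testing.assert_allclose(
            result.timecourse.mass_per_area, expected, rtol=1e-9
        )

    def test_combined_mass_never_exceeds_administered(self, culture_medium):
        mono = ParticleSpec(34.8e-9, 5200.0)
        dist = SizeDistribution(((600e-9, 0.5), (1400e-9, 0.5)))
        exposure = self._exposure(duration=8 * 3600.0)
        result = simulate_polydisperse(
            dist, mono, culture_medium, exposure,
            fractal_dimension=2.3, settings=FAST,
        )
        tc = result.timecourse
        assert np.all(
            tc.mass_per_area <= tc.totals.mass_per_area * (1 + 1e-9)
        )
        assert np.all(np.diff(tc.mass_per_area) >= -1e-12)

    def test_timecourse_csv_json_round_trip(self, tmp_path, culture_medium):
        import json

        import pandas as pd

        particle = ParticleSpec(100e-9, 1050.0)
        exposure = ExposureSetup(
            concentration=1e-2, basis="mass", duration=3600.0,
            media_height=3.1e-3, deposition_area=9.68e-4,
        )
        problem = build_problem(particle, culture_medium, 3.1e-3, 3600.0)
        sol = solve_transport(problem, settings=FAST)
        tc = delivered_dose(sol, exposure, particle)
        tc.to_csv(tmp_path / "tc.csv")
        frame = pd.read_csv(tmp_path / "tc.csv")
        assert list(frame.columns) == [
            "time_s", "fraction_delivered", "number_per_cm2",
            "sa_cm2_per_cm2", "mass_ug_per_cm2",
        ]
        np.testing.assert_allclose(frame.time_s, tc.times)
        np.testing.assert_allclose(
            frame.mass_ug_per_cm2, tc.mass_per_area * 1e5, rtol=1e-9
        )
        tc.to_json(tmp_path / "tc.json")
        summary = json.loads((tmp_path / "tc.json").read_text())
        assert summary["final_fraction_delivered"] == pytest.approx(
            tc.fraction_delivered[-1]
        )
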