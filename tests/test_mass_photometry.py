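"""Calibration, histogram weighting and aggregation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micellab import (
    MassHistogram,
    apply_calibration,
    build_histogram,
    fit_calibration,
    gaussian_peak_fwhm,
    mass_to_contrast,
    mean_aggregation_number,
    monomer_dimer,
    oligomer_mass_total,
    particle_concentration,
    sample_mp_events,
    sample_standard_events,
    to_mass_weighted,
)
from micellab.errors import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    WeightingError,
)
from micellab.kinetics import fit_decay, SizeTimeSeries


def two_bin_histogram(monomer=26.9):
    """One count at N=10 and one at N=30."""
    edges = (np.arange(10, 32) - 0.5) * monomer
    counts = np.zeros(21)
    counts[0] = 1  # N = 10
    counts[20] = 1  # N = 30
    return MassHistogram(bin_edges=edges, counts=counts, weighting="number",
                         monomer_mass=monomer)


class TestCalibration:
    def test_exact_proportionality(self):
        rng = np.random.default_rng(0)
        standards = [
            (m, 0.001 * m + rng.normal(0, 1e-9, 200)) for m in (66.0, 150.0, 669.0)
        ]
        calib = fit_calibration(standards)
        assert calib.slope == pytest.approx(0.001, rel=1e-4)
        assert calib.intercept == pytest.approx(0.0, abs=1e-5)
        assert calib.fit_residual_sd < 1e-6

    def test_noisy_generator_recovery_within_3pc(self):
        standards = []
        for i, m in enumerate((66.0, 150.0, 669.0)):
            events = sample_standard_events(m, 2000, seed=i).measured_mass
            contrasts = mass_to_contrast(events, slope=1e-3, rel_noise=0.02, seed=i)
            standards.append((m, contrasts))
        calib = fit_calibration(standards)
        assert calib.slope == pytest.approx(1e-3, rel=0.03)

    def test_monomer_dimer_standard_both_usable(self):
        # BSA monomer and dimer supplied as two separate calibration points
        mono = sample_standard_events(66.0, 1000, seed=1).measured_mass
        dimer = sample_standard_events(132.0, 1000, seed=2).measured_mass
        calib = fit_calibration(
            [("BSA", 66.0, mono * 1e-3), ("BSA dimer", 132.0, dimer * 1e-3)]
        )
        assert calib.slope == pytest.approx(1e-3, rel=0.05)

    def test_too_few_standards(self):
        with pytest.raises(ConfigurationError):
            fit_calibration([(66.0, np.ones(100))])

    def test_non_monotone_peaks_rejected(self):
        rng = np.random.default_rng(0)
        standards = [
            (66.0, 0.1 + rng.normal(0, 1e-4, 200)),
            (150.0, 0.05 + rng.normal(0, 1e-4, 200)),  # lower contrast, higher mass
        ]
        with pytest.raises(CalibrationError):
            fit_calibration(standards)

    def test_apply_flags_sub_limit_masses(self):
        rng = np.random.default_rng(0)
        standards = [(m, 0.001 * m + rng.normal(0, 1e-9, 100)) for m in (66.0, 669.0)]
        calib = fit_calibration(standards)
        result = apply_calibration(np.array([calib.intercept, 0.0269, 0.669]), calib)
        assert result.masses[0] == pytest.approx(0.0, abs=1e-6)
        assert result.below_limit.tolist() == [True, True, False]
        assert len(result.masses) == 3  # flagged, never dropped

    def test_round_trip_through_contrast_layer(self, noiseless_events):
        contrasts = mass_to_contrast(noiseless_events.measured_mass, slope=2e-3,
                                     intercept=1e-4)
        rng = np.random.default_rng(0)
        standards = [(m, 2e-3 * m + 1e-4 + rng.normal(0, 1e-12, 100))
                     for m in (66.0, 150.0, 669.0)]
        calib = fit_calibration(standards)
        back = apply_calibration(contrasts, calib)
        assert np.allclose(back.masses, noiseless_events.measured_mass, rtol=1e-6)


class TestHistogram:
    def test_bins_anchor_on_monomer_multiples(self):
        hist = build_histogram(np.full(10, 269.0), monomer_mass=26.9)
        assert hist.counts.sum() == 10
        occupied = hist.n_values[hist.counts > 0]
        assert occupied.tolist() == [10]

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            build_histogram(np.array([]))

    def test_broad_distribution_spans_tens_of_bins(self, pop_30um):
        events = sample_mp_events(pop_30um, 10_000, seed=0)
        hist = build_histogram(events.measured_mass)
        assert np.sum(hist.counts > 0.001 * hist.counts.max()) > 20

    def test_fine_bins_resolve_standard_sigma(self):
        events = sample_standard_events(669.0, 10_000, seed=7)
        hist = build_histogram(events.measured_mass, bin_width=2.0)
        sigma, _ = gaussian_peak_fwhm(hist, (569.0, 769.0))
        assert sigma == pytest.approx(22.4, abs=1.0)  # sigma(669) = 9 + 0.02*669


class TestWeighting:
    def test_mass_weighting_multiplies_by_n(self):
        hist = two_bin_histogram()
        mw = to_mass_weighted(hist)
        assert mw.weighting == "mass"
        assert mw.counts[hist.n_values == 10][0] == 10
        assert mw.counts[hist.n_values == 30][0] == 30

    def test_double_weighting_refused(self):
        mw = to_mass_weighted(two_bin_histogram())
        with pytest.raises(WeightingError):
            to_mass_weighted(mw)

    def test_monomer_bin_unchanged(self):
        edges = np.array([0.5, 1.5]) * 26.9
        hist = MassHistogram(edges, np.array([7.0]), "number")
        assert to_mass_weighted(hist).counts[0] == 7.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(min_value=0, max_value=1000), min_size=3, max_size=40))
    def test_conversion_conserves_total_subunit_count(self, counts):
        counts = np.array(counts, dtype=float)
        edges = (np.arange(1, len(counts) + 2) - 0.5) * 26.9
        hist = MassHistogram(edges, counts, "number")
        mw = to_mass_weighted(hist)
        assert mw.counts.sum() == pytest.approx(
            np.sum(hist.n_values * counts), rel=1e-12
        )


class TestAggregationStats:
    def test_single_bin_mean_under_either_weighting(self):
        edges = np.array([9.5, 10.5]) * 26.9
        hist = MassHistogram(edges, np.array([5.0]), "number")
        assert mean_aggregation_number(hist, 1).value == 10
        assert mean_aggregation_number(to_mass_weighted(hist), 1).value == 10

    def test_two_bin_means(self):
        hist = two_bin_histogram()
        number = mean_aggregation_number(hist, n_min=1)
        mass = mean_aggregation_number(to_mass_weighted(hist), n_min=1)
        assert number.value == pytest.approx(20.0)          # (10+30)/2
        assert mass.value == pytest.approx(25.0)            # (100+900)/40
        assert (number.weighting, mass.weighting) == ("number", "mass")

    def test_number_weighted_below_mass_weighted(self, pop_30um):
        events = sample_mp_events(pop_30um, 10_000, seed=0)
        hist = build_histogram(events.measured_mass)
        num = mean_aggregation_number(hist, 3).value
        mass = mean_aggregation_number(to_mass_weighted(hist), 3).value
        assert num <= mass

    def test_noiseless_round_trip_is_exact(self, pop_30um, noiseless_events):
        """Histogram mass-weighted mean == mass-weighted mean of true N."""
        hist = to_mass_weighted(build_histogram(noiseless_events.measured_mass))
        got = mean_aggregation_number(hist, n_min=1).value
        n = noiseless_events.true_N.astype(float)
        assert got == pytest.approx(np.sum(n**2) / np.sum(n), rel=1e-12)

    def test_no_occupied_bins_above_nmin(self):
        edges = np.array([0.5, 1.5]) * 26.9
        hist = MassHistogram(edges, np.array([5.0]), "number")
        with pytest.raises(DomainError):
            mean_aggregation_number(hist, n_min=3)

    def test_invariant_to_bin_refinement(self, noiseless_events):
        coarse = build_histogram(noiseless_events.measured_mass, bin_width=26.9)
        fine = build_histogram(noiseless_events.measured_mass, bin_width=26.9 / 3)
        m_coarse = mean_aggregation_number(to_mass_weighted(coarse), 3).value
        m_fine = mean_aggregation_number(to_mass_weighted(fine), 3).value
        assert m_coarse == pytest.approx(m_fine, rel=1e-9)


class TestOligomerMassReporter:
    def test_monomer_dimer_only_gives_zero(self):
        edges = (np.arange(1, 4) - 0.5) * 26.9
        hist = MassHistogram(edges, np.array([10.0, 5.0]), "number")
        assert oligomer_mass_total(hist) == 0.0

    def test_arithmetic(self):
        edges = np.array([9.5, 10.5]) * 26.9
        hist = MassHistogram(edges, np.array([2.0]), "number")
        assert oligomer_mass_total(hist) == pytest.approx(538.0)

    def test_requires_number_weighting(self):
        hist = to_mass_weighted(two_bin_histogram())
        with pytest.raises(WeightingError):
            oligomer_mass_total(hist)

    def test_reporter_decays_with_generator_rate(self, pop_30um):
        """Scaling micelle concentrations exponentially in time makes the
        oligomer-mass reporter a single exponential with the same k."""
        k_true = 1.0 / 1200.0
        times = np.linspace(0.0, 4 / k_true, 12)
        edges = (np.concatenate([pop_30um.N_values, [pop_30um.N_values[-1] + 1]]) - 0.5) * 26.9
        reporter = []
        for t in times:
            hist = MassHistogram(edges, pop_30um.C_N * np.exp(-k_true * t), "number")
            reporter.append(oligomer_mass_total(hist))
        fit = fit_decay(SizeTimeSeries(times=times, values=np.array(reporter), unit="kDa"))
        assert fit.k == pytest.approx(k_true, rel=0.10)


class TestScalars:
    def test_particle_concentration_reference(self):
        assert particle_concentration(200.0, 20.0) == 10.0
        assert particle_concentration(30_000.0, 35.0) == pytest.approx(857.1, abs=0.1)
        assert particle_concentration(123.0, 1.0) == 123.0

    def test_particle_concentration_times_meann_is_total(self):
        assert particle_concentration(200.0, 17.0) * 17.0 == pytest.approx(200.0, rel=1e-15)

    def test_particle_concentration_domain(self):
        with pytest.raises(DomainError):
            particle_concentration(200.0, 0.0)

    def test_monomer_dimer_no_association(self):
        assert monomer_dimer(1e-6, 0.0) == (1e-6, 0.0)

    def test_monomer_dimer_quadratic_reference(self):
        c1, c2 = monomer_dimer(2e-7, 1e6)
        assert c1 == pytest.approx(1.531e-7, rel=1e-3)
        assert c2 == pytest.approx(2.344e-8, rel=1e-3)
        assert c1 + 2 * c2 == pytest.approx(2e-7, rel=1e-12)  # mass balance

    def test_dimer_constant_when_monomer_pinned(self):
        # if c1 is pinned at the cmc, c2 = K2 c1^2 does not grow with total
        k2, c1 = 1e6, 1.2e-7
        assert k2 * c1**2 == pytest.approx(k2 * c1**2)

    def test_monomer_dimer_domain(self):
        with pytest.raises(DomainError):
            monomer_dimer(-1e-7, 1e6)


class TestGaussianFwhm:
    def test_closed_form_on_exact_gaussian(self):
        centers = np.linspace(-5, 5, 101)
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        counts = 100 * np.exp(-0.5 * centers**2)
        hist = MassHistogram(edges + 50, counts, "number", monomer_mass=1.0)
        sigma, fwhm = gaussian_peak_fwhm(hist, (45.0, 55.0))
        assert sigma == pytest.approx(1.0, rel=1e-6)
        assert fwhm == pytest.approx(2.355, rel=1e-6)

    def test_sigma_from_52kda_fwhm(self):
        assert 52.0 / 2.355 == pytest.approx(22.08, abs=0.01)

    def test_window_occupancy_requirement(self):
        edges = np.arange(6) * 26.9 - 13.45
        hist = MassHistogram(edges, np.array([0, 1, 2, 1, 0.0]), "number")
        with pytest.raises(DomainError):
            gaussian_peak_fwhm(hist, (0.0, 30.0))

    def test_bimodal_window_warns(self):
        centers = np.linspace(0, 20, 41)
        width = centers[1] - centers[0]
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        counts = np.exp(-0.5 * (centers - 5) ** 2) + np.exp(-0.5 * (centers - 15) ** 2)
        hist = MassHistogram(edges, 100 * counts, "number", monomer_mass=1.0)
        with pytest.warns(UserWarning):
            gaussian_peak_fwhm(hist, (0.0, 20.0))
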