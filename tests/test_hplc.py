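"""Chromatogram peak integration and isomer composition recovery."""

import numpy as np
import pytest

from opsinspec import hplc
from opsinspec.errors import ParameterError, UnassignedPeakError
from opsinspec.hplc import (
    Chromatogram,
    IsomerComposition,
    Peak,
    PeakTable,
    compose_fractions,
    composition_from_state_fraction,
    detect_and_integrate_peaks,
    simulate_chromatogram,
)
from opsinspec.photosim import photosteady_fraction, rh7_like_pigments, uv_d35


def gaussian_trace(centers, areas, sigma=0.1, noise=0.0, seed=0):
    t = np.arange(3.0, 15.0, 0.01)
    s = np.zeros_like(t)
    for mu, area in zip(centers, areas):
        s += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    if noise > 0:
        s += np.random.default_rng(seed).normal(0, noise, t.size)
    return Chromatogram(t, s)


class TestDetectAndIntegrate:
    def test_single_gaussian_area_within_one_percent(self):
        table = detect_and_integrate_peaks(gaussian_trace([8.0], [1.0]), 0.05)
        assert len(table) == 1
        assert table.peaks[0].area == pytest.approx(1.0, rel=0.01)
        assert table.peaks[0].position == pytest.approx(8.0, abs=0.01)

    def test_flat_trace_returns_empty_table_with_warning(self):
        chrom = Chromatogram(np.arange(3.0, 15.0, 0.01), np.zeros(1200))
        table = detect_and_integrate_peaks(chrom, 0.05)
        assert len(table) == 0
        assert table.warning is not None

    def test_two_well_separated_gaussians(self):
        table = detect_and_integrate_peaks(
            gaussian_trace([6.0, 6.5], [0.6, 0.4]), 0.05
        )  # 5 sigma apart
        assert len(table) == 2
        assert table.peaks[0].area == pytest.approx(0.6, rel=0.01)
        assert table.peaks[1].area == pytest.approx(0.4, rel=0.01)

    def test_prominence_must_be_positive(self):
        with pytest.raises(ParameterError):
            detect_and_integrate_peaks(gaussian_trace([8.0], [1.0]), 0.0)


class TestComposeFractions:
    def test_area_shares_become_fractions(self):
        table = PeakTable((
            Peak(5.6, 0.7, 0.1, 1.0),
            Peak(6.4, 0.1, 0.1, 1.0),
            Peak(7.6, 0.2, 0.1, 1.0),
        ))
        comp = compose_fractions(table)
        iso = comp.isomer_fractions()
        assert iso["11-cis"] == pytest.approx(0.70)
        assert iso["13-cis"] == pytest.approx(0.10)
        assert iso["all-trans"] == pytest.approx(0.20)

    def test_single_species_is_unity(self):
        comp = compose_fractions(PeakTable((Peak(10.4, 0.5, 0.1, 1.0),)))
        assert comp.isomer_fractions()["11-cis"] == pytest.approx(1.0)

    def test_unassigned_large_peak_raises(self):
        table = PeakTable((Peak(5.6, 0.7, 0.1, 1.0), Peak(8.9, 0.3, 0.1, 1.0)))
        with pytest.raises(UnassignedPeakError, match="8.9"):
            compose_fractions(table)

    def test_extinction_corrections_divide_areas(self):
        table = PeakTable((Peak(5.6, 0.5, 0.1, 1.0), Peak(7.6, 0.5, 0.1, 1.0)))
        comp = compose_fractions(table, extinction_corrections={"11-cis syn": 2.0})
        iso = comp.isomer_fractions()
        assert iso["11-cis"] == pytest.approx(1.0 / 3.0)
        assert iso["all-trans"] == pytest.approx(2.0 / 3.0)


class TestSimulateChromatogram:
    def test_pure_composition_gives_expected_peaks(self):
        comp = IsomerComposition.from_isomers({"11-cis": 1.0})
        trace = simulate_chromatogram(comp)
        table = detect_and_integrate_peaks(trace, 0.05)
        assert len(table) == 2  # syn and anti oximes
        assert table.peaks[0].area / table.peaks[1].area == pytest.approx(
            0.7 / 0.3, rel=0.02
        )

    def test_same_seed_identical_trace(self):
        comp = IsomerComposition.from_isomers({"11-cis": 0.8, "all-trans": 0.2})
        a = simulate_chromatogram(comp, noise_sigma=0.01, seed=3)
        b = simulate_chromatogram(comp, noise_sigma=0.01, seed=3)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_overlapping_retention_times_warn(self):
        comp = IsomerComposition.from_isomers({"11-cis": 1.0})
        with pytest.warns(UserWarning, match="overlap"):
            simulate_chromatogram(
                comp, retention_map={"11-cis syn": 5.0, "11-cis anti": 5.1}
            )


class TestRoundTrip:
    TRUE = {"11-cis": 0.85, "13-cis": 0.05, "all-trans": 0.10}

    def test_known_composition_recovered(self):
        """Detect/compose closes the loop within 0.02 per isomer, 10 seeds."""
        comp = IsomerComposition.from_isomers(self.TRUE)
        clean = simulate_chromatogram(comp)
        sigma = 0.005 * float(clean.signal.max())
        for seed in range(10):
            trace = simulate_chromatogram(comp, noise_sigma=sigma, seed=seed)
            got = compose_fractions(detect_and_integrate_peaks(trace, 0.05))
            for iso, truth in self.TRUE.items():
                assert got.isomer_fractions()[iso] == pytest.approx(truth, abs=0.02)

    def test_composition_invariant_to_uniform_rescaling(self):
        comp = IsomerComposition.from_isomers(self.TRUE)
        base = simulate_chromatogram(comp)
        scaled = Chromatogram(base.retention_time, 5.0 * base.signal)
        a = compose_fractions(detect_and_integrate_peaks(base, 0.05))
        b = compose_fractions(detect_and_integrate_peaks(scaled, 0.25))
        for iso in self.TRUE:
            assert a.isomer_fractions()[iso] == pytest.approx(
                b.isomer_fractions()[iso], abs=1e-6
            )


class TestLightProtocolConsistency:
    def test_uv_irradiation_shifts_11cis_to_all_trans(self):
        """Compositions generated from simulator state fractions move the right way."""
        pair = rh7_like_pigments()
        f_uv = photosteady_fraction(pair, uv_d35())
        before = composition_from_state_fraction(0.0).isomer_fractions()
        after = composition_from_state_fraction(f_uv).isomer_fractions()
        assert after["11-cis"] < before["11-cis"]
        assert after["all-trans"] > before["all-trans"]
        # the decrease in 11-cis matches the increase in all-trans
        assert (before["11-cis"] - after["11-cis"]) == pytest.approx(
            after["all-trans"] - before["all-trans"], abs=1e-12
        )


class TestIsomerComposition:
    def test_fractions_validated(self):
        with pytest.raises(ParameterError):
            IsomerComposition((("11-cis syn", 0.5),))  # does not sum to 1
        with pytest.raises(ParameterError):
            IsomerComposition((("9-cis syn", 1.0),))  # unknown species

    def test_aggregation_sums_to_one(self):
        comp = IsomerComposition.from_isomers({"11-cis": 0.6, "all-trans": 0.4})
        assert sum(comp.isomer_fractions().values()) == pytest.approx(1.0, abs=1e-9)
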