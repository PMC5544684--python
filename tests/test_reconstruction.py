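"""State reconstruction from photoconversion difference spectra."""

import numpy as np
import pytest

from opsinspec.errors import NoSignalError, WindowError
from opsinspec.photosim import mixture_spectrum, rh7_like_pigments
from opsinspec.reconstruction import (
    FitWindow,
    fit_irradiated_state,
    reconstruct_bistable_pair,
    reconstruct_original,
)
from opsinspec.spectra import (
    CANONICAL_GRID,
    DifferenceSpectrum,
    Spectrum,
    difference,
)
from opsinspec.templates import TemplateParams, template_spectrum

G = CANONICAL_GRID
WINDOW = FitWindow(480.0, 650.0)


def make_diff(meta_amp=1.0, dark_amp=0.8, meta_lam=510.0, dark_lam=350.0, noise=None):
    """Difference spectrum irradiated-minus-original for a synthetic pair."""
    meta = template_spectrum(
        TemplateParams(meta_lam, family="metarhodopsin_like"), G
    ).absorbance
    dark = template_spectrum(TemplateParams(dark_lam), G).absorbance
    v = meta_amp * meta - dark_amp * dark
    if noise is not None:
        v = v + noise
    return DifferenceSpectrum(G, v)


class TestFitIrradiatedState:
    def test_noise_free_recovery(self):
        fit = fit_irradiated_state(make_diff(), window=WINDOW)
        assert fit.params.lambda_max == pytest.approx(510.0, abs=1.0)
        assert fit.amplitude == pytest.approx(1.0, rel=0.01)

    def test_amplitude_linearity(self):
        base = fit_irradiated_state(make_diff(), window=WINDOW)
        for c in (0.25, 3.0):
            scaled = fit_irradiated_state(
                make_diff(meta_amp=c, dark_amp=0.8 * c), window=WINDOW
            )
            assert scaled.amplitude == pytest.approx(c * base.amplitude, rel=1e-9)
            assert scaled.params.lambda_max == pytest.approx(
                base.params.lambda_max, abs=1e-9
            )

    def test_all_zero_diff_is_no_signal(self):
        d = DifferenceSpectrum(G, np.zeros(G.size))
        with pytest.raises(NoSignalError):
            fit_irradiated_state(d, window=WINDOW)

    def test_window_too_small_rejected(self):
        with pytest.raises(WindowError):
            fit_irradiated_state(make_diff(), window=FitWindow(480.0, 485.0))

    def test_matches_exhaustive_grid_search(self):
        """Dual route: parametric fit vs brute-force 2-D (lambda, amplitude) scan."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            lam_true = float(rng.integers(460, 561))
            amp_true = float(rng.uniform(0.5, 1.5))
            d = make_diff(meta_amp=amp_true, meta_lam=lam_true)
            fit = fit_irradiated_state(d, window=WINDOW)
            # oracle: per-lambda scan with amplitude over a fine grid and the
            # baseline set by the residual mean
            mask = WINDOW.mask(G)
            y = d.absorbance[mask]
            best = (np.inf, None, None)
            for lam in np.arange(380.0, 651.0):
                t = template_spectrum(
                    TemplateParams(lam, family="metarhodopsin_like"), G[mask]
                ).absorbance
                for amp in np.linspace(0.9 * amp_true, 1.1 * amp_true, 81):
                    r = y - amp * t
                    r = r - r.mean()  # optimal constant baseline
                    rss = float(r @ r)
                    if rss < best[0]:
                        best = (rss, lam, amp)
            assert fit.params.lambda_max == pytest.approx(best[1], abs=1.0)
            assert fit.amplitude == pytest.approx(best[2], rel=0.01)

    def test_monte_carlo_lambda_recovery(self):
        """sigma = 0.002 AU on a unit-amplitude band: lambda within 2 nm."""
        truth = make_diff().absorbance
        rng = np.random.default_rng(99)
        lams = []
        for _ in range(50):
            d = DifferenceSpectrum(G, truth + rng.normal(0, 0.002, G.size))
            lams.append(fit_irradiated_state(d).params.lambda_max)
        lams = np.asarray(lams)
        assert np.mean(np.abs(lams - 510.0) <= 2.0) >= 0.95
        assert abs(np.mean(lams) - 510.0) < 1.0


class TestReconstructOriginal:
    def test_zero_diff_returns_irradiated(self):
        meta = template_spectrum(TemplateParams(510.0), G)
        d = DifferenceSpectrum(G, np.zeros(G.size))
        out = reconstruct_original(d, meta)
        np.testing.assert_array_equal(out.absorbance, meta.absorbance)

    def test_exact_identity_when_meta_is_truth(self):
        pair = rh7_like_pigments()
        d = difference(pair.dark_spectrum, pair.meta_spectrum)  # original - irradiated
        out = reconstruct_original(d, pair.meta_spectrum)
        np.testing.assert_allclose(
            out.absorbance, pair.dark_spectrum.absorbance, atol=1e-12
        )

    def test_orientation_flag_negates(self):
        pair = rh7_like_pigments()
        d = difference(pair.meta_spectrum, pair.dark_spectrum)  # irradiated - original
        out = reconstruct_original(d, pair.meta_spectrum,
                                   orientation="irradiated_minus_original")
        np.testing.assert_allclose(
            out.absorbance, pair.dark_spectrum.absorbance, atol=1e-12
        )


class TestBistablePair:
    def _cycle(self, f_uv=1.0, f_yellow=0.0, initial=0.0):
        pair = rh7_like_pigments()
        before = mixture_spectrum(pair, initial)
        after_uv = mixture_spectrum(pair, f_uv)
        after_yellow = mixture_spectrum(pair, f_yellow)
        return pair, before, after_uv, after_yellow

    def test_fully_reversible_cycle_has_zero_residual(self):
        pair, b, a1, a2 = self._cycle()
        res = reconstruct_bistable_pair(b, a1, a2)
        assert res.regeneration_residual == pytest.approx(0.0, abs=1e-12)
        assert res.irradiated_fit.params.lambda_max == pytest.approx(510.0, abs=1.0)

    def test_all_trans_contamination_leaves_positive_residual_at_dark_peak(self):
        # sample starts with 5% metarhodopsin; yellow light over-regenerates
        pair, b, a1, a2 = self._cycle(initial=0.05)
        res = reconstruct_bistable_pair(b, a1, a2)
        regen = difference(a2, b)
        dark_peak = pair.dark_spectrum.peak_wavelength()
        assert regen.value_at(dark_peak) > 0
        assert res.regeneration_residual > 1e-4

    def test_partial_conversion_scales_amplitude_not_lambda(self):
        _, b, a1, a2 = self._cycle(f_uv=1.0)
        full = reconstruct_bistable_pair(b, a1, a2)
        _, b, a1, a2 = self._cycle(f_uv=0.7)
        partial = reconstruct_bistable_pair(b, a1, a2)
        assert partial.irradiated_fit.amplitude == pytest.approx(
            0.7 * full.irradiated_fit.amplitude, rel=0.01
        )
        assert partial.irradiated_fit.params.lambda_max == pytest.approx(
            full.irradiated_fit.params.lambda_max, abs=1.0
        )

    def test_conservation_identity_holds_exactly(self):
        pair, b, a1, a2 = self._cycle(initial=0.03, f_uv=0.9, f_yellow=0.05)
        res = reconstruct_bistable_pair(b, a1, a2)
        back = difference(a2, a1)  # original - irradiated orientation
        np.testing.assert_allclose(
            res.original_spectrum.absorbance,
            res.irradiated_spectrum.absorbance + back.absorbance,
            atol=1e-15, rtol=0,
        )
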