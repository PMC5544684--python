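"""Reconstruction of bistable-pigment state spectra from difference spectra.

The core inference of the toolkit: the long-wavelength flank of a
photoconversion difference spectrum is dominated by the visible-absorbing
metarhodopsin (the UV-absorbing dark state contributes nothing there), so
fitting that flank with a single template yields the metarhodopsin spectrum,
and the original (dark) state follows by adding the signed difference back:

    original = irradiated + (original - irradiated)

an exact algebraic identity that this module preserves to machine precision.

Sign conventions are explicit everywhere.  The internal canonical
orientation for reconstruction is ``original - irradiated``; helpers accept
the opposite orientation and negate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NoSignalError, WindowError
from .spectra import (
    DifferenceSpectrum,
    Spectrum,
    difference,
    resample,
)
from .templates import TemplateParams, bank_matrix, template_spectrum

#: default metarhodopsin lambda_max search range (visible-absorbing states)
DEFAULT_SEARCH = (380.0, 650.0)


@dataclass(frozen=True)
class FitWindow:
    """Wavelength window used for the red-flank template fit."""

    lower: float
    upper: float
    selection_rule: str = "manual"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise WindowError(f"window lower {self.lower} must be < upper {self.upper}")

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.lower) & (wavelengths <= self.upper)


@dataclass(frozen=True)
class IrradiatedFit:
    """Best-fit template description of the irradiated (metarhodopsin) state."""

    params: TemplateParams
    amplitude: float
    baseline_offset: float
    rmse: float
    window: FitWindow


@dataclass(frozen=True)
class ReconstructionResult:
    """Full output of one state reconstruction."""

    irradiated_fit: IrradiatedFit
    irradiated_spectrum: Spectrum
    original_spectrum: Spectrum
    fit_rmse: float
    baseline_offset: float
    window: FitWindow
    regeneration_residual: float | None = None
    diagnostics: tuple[tuple[str, float], ...] = ()


def estimate_noise(values: np.ndarray) -> float:
    """Robust noise-sigma estimate from successive differences.

    For white noise sigma the successive differences have standard deviation
    sigma*sqrt(2); the median absolute successive difference is scaled
    accordingly (Gaussian consistency factor 1.4826).
    """
    d = np.diff(np.asarray(values, float))
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def auto_red_flank_window(diff_values: np.ndarray, wavelengths: np.ndarray) -> FitWindow:
    """Window rule: start 10 nm red of the positive-lobe maximum, end where
    the signal drops below 3x the estimated noise floor.

    Excludes the region where the original state still absorbs, which is the
    motivation for fitting the long-wavelength flank only.
    """
    v = np.asarray(diff_values, float)
    if np.max(v) <= 0:
        raise NoSignalError("no positive lobe: cannot place red-flank window")
    i_peak = int(np.argmax(v))
    lower = wavelengths[i_peak] + 10.0
    sigma = estimate_noise(v)
    above = np.abs(v) > 3.0 * sigma if sigma > 0 else np.abs(v) > 0
    idx = np.nonzero(above)[0]
    upper = wavelengths[idx[-1]] if idx.size else wavelengths[-1]
    if upper <= lower:
        upper = wavelengths[-1]
    return FitWindow(lower, float(upper), selection_rule="auto_red_flank")


def fit_irradiated_state(
    diff: DifferenceSpectrum | Spectrum,
    family: str = "metarhodopsin_like",
    window: FitWindow | None = None,
    search_grid: np.ndarray | Sequence[float] | None = None,
) -> IrradiatedFit:
    """Fit ``amplitude * template(lambda_max) + baseline`` to the positive lobe.

    The difference spectrum must be oriented so the irradiated state appears
    as the positive lobe inside the window.  lambda_max is found by 1 nm grid
    search with the amplitude and a constant baseline solved linearly at each
    node, followed by local parabolic refinement; ties break toward lower
    lambda_max.  The red-flank fit uses the alpha band only (no beta band:
    the window lies far from any beta satellite, which the fit could not
    constrain).
    """
    w = diff.wavelengths
    v = diff.absorbance
    if window is None:
        window = auto_red_flank_window(v, w)
    mask = window.mask(w)
    if int(mask.sum()) < 10:
        raise WindowError(
            f"window [{window.lower:g}, {window.upper:g}] nm holds "
            f"{int(mask.sum())} grid points; need >= 10"
        )
    y = v[mask]
    wl = w[mask]
    if np.max(y) <= 0:
        raise NoSignalError("no positive lobe inside the fit window")
    if search_grid is None:
        search_grid = np.arange(DEFAULT_SEARCH[0], DEFAULT_SEARCH[1] + 0.5, 1.0)
    lams = np.asarray(search_grid, float)

    amp, base, rss = _linear_solve_bank(y, wl, lams, family)
    if not np.any(np.isfinite(rss)):
        raise WindowError("rank-deficient window: templates are flat inside it")
    i = int(np.argmin(rss))  # argmin takes the first (lowest lambda) on ties
    lam_best, amp_best, base_best, rss_best = lams[i], amp[i], base[i], rss[i]

    # parabolic refinement on the discrete RSS profile
    if 0 < i < len(lams) - 1 and np.isfinite(rss[i - 1]) and np.isfinite(rss[i + 1]):
        denom = rss[i - 1] - 2.0 * rss[i] + rss[i + 1]
        if denom > 0:
            delta = 0.5 * (rss[i - 1] - rss[i + 1]) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            lam_ref = float(lams[i] + delta * (lams[i + 1] - lams[i]))
            a_r, b_r, r_r = _linear_solve_bank(y, wl, np.array([lam_ref]), family)
            if np.isfinite(r_r[0]) and r_r[0] <= rss_best:
                lam_best, amp_best, base_best, rss_best = lam_ref, a_r[0], b_r[0], r_r[0]

    params = TemplateParams(float(lam_best), family=family, include_beta_band=False)
    rmse = float(np.sqrt(max(rss_best, 0.0) / y.size))
    return IrradiatedFit(params, float(amp_best), float(base_best), rmse, window)


def _linear_solve_bank(
    y: np.ndarray, wl: np.ndarray, lams: np.ndarray, family: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-lambda closed-form LSQ of (amplitude, baseline); returns RSS array."""
    T = bank_matrix(lams, wl, family=family, include_beta_band=False)
    m = y.size
    st = T.sum(axis=0)
    stt = np.einsum("ij,ij->j", T, T)
    sty = T.T @ y
    sy = y.sum()
    det = stt * m - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = (sty * m - st * sy) / det
        base = (stt * sy - st * sty) / det
        rss = y @ y - amp * sty - base * sy
    bad = ~np.isfinite(rss) | (det <= 1e-12 * m * np.maximum(stt, 1e-300))
    rss = np.where(bad, np.inf, rss)
    return amp, base, rss


def reconstruct_original(
    diff: DifferenceSpectrum,
    irradiated_spectrum: Spectrum,
    orientation: str = "original_minus_irradiated",
) -> Spectrum:
    """``original = irradiated + diff`` on the shared grid.

    ``orientation`` states what the supplied difference values mean:
    ``original_minus_irradiated`` (canonical) or ``irradiated_minus_original``
    (the values are negated first).  Negative reconstructed absorbances are
    allowed (flagged by callers via diagnostics), since noise and baseline
    drift can push near-zero regions slightly negative.
    """
    if orientation not in ("original_minus_irradiated", "irradiated_minus_original"):
        raise WindowError(f"unknown orientation {orientation!r}")
    if not irradiated_spectrum.same_grid(diff):
        irradiated_spectrum = resample(irradiated_spectrum, diff.wavelengths)
    d = diff.absorbance
    if orientation == "irradiated_minus_original":
        d = -d
    return Spectrum(
        diff.wavelengths,
        irradiated_spectrum.absorbance + d,
        label="reconstructed original state",
    )


def reconstruct_bistable_pair(
    before: Spectrum,
    after_first: Spectrum,
    after_second: Spectrum,
    family: str = "metarhodopsin_like",
    window: FitWindow | None = None,
    search_grid: np.ndarray | Sequence[float] | None = None,
) -> ReconstructionResult:
    """Reconstruct both states from one forward/back irradiation cycle.

    ``before`` is the dark measurement, ``after_first`` follows the forward
    (e.g. UV) irradiation that populates the visible-absorbing state, and
    ``after_second`` follows the back-converting (e.g. yellow) irradiation.
    The back-conversion difference ``after_second - after_first`` is in the
    canonical ``original - irradiated`` orientation; its negative visible
    lobe, mirrored to positive, is fitted with a template to estimate the
    irradiated state, and the original state follows additively.

    The RMS of ``after_second - before`` is reported as the photoregeneration
    residual: ~0 for a fully reversible cycle, positive when e.g. all-trans
    contamination over-regenerates the dark state.
    """
    back = difference(after_second, after_first)  # = original - irradiated
    mirrored = back.flipped()  # positive visible lobe = irradiated state
    fit = fit_irradiated_state(mirrored, family=family, window=window, search_grid=search_grid)
    irradiated = template_spectrum(fit.params, back.wavelengths)
    irradiated = irradiated.with_values(
        fit.amplitude * irradiated.absorbance, label="fitted irradiated state"
    )
    original = reconstruct_original(back, irradiated)
    regen = difference(after_second, before)
    residual = float(np.sqrt(np.mean(regen.absorbance**2)))
    n_neg = int(np.sum(original.absorbance < 0))
    diag = (
        ("n_negative_original_points", float(n_neg)),
        ("min_original_value", float(np.min(original.absorbance))),
    )
    return ReconstructionResult(
        irradiated_fit=fit,
        irradiated_spectrum=irradiated,
        original_spectrum=original,
        fit_rmse=fit.rmse,
        baseline_offset=fit.baseline_offset,
        window=fit.window,
        regeneration_residual=residual,
        diagnostics=diag,
    )
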