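"""Forward simulation of a bistable pigment under filtered-light irradiation.

The generator emulates the bench protocol used to characterize bistable
opsins: a UV-absorbing dark state (11-cis chromophore) and a
visible-absorbing metarhodopsin (all-trans) interconvert under light, and
each irradiation step is held until the photosteady state, where forward
and reverse photoconversion rates balance:

    f_meta(steady) = k_fwd / (k_fwd + k_rev),
    k_fwd = sum_l I(l) eps_dark(l) phi_fwd,   k_rev = sum_l I(l) eps_meta(l) phi_rev.

Finite-duration steps follow the two-state photokinetic rate equation
``df/dt = k_fwd (1 - f) - k_rev f`` (solved analytically).  The optically
thin-sample assumption (rate proportional to absorbance, no inner-filter
effect) is standard for low-AU cuvette spectroscopy and is a documented
limitation.  Measured spectra are convex mixtures of the two state spectra
plus seeded additive Gaussian noise and a random slow linear baseline
drift per measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import NoPhotochemistryError, ParameterError
from .spectra import CANONICAL_GRID, Spectrum
from .templates import TemplateParams, template_spectrum


@dataclass(frozen=True)
class PigmentPair:
    """Ground-truth bistable pigment: the simulator's two interconvertible states."""

    dark_spectrum: Spectrum
    meta_spectrum: Spectrum
    phi_forward: float = 1.0
    phi_reverse: float = 1.0

    def __post_init__(self) -> None:
        if not self.dark_spectrum.same_grid(self.meta_spectrum):
            raise ParameterError("dark and meta spectra must share a grid")
        for name, phi in (("phi_forward", self.phi_forward),
                          ("phi_reverse", self.phi_reverse)):
            if not 0.0 < phi <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1], got {phi}")

    @property
    def grid(self) -> np.ndarray:
        return self.dark_spectrum.wavelengths


@dataclass(frozen=True)
class LightSource:
    """Idealized irradiation source: monochromatic line or top-hat band.

    A longpass filter is encoded as a band from its cut-on wavelength to the
    end of the grid (``bandwidth = inf``).
    """

    kind: str
    center_or_cut: float
    bandwidth: float = 0.0
    relative_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("monochromatic", "band"):
            raise ParameterError(f"unknown light source kind {self.kind!r}")
        if self.relative_intensity <= 0:
            raise ParameterError("relative_intensity must be positive")

    @classmethod
    def monochromatic_line(cls, wavelength: float, intensity: float = 1.0) -> "LightSource":
        return cls("monochromatic", wavelength, 0.0, intensity)

    @classmethod
    def band(cls, center: float, bandwidth: float, intensity: float = 1.0) -> "LightSource":
        return cls("band", center, bandwidth, intensity)

    @classmethod
    def longpass(cls, cut_on: float, intensity: float = 1.0) -> "LightSource":
        return cls("band", cut_on, math.inf, intensity)

    def transmission(self, grid: np.ndarray) -> np.ndarray:
        """Per-grid-point spectral intensity (top-hat transmission x intensity)."""
        if self.kind == "monochromatic":
            tr = np.zeros_like(grid)
            tr[int(np.argmin(np.abs(grid - self.center_or_cut)))] = 1.0
        elif math.isinf(self.bandwidth):
            tr = (grid > self.center_or_cut).astype(float)
        else:
            half = 0.5 * self.bandwidth
            tr = (np.abs(grid - self.center_or_cut) <= half).astype(float)
        return tr * self.relative_intensity


# idealized versions of a standard bench filter set (top-hat transmissions)
def uv_d35() -> LightSource:
    """UV transmitting glass filter, ~330-390 nm band."""
    return LightSource.band(360.0, 60.0)


def bp450() -> LightSource:
    """Blue band-pass, 440-460 nm."""
    return LightSource.band(450.0, 20.0)


def y52() -> LightSource:
    """Yellow cutoff, transmits >500 nm."""
    return LightSource.longpass(500.0)


def o57() -> LightSource:
    """Orange cutoff, transmits >550 nm."""
    return LightSource.longpass(550.0)


def o58() -> LightSource:
    """Orange cutoff, transmits >575 nm."""
    return LightSource.longpass(575.0)


TO_STEADY_STATE = "to_steady_state"


@dataclass(frozen=True)
class ProtocolStep:
    """One irradiation step: a source held to steady state or for a finite time (s)."""

    source: LightSource
    duration: str | float = TO_STEADY_STATE


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise and slow baseline drift, fully seeded.

    ``baseline_drift_slope`` is the standard deviation of a per-measurement
    random linear baseline, in AU per 100 nm.  Stands in for instrument
    noise and unsteady baselines seen in real photobleaching series.
    """

    sigma_additive: float = 0.002
    baseline_drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_additive < 0:
            raise ParameterError("sigma_additive must be >= 0")
        if self.baseline_drift_slope < 0:
            raise ParameterError("baseline_drift_slope must be >= 0")


def photo_rates(pigments: PigmentPair, source: LightSource) -> tuple[float, float]:
    """(k_fwd, k_rev): photoconversion rate constants under the source."""
    tr = source.transmission(pigments.grid)
    k_fwd = float(np.sum(tr * np.maximum(pigments.dark_spectrum.absorbance, 0.0))
                  * pigments.phi_forward)
    k_rev = float(np.sum(tr * np.maximum(pigments.meta_spectrum.absorbance, 0.0))
                  * pigments.phi_reverse)
    if k_fwd == 0.0 and k_rev == 0.0:
        raise NoPhotochemistryError(
            "light source does not overlap the absorbance of either state"
        )
    return k_fwd, k_rev


def photosteady_fraction(pigments: PigmentPair, source: LightSource) -> float:
    """Metarhodopsin fraction at the photosteady state under ``source``."""
    k_fwd, k_rev = photo_rates(pigments, source)
    return k_fwd / (k_fwd + k_rev)


def mixture_spectrum(pigments: PigmentPair, fraction_meta: float) -> Spectrum:
    """Convex combination ``(1-f) dark + f meta`` (noise-free observable)."""
    if not 0.0 <= fraction_meta <= 1.0:
        raise ParameterError(f"fraction_meta must be in [0, 1], got {fraction_meta}")
    vals = ((1.0 - fraction_meta) * pigments.dark_spectrum.absorbance
            + fraction_meta * pigments.meta_spectrum.absorbance)
    return Spectrum(pigments.grid, vals,
                    label=f"mixture f_meta={fraction_meta:.4g}")


def _measure(pigments: PigmentPair, f: float, noise: NoiseModel | None,
             rng: np.random.Generator, label: str) -> Spectrum:
    grid = pigments.grid
    vals = mixture_spectrum(pigments, f).absorbance.copy()
    if noise is not None:
        if noise.baseline_drift_slope > 0:
            slope = noise.baseline_drift_slope * rng.standard_normal()
            mid = 0.5 * (grid[0] + grid[-1])
            vals = vals + slope * (grid - mid) / 100.0
        if noise.sigma_additive > 0:
            vals = vals + rng.normal(0.0, noise.sigma_additive, grid.size)
    return Spectrum(grid, vals, label=label)


def run_protocol(
    pigments: PigmentPair,
    steps: Sequence[ProtocolStep],
    initial_fraction_meta: float = 0.0,
    noise: NoiseModel | None = None,
    include_initial: bool = False,
) -> list[tuple[Spectrum, float]]:
    """Run an irradiation protocol, measuring a spectrum after every step.

    Returns ``(spectrum, fraction_meta)`` per step; with ``include_initial``
    a pre-irradiation measurement is prepended.  All randomness flows from
    the seed of the :class:`NoiseModel` (``noise=None`` means noise-free).
    """
    if not 0.0 <= initial_fraction_meta <= 1.0:
        raise ParameterError("initial_fraction_meta must be in [0, 1]")
    rng = np.random.default_rng(noise.seed if noise is not None else 0)
    f = float(initial_fraction_meta)
    out: list[tuple[Spectrum, float]] = []
    if include_initial:
        out.append((_measure(pigments, f, noise, rng, "before irradiation"), f))
    for i, step in enumerate(steps, start=1):
        k_fwd, k_rev = photo_rates(pigments, step.source)
        f_ss = k_fwd / (k_fwd + k_rev)
        if step.duration == TO_STEADY_STATE:
            f = f_ss
        else:
            t = float(step.duration)
            if t < 0:
                raise ParameterError("finite step duration must be >= 0 seconds")
            f = f_ss + (f - f_ss) * math.exp(-(k_fwd + k_rev) * t)
        out.append((_measure(pigments, f, noise, rng, f"after step {i}"), f))
    return out


def isosbestic_wavelengths(pigments: PigmentPair) -> np.ndarray:
    """Grid wavelengths bracketing sign changes of ``dark - meta`` (crossings)."""
    d = pigments.dark_spectrum.absorbance - pigments.meta_spectrum.absorbance
    s = np.sign(d)
    idx = np.nonzero(np.diff(s) != 0)[0]
    g = pigments.grid
    # linear interpolation of the crossing position inside each bracket
    lam = g[idx] - d[idx] * (g[idx + 1] - g[idx]) / (d[idx + 1] - d[idx])
    return lam


def rh7_like_pigments(
    grid: np.ndarray | None = None,
    dark_peak: float = 0.1,
    visible_to_uv_ratio: float = 8.0,
) -> PigmentPair:
    """Synthetic Rh7-like bistable pigment fixture (not measured truth).

    The dark state is a broad composite band, 0.65*T(360) + 0.35*T(415) with
    beta bands, scaled to ``dark_peak`` AU at its maximum.  The metarhodopsin
    is a single T(510) alpha band whose amplitude is ``visible_to_uv_ratio``
    times the dark peak, giving difference spectra with a UV:visible lobe
    ratio of about 1:8.  The metarhodopsin beta band is omitted so the UV
    lobe keeps the sign observed for real UV pigments (a full-strength beta
    satellite on an 8x-amplitude photoproduct would swamp the weak dark band).
    """
    g = CANONICAL_GRID if grid is None else np.asarray(grid, float)
    t360 = template_spectrum(TemplateParams(360.0, include_beta_band=True), g)
    t415 = template_spectrum(TemplateParams(415.0, include_beta_band=True), g)
    dark_raw = 0.65 * t360.absorbance + 0.35 * t415.absorbance
    dark_vals = dark_raw * (dark_peak / float(np.max(dark_raw)))
    meta = template_spectrum(
        TemplateParams(510.0, family="metarhodopsin_like", include_beta_band=False), g
    )
    meta_vals = meta.absorbance * (visible_to_uv_ratio * dark_peak)
    return PigmentPair(
        Spectrum(g, dark_vals, label="synthetic Rh7-like dark state"),
        Spectrum(g, meta_vals, label="synthetic Rh7-like metarhodopsin"),
    )
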