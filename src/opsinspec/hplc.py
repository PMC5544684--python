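"""Retinal-isomer quantification from HPLC chromatograms.

Chromophores extracted as retinaloximes separate on a silica column into
syn and anti oxime peaks of each retinal isomer; the trace is the 360 nm
absorbance versus retention time.  Peaks are detected by prominence,
co-fitted as a sum of Gaussians, and converted to fractional isomer
compositions by (extinction-corrected) area shares.  A matching simulator
generates traces for known compositions so the whole loop is testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .errors import DegenerateInputError, ParameterError, UnassignedPeakError

ISOMERS = ("11-cis", "13-cis", "all-trans")
SPECIES = (
    "11-cis syn", "11-cis anti",
    "13-cis syn", "13-cis anti",
    "all-trans syn", "all-trans anti",
)

#: synthetic default retention times (minutes) on a normal-phase silica
#: column; syn oximes elute before anti oximes.  These are package fixture
#: values, not measured data.
DEFAULT_RETENTION: dict[str, float] = {
    "11-cis syn": 5.6,
    "13-cis syn": 6.4,
    "all-trans syn": 7.6,
    "11-cis anti": 10.4,
    "13-cis anti": 11.6,
    "all-trans anti": 13.0,
}

#: default syn:anti oxime split used in simulation (adjustable)
DEFAULT_SYN_FRACTION = 0.7


@dataclass(frozen=True)
class Chromatogram:
    """A360 trace versus retention time (minutes, strictly increasing)."""

    retention_time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.retention_time, float)
        s = np.asarray(self.signal, float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ParameterError("retention_time and signal must be 1-D, equal length")
        if t.size < 10:
            raise ParameterError("chromatogram needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("retention times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ParameterError("chromatogram contains non-finite values")
        t.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "retention_time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class Peak:
    position: float  # minutes
    area: float      # AU * min
    width: float     # Gaussian sigma, minutes
    height: float    # AU


@dataclass(frozen=True)
class PeakTable:
    """Detected peaks sorted by retention time; empty tables carry a warning."""

    peaks: tuple[Peak, ...]
    warning: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class IsomerComposition:
    """Fractions per oxime species; per-isomer aggregates sum to 1."""

    fractions: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        d = dict(self.fractions)
        unknown = set(d) - set(SPECIES)
        if unknown:
            raise ParameterError(f"unknown species {sorted(unknown)}")
        if any(v < 0 for v in d.values()):
            raise ParameterError("fractions must be nonnegative")
        if abs(sum(d.values()) - 1.0) > 1e-9:
            raise ParameterError("fractions must sum to 1 within 1e-9")
        object.__setattr__(self, "fractions", tuple(sorted(d.items())))

    def species_fraction(self, species: str) -> float:
        return dict(self.fractions).get(species, 0.0)

    def isomer_fractions(self) -> dict[str, float]:
        """syn + anti aggregated per retinal isomer."""
        d = dict(self.fractions)
        return {
            iso: d.get(f"{iso} syn", 0.0) + d.get(f"{iso} anti", 0.0)
            for iso in ISOMERS
        }

    @classmethod
    def from_isomers(
        cls, isomer_fractions: Mapping[str, float],
        syn_fraction: float = DEFAULT_SYN_FRACTION,
    ) -> "IsomerComposition":
        """Build a full species composition from per-isomer fractions."""
        total = sum(isomer_fractions.values())
        if total <= 0:
            raise DegenerateInputError("isomer fractions sum to zero")
        items = []
        for iso in ISOMERS:
            f = isomer_fractions.get(iso, 0.0) / total
            items.append((f"{iso} syn", f * syn_fraction))
            items.append((f"{iso} anti", f * (1.0 - syn_fraction)))
        return cls(tuple(items))


def composition_from_state_fraction(
    fraction_meta: float,
    thirteen_cis: float = 0.05,
    syn_fraction: float = DEFAULT_SYN_FRACTION,
) -> IsomerComposition:
    """Isomer composition implied by a metarhodopsin fraction.

    The photoconvertible pool (1 - thirteen_cis) splits into 11-cis (dark
    state) and all-trans (metarhodopsin) according to ``fraction_meta``; a
    small fixed 13-cis contaminant is untouched by light.
    """
    if not 0.0 <= fraction_meta <= 1.0:
        raise ParameterError("fraction_meta must be in [0, 1]")
    pool = 1.0 - thirteen_cis
    return IsomerComposition.from_isomers(
        {
            "11-cis": pool * (1.0 - fraction_meta),
            "13-cis": thirteen_cis,
            "all-trans": pool * fraction_meta,
        },
        syn_fraction=syn_fraction,
    )


def _gauss_sum(t: np.ndarray, *p: float) -> np.ndarray:
    # p = [offset, (amp, mu, sigma) per peak]; the constant offset absorbs
    # the pedestal left by rolling-minimum baseline subtraction on noisy
    # data (the rolling minimum sits ~3 sigma below the local mean)
    out = np.full_like(t, p[0])
    for i in range(1, len(p), 3):
        amp, mu, sig = p[i], p[i + 1], p[i + 2]
        out = out + amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def rolling_minimum_baseline(signal: np.ndarray, window: int = 201) -> np.ndarray:
    """Simple deterministic baseline: rolling minimum over ``window`` samples.

    The window must be much wider than a chromatographic peak or the
    subtraction eats the peaks themselves; the default of 201 samples is
    ~2 min at the simulator's 0.01-min sampling, several times the widest
    peak.
    """
    s = np.asarray(signal, float)
    return minimum_filter1d(s, size=window, mode="nearest")


def detect_and_integrate_peaks(
    chromatogram: Chromatogram,
    min_prominence: float,
    baseline_window: int = 201,
    min_width_points: int = 5,
) -> PeakTable:
    """Detect local maxima above ``min_prominence`` and co-fit Gaussians.

    The trace is baseline-corrected by rolling-minimum subtraction; all
    detected peaks are fitted jointly as a sum of Gaussians (handles
    overlapping peaks); ``area = amplitude * sigma * sqrt(2 pi)``.  A trace
    with no peaks yields an empty table with a warning string, not an error.
    """
    if min_prominence <= 0:
        raise ParameterError("min_prominence must be > 0")
    t = chromatogram.retention_time
    s = chromatogram.signal - rolling_minimum_baseline(
        chromatogram.signal, baseline_window
    )
    # detection runs on a lightly smoothed copy so noise wiggles cannot
    # split the top of a tall peak; integration fits the raw trace.  The
    # width floor rejects residual single-sample spikes.
    win = 2 * min_width_points + 1
    s_det = savgol_filter(s, win, 2) if s.size > win else s
    idx, props = find_peaks(s_det, prominence=min_prominence, width=min_width_points)
    if idx.size == 0:
        return PeakTable((), warning="no peaks above prominence threshold")
    dt = float(np.median(np.diff(t)))
    widths_pts = peak_widths(s_det, idx, rel_height=0.5)[0]
    sig0 = np.maximum(widths_pts * dt / 2.3548, dt)  # FWHM -> sigma
    p0: list[float] = [float(np.median(s))]
    lo: list[float] = [-np.inf]
    hi: list[float] = [np.inf]
    for k, i in enumerate(idx):
        p0 += [float(s_det[i]), float(t[i]), float(sig0[k])]
        # keep each Gaussian near its detected position so no component can
        # wander off and absorb baseline noise
        lo += [0.0, float(t[i] - 3 * sig0[k]), dt / 4.0]
        hi += [np.inf, float(t[i] + 3 * sig0[k]), float(5 * sig0[k])]
    try:
        popt, _ = curve_fit(_gauss_sum, t, s, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError:
        popt = np.asarray(p0)  # fall back to moment estimates
    peaks = []
    for i in range(1, len(popt), 3):
        amp, mu, sig = float(popt[i]), float(popt[i + 1]), float(popt[i + 2])
        peaks.append(Peak(mu, amp * sig * np.sqrt(2.0 * np.pi), sig, amp))
    peaks.sort(key=lambda p: p.position)
    return PeakTable(tuple(peaks))


def compose_fractions(
    peaks: PeakTable,
    assignment_map: Mapping[str, float] | None = None,
    extinction_corrections: Mapping[str, float] | None = None,
    match_tolerance: float = 0.8,
    unassigned_area_fraction: float = 0.01,
) -> IsomerComposition:
    """Convert a peak table to an isomer composition by corrected area share.

    ``assignment_map`` maps species to expected retention times (minutes);
    each peak is assigned to the nearest species within ``match_tolerance``.
    A peak carrying more than ``unassigned_area_fraction`` of the total area
    with no assignment raises :class:`UnassignedPeakError` naming its
    retention time.  Extinction corrections divide areas (default 1.0:
    equal molar extinction across oxime species).
    """
    amap = dict(DEFAULT_RETENTION if assignment_map is None else assignment_map)
    eps = dict(extinction_corrections or {})
    if not peaks.peaks:
        raise DegenerateInputError("empty peak table: nothing to compose")
    total_area = sum(p.area for p in peaks.peaks)
    if total_area <= 0:
        raise DegenerateInputError("peak table has zero total area")
    corrected: dict[str, float] = {}
    for p in peaks.peaks:
        species, best = None, np.inf
        for sp, rt in amap.items():
            d = abs(p.position - rt)
            if d < best:
                species, best = sp, d
        if species is None or best > match_tolerance:
            if p.area / total_area > unassigned_area_fraction:
                raise UnassignedPeakError(
                    f"peak at {p.position:.2f} min (area share "
                    f"{p.area / total_area:.3f}) has no species assignment"
                )
            continue
        corrected[species] = corrected.get(species, 0.0) + p.area / eps.get(species, 1.0)
    norm = sum(corrected.values())
    if norm <= 0:
        raise DegenerateInputError("no assignable peak area")
    fracs = {sp: a / norm for sp, a in corrected.items()}
    # exact renormalization guard against float round-off
    total = sum(fracs.values())
    return IsomerComposition(tuple((sp, v / total) for sp, v in fracs.items()))


def simulate_chromatogram(
    composition: IsomerComposition,
    retention_map: Mapping[str, float] | None = None,
    width: float = 0.1,
    noise_sigma: float = 0.0,
    seed: int = 0,
    time_grid: np.ndarray | Sequence[float] | None = None,
    total_area: float = 1.0,
) -> Chromatogram:
    """Sum-of-Gaussians trace with areas proportional to the composition.

    Retention times closer than two peak widths trigger an overlap warning
    (``warnings.warn``); the trace is still produced.  Fully seeded.
    """
    rmap = dict(DEFAULT_RETENTION if retention_map is None else retention_map)
    if width <= 0:
        raise ParameterError("width (sigma, minutes) must be > 0")
    rts = sorted(rmap.values())
    if any(b - a < 2 * width for a, b in zip(rts, rts[1:])):
        warnings.warn("retention times closer than 2 sigma: peaks overlap",
                      stacklevel=2)
    if time_grid is None:
        time_grid = np.arange(3.0, 15.0 + 1e-9, 0.01)
    t = np.asarray(time_grid, float)
    s = np.zeros_like(t)
    for sp, frac in composition.fractions:
        if frac == 0.0:
            continue
        if sp not in rmap:
            raise ParameterError(f"no retention time for species {sp!r}")
        area = frac * total_area
        amp = area / (width * np.sqrt(2.0 * np.pi))
        s += amp * np.exp(-0.5 * ((t - rmap[sp]) / width) ** 2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sigma, t.size)
    return Chromatogram(t, s)
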