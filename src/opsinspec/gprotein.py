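"""Initial-rate estimation for G-protein activation time courses.

Filter-binding assays of GDP/GTPgammaS exchange yield bound-nucleotide
signal versus time per illumination condition (dark / UV-irradiated /
subsequently yellow-irradiated).  Rates are estimated per replicate and
summarized as mean +/- standard error per condition with fold change
relative to dark.  Signals are treated as arbitrary linear units; no
counts-to-moles conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .errors import InsufficientDataError, MissingReferenceError, ParameterError

MODELS = ("linear_through_origin", "linear_with_intercept", "exponential_saturation")
#: default: intercept model over the first few points (the near-linear early
#: phase); the intercept absorbs filter background
DEFAULT_MODEL = "linear_with_intercept"
DEFAULT_N_POINTS = 5


@dataclass(frozen=True)
class TimeCourse:
    """One replicate: bound-nucleotide signal versus time (minutes)."""

    time: np.ndarray
    signal: np.ndarray
    condition: str
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        s = np.asarray(self.signal, float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ParameterError("time and signal must be 1-D, equal length")
        if t.size < 3:
            raise InsufficientDataError("time course needs at least 3 points")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("times must be increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ParameterError("time course contains non-finite values")
        t.setflags(write=False)
        s.setflags(write=False)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    mean_rate: float
    stderr: float
    n_replicates: int
    fold_change_vs_dark: float


@dataclass(frozen=True)
class ActivationSummary:
    """Per-condition initial rates and the resulting rate ordering."""

    conditions: tuple[ConditionSummary, ...]
    ordering: tuple[str, ...]  # conditions sorted by descending mean rate

    def get(self, condition: str) -> ConditionSummary:
        for c in self.conditions:
            if c.condition == condition:
                return c
        raise MissingReferenceError(f"no condition {condition!r} in summary")


def fit_initial_rate(
    timecourse: TimeCourse,
    model: str = DEFAULT_MODEL,
    n_points: int | None = None,
) -> tuple[float, float]:
    """(initial rate, standard error) in signal units per minute.

    ``linear_through_origin`` and ``linear_with_intercept`` fit straight
    lines (optionally restricted to the first ``n_points``);
    ``exponential_saturation`` fits ``A (1 - exp(-k t))`` and reports the
    analytic initial slope ``A k`` with a delta-method standard error.
    """
    if model not in MODELS:
        raise ParameterError(f"unknown model {model!r}; choose from {MODELS}")
    t, s = timecourse.time, timecourse.signal
    if n_points is not None:
        if n_points < 3:
            raise InsufficientDataError("need at least 3 points for a rate fit")
        t, s = t[:n_points], s[:n_points]
    if t.size < 3:
        raise InsufficientDataError("need at least 3 points for a rate fit")

    if model == "linear_through_origin":
        stt = float(t @ t)
        slope = float(t @ s) / stt
        resid = s - slope * t
        dof = t.size - 1
        se = float(np.sqrt((resid @ resid) / dof / stt))
        return slope, se
    if model == "linear_with_intercept":
        res = linregress(t, s)
        se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        return float(res.slope), se
    # exponential_saturation
    if np.ptp(s) == 0.0:
        return 0.0, 0.0  # constant signal: no exchange
    a0 = float(np.max(np.abs(s))) or 1.0
    k0 = 1.0 / max(float(t[-1]), 1e-9)
    popt, pcov = curve_fit(
        lambda tt, A, k: A * (1.0 - np.exp(-k * tt)),
        t, s, p0=[a0, k0], maxfev=10000,
    )
    A, k = float(popt[0]), float(popt[1])
    rate = A * k
    grad = np.array([k, A])
    var = float(grad @ pcov @ grad) if np.all(np.isfinite(pcov)) else 0.0
    return rate, float(np.sqrt(max(var, 0.0)))


def summarize_conditions(
    timecourses: Sequence[TimeCourse],
    model: str = DEFAULT_MODEL,
    n_points: int | None = DEFAULT_N_POINTS,
    reference: str = "dark",
) -> ActivationSummary:
    """Mean rate +/- S.E. per condition and fold change versus the dark reference.

    The standard error is the across-replicate S.E. of the mean (0 for a
    single replicate).  A condition labelled ``reference`` must be present.
    """
    groups: dict[str, list[float]] = {}
    for tc in timecourses:
        rate, _ = fit_initial_rate(tc, model=model, n_points=n_points)
        groups.setdefault(tc.condition, []).append(rate)
    if reference not in groups:
        raise MissingReferenceError(
            f"reference condition {reference!r} absent; have {sorted(groups)}"
        )
    dark_mean = float(np.mean(groups[reference]))
    summaries = []
    for cond in sorted(groups):
        rates = np.asarray(groups[cond], float)
        mean = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
        fold = mean / dark_mean if dark_mean != 0 else np.inf
        summaries.append(ConditionSummary(cond, mean, se, rates.size, fold))
    ordering = tuple(
        c.condition for c in sorted(summaries, key=lambda c: -c.mean_rate)
    )
    return ActivationSummary(tuple(summaries), ordering)


def simulate_timecourse(
    rate: float,
    condition: str,
    times: np.ndarray | Sequence[float] | None = None,
    relative_noise: float = 0.05,
    seed: int = 0,
    replicate: int = 0,
    background: float = 0.1,
) -> TimeCourse:
    """Synthetic linear-phase time course with multiplicative-scale noise."""
    t = np.arange(0.0, 11.0, 2.0) if times is None else np.asarray(times, float)
    rng = np.random.default_rng(seed)
    scale = max(abs(rate) * float(t[-1]), 1e-12)
    s = background + rate * t + rng.normal(0.0, relative_noise * scale, t.size)
    return TimeCourse(t, s, condition=condition, replicate=replicate)
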