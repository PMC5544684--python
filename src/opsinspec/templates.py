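"""Visual-pigment template (nomogram) absorbance curves.

The alpha band follows the Govardovskii et al. (2000) A1 closed form: with
``x = lambda_max / lambda``,

    S(x) = 1 / ( exp(A*(a - x)) + exp(B*(b - x)) + exp(C*(c - x)) + D )

where ``a`` depends weakly on lambda_max, capturing the natural narrowing of
pigment bands at longer lambda_max:

    a(lambda_max) = 0.8795 + 0.0459 * exp(-(lambda_max - 300)^2 / 11940)

The optional beta band is the Govardovskii Gaussian satellite at
``189 + 0.315*lambda_max`` nm with width ``-40.5 + 0.195*lambda_max`` nm and
amplitude 0.26 of the alpha peak.  Curves are normalized so the alpha-band
maximum equals 1.0.

Three families share this functional form and differ only in default shape
constants: ``a1_pigment`` (the published A1 constants), and the broadened
``metarhodopsin_like`` (bovine meta-I-like) and ``retinochrome_like`` (squid
retinochrome-like) bases used to fit visible-absorbing photoproduct states.
The family constants are package defaults (tabulated in the docs) and can be
overridden per-call via ``shape_overrides``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ParameterError
from .spectra import Spectrum

LAMBDA_MAX_MIN = 300.0
LAMBDA_MAX_MAX = 650.0

#: alpha-band shape constants per family; a1_pigment holds the published A1
#: values, the other two are package defaults with slightly broader flanks.
FAMILY_CONSTANTS: dict[str, dict[str, float]] = {
    "a1_pigment": dict(A=69.7, B=28.0, C=-14.9, D=0.674, b=0.922, c=1.104),
    "metarhodopsin_like": dict(A=64.0, B=26.0, C=-14.9, D=0.674, b=0.922, c=1.104),
    "retinochrome_like": dict(A=60.0, B=26.0, C=-14.9, D=0.684, b=0.922, c=1.104),
}

#: beta-band (Gaussian satellite) constants, shared across families
BETA_CONSTANTS = dict(amp=0.26, m0=189.0, m1=0.315, w0=-40.5, w1=0.195)

#: lambda_max dependence of the alpha-band exponent offset `a`
A_PARAM = dict(a0=0.8795, a1=0.0459, center=300.0, scale=11940.0)

GRID_MIN = 250.0
GRID_MAX = 800.0


@dataclass(frozen=True)
class TemplateParams:
    """Parameters of one template curve.

    ``shape_overrides`` may replace any of the alpha-band constants
    (A, B, C, D, b, c) or pin the exponent offset ``a`` to a fixed value
    (key ``"a"``), removing its lambda_max dependence.
    """

    lambda_max: float
    family: str = "a1_pigment"
    include_beta_band: bool = False
    shape_overrides: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_CONSTANTS:
            raise ParameterError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILY_CONSTANTS)}"
            )
        if not (LAMBDA_MAX_MIN <= self.lambda_max <= LAMBDA_MAX_MAX):
            raise ParameterError(
                f"lambda_max {self.lambda_max:g} nm outside "
                f"[{LAMBDA_MAX_MIN:g}, {LAMBDA_MAX_MAX:g}]"
            )
        if self.shape_overrides is not None and not isinstance(self.shape_overrides, tuple):
            # accept a mapping for convenience, store hashable
            object.__setattr__(
                self, "shape_overrides", tuple(sorted(dict(self.shape_overrides).items()))
            )

    def constants(self) -> tuple[dict[str, float], float]:
        """Resolved alpha constants and the exponent offset ``a``."""
        consts = dict(FAMILY_CONSTANTS[self.family])
        over = dict(self.shape_overrides or ())
        a = over.pop("a", None)
        for k, v in over.items():
            if k not in consts:
                raise ParameterError(f"unknown shape constant {k!r}")
            consts[k] = float(v)
        if a is None:
            a = A_PARAM["a0"] + A_PARAM["a1"] * np.exp(
                -((self.lambda_max - A_PARAM["center"]) ** 2) / A_PARAM["scale"]
            )
        return consts, float(a)


def _alpha_raw(x: np.ndarray, consts: Mapping[str, float], a: float) -> np.ndarray:
    A, B, C, D = consts["A"], consts["B"], consts["C"], consts["D"]
    b, c = consts["b"], consts["c"]
    with np.errstate(over="ignore"):
        return 1.0 / (
            np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
        )


@lru_cache(maxsize=4096)
def _alpha_peak(consts_key: tuple, a: float) -> float:
    """Maximum of the raw alpha band over x, for normalization to 1.0."""
    consts = dict(consts_key)
    res = minimize_scalar(
        lambda x: -_alpha_raw(np.asarray(x), consts, a),
        bounds=(0.7, 1.3),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(-res.fun)


def template_spectrum(params: TemplateParams, grid: np.ndarray | Sequence[float]) -> Spectrum:
    """Evaluate a template on ``grid`` (nm), alpha-band peak normalized to 1.0."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < GRID_MIN or grid[-1] > GRID_MAX:
        raise ParameterError(
            f"grid must lie within [{GRID_MIN:g}, {GRID_MAX:g}] nm"
        )
    consts, a = params.constants()
    x = params.lambda_max / grid
    peak = _alpha_peak(tuple(sorted(consts.items())), a)
    curve = _alpha_raw(x, consts, a) / peak
    if params.include_beta_band:
        bc = BETA_CONSTANTS
        mu = bc["m0"] + bc["m1"] * params.lambda_max
        width = bc["w0"] + bc["w1"] * params.lambda_max
        curve = curve + bc["amp"] * np.exp(-(((grid - mu) / width) ** 2))
    label = f"template lmax={params.lambda_max:g}nm {params.family}"
    return Spectrum(grid, curve, label=label)


def template_bank(
    lambda_max_list: Sequence[float],
    family: str = "a1_pigment",
    grid: np.ndarray | Sequence[float] | None = None,
    include_beta_band: bool = False,
) -> list[Spectrum]:
    """One template per lambda_max on a shared grid (deterministic)."""
    if len(lambda_max_list) == 0:
        raise ParameterError("lambda_max_list must be nonempty")
    from .spectra import CANONICAL_GRID

    g = CANONICAL_GRID if grid is None else np.asarray(grid, float)
    return [
        template_spectrum(
            TemplateParams(lm, family=family, include_beta_band=include_beta_band), g
        )
        for lm in lambda_max_list
    ]


@lru_cache(maxsize=64)
def _bank_matrix_cached(
    lams_key: tuple, family: str, grid_key: tuple, include_beta: bool
) -> np.ndarray:
    grid = np.asarray(grid_key, float)
    cols = [
        template_spectrum(
            TemplateParams(lm, family=family, include_beta_band=include_beta), grid
        ).absorbance
        for lm in lams_key
    ]
    out = np.column_stack(cols)
    out.setflags(write=False)
    return out


def bank_matrix(
    lams: np.ndarray | Sequence[float],
    grid: np.ndarray | Sequence[float],
    family: str = "a1_pigment",
    include_beta_band: bool = False,
) -> np.ndarray:
    """(n_grid, n_lambda) matrix of template columns, cached for repeated fits."""
    return _bank_matrix_cached(
        tuple(float(l) for l in lams),
        family,
        tuple(float(g) for g in grid),
        bool(include_beta_band),
    )
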