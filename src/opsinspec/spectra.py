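"""Core spectrum data model, I/O, resampling and difference spectra.

A :class:`Spectrum` is an absorbance curve on a strictly increasing
wavelength grid (nm) with values in arbitrary absorbance units (AU); the
whole toolkit works with relative spectra, so no pathlength or
concentration handling is provided.  A :class:`DifferenceSpectrum` is the
pointwise subtraction of two spectra measured before/after irradiation and
always carries an explicit sign-convention tag — sign mistakes are the
dominant failure mode when mixing photoconversion directions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, EmptyInputError, GridError, ParseError

#: sign-convention tags for difference spectra
AFTER_MINUS_BEFORE = "after_minus_before"
BEFORE_MINUS_AFTER = "before_minus_after"

WAVELENGTH_MIN = 200.0
WAVELENGTH_MAX = 800.0


def make_grid(start: float = 250.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """Wavelength grid in nm, inclusive of both endpoints when they align."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


#: canonical 1 nm analysis grid, 250-700 nm (covers the 300-650 nm
#: observation window of bench spectrophotometry with margin)
CANONICAL_GRID = make_grid()


@dataclass(frozen=True)
class Spectrum:
    """Absorbance curve on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing, finite, within [200, 800] nm, length >= 2.
    absorbance : array-like
        Same length as ``wavelengths``; finite; arbitrary units.
    label : str
        Free-text description carried through arithmetic.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.shape != a.shape:
            raise GridError("wavelengths and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise GridError("spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise GridError("spectrum contains non-finite values")
        if np.any(np.diff(w) <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if w[0] < WAVELENGTH_MIN or w[-1] > WAVELENGTH_MAX:
            raise GridError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        w.setflags(write=False)
        a.setflags(write=False)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at one wavelength (must be in range)."""
        w = self.wavelengths
        if wavelength < w[0] or wavelength > w[-1]:
            raise GridError(f"{wavelength} nm outside spectrum range [{w[0]}, {w[-1]}]")
        return float(np.interp(wavelength, w, self.absorbance))

    def peak_wavelength(self) -> float:
        """Wavelength of the absorbance maximum (grid resolution)."""
        return float(self.wavelengths[int(np.argmax(self.absorbance))])

    def with_values(self, absorbance: np.ndarray, label: str | None = None) -> "Spectrum":
        return replace(
            self, absorbance=np.asarray(absorbance, float),
            label=self.label if label is None else label,
        )

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            len(self) == len(other)
            and bool(np.array_equal(self.wavelengths, other.wavelengths))
        )


@dataclass(frozen=True)
class DifferenceSpectrum(Spectrum):
    """A :class:`Spectrum` holding an after/before subtraction with explicit sign tag."""

    sign: str = field(default=AFTER_MINUS_BEFORE)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.sign not in (AFTER_MINUS_BEFORE, BEFORE_MINUS_AFTER):
            raise ParseError(f"unknown sign convention {self.sign!r}")

    def flipped(self) -> "DifferenceSpectrum":
        """Negate values and swap the sign tag (same physical content)."""
        other = BEFORE_MINUS_AFTER if self.sign == AFTER_MINUS_BEFORE else AFTER_MINUS_BEFORE
        return DifferenceSpectrum(
            self.wavelengths, -self.absorbance, label=self.label, sign=other
        )


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()  # tabs and spaces


def read_spectrum(path, dialect: str = "auto", label: str | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, absorbance AU) delimited text file.

    The delimiter is auto-detected among comma / tab / whitespace; lines
    starting with ``#`` are comments; a single non-numeric header line is
    tolerated.  Rows are sorted by wavelength; duplicate wavelengths are an
    error.
    """
    if dialect not in ("auto", "csv", "tsv", "whitespace"):
        raise ParseError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    rows: list[tuple[float, float]] = []
    header_seen = False
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_row(line)
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        f0, f1 = fields[0], fields[1]
        if not (_NUMERIC_RE.match(f0) and _NUMERIC_RE.match(f1)):
            if not rows and not header_seen:
                header_seen = True  # tolerate one header line
                continue
            raise ParseError(f"line {lineno}: non-numeric row {line!r}")
        rows.append((float(f0), float(f1)))
    if not rows:
        raise EmptyInputError(f"{path}: no data rows")
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 data rows")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise ParseError(f"{path}: duplicate wavelength {dup:g} nm")
    return Spectrum(arr[:, 0], arr[:, 1], label=label if label is not None else str(path))


def write_spectrum(spectrum: Spectrum, path, delimiter: str = "\t") -> None:
    """Write a two-column text file at 6 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        if spectrum.label:
            fh.write(f"# {spectrum.label}\n")
        fh.write(f"# wavelength_nm{delimiter}absorbance_AU\n")
        for w, a in zip(spectrum.wavelengths, spectrum.absorbance):
            fh.write(f"{w:.6g}{delimiter}{a:.6g}\n")


def resample(spectrum: Spectrum, grid: np.ndarray, extrapolate: bool = False) -> Spectrum:
    """Linear interpolation onto ``grid``; values at shared points unchanged.

    Without ``extrapolate`` the target grid must lie within the source range;
    with it, out-of-range points clamp to the edge values.
    """
    grid = np.asarray(grid, dtype=float)
    w = spectrum.wavelengths
    if not extrapolate and (grid[0] < w[0] - 1e-9 or grid[-1] > w[-1] + 1e-9):
        raise GridError(
            f"target grid [{grid[0]:g}, {grid[-1]:g}] exceeds source range "
            f"[{w[0]:g}, {w[-1]:g}] (set extrapolate=True to clamp to edges)"
        )
    vals = np.interp(grid, w, spectrum.absorbance)
    out = Spectrum(grid, vals, label=spectrum.label)
    if isinstance(spectrum, DifferenceSpectrum):
        return DifferenceSpectrum(grid, vals, label=spectrum.label, sign=spectrum.sign)
    return out


def _common_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if hi <= lo:
        raise GridError("spectra have disjoint wavelength ranges")
    grid = a.wavelengths[(a.wavelengths >= lo) & (a.wavelengths <= hi)]
    if grid.size < 2:
        raise GridError("wavelength overlap contains fewer than 2 grid points")
    return grid


def difference(after: Spectrum, before: Spectrum) -> DifferenceSpectrum:
    """``after - before`` on the shared grid, tagged ``after_minus_before``.

    Grids are auto-resampled onto their intersection (the ``after`` grid
    restricted to the overlap) when they differ.
    """
    if not after.same_grid(before):
        grid = _common_grid(after, before)
        after = resample(after, grid)
        before = resample(before, grid)
    return DifferenceSpectrum(
        after.wavelengths,
        after.absorbance - before.absorbance,
        label=f"({after.label}) - ({before.label})",
        sign=AFTER_MINUS_BEFORE,
    )


def normalize_at_extremum(
    diff: DifferenceSpectrum, which: str = "negative_max"
) -> tuple[DifferenceSpectrum, float]:
    """Scale a difference spectrum so the chosen extremum has magnitude 1.

    ``which`` selects the negative minimum or the positive maximum.  Returns
    the scaled spectrum and the scale factor applied (1/|extremum|).
    """
    v = diff.absorbance
    if which == "negative_max":
        ext = float(np.min(v))
        if ext >= 0.0:
            raise DegenerateInputError("no negative lobe to normalize at")
    elif which == "positive_max":
        ext = float(np.max(v))
        if ext <= 0.0:
            raise DegenerateInputError("no positive lobe to normalize at")
    else:
        raise ParseError(f"unknown extremum selector {which!r}")
    scale = 1.0 / abs(ext)
    out = DifferenceSpectrum(
        diff.wavelengths, v * scale, label=diff.label, sign=diff.sign
    )
    return out, scale
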