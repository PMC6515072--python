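"""Visible-range colorimetry: absorbance spectra to A520 and CIELAB.

Spectra are absorbance curves (10 mm path) over 400-800 nm.  Color is
computed by converting absorbance to transmittance, integrating against
the CIE 1964 10-degree standard observer under illuminant D65 on a fixed
5 nm grid (400-780 nm), and applying the CIE XYZ -> L*a*b* transform.
The whitepoint is recomputed on the same truncated grid so that a
zero-absorbance spectrum maps to L* = 100 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "SampleMeta",
    "ObserverIlluminant",
    "ColorCoordinates",
    "CoverageError",
    "GridMismatchError",
    "FAMILIES",
    "ROLES",
    "resample_to_grid",
    "absorbance_to_transmittance",
    "tristimulus",
    "xyz_to_lab",
    "chroma_hue",
    "a520",
    "spectrum_color",
]

#: Tannin family vocabulary (plus the reference copigment).
FAMILIES = ("PC/PD", "PF/PR", "GT", "ET", "reference")

#: Sample roles understood by the pipeline.
ROLES = ("mix", "blank", "control", "corrected")

#: Wavelength span (nm) any spectrum must cover to be colorimetrically usable.
REQUIRED_COVERAGE = (420.0, 700.0)


class CoverageError(ValueError):
    """A spectrum does not cover a required wavelength span."""


class GridMismatchError(ValueError):
    """Two spectra (or a spectrum and an observer grid) are on different grids."""


@dataclass(frozen=True)
class SampleMeta:
    """Experimental metadata attached to one spectrum."""

    role: str = "mix"
    copigment: str = ""
    family: str = "reference"
    dose_g_per_l: float = 0.0
    pigment_mg_per_l: float = 50.0
    ph: float = 3.5
    ethanol_pct: float = 12.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    def condition_key(self) -> tuple:
        """(copigment, dose, pH, ethanol) — what a blank must share with its mix."""
        return (self.copigment, self.dose_g_per_l, self.ph, self.ethanol_pct)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed absorbance curve with sample metadata.

    Wavelengths must be strictly increasing, in nm, within [400, 800], and
    the curve must cover at least 420-700 nm.  Absorbance is in AU for a
    10 mm path; negative values are allowed (blank-subtraction artifacts)
    and are surfaced through ``flags``.
    """

    sample_id: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 1:
            raise ValueError("wavelengths and absorbance must be 1-D")
        if wl.size != ab.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {ab.size} absorbances"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 400.0 - 1e-9 or wl[-1] > 800.0 + 1e-9:
            raise ValueError(
                f"wavelengths must lie within [400, 800] nm, got "
                f"[{wl[0]:g}, {wl[-1]:g}]"
            )
        lo, hi = REQUIRED_COVERAGE
        if wl[0] > lo or wl[-1] < hi:
            raise CoverageError(
                f"spectrum {self.sample_id!r} covers [{wl[0]:g}, {wl[-1]:g}] nm "
                f"but must include [{lo:g}, {hi:g}] nm"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"non-finite absorbance in spectrum {self.sample_id!r}")

    def with_flags(self, *names: str) -> "Spectrum":
        return replace(self, flags=self.flags | frozenset(names))

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


@dataclass(frozen=True)
class ObserverIlluminant:
    """Color-matching functions and illuminant power on one fixed grid.

    All four tables share the identical, evenly spaced wavelength grid.
    The whitepoint (Xn, Yn, Zn) is derived from the same truncated grid,
    which guarantees Yn = 100 and makes unit transmittance map to
    L* = 100 exactly.
    """

    wavelengths: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    illuminant: np.ndarray
    observer_name: str = "CIE 1964 10 deg"
    illuminant_name: str = "D65"

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("wavelengths", "xbar", "ybar", "zbar", "illuminant"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        n = arrays["wavelengths"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("observer/illuminant tables must share one grid")
        steps = np.diff(arrays["wavelengths"])
        if n < 2 or not np.allclose(steps, steps[0]):
            raise ValueError("observer grid must be evenly spaced")
        if np.any(arrays["ybar"] < 0) or np.any(arrays["illuminant"] < 0):
            raise ValueError("ybar and illuminant must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def integrate(self, values: np.ndarray) -> float:
        """Trapezoidal quadrature of a per-wavelength integrand.

        Trapezoid rather than plain rectangular summation so the 5 nm
        computation agrees with fine-grid trapezoidal integration to well
        under 0.1% (the endpoint half-weights matter for Z).
        """
        return float(np.trapezoid(values, self.wavelengths))

    @property
    def normalisation(self) -> float:
        """k = 100 / integral(S * ybar), so that Yn = 100."""
        return 100.0 / self.integrate(self.illuminant * self.ybar)

    @property
    def whitepoint(self) -> tuple[float, float, float]:
        k = self.normalisation
        xn = k * self.integrate(self.illuminant * self.xbar)
        zn = k * self.integrate(self.illuminant * self.zbar)
        return (xn, 100.0, zn)

    def matches(self, spec: Spectrum) -> bool:
        return spec.wavelengths.size == self.wavelengths.size and np.allclose(
            spec.wavelengths, self.wavelengths
        )


@lru_cache(maxsize=1)
def default_grid() -> ObserverIlluminant:
    """CIE 1964 10-degree observer with D65, 5 nm over 400-780 nm."""
    path = resources.files("copigment.data") / "cie1964_10deg_d65_5nm.csv"
    raw = np.loadtxt(str(path), delimiter=",", skiprows=4)
    return ObserverIlluminant(
        wavelengths=raw[:, 0],
        xbar=raw[:, 1],
        ybar=raw[:, 2],
        zbar=raw[:, 3],
        illuminant=raw[:, 4],
    )


@dataclass(frozen=True)
class ColorCoordinates:
    """A520 plus tristimulus and CIELAB quantities for one spectrum.

    ``hab`` is the signed hue angle in degrees, in (-180, 180]; it is NaN
    (the undefined marker) for achromatic points with C*ab = 0.
    """

    a520: float
    X: float
    Y: float
    Z: float
    L: float
    a: float
    b: float
    C: float
    hab: float
    flags: frozenset = frozenset()

    _BY_NAME = {"A520": "a520", "L*": "L", "a*": "a", "b*": "b",
                "hab": "hab", "C*ab": "C"}

    def parameter(self, name: str) -> float:
        """Value of one of the six color parameters by canonical name."""
        try:
            return getattr(self, self._BY_NAME[name])
        except KeyError:
            raise KeyError(
                f"unknown color parameter {name!r}; expected one of "
                f"{sorted(self._BY_NAME)}"
            ) from None


#: Canonical order of the six color parameters reported by the pipeline.
COLOR_PARAMETERS = ("A520", "L*", "a*", "b*", "hab", "C*ab")


def resample_to_grid(spec: Spectrum, grid: ObserverIlluminant) -> Spectrum:
    """Linearly interpolate a spectrum onto the observer grid.

    Metadata and flags are preserved.  Raises :class:`CoverageError` if the
    spectrum does not cover the grid's span, naming the missing region.
    """
    lo, hi = grid.wavelengths[0], grid.wavelengths[-1]
    if not spec.covers(lo, hi):
        missing = []
        if spec.wavelengths[0] > lo:
            missing.append(f"[{lo:g}, {spec.wavelengths[0]:g}] nm")
        if spec.wavelengths[-1] < hi:
            missing.append(f"[{spec.wavelengths[-1]:g}, {hi:g}] nm")
        raise CoverageError(
            f"spectrum {spec.sample_id!r} does not cover the grid span: "
            f"missing {' and '.join(missing)}"
        )
    values = np.interp(grid.wavelengths, spec.wavelengths, spec.absorbance)
    return replace(spec, wavelengths=grid.wavelengths.copy(), absorbance=values)


def absorbance_to_transmittance(a):
    """Beer-Lambert link T = 10**(-A).

    Accepts scalars or arrays.  Negative absorbance yields T > 1 and is
    legal (blank-subtraction artifacts); callers flag it.  Non-finite
    input raises.
    """
    arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("absorbance must be finite")
    t = np.power(10.0, -arr)
    return float(t) if np.isscalar(a) or arr.ndim == 0 else t


def tristimulus(spec: Spectrum, grid: ObserverIlluminant) -> tuple[float, float, float]:
    """CIE XYZ of a spectrum already resampled onto the observer grid.

    X = k * integral(T * S * xbar) with k = 100 / integral(S * ybar),
    both by trapezoidal quadrature on the fixed 5 nm grid.
    """
    if not grid.matches(spec):
        raise GridMismatchError(
            f"spectrum {spec.sample_id!r} is not on the observer grid; "
            f"call resample_to_grid first"
        )
    t = absorbance_to_transmittance(spec.absorbance)
    k = grid.normalisation
    x = k * grid.integrate(t * grid.illuminant * grid.xbar)
    y = k * grid.integrate(t * grid.illuminant * grid.ybar)
    z = k * grid.integrate(t * grid.illuminant * grid.zbar)
    return (x, y, z)


_DELTA = 6.0 / 29.0  # CIE L*a*b* linear/cube-root breakpoint


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t * (841.0 / 108.0) + 4.0 / 29.0)


def xyz_to_lab(
    x: float, y: float, z: float, whitepoint: tuple[float, float, float]
) -> tuple[float, float, float]:
    """CIE 1976 L*a*b* from tristimulus values and a positive whitepoint."""
    xn, yn, zn = whitepoint
    if min(xn, yn, zn) <= 0:
        raise ValueError("whitepoint must be positive")
    fx, fy, fz = _lab_f(np.array([x / xn, y / yn, z / zn]))
    lstar = 116.0 * fy - 16.0
    astar = 500.0 * (fx - fy)
    bstar = 200.0 * (fy - fz)
    return (float(lstar), float(astar), float(bstar))


def chroma_hue(a: float, b: float) -> tuple[float, float]:
    """Chroma C*ab and signed hue angle hab in degrees, in (-180, 180].

    Returns hab = NaN for the degenerate achromatic case C*ab = 0; the NaN
    is the explicit "undefined hue" marker, never a fabricated angle.
    """
    c = math.hypot(a, b)
    if c == 0.0:
        return (0.0, math.nan)
    h = math.degrees(math.atan2(b, a))
    if h <= -180.0:  # atan2 returns (-180, 180]; keep that convention exactly
        h += 360.0
    return (c, h)


def a520(spec: Spectrum) -> float:
    """Absorbance at 520 nm: exact if sampled, else linear interpolation."""
    if not spec.covers(520.0, 520.0):
        raise CoverageError(
            f"spectrum {spec.sample_id!r} does not cover 520 nm "
            f"(range [{spec.wavelengths[0]:g}, {spec.wavelengths[-1]:g}])"
        )
    return float(np.interp(520.0, spec.wavelengths, spec.absorbance))


def spectrum_color(
    spec: Spectrum, grid: Optional[ObserverIlluminant] = None
) -> ColorCoordinates:
    """Full color readout of one spectrum: A520, XYZ, CIELAB, chroma, hue.

    A520 is read off the native sampling of the input spectrum; the CIELAB
    quantities are computed after resampling to the observer grid.
    """
    if grid is None:
        grid = default_grid()
    flags = set(spec.flags)
    value520 = a520(spec)
    on_grid = spec if grid.matches(spec) else resample_to_grid(spec, grid)
    if np.any(on_grid.absorbance < 0):
        flags.add("negative_absorbance")
    x, y, z = tristimulus(on_grid, grid)
    lstar, astar, bstar = xyz_to_lab(x, y, z, grid.whitepoint)
    c, h = chroma_hue(astar, bstar)
    if math.isnan(h):
        flags.add("undefined_hue")
    return ColorCoordinates(
        a520=value520, X=x, Y=y, Z=z, L=lstar, a=astar, b=bstar, C=c, hab=h,
        flags=frozenset(flags),
    )
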