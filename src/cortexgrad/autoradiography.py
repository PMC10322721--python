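"""Densitometry mathematics for quantitative receptor autoradiography.

Tritiated-ligand binding in tissue sections is quantified from 8-bit
film images: co-exposed standards of known radioactivity are converted
to binding-site concentrations, a monotone calibration curve maps gray
value to concentration, images are linearized pixel-wise, laminar
density profiles are extracted across the cortical ribbon, and per-area
means with coefficient-of-variation QC summarize sections and subjects.

A standard with radioactivity ``R`` (counts/min) and protein weight
``W_b`` (mg) corresponds to a binding-site concentration

    C_b = R / (E * B * W_b * S_a) * (K_D + L) / L    [fmol / mg protein]

where ``E`` is the scintillation-counter efficiency, ``B`` the decays
per unit time and radioactivity, ``S_a`` the ligand's specific activity
(Ci/mmol), ``K_D`` its dissociation constant and ``L`` the free ligand
concentration during incubation (both nM).  The saturation term
``(K_D + L)/L`` scales bound sites up to total sites.

Total binding is treated as equivalent to specific binding (non-specific
binding of the ligands used is a few percent of total); an optional
subtract-nonspecific mode is available on :func:`linearize_image` inputs
by subtracting a blank image beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .exceptions import DataError, ParameterError

__all__ = [
    "LigandParams",
    "Standard",
    "CalibrationCurve",
    "LaminarProfile",
    "standard_concentration",
    "fit_calibration_curve",
    "linearize_image",
    "laminar_profile",
    "area_mean_density",
    "cohort_cov_summary",
]


@dataclass(frozen=True)
class LigandParams:
    """Ligand and counter constants entering the standard conversion."""

    E: float  # scintillation counter efficiency, fraction
    B: float  # decays per unit time and radioactivity, Ci min^-1
    S_a: float  # specific activity, Ci mmol^-1
    K_D: float  # dissociation constant, nM
    L: float  # incubation ligand concentration, nM

    def __post_init__(self) -> None:
        for name in ("E", "B", "S_a", "K_D", "L"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"LigandParams.{name} must be strictly positive")
        if self.E > 1:
            raise ParameterError("counter efficiency E cannot exceed 1")


@dataclass(frozen=True)
class Standard:
    """One co-exposed standard: radioactivity, protein weight, gray value."""

    R: float  # counts min^-1
    W_b: float  # mg protein
    gray: float  # 8-bit gray value

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ParameterError("standard radioactivity R must be >= 0")
        if self.W_b <= 0:
            raise ParameterError("standard protein weight W_b must be > 0")
        if not (0 <= self.gray <= 255):
            raise ParameterError("gray value must lie in [0, 255]")


def standard_concentration(R: float, W_b: float, p: LigandParams) -> float:
    """Binding-site concentration of a standard, fmol per mg protein."""
    if R < 0:
        raise ParameterError("R must be >= 0")
    return R / (p.E * p.B * W_b * p.S_a) * (p.K_D + p.L) / p.L


@dataclass
class CalibrationCurve:
    """Monotone gray-value -> concentration interpolant through standards.

    A monotone piecewise-cubic (PCHIP) through the (gray, C_b) knots:
    exact at every standard, no oscillation between knots — standard
    practice for a film response curve.  Gray values outside the knot
    range clamp to the nearest knot's concentration with a warning
    (film saturates; extrapolation would be unphysical).
    """

    gray_knots: np.ndarray
    cb_knots: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gray_knots, dtype=float)
        c = np.asarray(self.cb_knots, dtype=float)
        order = np.argsort(g)
        g, c = g[order], c[order]
        dg = np.diff(g)
        if (dg == 0).any():
            raise DataError("duplicate gray values among standards")
        dc = np.diff(c)
        if not ((dc > 0).all() or (dc < 0).all()):
            trend = np.sign(np.median(dc)) or 1.0
            bad = np.nonzero(np.sign(dc) != trend)[0]
            i = int(bad[0]) if bad.size else 0
            raise DataError(
                f"standards not jointly monotone: gray {g[i]:.6g}->{g[i + 1]:.6g} "
                f"maps to C_b {c[i]:.6g}->{c[i + 1]:.6g}")
        object.__setattr__(self, "gray_knots", g)
        object.__setattr__(self, "cb_knots", c)
        self._interp = PchipInterpolator(g, c, extrapolate=False)

    @property
    def gray_range(self) -> tuple[float, float]:
        return float(self.gray_knots[0]), float(self.gray_knots[-1])

    def __call__(self, gray) -> np.ndarray:
        gray = np.asarray(gray, dtype=float)
        lo, hi = self.gray_range
        clipped = np.clip(gray, lo, hi)
        n_out = int((gray < lo).sum() + (gray > hi).sum())
        if n_out:
            warnings.warn(
                f"{n_out} gray value(s) outside calibration range [{lo:g}, {hi:g}] "
                "clamped to nearest knot", stacklevel=2)
        return self._interp(clipped)


def fit_calibration_curve(standards: list[Standard], p: LigandParams) -> CalibrationCurve:
    """Fit the calibration curve from co-exposed standards.

    Needs at least 4 standards with distinct gray values; (gray, C_b)
    must be jointly monotone after sorting by gray.
    """
    if len(standards) < 4:
        raise DataError("need at least 4 standards to fit a calibration curve")
    gray = np.array([s.gray for s in standards], dtype=float)
    cb = np.array([standard_concentration(s.R, s.W_b, p) for s in standards])
    return CalibrationCurve(gray, cb)


def linearize_image(gray_image: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Convert an 8-bit gray image to a concentration image, pixel-wise."""
    img = np.asarray(gray_image, dtype=float)
    return curve(img)


@dataclass(frozen=True)
class LaminarProfile:
    """Mean receptor density per cortical-depth bin (0% = pial surface)."""

    depth_percent: np.ndarray  # bin centers, percent of pial-to-white depth
    density: np.ndarray  # fmol mg^-1 protein per bin
    n_columns: int

    def mean_density(self) -> float:
        """Depth-averaged density of this profile."""
        return float(np.mean(self.density))


def laminar_profile(conc_image: np.ndarray, pial_row: int, wm_row: int,
                    columns, n_bins: int = 10) -> LaminarProfile:
    """Extract a laminar density profile from a rectified cortical patch.

    The patch is assumed rectified: rows run from the pial surface
    (``pial_row``, inclusive) to the white-matter boundary (``wm_row``,
    exclusive) and the requested columns run tangentially.  Each depth
    bin is the mean concentration over its row band and those columns;
    depth is expressed as percent of the pial-to-white distance.
    """
    if pial_row >= wm_row:
        raise ParameterError("pial_row must precede wm_row")
    if n_bins < 5:
        raise ParameterError("n_bins must be >= 5")
    img = np.asarray(conc_image, dtype=float)
    cols = np.atleast_1d(np.arange(img.shape[1])[columns])
    if cols.size == 0:
        raise ParameterError("empty column range")
    band = img[pial_row:wm_row][:, cols]
    row_means = band.mean(axis=1)
    chunks = np.array_split(row_means, n_bins)
    density = np.array([c.mean() for c in chunks])
    centers = (np.arange(n_bins) + 0.5) / n_bins * 100.0
    return LaminarProfile(depth_percent=centers, density=density, n_columns=cols.size)


def area_mean_density(profiles: list[LaminarProfile]) -> tuple[float, float]:
    """Area mean density and across-section CoV from 3-5 section profiles.

    The area mean is the mean over sections of each profile's
    depth-averaged density; CoV = sample SD (n-1) / mean.  Outside the
    3-5 section range a warning is issued and the computation proceeds;
    with one section the CoV is reported as NaN.
    """
    if not profiles:
        raise ParameterError("no profiles supplied")
    n = len(profiles)
    if not (3 <= n <= 5):
        warnings.warn(f"{n} sections supplied; 3-5 expected", stacklevel=2)
    means = np.array([p.mean_density() for p in profiles])
    area_mean = float(means.mean())
    if area_mean == 0:
        raise DataError("zero mean density; CoV undefined")
    cov = float(means.std(ddof=1) / area_mean) if n >= 2 else float("nan")
    return area_mean, cov


def cohort_cov_summary(replicates: list) -> tuple[float, int]:
    """Median coefficient of variation over area x receptor cells.

    ``replicates`` is a list of same-shaped areas x receptors DataFrames
    (one per section or subject).  For each cell with >= 2 finite
    replicate values, CoV = sample SD / mean; the median over all such
    cells is returned along with the number of cells skipped as missing.
    """
    if len(replicates) < 2:
        raise DataError("need at least 2 replicates for a CoV summary")
    stack = np.stack([np.asarray(r, dtype=float) for r in replicates])
    finite = np.isfinite(stack)
    n_ok = finite.sum(axis=0)
    valid = n_ok >= 2
    n_skipped = int((~valid).sum())
    if not valid.any():
        raise DataError("all cells missing; cannot summarize CoV")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        masked = np.where(finite, stack, np.nan)
        mean = np.nanmean(masked, axis=0)
        sd = np.nanstd(masked, axis=0, ddof=1)
    cov = np.where(valid & (mean != 0), sd / mean, np.nan)
    return float(np.nanmedian(cov)), n_skipped
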