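"""Seeded generators for emission spectra and hyperspectral cubes.

Real autofluorescence data for the band-optimization problem consists of two
smooth, overlapping emission profiles — one blue-shifted relative to the
other — measured on a uniform wavelength grid, plus hyperspectral image
cubes in which distinct regions carry distinct spectra.  This module
produces such data from Gaussian mixture models with seeded noise, so every
pipeline stage is testable end to end without measured input.

The default two-class model mimics live-cell autofluorescence dominated by
an NAD(P)H-like emission near 470 nm and a weaker FAD-like emission near
540 nm, with one class blue-shifted by 15 nm relative to the other.  It is a
test fixture with qualitatively realistic structure, not a photophysical
model of any particular cell line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .spectra import PMFSpectrum, Spectrum, normalize_pmf
from .imaging import HyperspectralCube


@dataclass(frozen=True)
class FluorophoreModel:
    """Sum-of-Gaussians emission model.

    ``peaks`` is a list of (center_nm, sigma_nm, weight) triples; widths are
    Gaussian standard deviations.
    """

    peaks: tuple[tuple[float, float, float], ...]
    name: str = "synthetic"

    def __post_init__(self) -> None:
        for center, width, weight in self.peaks:
            if width <= 0 or weight <= 0:
                raise InputError("peak widths and weights must be positive")

    def shifted(self, shift_nm: float) -> "FluorophoreModel":
        """Same model with every peak center moved by ``shift_nm``."""
        return FluorophoreModel(
            peaks=tuple((c + shift_nm, w, a) for c, w, a in self.peaks),
            name=f"{self.name}{shift_nm:+g}nm",
        )

    def profile(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        out = np.zeros_like(grid)
        for center, width, weight in self.peaks:
            out += weight * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return out


#: default cell-like emission: strong NAD(P)H-like peak + weaker FAD-like peak
DEFAULT_MODEL = FluorophoreModel(
    peaks=((470.0, 35.0, 0.7), (540.0, 45.0, 0.3)),
    name="cell-like",
)

#: default blue-shift of the "abnormal" class relative to the "normal" one
DEFAULT_SHIFT_NM = 15.0


def default_grid(lo_nm: float = 425.0, hi_nm: float = 650.0,
                 step_nm: float = 1.0) -> np.ndarray:
    """Uniform wavelength grid over the standard 425-650 nm detection range."""
    n = int(round((hi_nm - lo_nm) / step_nm)) + 1
    return lo_nm + step_nm * np.arange(n)


def gaussian_spectrum(
    model: FluorophoreModel,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Spectrum:
    """Evaluate a Gaussian-mixture model on a grid with seeded additive noise.

    Noise is Gaussian with standard deviation ``noise_sd`` (in the same
    arbitrary units as the unit-peak profile) and the result is clipped at
    zero.  Output is bit-reproducible for a fixed seed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 350.0 or grid[-1] > 750.0:
        raise InputError("grid must lie within 350-750 nm")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    values = model.profile(grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        values = values + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(values, 0.0, None))


def two_class_pair(
    shift_nm: float = DEFAULT_SHIFT_NM,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: FluorophoreModel = DEFAULT_MODEL,
) -> tuple[Spectrum, Spectrum]:
    """Two spectra from one peak model, class A blue-shifted by ``shift_nm``.

    Class B is the base model; class A has every peak center moved by
    ``-shift_nm`` (a positive shift makes A bluer, the structure expected
    when comparing abnormal to normal specimens).  Independent noise streams
    are drawn from one seeded generator.
    """
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    spec_a = gaussian_spectrum(model.shifted(-shift_nm), grid, noise_sd, rng)
    spec_b = gaussian_spectrum(model, grid, noise_sd, rng)
    return spec_a, spec_b


def synth_cube(
    shape: tuple[int, int],
    regions: np.ndarray,
    spectra: dict[int, PMFSpectrum],
    counts_scale: float | np.ndarray = 1000.0,
    seed: int = 0,
    pixel_size_um: float = 1.0,
) -> HyperspectralCube:
    """Hyperspectral cube with per-region spectra and shot-like noise.

    Each pixel's spectral vector is ``counts_scale`` times its region label's
    PMF, plus Gaussian noise with variance proportional to the signal (a
    cheap, seedable stand-in for photon shot noise), clipped at zero.  With
    ``counts_scale`` interpreted as a mean photon count, larger values give
    higher signal-to-noise, as for longer pixel dwell times.

    Parameters
    ----------
    shape
        (rows, cols) of the cube.
    regions
        Integer label mask of that shape; every label must have a spectrum.
    spectra
        Mapping from region label to a PMF spectrum; all on one grid.
    counts_scale
        Mean total photon count per pixel, either one scalar or a positive
        per-pixel brightness map of the cube's spatial shape (real specimens
        vary in brightness independently of their emission shape).
    """
    regions = np.asarray(regions)
    if regions.shape != tuple(shape):
        raise InputError("region mask shape does not match the cube shape")
    counts_scale = np.asarray(counts_scale, dtype=float)
    if counts_scale.ndim not in (0, 2):
        raise InputError("counts_scale must be a scalar or a 2-D brightness map")
    if counts_scale.ndim == 2 and counts_scale.shape != tuple(shape):
        raise InputError("brightness map shape does not match the cube shape")
    if np.any(counts_scale <= 0):
        raise InputError("counts_scale must be positive")
    labels = np.unique(regions)
    missing = [int(lb) for lb in labels if int(lb) not in spectra]
    if missing:
        raise InputError(f"no spectrum supplied for region label(s) {missing}")
    grids = [spectra[int(lb)].wavelengths_nm for lb in labels]
    for g in grids[1:]:
        if g.size != grids[0].size or not np.allclose(g, grids[0]):
            raise InputError("all region spectra must share one grid")
    wl = grids[0]

    rng = np.random.default_rng(seed)
    data = np.empty((*shape, wl.size), dtype=float)
    for lb in labels:
        mask = regions == lb
        data[mask] = spectra[int(lb)].pmf
    if counts_scale.ndim == 2:
        data *= counts_scale[:, :, None]
    else:
        data *= counts_scale
    # shot-like noise: Gaussian with variance equal to the mean signal
    noise = rng.normal(0.0, 1.0, size=data.shape) * np.sqrt(data)
    data = np.clip(data + noise, 0.0, None)
    return HyperspectralCube(data, wl, pixel_size_um=pixel_size_um)


def two_region_mask(shape: tuple[int, int]) -> np.ndarray:
    """Label mask splitting an image into a left (0) and right (1) half."""
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=int)
    mask[:, cols // 2:] = 1
    return mask


def expected_ratio(
    pmf: PMFSpectrum, band_red, band_cyan
) -> float:
    """Analytic ratiometric value red/(red+cyan) for a noise-free region."""
    from .bands import band_power

    red = band_power(pmf, band_red)
    cyan = band_power(pmf, band_cyan)
    return red / (red + cyan)
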