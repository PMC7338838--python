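"""Representation and preprocessing of 1-D fluorescence emission spectra.

A raw measurement is a :class:`Spectrum` (wavelength grid in nm plus
intensities in arbitrary units).  The band-pair optimizer consumes
:class:`PMFSpectrum` objects: spectra resampled onto a uniform grid and
normalized to unit sum, so that the power falling into a spectral band is a
probability.  The standard preprocessing chain is::

    read_spectrum -> subtract_baseline -> smooth_sliding_window
        -> crop_range -> resample_uniform -> normalize_pmf

Replicate spectra of one specimen group are combined with
:func:`mean_spectrum` before optimization.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    GridError,
    InputError,
    NormalizationError,
    RangeError,
    SpectrumParseError,
)

logger = logging.getLogger(__name__)

_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class Spectrum:
    """A 1-D emission spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres, length >= 2.
    intensities
        Intensities in arbitrary units, same length as the grid.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise InputError("spectrum arrays must be one-dimensional")
        if wl.size != it.size:
            raise InputError(
                f"wavelength/intensity length mismatch: {wl.size} vs {it.size}"
            )
        if wl.size < 2:
            raise InputError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise InputError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class PMFSpectrum:
    """A spectrum on a uniform grid, normalized to unit sum (a discrete PMF).

    Band powers computed from a PMF spectrum are dimensionless fractions of
    the total collected signal, which makes them comparable across specimens
    regardless of absolute brightness.
    """

    wavelengths_nm: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        p = np.asarray(self.pmf, dtype=float)
        if wl.size != p.size or wl.size < 2:
            raise InputError("PMF spectrum needs matching arrays of length >= 2")
        steps = np.diff(wl)
        if not np.all(steps > 0):
            raise InputError("wavelengths must be strictly increasing")
        if np.ptp(steps) > _GRID_ATOL:
            raise GridError("PMF spectrum grid must be uniform")
        if np.any(p < 0):
            raise InputError("PMF weights must be non-negative")
        total = p.sum()
        if not math.isclose(total, 1.0, rel_tol=0.0, abs_tol=1e-9):
            raise NormalizationError(f"PMF must sum to 1, got {total!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "pmf", p)

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def __len__(self) -> int:
        return self.wavelengths_nm.size


def same_grid(a: PMFSpectrum | Spectrum, b: PMFSpectrum | Spectrum) -> bool:
    """True when two spectra share one wavelength grid (within 1e-9 nm)."""
    return a.wavelengths_nm.size == b.wavelengths_nm.size and bool(
        np.allclose(a.wavelengths_nm, b.wavelengths_nm, rtol=0.0, atol=_GRID_ATOL)
    )


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(path: str | Path, *, wavelength_col: int = 0,
                  intensity_col: int = 1) -> Spectrum:
    """Read a spectrum from delimited text (CSV/TSV/whitespace).

    The first line may be a header; it is skipped when it does not parse as
    numbers.  Rows are sorted by wavelength and duplicate wavelengths are
    averaged (spectrometers often re-read a pixel).

    Raises
    ------
    SpectrumParseError
        If a non-header row fails to parse; the message names the line.
    InputError
        If fewer than two distinct wavelengths remain.
    """
    text = Path(path).read_text()
    return parse_spectrum_text(
        text, wavelength_col=wavelength_col, intensity_col=intensity_col,
        name=str(path),
    )


def parse_spectrum_text(text: str, *, wavelength_col: int = 0,
                        intensity_col: int = 1, name: str = "<text>") -> Spectrum:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"{name}: empty spectrum file")
    try:
        dialect = csv.Sniffer().sniff(lines[0], delimiters=",;\t ")
        delim = dialect.delimiter
    except csv.Error:
        delim = ","
    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = next(csv.reader(io.StringIO(line), delimiter=delim))
        fields = [f for f in fields if f.strip()]
        try:
            wl = float(fields[wavelength_col])
            it = float(fields[intensity_col])
        except (ValueError, IndexError):
            if lineno == 1:  # header line
                continue
            raise SpectrumParseError(
                f"{name}: line {lineno} is not numeric: {line!r}"
            ) from None
        rows.append((wl, it))
    if len(rows) < 2:
        raise InputError(f"{name}: need at least 2 data points, got {len(rows)}")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # average duplicate wavelengths
    uniq, inverse, counts = np.unique(
        arr[:, 0], return_inverse=True, return_counts=True
    )
    sums = np.zeros_like(uniq)
    np.add.at(sums, inverse, arr[:, 1])
    if uniq.size < 2:
        raise InputError(f"{name}: need at least 2 distinct wavelengths")
    return Spectrum(uniq, sums / counts)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV with a ``wavelength_nm,intensity`` header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "intensity"])
        for wl, it in zip(s.wavelengths_nm, s.intensities):
            writer.writerow([repr(float(wl)), repr(float(it))])


# ---------------------------------------------------------------------------
# Preprocessing


def subtract_baseline(s: Spectrum, mode: str = "constant-min",
                      dark: Spectrum | None = None) -> Spectrum:
    """Remove a background baseline and clip negatives at zero.

    ``constant-min`` subtracts the spectrum's own minimum (flat dark floor);
    ``dark-reference`` subtracts a dark measurement on the identical grid.
    """
    if mode == "constant-min":
        baseline = float(s.intensities.min())
        out = s.intensities - baseline
    elif mode == "dark-reference":
        if dark is None:
            raise InputError("dark-reference mode requires a dark spectrum")
        if not same_grid(s, dark):
            raise GridError("dark reference is not on the spectrum's grid")
        out = s.intensities - dark.intensities
    else:
        raise InputError(f"unknown baseline mode {mode!r}")
    return Spectrum(s.wavelengths_nm, np.clip(out, 0.0, None))


def smooth_sliding_window(s: Spectrum, window_nm: float = 10.0) -> Spectrum:
    """Boxcar-smooth a spectrum with a sliding window of given width in nm.

    The window is converted to the smallest odd sample count spanning at
    least ``window_nm``; at the spectrum edges the window truncates to the
    available samples, so a constant spectrum is a fixed point.
    """
    if window_nm <= 0:
        raise InputError("window_nm must be positive")
    steps = np.diff(s.wavelengths_nm)
    step = float(steps.min())
    if window_nm < step:
        logger.warning(
            "smoothing window %.3g nm is below the grid step %.3g nm; no-op",
            window_nm, step,
        )
        return s
    # n samples span (n - 1) * step nm; round up to odd
    n = int(math.ceil(window_nm / step)) + 1
    if n % 2 == 0:
        n += 1
    kernel = np.ones(n)
    sums = np.convolve(s.intensities, kernel, mode="same")
    counts = np.convolve(np.ones(len(s)), kernel, mode="same")
    return Spectrum(s.wavelengths_nm, sums / counts)


def crop_range(s: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Keep only samples with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
    if lo_nm >= hi_nm:
        raise InputError(f"invalid crop range [{lo_nm}, {hi_nm}]")
    mask = (s.wavelengths_nm >= lo_nm) & (s.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise RangeError(
            f"crop range [{lo_nm}, {hi_nm}] nm selects no samples from "
            f"[{s.wavelengths_nm[0]}, {s.wavelengths_nm[-1]}] nm"
        )
    if mask.sum() == 1:
        # Spectrum requires >= 2 points; surface the single-point selection
        # as arrays rather than failing construction.
        idx = int(np.flatnonzero(mask)[0])
        return _SinglePointSelection(s.wavelengths_nm[idx], s.intensities[idx])
    return Spectrum(s.wavelengths_nm[mask], s.intensities[mask])


@dataclass(frozen=True)
class _SinglePointSelection:
    """Degenerate one-sample crop result (cannot be a full Spectrum)."""

    wavelength_nm: float
    intensity: float


def resample_uniform(s: Spectrum, step_nm: float = 1.0) -> Spectrum:
    """Linearly interpolate onto a uniform grid inside the spectrum support.

    The grid runs from ``ceil(min wavelength)`` to ``floor(max wavelength)``
    in steps of ``step_nm``; no extrapolation is performed.
    """
    if step_nm <= 0:
        raise InputError("step_nm must be positive")
    lo = math.ceil(s.wavelengths_nm[0])
    hi = math.floor(s.wavelengths_nm[-1])
    if hi - lo < step_nm:
        raise InputError(
            f"step {step_nm} nm exceeds the spectral span [{lo}, {hi}] nm"
        )
    n = int(math.floor((hi - lo) / step_nm)) + 1
    grid = lo + step_nm * np.arange(n)
    values = np.interp(grid, s.wavelengths_nm, s.intensities)
    return Spectrum(grid, values)


def normalize_pmf(s: Spectrum) -> PMFSpectrum:
    """Normalize a uniform-grid spectrum to unit sum (PMF normalization)."""
    total = float(s.intensities.sum())
    if total <= 0:
        raise NormalizationError("cannot PMF-normalize an all-zero spectrum")
    pmf = s.intensities / total
    # guard against accumulated rounding
    pmf = pmf / pmf.sum()
    return PMFSpectrum(s.wavelengths_nm, pmf)


def mean_spectrum(group: Sequence[PMFSpectrum]) -> PMFSpectrum:
    """Pointwise mean of replicate PMF spectra, renormalized to unit sum."""
    if not group:
        raise InputError("mean_spectrum needs a non-empty group")
    first = group[0]
    for other in group[1:]:
        if not same_grid(first, other):
            raise GridError("all spectra in a group must share one grid")
    mean = np.mean([g.pmf for g in group], axis=0)
    return PMFSpectrum(first.wavelengths_nm, mean / mean.sum())


def preprocess(
    s: Spectrum,
    *,
    window_nm: float = 10.0,
    range_lo_nm: float = 425.0,
    range_hi_nm: float = 650.0,
    baseline_mode: str = "constant-min",
    dark: Spectrum | None = None,
    step_nm: float = 1.0,
) -> PMFSpectrum:
    """Full preprocessing chain from a raw measurement to a PMF spectrum.

    Defaults follow the standard workflow for two-photon autofluorescence:
    background subtraction, 10-nm boxcar smoothing matching a 10-nm
    spectrometer slit resolution, cropping to the 425-650 nm range where the
    detection response is linear and the excitation line is excluded, then
    resampling to a uniform 1-nm grid and PMF normalization.
    """
    s = subtract_baseline(s, mode=baseline_mode, dark=dark)
    s = smooth_sliding_window(s, window_nm=window_nm)
    s = crop_range(s, range_lo_nm, range_hi_nm)
    if isinstance(s, _SinglePointSelection):
        raise RangeError("preprocessing crop left a single sample")
    s = resample_uniform(s, step_nm=step_nm)
    return normalize_pmf(s)
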