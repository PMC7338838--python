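"""Hyperspectral cubes to two-channel composites, ratio images and SNR.

A :class:`HyperspectralCube` carries a full emission spectrum per pixel.
Integrating the cube over a spectral band produces a :class:`ChannelImage`,
the idealized image a detector behind a perfect band-pass filter would
record.  Two channel images are combined into a cyan/red false-color
composite for display, or into a ratiometric image ``red / (red + cyan)``
(the redox-ratio convention when the red band captures flavin-like emission
and the cyan band captures NAD(P)H-like emission).

Image quality is quantified in the spatial-frequency domain: the 2-D power
spectrum is split at a cutoff proportional to the system's resolution limit,
with power below the cutoff counted as signal and power above it as noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bands import Band
from .errors import BandError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperspectralCube:
    """(row, col, wavelength) intensity cube with its wavelength axis.

    Parameters
    ----------
    data
        Non-negative intensities, shape (rows, cols, n_wavelengths).
    wavelengths_nm
        Increasing wavelength per spectral plane.
    pixel_size_um
        Physical pixel pitch in micrometres.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if data.ndim != 3:
            raise InputError("cube data must be 3-D (row, col, wavelength)")
        if wl.ndim != 1 or wl.size != data.shape[2]:
            raise InputError(
                f"wavelength axis length {wl.size} does not match the cube's "
                f"third dimension {data.shape[2]}"
            )
        if not np.all(np.diff(wl) > 0):
            raise InputError("cube wavelengths must be strictly increasing")
        if np.any(data < 0):
            raise InputError("cube intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "wavelengths_nm", wl)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass(frozen=True)
class ChannelImage:
    """Per-pixel band-integrated intensity image and the band that made it."""

    data: np.ndarray
    band: Band

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InputError("channel image must be 2-D")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class SNRReport:
    """Frequency-domain SNR of an image.

    ``snr`` is the ratio of total spectral power at radial frequencies in
    (0, cutoff] (signal) to power above the cutoff (noise), DC excluded from
    both.  ``infinite`` flags an empty noise band.
    """

    snr: float
    cutoff_cycles_per_um: float
    resolution_um: float
    signal_power: float
    noise_power: float
    infinite: bool = False


def two_photon_resolution_um(
    excitation_um: float = 0.785, numerical_aperture: float = 0.8
) -> float:
    """Lateral two-photon resolution estimate r = lambda_exc / (2 NA), in um."""
    return excitation_um / (2.0 * numerical_aperture)


# ---------------------------------------------------------------------------
# cube I/O


def read_cube(
    tiff_path: str | Path, wavelengths_csv: str | Path, pixel_size_um: float = 1.0
) -> HyperspectralCube:
    """Load a cube from a multi-page TIFF plus a wavelength sidecar CSV.

    The TIFF holds one page per wavelength (page order = row order of the
    sidecar).  The sidecar is a single-column CSV of wavelengths in nm, with
    an optional header line.
    """
    import tifffile

    stack = tifffile.imread(str(tiff_path))
    if stack.ndim == 2:
        stack = stack[None]
    wl = _read_wavelength_column(wavelengths_csv)
    data = np.moveaxis(np.asarray(stack, dtype=float), 0, -1)
    return HyperspectralCube(data, wl, pixel_size_um=pixel_size_um)


def write_cube(cube: HyperspectralCube, tiff_path: str | Path,
               wavelengths_csv: str | Path) -> None:
    """Write a cube as a multi-page TIFF plus a wavelength sidecar CSV."""
    import tifffile

    stack = np.moveaxis(cube.data, -1, 0).astype(np.float32)
    tifffile.imwrite(str(tiff_path), stack)
    with open(wavelengths_csv, "w") as fh:
        fh.write("wavelength_nm\n")
        for wl in cube.wavelengths_nm:
            fh.write(f"{float(wl)!r}\n")


def _read_wavelength_column(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    values = []
    for i, ln in enumerate(lines):
        token = ln.split(",")[0]
        try:
            values.append(float(token))
        except ValueError:
            if i == 0:
                continue
            raise InputError(f"{path}: line {i + 1} is not a wavelength: {ln!r}")
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# channelization


def integrate_band(cube: HyperspectralCube, b: Band) -> ChannelImage:
    """Sum the cube's spectral planes with band.start <= wavelength <= end."""
    wl = cube.wavelengths_nm
    if b.start_nm > wl[-1] or b.end_nm < wl[0]:
        raise BandError(
            f"band [{b.start_nm}, {b.end_nm}] nm outside cube range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    mask = (wl >= b.start_nm) & (wl <= b.end_nm)
    if not mask.any():
        raise BandError(
            f"band [{b.start_nm}, {b.end_nm}] nm contains no spectral plane"
        )
    return ChannelImage(cube.data[:, :, mask].sum(axis=2), b)


def _scale_channel(img: np.ndarray) -> np.ndarray:
    """Map mean-2*sigma -> 0 and mean+5*sigma -> 1, clipping to [0, 1]."""
    mean = img.mean()
    sd = img.std()
    if sd == 0:
        warnings.warn("zero-variance channel; rendering as flat 0.5", stacklevel=3)
        return np.full_like(img, 0.5)
    return np.clip((img - (mean - 2.0 * sd)) / (7.0 * sd), 0.0, 1.0)


def two_channel_composite(cyan: ChannelImage, red: ChannelImage) -> np.ndarray:
    """Cyan/red false-color composite with histogram-relative scaling.

    Each channel is linearly mapped so that its mean - 2 sigma renders as 0
    and its mean + 5 sigma as 1 (values beyond are clipped).  The cyan
    channel feeds green and blue, the red channel feeds red; output is an
    (rows, cols, 3) float RGB image in [0, 1].
    """
    if cyan.data.shape != red.data.shape:
        raise InputError("channel shapes differ")
    c = _scale_channel(cyan.data)
    r = _scale_channel(red.data)
    return np.stack([r, c, c], axis=-1)


def ratiometric_image(red: ChannelImage, cyan: ChannelImage) -> np.ndarray:
    """Per-pixel red / (red + cyan); NaN where both channels are zero.

    Undefined pixels (zero total intensity) are returned as NaN and must be
    excluded from downstream statistics.
    """
    if red.data.shape != cyan.data.shape:
        raise InputError("channel shapes differ")
    total = red.data + cyan.data
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, red.data / np.where(total > 0, total, 1.0), np.nan)
    return ratio


def bin2x2(img: np.ndarray) -> np.ndarray:
    """Average non-overlapping 2x2 blocks; trailing odd row/column dropped."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise InputError("bin2x2 needs a 2-D image of at least 2x2 pixels")
    rows = img.shape[0] // 2 * 2
    cols = img.shape[1] // 2 * 2
    trimmed = img[:rows, :cols]
    return trimmed.reshape(rows // 2, 2, cols // 2, 2).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# frequency-domain SNR


def fft_snr(
    img: np.ndarray,
    resolution_um: float,
    pixel_size_um: float,
    cutoff_factor: float = 4.0,
) -> SNRReport:
    """Frequency-domain SNR: low-frequency power over high-frequency power.

    The 2-D FFT power spectrum is integrated over two radial-frequency
    regions split at ``f_c = cutoff_factor / resolution_um`` (by default four
    times the resolution-limit frequency 1/r): power at 0 < f <= f_c counts
    as signal, power at f > f_c as noise.  The DC term is excluded from both
    integrals, so the result is invariant to constant offsets.  NaN pixels
    (e.g. undefined ratio pixels) are replaced by the image mean before the
    transform.

    Raises
    ------
    InputError
        For an all-zero or constant image (no structure to measure).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise InputError("fft_snr needs a 2-D image")
    if pixel_size_um <= 0 or resolution_um <= 0:
        raise InputError("pixel size and resolution must be positive")
    finite = np.isfinite(img)
    if not finite.any():
        raise InputError("image has no finite pixels")
    if not finite.all():
        img = np.where(finite, img, img[finite].mean())
    if np.ptp(img) == 0:
        raise InputError("constant image: SNR undefined")

    power = np.abs(np.fft.fft2(img)) ** 2
    fy = np.fft.fftfreq(img.shape[0], d=pixel_size_um)
    fx = np.fft.fftfreq(img.shape[1], d=pixel_size_um)
    radial = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    cutoff = cutoff_factor / resolution_um

    signal_mask = (radial > 0) & (radial <= cutoff)
    noise_mask = radial > cutoff
    signal_power = float(power[signal_mask].sum())
    noise_power = float(power[noise_mask].sum())

    if noise_power == 0.0:
        return SNRReport(
            snr=np.inf,
            cutoff_cycles_per_um=cutoff,
            resolution_um=resolution_um,
            signal_power=signal_power,
            noise_power=0.0,
            infinite=True,
        )
    return SNRReport(
        snr=signal_power / noise_power,
        cutoff_cycles_per_um=cutoff,
        resolution_um=resolution_um,
        signal_power=signal_power,
        noise_power=noise_power,
        infinite=False,
    )
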