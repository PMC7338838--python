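"""Group-level statistics: spectral center of gravity, variability, T-ratio.

These summarize how reliably two specimen groups (e.g. cancerous vs. normal
cell cultures) can be told apart: the center of gravity quantifies the
blue-shift of one group's emission relative to the other, the relative
variability compares within-group spread of that quantity to the
between-group shift, and the T-ratio is a two-sample t-statistic on
per-image redox-ratio means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ZeroVarianceError
from .spectra import PMFSpectrum


@dataclass(frozen=True)
class GroupSummary:
    """Per-image redox means of one specimen group with their summary.

    Standard deviation is the sample (n-1) form; ``sd`` is 0.0 for n = 1.
    """

    values: np.ndarray
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InputError("a group needs at least one value")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(values=arr, mean=float(arr.mean()), sd=sd, n=int(arr.size))


def center_of_gravity(s: PMFSpectrum) -> float:
    """Intensity-weighted mean emission wavelength, sum(lambda * pmf), in nm."""
    return float(np.dot(s.wavelengths_nm, s.pmf))


def relative_variability(
    group_a: Sequence[PMFSpectrum], group_b: Sequence[PMFSpectrum]
) -> tuple[float, float]:
    """Within-group center-of-gravity spread over the between-group shift.

    For each group, the sample standard deviation of the replicate spectra's
    centers of gravity is divided by the absolute difference of the two
    groups' mean centers of gravity; both results are returned as fractions
    (0.12 means the within-group scatter is 12% of the spectral shift that
    distinguishes the groups).

    Raises
    ------
    InputError
        If either group has fewer than two spectra.
    ZeroVarianceError
        If the two group mean centers of gravity coincide (no shift to
        normalize by).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InputError("relative variability needs >= 2 spectra per group")
    cogs_a = np.array([center_of_gravity(s) for s in group_a])
    cogs_b = np.array([center_of_gravity(s) for s in group_b])
    shift = abs(cogs_a.mean() - cogs_b.mean())
    if shift == 0:
        raise ZeroVarianceError(
            "group mean centers of gravity coincide; relative variability "
            "is undefined"
        )
    return (
        float(cogs_a.std(ddof=1) / shift),
        float(cogs_b.std(ddof=1) / shift),
    )


def redox_per_image(ratio_img: np.ndarray) -> float:
    """Mean of the defined (non-NaN) pixels of a ratiometric image."""
    ratio_img = np.asarray(ratio_img, dtype=float)
    defined = np.isfinite(ratio_img)
    if not defined.any():
        raise InputError("ratiometric image has no defined pixels")
    return float(ratio_img[defined].mean())


def t_ratio(a: GroupSummary, b: GroupSummary, pooled: bool = False) -> float:
    """Two-sample t-statistic on per-image redox means, as a magnitude.

    By default the Welch (unequal-variance) form is used:

        |mean_a - mean_b| / sqrt(sd_a^2 / n_a + sd_b^2 / n_b)

    With ``pooled=True`` the classical equal-variance Student form is used
    instead.  Larger values mean the two groups separate more reliably;
    shrinking either group's spread (at fixed means) strictly increases the
    ratio.

    Raises
    ------
    InputError
        If either group has fewer than two images.
    ZeroVarianceError
        If both standard deviations are zero and the means coincide.
    """
    if a.n < 2 or b.n < 2:
        raise InputError("t_ratio needs n >= 2 per group")
    diff = abs(a.mean - b.mean)
    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            raise ZeroVarianceError(
                "zero variance and equal means: T-ratio undefined"
            )
        return math.inf
    if pooled:
        pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = math.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    else:
        se = math.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
    return diff / se
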