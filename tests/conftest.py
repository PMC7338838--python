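import numpy as np
import pytest

from bandopt.spectra import PMFSpectrum


@pytest.fixture
def hand_spectra() -> tuple[PMFSpectrum, PMFSpectrum]:
    """5-bin hand-checkable PMF pair: s1 decreasing, s2 its mirror image."""
    wl = np.arange(500.0, 541.0, 10.0)
    s1 = PMFSpectrum(wl, [0.4, 0.3, 0.2, 0.1, 0.0])
    s2 = PMFSpectrum(wl, [0.0, 0.1, 0.2, 0.3, 0.4])
    return s1, s2


@pytest.fixture
def random_pmf_factory():
    """Factory for random PMF spectra on the standard 425-650 nm 1-nm grid."""
    grid = 425.0 + np.arange(226.0)

    def make(rng: np.random.Generator, n_points: int | None = None) -> PMFSpectrum:
        g = grid if n_points is None else np.linspace(425.0, 650.0, n_points)
        vals = rng.uniform(size=g.size)
        return PMFSpectrum(g, vals / vals.sum())

    return make


def brute_force_band_power(pmf: PMFSpectrum, start_nm: float, end_nm: float) -> float:
    """Independent oracle: direct per-node summation of PMF mass in a band."""
    total = 0.0
    for wl, p in zip(pmf.wavelengths_nm, pmf.pmf):
        if start_nm <= wl <= end_nm:
            total += p
    return total


def brute_force_pair_count(n_nodes: int, min_width_steps: int = 0) -> int:
    """Independent oracle: count quadruples i <= j < k <= l with widths."""
    count = 0
    for i in range(n_nodes):
        for j in range(i, n_nodes):
            if j - i < min_width_steps:
                continue
            for k in range(j + 1, n_nodes):
                for l in range(k, n_nodes):
                    if l - k < min_width_steps:
                        continue
                    count += 1
    return count


def brute_force_front_mask(eff: np.ndarray, sep: np.ndarray) -> np.ndarray:
    """O(n^2) dominance oracle: True where no other point has eff >= and sep >."""
    n = eff.size
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        dominated = (eff >= eff[i]) & (sep > sep[i])
        if dominated.any():
            mask[i] = False
    return mask
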