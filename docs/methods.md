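# Methods

## Model and assumptions

`bandopt` treats a two-channel detection setup as two ideal top-hat band-pass
filters: a band transmits every wavelength inside its closed interval with
unit efficiency and nothing outside.  Spectra are discretized on a uniform
wavelength grid and normalized to unit sum ("PMF normalization"), so the
power a band collects from a spectrum is the sum of PMF weights at the grid
nodes inside the band — a probability.  All metrics are therefore invariant
to the absolute brightness of either specimen, which is the point: the method
ranks filter sets by spectral *shape* contrast, not by intensity.

For spectra S₁, S₂ and a band pair (b₁, b₂) with b₁.end < b₂.start:

* within-spectrum band ratio: ratioᵢ = Pᵢ(b₁) / Pᵢ(b₂);
* separation: r = ratio₁ / ratio₂, reported as max(r, 1/r) with a `swapped`
  flag when the inverse branch is taken (r < 1 only means the channels
  separate the spectra with their roles exchanged);
* relative signal collection efficiency: the geometric mean
  (P₁(b₁)·P₁(b₂)·P₂(b₁)·P₂(b₂))^¼.  The geometric mean penalizes any single
  weak band, and is bounded by 0.5, attained exactly when each band collects
  half of each spectrum.

Separation ≥ 1 always; separation = 1 iff the two spectra distribute power
across the two bands in the same proportion.  Both metrics are symmetric
under exchanging the spectra and under exchanging the band roles (only the
swap flag flips).

## Enumeration and numerics

Band edges live on a lattice (default 5 nm step over the working grid; 1 nm
is available but multiplies the pair count by ~625).  All quadruples
i ≤ j < k ≤ l of lattice nodes are enumerated — closed intervals, inclusive
endpoint sums, strict non-overlap — giving C(N+2, 4) pairs for an N-node
lattice (35 for N = 5, 194,580 for the 46-node default).  Band powers are
differences of prefix sums; the prefix sums are accumulated in extended
precision and rounded to float64 so each power equals the exactly rounded
direct sum of its PMF slice.  The scalar path uses `math.fsum` and the same
operation order, so the fast path and per-pair summation agree to well below
1e-9 even on high-separation pairs where ulp errors in a small band power
would be amplified by the ratio of ratios.

Pairs in which any of the four band powers is ≤ 1e-12 are excluded and
counted rather than scored: the ratios divide by band powers, and a band
sitting on an empty stretch of a spectrum (e.g. a flavin-like spectrum has
essentially no emission below ~470 nm) would otherwise produce unbounded,
meaningless separations.  The exclusion count is surfaced on the result.

Ties are resolved deterministically everywhere: equal separation prefers
higher efficiency, remaining ties the lexicographically smallest band edges.
Result tables are ordered by the four edges, so identical inputs give
byte-identical CSV output.

A band partially outside the working grid is clamped to the overlap (a
physical filter wider than the investigated range still only collects what
the range holds); a band with no overlap raises an error.

## Pareto front and efficiency matching

The "maximal achievable separation" envelope is the strict dominance front:
a pair is kept iff no other pair has efficiency ≥ its efficiency and strictly
larger separation.  `match_at_efficiency` scores a user-supplied reference
pair on the fly, collects all evaluated pairs within a relative efficiency
tolerance (default 0.1 %), and returns the best-separating one together with
the separation gain over the reference.  The reference itself is always a
candidate, so the reported gain is ≥ 1; for an off-lattice reference that
beats every lattice pair, the reference is returned with gain 1.

## Preprocessing

The standard chain mirrors common spectrometer practice: background
subtraction (own-minimum constant or a dark reference on the same grid,
clipped at zero), boxcar smoothing with a 10 nm default window (matching a
10 nm slit resolution; the window is the smallest odd sample count spanning
the requested width, truncated at the spectrum edges so a constant spectrum
is a fixed point), cropping to 425–650 nm (inclusive endpoints), linear
resampling to a uniform 1 nm grid without extrapolation, and PMF
normalization.  Replicate spectra are combined as the renormalized pointwise
mean of their PMFs.  Duplicate wavelengths in input files are averaged
(spectrometer re-reads).  The boxcar kernel is the plainest reading of a
"sliding window"; no claim is made that it matches any specific vendor
software's background or temperature-offset compensation.

## Imaging pipeline

Channel images integrate the cube over a band (inclusive wavelength
endpoints).  Composites scale each channel linearly from mean−2σ (→ 0) to
mean+5σ (→ 1), clipped; a zero-variance channel renders flat 0.5 with a
warning.  The ratiometric image is red/(red+cyan) per pixel with NaN where
the denominator is zero; NaNs are excluded from all downstream statistics.
2×2 binning averages non-overlapping blocks and drops a trailing odd
row/column.

The frequency-domain SNR splits the 2-D FFT power spectrum at a radial
cutoff f_c = 4/r where r is the theoretical resolution: power at 0 < f ≤ f_c
is signal, power above is noise, and the SNR is the ratio of the two sums
with the DC term excluded from both (hence invariance to constant offsets).
"Four times the resolution" is dimensionally ambiguous; this package reads it
as four times the resolution-limit frequency 1/r, and both the cutoff factor
and r are explicit, reported parameters, so the alternative reading
f_c = 1/(4r) is one argument away.  The default resolution is the two-photon
lateral estimate λ_exc/(2·NA) with λ_exc = 0.785 µm and NA = 0.8, both
overridable.  An empty noise band (cutoff at or above Nyquist) is reported as
an infinite-SNR flag rather than an error.  Radial integration is a plain sum
over power-spectrum pixels per region, without windowing or annular binning;
these conventions are recorded in the report object.

## Statistics

The spectral center of gravity is Σ λ·pmf(λ).  Relative variability of two
specimen groups is defined here as the sample standard deviation of
within-group centers of gravity divided by the absolute difference of the
group mean centers of gravity — a fraction answering "how large is the
within-group scatter compared to the shift that distinguishes the groups".
This is a substitute definition chosen for transparency; published variants
of such variability measures differ in detail, so values should not be
compared across implementations.

The T-ratio on per-image (or per-pixel) redox means defaults to the Welch
unequal-variance form |m_a − m_b| / √(s_a²/n_a + s_b²/n_b); the
pooled-variance Student form is available behind a flag.  Sample (n−1)
standard deviations are used throughout.  The ratio is symmetric, invariant
to common shifts and scalings, and strictly increases when either group's
spread shrinks at fixed means — the sense in which better bands "separate"
groups more reliably.

## Synthetic data

The generator produces what the optimizer assumes real data looks like:
smooth overlapping emission profiles on a uniform grid.  The default
two-class model is a Gaussian mixture with a strong NAD(P)H-like peak
(470 nm, σ 35 nm, weight 0.7) and a weaker FAD-like peak (540 nm, σ 45 nm,
weight 0.3); class A is the same model blue-shifted 15 nm, the direction and
rough magnitude of the shift reported between abnormal and normal epithelial
cells.  Peak widths are Gaussian standard deviations.  These defaults are a
qualitative fixture, not a photophysical model of any cell line.

Hyperspectral cubes assign each pixel its region label's PMF times a mean
photon count (`counts_scale`, scalar or a per-pixel brightness map — real
specimens vary in brightness independently of emission shape), plus
shot-like noise approximated as Gaussian with variance equal to the mean
signal, clipped at zero.  The Gaussian approximation to Poisson noise is
adequate at the default count scale (≥ ~100 photons/pixel) and keeps the
generator cheap and seedable; at very low counts the clipping bias would
matter and the generator should not be trusted there.  All generators are
bit-reproducible for a fixed seed.

What passing tests on synthetic data do and do not show: they verify the
algebra, bounds, determinism and end-to-end plumbing of the pipeline, and
the direction of the efficiency-vs-contrast trade-off under shot noise.
They do not show that any particular band pair is optimal for real
specimens, whose spectra include additional fluorophores, instrument
response, scattering and biological variability absent from the generator.

## Problem sizes and defaults

The default sweep (5 nm lattice, 425–650 nm, 1 nm grid) evaluates 194,580
pairs in ~20 ms after the lattice geometry is cached.  Test and demo cubes
are 32×32 pixels with 46 spectral planes; the statistical direction checks
use 3–8 replicate cubes at 200 mean counts/pixel.  These sizes were chosen
as the smallest that exercise every code path with stable statistics.

## Known limitations

* Two detection channels only; no multi-channel extension.
* Ideal top-hat filters; no real filter catalog matching, no detector
  quantum-efficiency weighting.
* Emission-side optimization only; excitation wavelength is out of scope.
* The SNR conventions (radial sum, no windowing) are documented but not
  claimed identical to any published implementation.
* Mosaic stitching is out of scope; the imaging pipeline consumes single
  (or pre-stitched) cubes.
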