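# bandopt

Optimal band-pass filter pair selection for two-channel fluorescence
detection, with the surrounding ratiometric-imaging pipeline.

## The problem

Multiphoton and fluorescence microscopes routinely split emitted light into
two detection channels with band-pass filters — for example an NAD(P)H-like
channel around 410–490 nm and an FAD-like channel around 510–650 nm, whose
ratio is a metabolic (redox) index.  When the emission spectra of the two
specimen classes to be distinguished overlap, the choice of filter bands is a
trade-off: narrow bands that avoid the overlap give high contrast but collect
few photons; wide bands collect many photons but mix the signals.  `bandopt`
quantifies this trade-off exhaustively, so the filter set for a diagnostic or
research instrument can be chosen deliberately instead of heuristically.

## The method

Both input spectra are normalized to unit sum over the investigated
wavelength range (PMF normalization), so the power a band collects is a
probability.  For a candidate pair of non-overlapping bands
(b₁ blue of b₂) and spectra S₁, S₂ with band powers Pᵢ(b):

* **separation** — the ratio of within-spectrum band ratios,

      r = (P₁(b₁)/P₁(b₂)) / (P₂(b₁)/P₂(b₂)),   separation = max(r, 1/r) ≥ 1,

  which scales the contrast a two-channel system can achieve between the two
  spectra (the inverse branch just means the channel roles are swapped);

* **relative signal collection efficiency** — the geometric mean of the four
  band powers,

      efficiency = (P₁(b₁)·P₁(b₂)·P₂(b₁)·P₂(b₂))^(1/4) ∈ (0, 0.5],

  a proxy for the achievable SNR, maximal (0.5) when each band collects half
  of each spectrum.

Every pair of bands with edges on a wavelength lattice (default 5 nm over
425–650 nm, ≈2·10⁵ pairs) is scored with a prefix-sum fast path; the Pareto
front of separation over efficiency is the menu of rational filter choices,
and `match_at_efficiency` finds the best-separating pair at the efficiency of
a given reference filter set (within 0.1 % relative tolerance by default).

The package also channelizes hyperspectral image cubes into band-integrated
images, builds cyan/red composites (histogram-scaled to mean−2σ … mean+5σ)
and ratiometric images red/(red+cyan), estimates image SNR in the spatial
frequency domain (power below vs. above a cutoff at four times the
resolution-limit frequency), and summarizes group differences with a Welch
T-ratio on redox values.  A seeded synthetic module generates two-class
Gaussian emission spectra and hyperspectral cubes with shot-like noise so the
whole pipeline is testable without measured data.

## Worked example

Generate a synthetic two-class spectrum pair (class A blue-shifted 15 nm,
light noise) and sweep all band pairs, comparing against the literature
410–490 / 510–650 nm filter set (clamped to the 425–650 nm working range):

```sh
$ bandopt synth spectra --seed 1 --shift 15 --noise-sd 0.01 \
    --out-a class_a.csv --out-b class_b.csv
wrote class_a.csv and class_b.csv

$ bandopt optimize --spectrum-a class_a.csv --spectrum-b class_b.csv \
    --reference 425:490,510:650 --plot scatter.png
evaluated 163185 band pairs (0 excluded for zero power); front holds 84 pairs
reference 425:490,510:650: separation 1.421, efficiency 0.4179
matched pair 425:460,465:600: separation 1.54, efficiency 0.4181, gain 1.084x
```

Reading the output: the conventional filter set separates these two spectra
by a factor 1.421 while collecting an efficiency-0.418 share of the signal;
at the *same* collection efficiency, the bands 425–460 nm and 465–600 nm
separate them by 1.54 — an 8.4 % contrast gain for free.  `pairs.csv` holds
every evaluated pair, `front.csv` the maximal-achievable-separation
envelope, and `scatter.png` the efficiency-vs-separation scatter with the
front and both setups marked.

The imaging pipeline runs the same bands over a hyperspectral cube:

```sh
$ bandopt synth cube --seed 1 --shape 32:32 --out-prefix cube
$ bandopt image --cube cube.tif --wavelengths cube_wavelengths.csv \
    --band1 425:490 --band2 510:650 --out-prefix run1
mean redox ratio: 0.390267

$ bandopt snr --image run1_ratio.tif --pixel-size 1.0 --resolution 16.0
{ "snr": 10.181630146821231, "cutoff_cycles_per_um": 0.25, ... }
```

The mean redox ratio is the average of red/(red+cyan) over defined pixels;
the SNR is the ratio of image power below to above the frequency cutoff.

Everything is also available as a library — see `bandopt.optimize`,
`bandopt.pareto_front`, `bandopt.match_at_efficiency` and the
`bandopt.imaging` / `bandopt.stats` / `bandopt.synthetic` modules.

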