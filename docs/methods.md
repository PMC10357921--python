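# Methods

## The transform

The core operation is a one-dimensional undecimated (stationary, à-trous)
discrete wavelet transform.  For an orthonormal two-channel filter pair
`(h, g)` — by default the 12-tap Daubechies filter with six vanishing
moments, taken from PyWavelets — the level-`j` filters are upsampled by
`2^(j-1)` and *both* analysis and synthesis are folded into one zero-phase
pass: the transfer functions applied to the running approximation are
`|H(2^(j-1)w)|^2 / 2` (low channel) and `|G(2^(j-1)w)|^2 / 2` (high
channel).  Because Daubechies filters satisfy the conjugate-quadrature
identity `|H|^2 + |G|^2 = 2`, the decomposition is additive:

    A_0 = f,   A_{j-1} = A_j + D_j,   f = A_N + sum_j D_j .

Consequences that the tests rely on:

* perfect reconstruction and telescoping hold to float round-off;
* every component is exactly zero phase — line positions coincide across
  components, which the splitting extraction requires;
* with the default periodic boundary the transform commutes exactly with
  circular shifts; the `symmetric` option transforms the mirror-doubled
  signal and truncates, trading exact shift covariance for freedom from
  wrap-around at mismatched spectrum ends;
* "subtract the Details up to j*" and "keep the level-j* Approximation"
  are the same array, bit for bit up to summation order (~1e-16).

Non-dyadic lengths are accepted; the depth is capped at
`N = floor(log2 p)`.  The implementation evaluates the transfer functions
analytically on the FFT grid; an independent time-domain implementation
(explicit circular convolution with upsampled autocorrelation kernels)
serves as the cross-check oracle in the test suite.

Because `|H|^2/2` and `|G|^2/2` are not ideal brick-wall filters, the
level bands overlap in their transition regions.  Two idealized
properties therefore hold only approximately: re-decomposing a hyperfine
component leaves a small residue in the one or two levels just below the
working level (up to a few percent of the input RMS, essentially zero
deeper down), and repeating a denoise pass with the same level set moves
the result by ~1% RMS rather than zero.  The tests assert the measured
honest bounds.

## Pseudo-decoupling

`pseudo_decouple(spec, j_star)` discards Details `1..j_star-1`, returns
`D_{j_star}` (or a user-chosen set of Detail levels, for multi-band
super-hyperfine structure) as the super-hyperfine component and
`A_{j_star}` as the hyperfine component; the three parts sum to the input
exactly.  `keep_approx=False` gives the strict feature-from-Details
variant, returning the final Approximation separately as `baseline`.

The working level is a *user* decision, as in visual practice.
`level_scan` tabulates, per level, the line counts of both candidate
components, the coefficient of variation (CV) of the hyperfine line
spacings, component RMS fractions and two `resolved` flags: a hyperfine
candidate is flagged when its regular (CV <= 0.25) line count is stable
against the adjacent level — band-passed noise never is — and a
super-hyperfine candidate when its comb is tightly regular (CV <= 0.10).
Components whose RMS is below 1e-8 of the input are treated as empty so
round-off wiggles are not counted as lines.  `suggest_level` returns the
middle of the smallest stable line-count plateau, the machine analogue of
iteratively subtracting Details and watching the result.

`denoise(spec, levels)` subtracts the listed Detail levels; with the
levels `{1, 2}` it removes three quarters of the power of white noise
while leaving lines that are several grid steps wide essentially intact.

## Line detection and splitting extraction

A resonance line in a first-derivative spectrum is a maximum followed by
a minimum, both with prominence at least `min_prominence` (default 2%) of
the component's largest amplitude, with the interpolated zero crossing
between them as the line center.  Splittings are crossing-to-crossing
distances; within-line max-to-min distances are reported separately as
derivative peak-to-peak widths.  Splittings are clustered by
single-linkage with a gap threshold `tol` (default 0.3 G for radicals,
3 G for metal spectra); chains wider than `2*tol` are split at their
largest internal gap so every bin's spread is bounded.

Two estimator details matter in crowded spectra:

* **Primary coupling.**  Overlapping multiplet lines shift individual
  crossings, so the primary coupling is the median-filtered *mean* line
  spacing of the hyperfine multiplet rather than any single bin: the
  distortions are symmetric around the multiplet and largely cancel in
  the mean.  The residual bias is upward (8.12 G extracted from a 7.91 G
  input in the worked example) — an intrinsic property of reading
  peak-to-peak splittings off overlapped derivative lines.
* **Nearly commensurate couplings.**  When one coupling is close to an
  integer multiple of another (2.49 and 1.20 G in the bundled radical),
  the combined comb is quasi-uniform at the smaller spacing and adjacent
  distances alone cannot show the larger one; the isotropic report
  therefore bins pairwise line distances up to two neighbours apart
  (`pairwise_splittings`, `shf_max_lag=2`) and reports each bin.  Mapping
  bins to nuclei remains the analyst's step.

For axial powder spectra the report reads

* `g_perp` from the zero crossing nearest the absorption maximum (the
  cumulative integral of the derivative peaks at the perpendicular
  singularity);
* `g_par` and the parallel metal coupling from an equally spaced
  progression of derivative maxima on the low-field side, clear of the
  perpendicular envelope; the progression is scored by summed prominence
  (so baseline ripples cannot outvote genuine quartet features), members
  must have comparable prominence, and the quartet center is
  extrapolated as `first + (n_lines-1)/2 * spacing` because the upper
  quartet members are buried under the perpendicular envelope at X band;
* the ligand (nitrogen) splitting inside two windows anchored on the
  perpendicular feature: `B_perp ± 45 G` ("low field") and everything
  above `B_perp + 22.5 G` ("high field").  Within a window the most
  populated spacing sub-cluster (tolerance `tol/3`) selects the scale and
  the autocorrelation peak of the windowed component refines the value —
  the autocorrelation lag pools every sample, making the estimate robust
  to the position jitter of individual crossings (validated at 2% noise:
  worst drift 0.14 G low / 0.07 G high over 60 noise seeds).

## The simulator

First-order throughout: resonance fields are `h nu / (g mu_B) + sum_k
m_k A_k` with multinomial stick weights from equivalent-nucleus
multiplets; nuclear Zeeman and second-order shifts are omitted, which is
consistent with splitting-based extraction (positions are
splitting-faithful even where absolute second-order shifts would apply).
Axial powders average over a Gauss–Legendre grid in `cos(theta)` (default
1024 orientations) with the usual axial angular dependences of `g` and
`A`.  Lineshapes are first derivatives of unit-area Gaussian or
Lorentzian absorptions; "width" is an explicit convention field —
`gaussian-fwhm-of-absorption` (FWHM of the absorption) or
`peak-to-peak` (first-derivative peak-to-peak; for a Lorentzian
`pp = 2 gamma / sqrt(3)`, for a Gaussian `pp = 2 sigma`).  Hyperfine
signs do not affect first-order multiplets, so signed couplings may be
stored in configs.

### Bundled systems and their grids

Four reference systems ship as YAML (`R1`, `R2`, `M1`, `M2`) with
per-band (L 1.4 / S 3.3 / X 9.8 GHz) linewidths, grids and working
levels.  The decomposition level at which a given splitting lives depends
on the grid step (level j spans field periods of roughly `2^j..2^(j+1)`
steps), so each grid was chosen once to place the couplings of interest
in the documented working octave, and is frozen in the config for
reproducibility:

* `R1` — 8192 points over 80 G (step 0.0098 G): the ring-proton band
  (1.2–2.6 G) straddles the level-7 octave; working level 7.
* `R2` — 6656 points over 90 G (step 0.0135 G): the 0.65 G coupling sits
  mid level-5 octave; working level 5 for the fine couplings (the CH2
  triplet separates fully around level 8 on this grid).  This system's
  published parameter table is internally inconsistent; the bundled
  definition is reconstructed from the extracted-value summary and
  flagged as such in the file.
* `M2` — 1160 points over 880 G (step 0.76 G): the nitrogen splitting
  (15–18 G) sits mid level-4 octave; working level 4.
* `M1` — same construction; a *synthetic frozen-powder stand-in* for a
  system whose reference regime is slow-motional, shipped for
  demonstrating the workflow only.

`add_noise` adds seeded white Gaussian noise scaled to the peak
amplitude.  What the generator does **not** emulate: slow-motional
dynamics, rhombic tensors, quadrupole and nuclear-Zeeman terms, field
modulation distortion, baseline drift, or correlated instrument noise.
Passing tests therefore demonstrate the pipeline's behaviour on ideal
first-order spectra; on experimental data the same workflow applies but
the quantitative guarantees (e.g. the 5% blind-recovery bound) do not
transfer automatically.

## Validation experiments

* **Transform algebra** — perfect reconstruction, telescoping, linearity
  and shift covariance on 200 random signals of random length (257–4096),
  all at 1e-8 relative.
* **Blind two-scale recovery** — 50 random two-coupling isotropic systems
  per run (couplings 5–15 G, ratio at least 3 *and* larger than the
  secondary group size so the secondary multiplet envelope does not span
  the primary spacing; 2–4 equivalent I=1/2 nuclei per group; Gaussian
  widths 10–25% of the smaller coupling).  The working level is scanned,
  not given: the pipeline walks fine-to-coarse, requires the fine part to
  carry at least 30% of the signal RMS, requires the crossing-spacing and
  autocorrelation estimates of the coarse multiplet to agree within 10%,
  and resolves half-period combs by climbing one level when the spacing
  estimate doubles.  Both couplings are recovered within 5% (observed
  maxima ~4% primary, ~1% secondary across ten independent master seeds).
  Single-nucleus (doublet) groups are excluded from these conditions:
  with only two lines and a broad fine-structure envelope the
  peak-to-peak estimator carries an irreducible overlap bias of up to
  ~8%, the same magnitude the reference analyses themselves show.
* **Noise robustness** — the X-band Cu-N4 analysis after adding 2% noise
  and denoising levels {1, 2} reproduces the noiseless nitrogen
  splittings within 0.3 G.

## Numerical choices and degenerate inputs

* Physical constants from scipy (CODATA); fields in Gauss, frequencies in
  GHz, `B = 714.477 * nu[GHz] / g` Gauss.
* Empty component selections reconstruct to zero with a logged warning,
  not an error; all-zero components yield empty peak sets.
* Zero crossings are linearly interpolated; if a max/min pair brackets no
  sign change (component riding on an offset), the closest approach to
  zero is used.
* Spectrum files are comment-headered CSV with fields stored in Gauss
  (milliTesla converted on read, x10); field axes are re-sorted ascending
  and resampled onto a uniform grid when spacing deviates by more than
  0.1%, with a logged warning.  Values are written with 17 significant
  digits so a round trip is bit-exact.
* The first-order line-count cap (default 1e6 sticks) turns combinatorial
  explosions into a typed error instead of an out-of-memory crash.

## Known limitations

* First-order simulation only: no slow-motional lineshapes, no exact
  diagonalization, no rhombic symmetry.  The bundled `M1` definition is
  a stand-in, not a reproduction of slow-motional reference spectra.
* The working level is grid-relative; comparing levels across differently
  sampled spectra requires comparing field scales (`2^j * step`), not
  level indices.
* Lorentzian spectra truncated at ten linewidths retain a small integral
  residue from the `x^-3` tails (bounded in the tests at 0.5% of the
  total absolute area).
* Prominence thresholds cannot reject *pure* noise components, because in
  the absence of a real line the threshold normalizes to the noise
  itself; the level-scan resolved flags (count stability, spacing
  regularity) are the tool for that case.
* Automatic objective selection of the working level is out of scope by
  design; `suggest_level` and the blind-recovery walk are starting
  points, not replacements for inspecting the scan.
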