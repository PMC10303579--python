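# Methods

This note documents the models, conventions and numerical choices behind
`memepr`, and what the synthetic generators do and do not emulate.

## Membrane composition model

The three membrane models are frozen concentration tables (mM):

| species | PM | YDM | ODM |
|---|---|---|---|
| DMPC | 2 | 1 | 1 |
| POPC | 3 | 1.5 | 2.75 |
| (16:0)(22:6)PC | – | 1 | 1 |
| (16:0)(22:6)PE | 0.5 | 2.5 | 2.5 |
| POPE | 0.5 | 1 | 2.25 |
| cholesterol | 4 | 3 | 0.5 |
| n-PC spin label | 0.1 | 0.1 | 0.1 |
| retinoid | 0 (control) or 1 | same | same |

**Denominator convention.** All mole percentages are computed relative to
the structural-lipid pool, PC + PE + sterol (10 mM in every model); the
trace spin label and the retinoid are excluded.  This is the only
convention under which the nominal figures — 40/30/5 mol% cholesterol,
5/35 mol% PUFA, 5:1 and 1:1 PC:PE, 10 mol% retinoid and 1 mol% label —
hold simultaneously.  The PC headgroup of the n-PC label is not counted
toward PC in the PC:PE ratio.  Custom compositions with arbitrary species
are allowed; the presets are constants.

## Synthetic EPR spectra

Field axes are in gauss (the 6.51·10⁻¹⁰ s/G prefactor of the correlation-
time formulas presumes gauss linewidths).  Sweep defaults: center 3350 G,
2048 points, width 120 G (fast/ordered) or 200 G (rigid).  All generators
normalise the peak amplitude to 1 and add Gaussian noise as a fraction of
it; noise is fully determined by the seed.

**Fast isotropic (motional narrowing).** Three first-derivative
Lorentzian lines at center and center ± a_iso (a_iso default 15 G;
mI = +1 at low field).  Peak-to-peak widths follow
ΔH(mI) = A + B·mI + C·mI² with B = −τ₂B/(2·6.51·10⁻¹⁰) and
C = τ₂C/(2·6.51·10⁻¹⁰); A is the prescribed central width.  Because the
derivative of a unit-area Lorentzian has peak-to-peak amplitude ∝ width⁻²,
the amplitude-ratio τ formulas are *exactly* inverted by this generator in
the noise-free limit — the lineshape was chosen for that property; the
physical lineshape of a real spectrometer is not asserted.  Parameter
combinations driving any ΔH(mI) ≤ 0 are rejected.

**Ordered powder (axial).** The target (S, a₀) pair is inverted to
effective splittings through S·a₀/0.5407 = T′∥ − T′⊥ and
T′∥ + 2T′⊥ = 3a₀.  Each mI = ±1 manifold is the powder average of
T(θ) = √(T′∥²cos²θ + T′⊥²sin²θ) over a sinθ-weighted hemisphere
(Gauss–Legendre quadrature in cosθ, default 400 nodes); the mI = 0
manifold is a single central line.  Sticks are deposited on the field grid
with two-bin linear interpolation and convolved with an analytic
derivative-of-Gaussian kernel whose peak-to-peak width is the prescribed
broadening — numerically indistinguishable from a direct kernel sum at
these widths, and fast.

**Rigid limit.** Full powder average of
A(θ,φ) = √(Azz²cos²θ + sin²θ(Axx²cos²φ + Ayy²sin²φ)) over an octant
(symmetry), three mI manifolds, same kernel convolution.  g anisotropy is
ignored by default (X band is splitting-dominated); if a g tensor is
supplied, each orientation is offset by the first-order field shift.

**Noise defaults.** noise_sigma = 0.002 (fast) and 0.005
(ordered/rigid) of the peak amplitude.  These emulate signal-averaged,
deoxygenated cw-EPR acquisitions; the amplitude-ratio τ extraction at
τ = 0.05 ns distinguishes line-height ratios of ~5%, which requires
roughly 0.1% effective amplitude accuracy — attainable in practice by
averaging, and by the smoothing window during extraction here.

**What the generators do not emulate:** field modulation broadening,
cavity background, microwave-power saturation, oxygen broadening,
slow-motion (stochastic-Liouville) lineshapes, or g-strain.  Passing
recovery tests therefore demonstrates the internal consistency of the
generator/extractor pair and the correctness of the formula
implementations, not instrument-level accuracy on real spectra.

## Spectral measurements

Conventions (fixed, since no reference measurement figure is bundled):

* amplitudes are peak-to-peak per hyperfine line; ΔH₀ is the central
  line's peak-to-peak width;
* low-field line = h₊ (mI = +1): with this assignment slower tumbling
  (broader high-field line) yields positive τ;
* 2T′∥ = low-field outer maximum → high-field outer minimum;
  2T′⊥ = inner low-field minimum → inner high-field maximum;
* 2Azz = first maximum → last minimum along the field axis.

Extrema are located with a prominence filter and refined by local
parabolic interpolation (sub-grid positions).  The prominence floor is
max(7 × edge sd, 1.5% of the peak amplitude), where the edge sd is taken
from the first and last 5% of points.  Prominence, not raw amplitude, is
filtered because noise wiggles riding the sloping tails of strong lines
can have large absolute values; the 7-sd scale bounds the worst
prominence a correlated-noise excursion attains over a few thousand
points, and the relative term is safe because the weakest genuine powder
features (outer wings of the broadest patterns in the supported regimes)
stay above ~3% of the dominant line.  Smoothing is a zero-phase moving
average, default off; a window comparable to the broadening is
recommended for noisy traces (it bias-broadens ΔH₀ slightly, which the
ratio-based observables tolerate).

Known bias: the inner (perpendicular) edge of an ordered powder pattern
is an inverse-square-root singularity; under the derivative kernel its
extremum shifts inward by about half the broadening, so 2T′⊥ is
underestimated by ≲1 G at 1 G broadening.  The resulting error in S is
≈ +0.02, well inside the ±0.05 recovery tolerance; the outer step edges
reproduce almost exactly.  A collapsing pattern (small S) is rejected as
unresolved when the apparent splitting difference falls below three times
the central line's peak-to-peak width.

An optional additive polarity correction to 2T′⊥ is available and always
recorded; it defaults to off.

## Observables

S, a₀, Θc, τ₂B, τ₂C and the anisotropy index are closed-form evaluations
of the formulas in the README.  Θc inverts S = cosΘc(1 + cosΘc)/2 through
the positive quadratic root cosΘc = (−1 + √(1 + 8S))/2.  τ values are
stored in seconds and exposed in ns at interfaces.  The anisotropy index
is defined as 0 when both times vanish.

**Polarity calibration.** The mapping 2Azz → ε is monotone
piecewise-linear interpolation over a solvent series.  The shipped
default (apolar hydrocarbon ε 2 at 66.2 G, short-chain alcohol ε 24 at
70.0 G, water ε 78.5 at 72.6 G) is a synthetic stand-in with
doxyl-nitroxide-typical magnitudes; quantitative work must supply a
measured calibration.  Raw 2Azz is always reported alongside ε, and
out-of-range queries clamp to the boundary with a flag.

## Depth profiles and statistics

Label depths are ordered headgroup → 5 → 7 → 10 → 12 → 16 (surface to
center); the depth annotation names the stearoyl-chain carbon, with no
Å conversion attempted.  Replicates are summarised as mean ± sd with n;
sd is undefined (not zero) for a single replicate.

Control vs treated comparisons use Welch's two-sample t-test per depth —
chosen because replicate groups are small (3–4) and variance homogeneity
is unknowable at that size — with tiers `*` p < 0.05 and `**` p < 0.02.
No multiple-testing correction is applied across depths by default,
matching the per-depth starring convention of this kind of analysis; Holm
correction is available behind a switch.  Two identical zero-variance
replicate sets compare as p = 1 (no difference) rather than NaN.
Profile tables carry an orientation note for polarity observables: 2Azz
increases with local polarity, while polarity-profile *plots* are
conventionally drawn with the axis inverted so that upward changes depict
decreasing polarity.

## MD post-processing

**Smol.** For chain carbon n the segmental vector joins carbons n−1 and
n+1; θₙ is its instantaneous angle to the bilayer normal (default z), and
Smol(n) = ½(3⟨cos²θₙ⟩ − 1) averaged over molecules and frames (the cos²
form; an order parameter must evaluate to 1 at θ = 0).  Errors are
standard errors over 7 equal contiguous frame blocks (count configurable;
trailing remainder frames enter the mean but not the block error).  For
an sp² pair (Cᵢ, Cⱼ) the vectors are taken along C(i−1)→Cⱼ and Cᵢ→C(j+1);
for adjacent pairs — the only ones the topology admits — this coincides
algebraically with the plain definition, so the toggle changes which
carbons are flagged in the output rather than the numbers.  Chains are
assumed whole (no minimum-image unwrapping of 2.5 Å segment vectors).

**Hydrogen bonds.** Geometric criteria, defaults donor–acceptor ≤ 3.5 Å
and H–donor–acceptor angle ≤ 30° (configurable; no universal values
exist).  Counting uses a periodic KD-tree neighbour search verified
against an all-pairs reference; minimum-image displacements are applied
whenever a box is present.  Membrane residency: a donor molecule counts
only while its centre of mass lies inside the z-band spanned by the two
phosphate planes ± 5 Å (margin configurable); per-molecule means divide
by the number of resident molecules per frame.

**Synthetic trajectories.** Each interior carbon's orientation is drawn
from a one-parameter family realising a prescribed ⟨cos²θ⟩: |cosθ|
uniform on [a, 1] with a = (−1 + √(12t − 3))/2 for t ≥ 1/3, uniform on
[0, √(3t)] for t < 1/3, random sign and azimuth; t = 1/3 is exactly
isotropic-in-cosθ and t = 1 is degenerate alignment.  Carbon positions
accumulate the sampled vectors along two interleaved sub-chains so the
(n−1, n+1) vectors *are* the sampled orientations — an exact ground truth
for the profile code.  The ensembles are stationary and uncorrelated
between frames; they verify the estimator, not lipid dynamics (no
autocorrelation, no inter-chain packing, no realistic bond geometry).

**File dialects.** Multi-MODEL PDB I/O goes through MDAnalysis; the
GRO-style dialect is a minimal fixed-column reader/writer using Å (not
nm) so round trips hold at 10⁻³ Å.  Frame rosters must be constant;
violations report the frame index.

## Pipeline determinism

A run is driven by one config and one master seed; every stage draws its
seed from a named `SeedSequence` substream recorded in the manifest, so a
rerun of the same config is byte-identical.  The manifest lists every
artifact with its stage and a hash of the config.

## Problem sizes

The verification suites use desk-scale sizes chosen to make sampling
error a small fraction of each tolerance: recovery grids of 5–8 points
per observable, 2048-point spectra, 400 quadrature orientations,
synthetic ensembles of 500 molecules × 200 frames (10⁵ orientation
samples per carbon), 50-seed oracle comparisons and 100-trial
significance experiments.

## Known limitations

* The spectral generators and extractors form a self-consistent pair;
  neither is a calibrated model of a particular spectrometer.
* The ε estimate is only as good as the user's solvent calibration.
* No slow-motion lineshape theory: correlation times are valid in the
  motional-narrowing regime the formulas assume.
* No automatic regime classification: feeding an ordered spectrum to the
  three-line measurement is a caller error the code cannot always detect.
* H-bond counting is geometric only (no energetic criterion).
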