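# Methods

`phasorflim` implements a label-free metabolic FLIM analysis pipeline:
two-channel NAD(P)H / FAD time-correlated single-photon-counting (TCSPC)
decay images are reduced to first-harmonic phasor coordinates, calibrated
against reference solutions, mapped to phase/modulation lifetimes and
fraction-of-bound cofactor maps, segmented into single fibroblasts, and fed
into the condition × timepoint × dose statistics of a UVA1 stress-response
study.  Because no raw tissue data ship with the package, a first-class
synthetic generator reproduces the acquisition geometry and the planted
biology, so every stage is testable end to end.

## Phasor model

Each pixel carries a decay histogram over `n_bins = 24` temporal bins
spanning one laser period `T = 12.48 ns` (bin width `T/24 = 0.52 ns`,
always derived, never stored).  With bin midpoints `t_k` and
`ω = 2π/T` (first harmonic), the phasor is

    g = Σ_k I_k cos(ω t_k) / Σ_k I_k ,   s = Σ_k I_k sin(ω t_k) / Σ_k I_k .

A mono-exponential decay of lifetime τ sits on the universal semicircle at
`g = 1/(1+(ωτ)²)`, `s = ωτ·g`; mixtures are intensity-weighted convex
combinations.  Phase and modulation lifetimes are

    τ_Φ = s / (g ω) ,   τ_M = (1/ω) √(1/(g²+s²) − 1) ,

equal only for mono-exponential decays.  Pixels whose phasor leaves the
physical range (negative or complex intermediates) are flagged NaN rather
than raising.

The fraction of bound cofactor `f_B` is read geometrically from the phasor's
position between the free and bound mono-exponential anchors.  Default
anchors: free NAD(P)H 0.4 ns, free FAD 3 ns (solution measurements), bound
NAD(P)H 3.2 ns and bound FAD 0.15 ns (literature-informed defaults; the
bound species are configurable because tissue values are not uniquely
established).  Quantum-yield differences between free and bound species are
neglected throughout, so `f_B` is an intensity fraction.  Two read-out modes
exist: orthogonal projection onto the free→bound chord (default — scatter
perpendicular to the chord, e.g. photon noise or residual background, does
not inflate `f_B`) and raw Euclidean distance from the free anchor.  Both
clip to [0, 1].

## Calibration

The instrument response (IRF position and width) and the TDC binning enter
the measured first harmonic as one complex factor, so a single reference of
known lifetime — SHG at 0 ns or fluorescein at pH 9 with a 4 ns single
exponential — fixes a rotation `phase_offset` and a radial scaling
`modulation_factor` that map the intensity-weighted mean reference phasor
onto its theoretical location.  The fitted transform then corrects every
lifetime.  `fit_calibration` refuses inhomogeneous references (per-pixel
phasor s.d. above a configurable bound, default 0.1) and degenerate ones
(mean modulation ≈ 0).  Median smoothing of `g` and `s` (3×3, one pass by
default; NaN-aware, intensity untouched) is applied after calibration; it
reduces phasor scatter without degrading the intensity image's spatial
resolution.

## Synthetic decay generator

`periodic_decay_curve` builds the steady-state periodic decay — each species
`exp(−t/τ)` wrapped over the laser period, i.e. scaled by
`1/(1 − e^(−T/τ))` — convolves it circularly with a Gaussian IRF
(`σ = 0.3 ns`, shift `0.5 ns` by default), integrates over the 24 bins, and
mixes species with weights `(1−f_B, f_B)`.  τ = 0 denotes an instantaneous
SHG-like response (without an IRF: all photons in the first bin).

**Phasor-faithful binning.**  Histogramming a periodic signal into 24 bins
folds harmonics beyond the Nyquist limit into the first one by a
lifetime-dependent amount: the raw discrete harmonic of a binned wrapped
exponential is `sinh(u/2)/sinh((u−iθ)/2)` with `u = Δ/τ`, `θ = ωΔ`, whose
ratio to the continuous phasor `1/(1−iωτ)` varies with τ.  A 24-bin
histogram therefore cannot carry the exact continuous decay — but the
pipeline consumes only the zeroth and first harmonics.  The generator
consequently projects the physically binned curve (minimal L2 adjustment,
typically 1e-4 .. 2e-2 per unit-mass curve) onto the set of non-negative
probability vectors whose first discrete harmonic *equals* the continuous
phasor times the IRF factor `exp(iωt₀ − (ωσ)²/2)`.  The projection is a
3-dimensional dual (semismooth Newton on the KKT system) solved to machine
precision.  In return, the quantities the method estimates behave exactly
as in the continuous model: phasor linearity holds, single-reference
calibration corrects all lifetimes, and mixtures lie exactly on the
free–bound chord.  Higher harmonics remain physical.

**Feasibility and the IRF width.**  A non-negative distribution on 24 bins
has first-harmonic modulus at most `cos(π/24) ≈ 0.9914` off the bin phases
(the inradius of the convex hull of the bin phasors).  The default IRF
width σ = 0.3 ns damps the target modulus to `e^(−(ωσ)²/2) ≈ 0.9887`,
below that bound, which makes *every* lifetime ≥ 0 representable at any IRF
shift — including the 0.15 ns bound-FAD anchor.  Narrower IRFs leave a
window of short lifetimes (≈ 0.02–0.24 ns at σ = 0.1) unrepresentable;
the generator detects this and raises with guidance rather than silently
degrading.  Without an IRF, pure decays with τ ≳ 0.19 ns remain exact.

**Scenes and noise.**  Fields default to 320 × 320 px at an assumed
0.5 µm/px (so a ~10 µm keratinocyte spans ~20 px).  The basal layer is
populated with round keratinocytes (diameter 10 ± 1.2 µm), the dermis with
sparse elongated fibroblasts (30 ± 4 µm × 6 µm ellipses, random
orientation), placed by rejection sampling with a 1 px clearance so
instances stay separable under 8-connectivity.  Cell pixels draw a total
photon budget uniformly in 400–1000 (interpreted per cell pixel); the
background is a zero-lifetime collagen SHG/SFG bleed-through at a Poisson
mean of 15 photons.  Photons are distributed over bins multinomially, so
per-pixel bin counts conserve the budget exactly and the empirical phasor
is an unbiased estimate of the curve's harmonic.  Noise-free stacks carry
exact float64 expected counts (required for the 1e-6 phasor identities);
the on-disk container accepts only integer-valued uint16 counts.

## Planted study

The study design mirrors the experimental accounting: arms of 21 control /
12 × 25 J/cm² / 10 × 40 J/cm² / 2 sunscreen-protected samples, three
timepoints (T0, T30min, T2h), two layers, 3 ROIs per layer.  The default
planted effects encode the qualitative stress-response structure: bound
NAD(P)H rises (+0.05) in dermal fibroblasts from 30 min but in basal
keratinocytes only at 2 h; bound FAD falls (−0.05) from 30 min in both
layers, with a keratinocyte dose dependence at 2 h (−0.04 at 25 vs −0.07 at
40 J/cm²); control and sunscreen arms are null.  Between-ROI s.d. 0.02 and
between-cell s.d. 0.03 are generator assumptions — true tissue variances
are not published — chosen so the planted effects are detectable at the
study's replication level.  Effect magnitudes are likewise assumptions, not
measured values.  The truth table (per-ROI for basal, per-cell for dermis)
is drawn first; images are rendered conditional on it, so truth and
rendering agree cell by cell.

## Segmentation

Dermal fibroblasts are segmented from a four-plane multimodal input —
NAD(P)H and FAD intensities plus their τ_Φ maps — each plane clipped at its
0.99 quantile and max-normalized to [0, 1].  The classifier is a compact
encoder-decoder network (two 2×2 pooling stages, two 3×3 convolutions per
level, skip concatenations, two-class softmax head; ~3 × 10⁴ parameters)
implemented directly in numpy (im2col convolutions, hand-derived gradients,
Adam), sized so CPU training on synthetic scenes takes seconds to minutes
and is bit-deterministic for a fixed seed and thread count.  Training uses
class-weighted cross-entropy (foreground ×3) and optional gamma
(γ ∈ [0.5, 2]) / log-contrast (c ∈ [0.5, 2]) augmentation.  Prediction
thresholds the foreground probability at 0.5, labels 8-connected
components, and removes labels below 150 px² (≈ 37 µm², configurable); the
classical fallback (Otsu threshold with an absolute floor on the smoothed
NAD(P)H intensity, morphological opening) shares the identical
postprocessing contract.  Basal keratinocytes are deliberately *not*
single-cell segmented: the basal unit of analysis is the whole-ROI average.

Because the synthetic scenes are high-contrast and lack the
acquisition-to-acquisition contrast drift of real tissue, both segmentation
routes essentially saturate the benchmark (IoU ≈ 0.99), and augmentation
yields parity rather than a measurable win; passing tests therefore
demonstrate the correctness of the pipeline's mechanics, not real-tissue
robustness.

## Statistics

The unit of inference is the basal ROI or the single dermal fibroblast,
never the pixel.  ROI values come from the intensity-weighted mean phasor
of valid pixels (above the 30-photon background threshold), then `f_B`/τ
from the mean phasor — equivalent, for pixels on the chord, to averaging
per-pixel fractions (exact by linearity; off-chord pixels make the two
differ, documented and tested).  Groups are summarized as mean ± s.e.m.
(s.d./√n over units; missing for n = 1).  Contrasts default to the
two-sided Mann–Whitney rank-sum test (robust to the skew of bounded
fractions; Welch's t selectable) with tiers ns / * / ** / *** at
p < 0.05 / 0.01 / 0.001.  `dynamics_report` contrasts each arm's
post-exposure timepoints against the same arm's T0 and reports signed
directions; no multiple-testing correction is applied by default (matching
per-panel reporting), but a Holm mode is provided — and used for the
end-to-end acceptance study, where the 24-panel direction matrix at
uncorrected α = 0.05 would have a ~70 % family-wise false-direction
probability against a zero-false-direction requirement.  The wavelength-
mixing utility returns the virtual two-photon excitation wavelength
`λ_v = 2/(1/λ₁ + 1/λ₂)` (760, 1045 nm → 880 nm).

## Numerical choices and problem sizes

- Moment projection: Newton tolerance 1e-13 on the constraint residual,
  damped line search, explicit infeasibility detection with a 1e-9 margin.
- Median filter: NaN-aware sliding-window median; invalid pixels neither
  contribute to nor receive values.
- Tie-breaks: max-pool argmax takes the first maximum; identical samples in
  the rank-sum test short-circuit to p = 1.
- Degenerate inputs raise informative errors: empty channels, mismatched
  bins/pages, >16-bit counts, coincident anchors, aliasing harmonics
  (h ≥ n_bins/2), datasets smaller than a batch.
- Test/benchmark sizes are scaled to desk hardware as the package's own
  choice: segmentation benchmark 96 × 96 scenes with 3–4 fibroblasts;
  end-to-end study arms {8, 8, 8, 2} × 2 ROIs × 128 px fields (the
  generator's defaults remain the full design); type-I calibration uses
  1000 table-level null replicates.

## Limitations

- The generator's cells are geometric primitives with uniform per-cell
  `f_B`; it does not model subcellular heterogeneity (mitochondrial
  texture, dim nuclei), detector afterpulsing, pile-up, dark counts, a
  melanin channel, or inter-sample contrast drift.  Results on synthetic
  data bound what the pipeline can do under its own assumptions, not
  instrument truth.
- Whether the 400–1000 photon budget is per pixel or per image is ambiguous
  in typical acquisition descriptions; it is treated here as a per-cell-pixel
  budget and exposed as a parameter.
- Only the first harmonic is analyzed; no multi-harmonic unmixing and no
  per-pixel bi-exponential fitting.
- Sample-level clustering (3 ROIs per sample) is not modeled in the
  inference, matching the ROI/cell accounting of the study design it
  mirrors; a mixed-effects treatment is out of scope.
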