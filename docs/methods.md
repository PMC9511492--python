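# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic benchmarks can show.  It is the design rationale for the
package; the README shows how to run it.

## Physical model

The supramolecular subunit (two β-cyclodextrin rings threaded by a
surfactant chain) has C7 point symmetry.  Its molecular-frame
hyperpolarizability tensor β_ijk for the CH₂ asymmetric stretch then has 13
nonzero entries built from 7 nondegenerate amplitudes

    β_zzz; β_xxz = β_yyz; β_xzx = β_yzy; β_zxx = β_zyy;
    β_xzy = −β_yzx; β_zxy = −β_zyx; β_xyz = −β_yxz,

the last three being the chiral (antisymmetric) pairs.  Kleinman symmetry
is not assumed.  A sheet's subunits are carried into the lab frame by an
intrinsic z–y′–z″ Euler rotation with in-plane rotation φ, tilt θ (from
the sheet normal) and twist ψ; the twist is physically arbitrary and is
averaged uniformly over [0, 2π).  With the axial Z field component
neglected (moderate-NA collection), the measurable response reduces to
eight lab-frame susceptibilities χ_IJK with I,J,K ∈ {X, Y}, labelled by
the polarization combinations SSS … PPP (S↔X, P↔Y).

The twist average was carried out symbolically once and the closed forms
frozen into `tensor.grouped_coefficients`.  Writing a = sinφ sinθ,
b = cosφ sinθ, c = cosθ, each χ is a homogeneous cubic in (a, b, c) whose
coefficients are linear in the six grouped amplitudes

    g = (β_zzz, β_xxz, β_xzx, β_zxx, β_xzy+β_zxy, β_xyz−β_zxy).

The seven amplitudes enter only through these six combinations — the
direction β_xzy − β_zxy − β_xyz is annihilated by the twist average — so
the β-dependence of the forward map has rank exactly 6.  A brute-force
oracle (`lab_susceptibilities_quadrature`) that rotates the full
27-element tensor at 720 twist angles and averages agrees with the frozen
forms to ~1e−14 relative error and guards them in the test suite.

### Exact invariances of the forward map

Three invariances, all verified to machine precision, structure the whole
inverse problem:

1. **Half-turn:** (φ+π, −β) produces identical susceptibilities.
2. **Tilt supplement:** (π−θ, β with the chiral components negated)
   produces identical susceptibilities.
3. **Continuous tilt compensation:** the twist-averaged response is a
   transversely isotropic cubic form in the unit direction u of the
   molecular axis.  Restricted to in-plane indices, its three coefficient
   families scale as sin³θ (u⊗u⊗u term), sinθ (δ·u terms) and
   sinθ·cosθ (chiral terms).  Rescaling the families
   (`tensor.tilt_compensated_beta`) therefore absorbs any tilt change
   exactly — simultaneously for every sheet that shares θ and β.

Invariances 1 and 2 are discrete: they are what makes angle-interval
disambiguation necessary, and the solver handles them by reporting the
canonical branch (φ ∈ [0,π), θ ∈ [0, π/2]) together with the degenerate
images as equivalent solutions.

Invariance 3 is more consequential: **the tilt angle is structurally
unidentifiable from in-plane polarization-resolved intensities when the
hyperpolarizability amplitudes are completely unknown.**  Any tilt can be
traded against the ratio of the u³-type, δ·u-type and chiral parts of β.
Tilt information enters only through prior knowledge about β — bounded or
structured amplitude ratios.  Under this package's study conditions
(independent uniform amplitudes, see below) the posterior over tilt given
an observation is broad, and no regressor, however well trained, can beat
that floor: empirically the tilt mean-squared error of the trained network
plateaus near 100–140 deg² in the sub-30° region, orders of magnitude
above the in-plane-rotation error.  The in-plane rotation φ, the coverage
ratio N and the susceptibility signs are *not* affected — they are cleanly
identifiable and are recovered well (benchmarks below).  Practical tilt
determination therefore requires constraining β (e.g. calculated
hyperpolarizability ratios), measuring axial (Z-polarized) components, or
independent structural checks such as the stacking-height and steric
analyses in `geometry`.

## Synthetic data — the study conditions

The generator defines the conditions under which everything is tested:

- **β sampling:** each of the 7 nondegenerate amplitudes independent
  uniform on [−1, 1].  Only ratios matter after normalization.
- **Angles:** φ uniform on [0, 2π), θ uniform on [0, π); ψ never sampled
  (averaged analytically).
- **Two-sheet structure:** sheet 2 shares β and θ, is rotated in plane by
  Δφ = 60° and scaled by a coverage ratio N uniform on [0.2, 5]
  (log-symmetric around 1).
- **Inputs:** the 16 signed susceptibilities (2 sheets × 8 combinations)
  normalized to unit Euclidean norm; N is the only carrier of relative
  scale between sheets.
- **Targets (11 values):** the canonical-branch representative
  [g₁…g₆ (unit norm), φ ∈ [0,π), θ ∈ [0,π/2], N, ind_φ, ind_θ] where the
  indicator slots carry the interval bits of the stored angles.  Because
  the generator stores the canonical branch, the indicators are zero for
  generated rows; they exist so that a decoded solution names its branch
  explicitly.  Storing the *pre*-canonicalization branch instead would add
  targets that are exactly independent of the input (invariances 1–2) —
  a pure-noise loss floor, measured at ~0.023, that stalls training.
- Every row satisfies the round-trip invariant: decoding the 11 targets
  and pushing them through the two-sheet forward model reproduces the
  16 inputs to better than 1e−10 (exactly, in practice).

Hyperspectral cubes emulate the measurement itself: rhombic sheet
footprints on a dark background; per pixel and polarization a constant
baseline plus |χ|²-scaled multiband Voigt profile (homodyne detection);
bands at 2910 cm⁻¹ (CH₂ asymmetric stretch, the analysis band) with
companions at 2860/2930/2960 cm⁻¹ at fixed relative heights 0.30/0.25/0.20;
additive Gaussian noise sized so the 2910 peak height over the sheet
footprint in the reference polarization hits the target per-pixel SNR
(default 56).  Overlapping sheets add in intensity.  The generator does
not model optical point-spread functions, detector nonlinearity,
non-resonant background interference, or wavenumber-dependent β — so
passing tests demonstrate the analysis chain, not robustness to every
instrumental artifact.

## Inverse solver

A multilayer perceptron (200–100–50 hidden units, tanh activations,
linear 11-wide output) maps normalized signed susceptibilities to the
target encoding.  Training: Adam with batch size 100, step size 1e−3
decayed geometrically to 5e−5 over the run, mean-squared-error loss on
affinely scaled targets (angles scaled by their interval lengths, N by
its upper bound), 90/10 train/validation split taken as the last tenth of
a seeded shuffle, per-epoch train and validation losses recorded.  The
implementation drives `sklearn.neural_network.MLPRegressor` one epoch at
a time; all randomness (shuffle, initialization, batch order) derives
from a single seed.

Inversion of a magnitude-only observation (`solver.solve`) enumerates all
2¹⁶ sign assignments, normalizes each signed candidate, predicts the
11-vector, decodes it (indicators thresholded at 0.5, angles folded into
the indicated intervals, grouped β renormalized), pushes the decoded
solution through the two-sheet forward model, normalizes, and scores the
mean squared error against the signed candidate.  The global minimum
wins; ties break to the lowest pattern index and are reported.  Flipping
all 16 signs is the homodyne global-phase symmetry: the solver evaluates
one representative per complement pair and reports the flip as an
equivalent pattern, making the invariance exact by construction.  Tilt is
reported folded into [0°, 90°] (a tilt and its supplement are physically
equivalent for a twist-averaged C7 unit).

The network decode is then polished: the best candidates are refined by
deterministic bounded least squares over (φ, θ, grouped β, log N)
against the signed normalized input, and re-ranked by the refined
misfit.  The network proposes — carrying the global structure of the
inverse map and the sign discrimination — and Gauss–Newton disposes: on
noiseless observations the refined misfit drops to numerical zero and
the in-plane rotation and coverage ratio recover to machine precision,
while the refined tilt stays wherever the degenerate valley was entered
(the polish moves freely along the tilt-compensation direction).  The
solution reports both the refined and the raw network misfit.

### Benchmark sizes

The study recipe is 100,000 training rows and 1000 epochs.  On one CPU an
epoch (900 minibatches) takes ≈1–2 s, so the package's benchmarks use the
full 100,000 rows with 600 epochs in `scripts/acceptance.py` and 400
epochs in the test-suite fixture; the training loss curve is flat well
before these points.  Measured with the default seeds and the full
1000-epoch recipe, the trained network reaches a median in-plane
rotation error of ≈1.9° (in-plane MSE ≈40–55 deg², dominated by the
unavoidable fold-seam tail: samples within 3° of the φ fold contribute
an MSE two orders of magnitude above the rest) and tilt MSE ≈100–140
deg² in the sub-30° region — the identifiability floor discussed above,
not an optimization failure.  Shorter runs (the suite fixture) land
within a factor ~1.5 of these numbers.

### Error metrics

The canonical in-plane rotation lives on a half-turn circle (invariance 1
identifies φ and φ+π), so in-plane errors are measured as circular
differences mod 180°; plain and circular MSE agree away from the fold
seam.  Tilt errors are plain differences on [0°, 90°].

## Spectral fitting and imaging

Spectra are modelled as a constant baseline plus Voigt components added
in intensity; resonance cross terms are deliberately ignored (adequate
for a spectrum dominated by one band; a known simplification).  Each
component is parameterized by its peak height, and |χ| of the analysis
band is √height — stable under the strong width correlations of
overlapping bands, and sufficient because only cross-polarization ratios
matter after normalization.  Fits run through lmfit with bounds (centers
inside the axis, nonnegative heights, positive widths); non-convergence
is flagged, never silently accepted, and a flat spectrum is rejected.
Width/center sharing across polarization combinations is available but
off by default.

Segmentation standardizes each pixel spectrum (standard normal variate)
— suppressing the flat baseline so clustering sees band shape — and runs
seeded k-means.  Class 0 is the class with the lowest mean 2910 cm⁻¹
intensity (background); remaining classes are ordered by brightness, so
sheet-overlap regions, which are about twice as bright, occupy the top
class.  A segmentation whose class centroids are separated by less than
0.5 in the standardized space (pure-noise separations are
O(1/√n_channels) ≈ 0.16; real spectral classes are O(1)) is flagged
"no structure".  ROI spectra are plain pixel sums with the pixel count
recorded, so Poisson-like √N noise averaging holds exactly.

## Geometry checks

Two independent consistency checks on a tilt value:

- **Stacking height:** a tilted column is shorter by cosθ, so
  θ = arccos(h_obs/h_upright).  The X-ray unit-cell heights 2.9 nm
  (observed) vs 3.1 nm (upright) give 20.7°, consistent with a ~20°
  tilt.
- **Steric packing:** subunits as parallel rigid cylinders on the 1.52 nm
  lattice; tilting in parallel shrinks the axis-to-axis distance to
  L·cosθ, so the gap is L·cosθ − d.  The effective diameter d = 1.25 nm
  was calibrated once so that 30° is "tight" (gap below 10% of d) and
  45–60° collide, then frozen.  At 23° the packing is clear.  The model
  ignores finite-height end effects; the subunit height parameter enters
  only the stacking-height check.

## Known limitations

- Tilt unidentifiability under unconstrained amplitudes (above) is a
  property of the physics of in-plane homodyne measurements, not of this
  implementation; quantitative tilt claims require external β priors.
- No Fresnel/local-field factors, no NA-dependent axial projection, no
  heterodyne phase: the forward model targets the normalized-ratio
  analysis only.
- The Gaussian noise model approximates shot noise at high counts; at low
  counts (per-pixel SNR of a few) the fitter's error bars are optimistic.
- The fold seams of the canonical branch (φ near 0/π, θ near π/2, and
  observations with nearly vanishing grouped amplitudes) are genuine
  discontinuities of any single-valued decoder; predictions for samples
  within a fraction of a degree of a seam can be off by the fold width,
  which dominates the tail of the in-plane error distribution.
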