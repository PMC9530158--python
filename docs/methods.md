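# Methods

## Signal model

Voxel intensities are generated from the ideally spoiled gradient-echo
steady-state equation

S(tissue, TE) = PD · sin α · (1 − E1) / (1 − cos α · E1) · exp(−TE/T2*),
E1 = exp(−TR/T1),

in relative (scale-free) units. The model assumes perfect RF and gradient
spoiling, a single compartment per tissue, mono-exponential T2* decay, and
no B0/B1 inhomogeneity, flow, or chemical-shift effects. All downstream
metrics are invariant to global intensity scaling, so the unit convention
is immaterial.

Default tissue parameters are cord literature values at 3 T: GM T1 994 ms,
T2* 41.3 ms, PD 0.8; WM T1 853 ms (dorsal-column value; the lateral-column
830 ms can be configured), T2* 39.8 ms, PD 0.7; CSF T1 4000 ms,
T2* ≈ 2000 ms, PD 1.0. With the default protocol (TR 38 ms, flip 8°, five
echoes at 6.85/10.85/14.85/18.85/22.85 ms) the model predicts a GM/WM
contrast of 0.125 and a WM/CSF contrast of 0.404 at the fifth echo.

A consequence worth noting: with these values the GM signal exceeds CSF for
TE ≲ 10.8 ms, so the tissue ordering CSF > GM > WM holds only from echo 3
onward; GM > WM holds at every echo. WM/CSF contrast rises steeply with
echo time while GM/WM contrast rises only mildly (similar T2*), which is
the physical core of the echo-combination trade-off.

## Phantom

The phantom is parametric rather than atlas-based so that every area and
signal has a closed-form oracle. Per axial slice (caudal → rostral, 0-based,
axial slices on the third array axis):

- the cord is an ellipse (reference semi-axes 4.8 × 3.6 mm) whose scale
  follows an asymmetric Gaussian profile of slice index — strict unique
  maximum at the configured LSE slice, faster caudal taper (conus). The
  rostral taper width (3 slices) is chosen so adjacent-slice area
  differences near the peak are much larger than voxel-quantisation jitter,
  keeping the binarized-area argmax well defined.
- GM is a union of five rotated ellipse lobes (two ventral horns, two
  dorsal horns, a central commissure band) forming the butterfly, scaled
  with the cord; slices caudal to the configured CM slice carry only a
  small round central blob (butterfly lost). Template containment inside
  the cord is validated analytically at construction.
- CSF is an annulus between the cord and an outer ellipse 3 mm larger in
  each semi-axis. Outside the annulus is signal-free background; epidural
  fat, bone and roots are not modelled.

Occupancy is rasterised by supersampling each voxel (default 4×4;
configurable ≥ 4) and block-averaging the analytic indicator; GM, WM and
CSF occupancies sum to ≤ 1 per voxel. The default study grid is
128 × 128 × 12 voxels at 0.5 × 0.5 × 5 mm (the full 384 × 384 × 20 matrix
is available by configuration); the reduced grid keeps a cohort simulation
in tens of seconds without changing any per-voxel statistics.

Noise is thermal: complex Gaussian of SD σ on two quadrature channels,
giving a Rician magnitude (default), or a Gaussian approximation
(|S + n|) for exact analytic checks. σ defaults to a closed-form
calibration such that WM SNR on the 2-echo combination at 8 averages
equals 20, matching the in-vivo scale of that measurement; the true noise
level of the reference acquisitions is not published, so this is a package
choice. Per-repetition bulk motion is a rigid translation applied to the
noiseless volume as a Fourier-domain sub-voxel shift (through-slice
included) before noise is added.

What the phantom deliberately omits: k-space sampling, GRAPPA/partial-
Fourier artifacts, off-resonance dropout, respiratory ghosting, physiological
noise, and anatomical texture within tissues. The last point matters for
interpretation: within-ROI SDs in the phantom are (almost) purely thermal,
so SNR/CNR follow the √NSA law almost exactly and GM/WM CNR keeps growing
with more combined echoes. In vivo the within-tissue SD also contains a
deterministic anatomical component, which flattens the NSA curve
(e.g. a 1.58× instead of 2× gain from 1 → 4 averages) and caps the GM/WM
optimum at 3–4 combined echoes. Passing phantom tests therefore validate
the measurement machinery and the thermal-noise physics, not the in-vivo
optimality of any specific echo count for GM.

## Series grid

RMS combination of the leading k echoes is voxel-wise √(mean_i I_i²) —
the mean rather than the sum, keeping intensity ranges comparable across k
(all metrics are scale-invariant either way). "NSA = n" means the
arithmetic mean of repetitions 1..n in acquisition order (prospective
scan-time shortening), on magnitude images; combination is applied within
each repetition first, then averaged. For E echoes and R repetitions the
grid holds (2E − 1)·R images: E single echoes plus E − 1 leading
combinations, each at NSA 1..R.

## Masks and metrics

Sub-voxel occupancies are binarized at inclusion thresholds of 100 % (SC)
and 50 % (GM, CSF); the 100 % threshold is applied as occupancy ≥ 1 − 10⁻⁶
to absorb rasterisation round-off. WM = SC AND NOT GM (after forcing
GM ⊆ SC), so GM and WM partition the binary cord. The CSF reference ROI is
an analytic 7.5 mm² ellipse anterior to the cord; its aspect ratio (2.0)
and anterior clearance (0.6 mm, deliberately more than one voxel so no
boundary voxel mixes cord and ROI) are package choices — the source
protocol specifies only the area — and are configurable for real data.

SNR, CNR and contrast use the tissue-uniformity convention (within-ROI
SD, not air noise), with sample SDs (n − 1). The CNR denominator is
√(SD₁² + SD₂²). Degenerate ROIs (zero SD, e.g. noiseless simulations)
yield an `inf` sentinel plus a flag rather than an exception so grid-wide
sweeps complete. Metrics are computed per slice and averaged over
three-slice stacks centred on the LSE slice (greatest binary cord area;
ties break toward the more rostral slice) and the CM slice (most caudal
slice with butterfly GM — taken from ground truth or user input, never
inferred from images). Acquisition time for CNR/√t is per-repetition time
× NSA from protocol metadata.

## Motion QA

Each repetition's rigid translation is estimated with upsampled-DFT
cross-correlation and reported relative to the mean of all repetitions;
the QA statistic is the maximum Euclidean displacement, flagged at 0.6 mm.
Two estimator details depart from the naive register-to-the-mean scheme,
both needed for sub-0.1-voxel accuracy:

- the reference for repetition r is the leave-one-out mean of the others
  (the all-mean contains r's own noise, whose zero-lag correlation spike
  biases sub-voxel estimates toward zero); the measured offset is rescaled
  by (R − 1)/R to the all-mean convention;
- the estimate is iterated (≤ 3 passes): repetitions are realigned by the
  current estimate and residuals are measured against the re-sharpened
  mean, removing the bias a motion-blurred reference induces once shifts
  approach a voxel.

Registration runs on the 3-echo RMS combination by default (high CNR,
stable correlation) and is for QA only — images are never resampled in the
analysis path. Note that with R repetitions, a lone shift of magnitude d
appears as a relative-to-mean displacement of d·(R − 1)/R.

## Scan-time model

Total time = per-repetition time × NSA, with the per-repetition time
anchored to the measured 17:56 min total of the full protocol (134.5 s)
and scaled by TR_min(n)/TR for shorter echo trains, where
TR_min(n) = TR − (E − n)·spacing. Reference lines, dummy scans and slice
oversampling are not modelled; the model reproduces the measured
six-average totals (10:38 at 3 echoes, 13:28 at 5) within a second.

## Simulated studies

`run_study` simulates a cohort by jittering the cord scale and σ by ±10 %
(uniform) per subject — enough to produce realistic across-subject error
bars without modelling an anatomical cohort — and pools slice-stack
metrics into mean ± SD summaries. Subject seeds spawn deterministically
from the study seed; identical configurations reproduce identical tables
bit-for-bit. Statistics are descriptive only (mean, SD, rankings);
inferential testing is out of scope.

## Numerical choices and edge cases

- Sample SD everywhere; `inf` sentinels for zero-SD ROIs; empty binarized
  masks are legal but logged.
- Series rankings break ties toward fewer echoes.
- Slice stacks extending past the volume are truncated with a warning.
- Gaussian-family noise uses |S + n|; the folding bias is negligible at
  the SNR ≥ 5 regimes simulated here.
- The Fourier shift wraps at volume edges; phantom content is surrounded
  by zero background, so wraparound is inert for sub-voxel QA motion.
- Seeds are plain integers < 2³¹; all randomness flows through
  `numpy.random.default_rng`/`SeedSequence`.

## Known limitations

Single-compartment tissues with literature parameters; no anatomical noise
component (see above); parametric geometry rather than subject anatomy;
translation-only motion (no rotation); scan-time model ignores sequence
overheads; CM-slice identification is not automated. These bound what the
phantom can claim about in-vivo optima but leave every measurement
definition — series construction, masks, metrics, QA — exactly testable.
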