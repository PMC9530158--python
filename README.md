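# cordgre

Multi-echo gradient-echo (GRE) protocol optimisation for spinal cord (SC)
and gray matter (GM) segmentability in the lumbosacral cord, built around a
fully synthetic, verifiable phantom.

Atrophy of the lower spinal cord is measured by segmenting SC, GM and white
matter (WM) on axial multi-echo spoiled-GRE images (FLASH/MEDIC/mFFE-type
sequences). How well those images can be segmented depends on two
acquisition choices: how many successive echoes are combined (via
root-mean-squares) and how many signal averages (NSA) are acquired.
`cordgre` implements the quantitative machinery to study that trade-off —
for people developing or standardising spinal-cord imaging protocols —
without requiring scanner data.

## What it computes

The steady-state signal of an ideally spoiled gradient-echo acquisition is

```
S = PD · sin α · (1 − e^(−TR/T1)) / (1 − cos α · e^(−TR/T1)) · e^(−TE/T2*)
```

with tissue parameters (defaults: GM T1 994 ms, T2* 41.3 ms, PD 0.8;
WM 853 ms, 39.8 ms, 0.7; CSF 4000 ms, 2000 ms, 1.0) and protocol parameters
(defaults: TR 38 ms, α 8°, five echoes at TE = 6.85 + 4(i−1) ms, eight
magnitude repetitions). On top of that:

- **phantom** — parametric lumbosacral-cord anatomy (elliptical cord peaking
  at the lumbosacral-enlargement (LSE) slice, butterfly-shaped GM down to the
  conus-medullaris (CM) slice, CSF annulus) rasterised with sub-voxel
  occupancy; Rician or Gaussian thermal noise; rigid per-repetition motion.
- **series** — the derived image grid: RMS combinations of the leading
  1..E echoes and running averages over 1..R repetitions,
  (2E − 1) · R = 72 images for the default 5 × 8 acquisition.
- **masks** — sub-voxel segmentations binarized at 100 % (SC) / 50 %
  (GM, CSF) inclusion, WM = SC − GM, a 7.5 mm² CSF reference ellipse
  anterior to the cord, and cross-sectional areas.
- **metrics** — SNR = mean/SD within a ROI, CNR = |Δmean|/√(SD₁²+SD₂²),
  contrast = |Δmean|/mean, CNR/√t efficiency; computed slice-wise and
  averaged over three-slice stacks around the LSE and CM slices.
- **motion** — per-repetition translation estimates relative to the mean
  image and the maximum-absolute-displacement QA statistic (0.6 mm bound).
- **protocol** — TE ladder, scan-time model (anchored to 17:56 min for
  5 echoes × 8 averages), and the recommendation rules: combine 5 echoes
  for SC-only, 3 (LSE) or 4 (CM) for GM-only, 3 for joint segmentation,
  with at least 6 averages.
- **pipeline** — multi-subject simulated studies with per-subject anatomy
  and noise jitter, pooled mean ± SD summaries, and series rankings.

## Worked example

```python
import cordgre as cg

grid = cg.GridSpec(shape=(128, 128), voxel_mm=0.5, n_slices=12)
phantom = cg.build_geometry(cg.PhantomGeometry.for_slices(12), grid)
protocol = cg.AcquisitionProtocol(matrix=grid.shape, n_slices=grid.n_slices)
tissue = cg.TissueModel()
sigma = cg.calibrate_sigma(tissue, protocol)   # WM SNR ~ 20 on the 2-echo combo

dataset = cg.simulate_dataset(phantom, tissue, protocol,
                              cg.NoiseSpec(sigma=sigma, seed=1))
images = cg.build_grid(dataset)                # 72 series images
rois = cg.binarize_phantom(phantom)
table = cg.metrics_table(images, rois,
                         cg.RegionDefinition(phantom.lse_slice, phantom.cm_slice))
```

For the LSE slice stack at NSA = 8 this prints (`examples/simulate_and_measure.py`):

```
metric     snr_wm  snr_gm  cnr_wm_csf  cnr_gm_wm  contrast_wm_csf  contrast_gm_wm
series_id
echo1       13.96   16.31        0.04       0.96             0.00            0.09
echo1-3     22.61   26.59        1.68       1.62             0.10            0.09
echo1-5     27.09   32.39        3.95       1.98             0.17            0.10
echo5       10.24   12.38        3.61       0.86             0.38            0.11
```

Reading: per-echo SNR falls with echo time while WM/CSF contrast rises, so
RMS-combining more echoes buys WM/CSF CNR — the 5-echo combination is best
for outlining the cord against CSF. Contrasts are noise-independent and
barely change with NSA, while SNR and CNR grow ∝ √NSA.

The closed-form signal model with the default tissue values predicts
echo-5 contrasts of 0.125 (GM/WM) and 0.404 (WM/CSF) — within one
across-participant SD of the measured in-vivo values.

Other narrative examples: `examples/signal_model_and_protocol.py`
(contrast ladders, scan times, recommendations),
`examples/motion_qa.py` (displacement QA on injected motion),
`examples/run_cohort_study.py` (multi-subject ranking).

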