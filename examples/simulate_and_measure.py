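"""Simulate one phantom acquisition and compute segmentability metrics.

Builds the lumbosacral-cord phantom on a desk-scale grid, simulates a
5-echo x 8-repetition magnitude acquisition with Rician thermal noise,
derives the 72-image series grid, binarizes the ground-truth masks with the
standard thresholds (100% SC, 50% GM/CSF), and prints SNR/CNR/contrast for
the echo combinations at full averaging.
"""

import cordgre as cg

grid = cg.GridSpec(shape=(128, 128), voxel_mm=0.5, n_slices=12)
geometry = cg.PhantomGeometry.for_slices(grid.n_slices)
protocol = cg.AcquisitionProtocol(matrix=grid.shape, n_slices=grid.n_slices)
tissue = cg.TissueModel()

phantom = cg.build_geometry(geometry, grid)
sigma = cg.calibrate_sigma(tissue, protocol)  # WM SNR ~ 20 on the 2-echo combo
dataset = cg.simulate_dataset(
    phantom, tissue, protocol, cg.NoiseSpec(sigma=sigma, seed=1)
)
print(f"raw images: {dataset.n_images} (5 echoes x 8 repetitions)")

images = cg.build_grid(dataset)
print(f"derived series grid: {len(images)} images (9 series x NSA 1..8)")

rois = cg.binarize_phantom(phantom)
print("ROI voxels:", {label: m.n_voxels for label, m in rois.items()})
print("LSE slice (greatest cord area):", cg.find_lse_slice(rois["sc"]))

region_def = cg.RegionDefinition(phantom.lse_slice, phantom.cm_slice)
table = cg.metrics_table(images, rois, region_def, rep_time_s=protocol.rep_time_s)

sel = table[(table.nsa == 8) & (table.region == "lse")]
wide = sel.pivot_table(index="series_id", columns="metric", values="value")
cols = ["snr_wm", "snr_gm", "cnr_wm_csf", "cnr_gm_wm", "contrast_wm_csf", "contrast_gm_wm"]
print("\nLSE slice stack, NSA = 8:")
print(wide[cols].round(2).to_string())
print(
    "\nCombining more echoes raises WM/CSF CNR (cord segmentability) up to\n"
    "the full 5-echo combination, while contrasts depend on the echo times\n"
    "only. Under pure thermal noise every combination also beats the first\n"
    "echo for GM/WM CNR; in vivo, anatomical intensity variation and rater\n"
    "assessment shift the GM optimum to 3-4 combined echoes."
)
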