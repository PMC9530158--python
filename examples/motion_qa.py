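"""Inject bulk motion into a simulated acquisition and run the QA check.

Each repetition gets a rigid translation (<= 0.6 mm); the estimator
registers every repetition to the mean image (3-echo RMS combination) and
reports per-repetition absolute displacements and their maximum — the
motion QA statistic.
"""

import numpy as np

import cordgre as cg
from cordgre.motion import qa_report

grid = cg.GridSpec(shape=(96, 96), voxel_mm=0.5, n_slices=8)
phantom = cg.build_geometry(cg.PhantomGeometry.for_slices(grid.n_slices), grid)
protocol = cg.AcquisitionProtocol(matrix=grid.shape, n_slices=grid.n_slices)
tissue = cg.TissueModel()
sigma = cg.calibrate_sigma(tissue, protocol)

trace = cg.MotionTrace.random(protocol.n_repetitions, max_mm=0.6, seed=3)
dataset = cg.simulate_dataset(
    phantom, tissue, protocol, cg.NoiseSpec(sigma=sigma, seed=3), trace
)

estimate = cg.estimate_translations(dataset)
table, flagged = qa_report(estimate)
print(table.round(3).to_string(index=False))
print(f"\nmax absolute displacement: {estimate.max_absolute_displacement_mm:.3f} mm")
print(f"flagged (>= 0.6 mm): {flagged}")

truth = trace.shifts_mm - trace.shifts_mm.mean(axis=0)
err = np.linalg.norm(estimate.translations_mm - truth, axis=1)
print(f"worst recovery error vs injected truth: {err.max():.3f} mm")
print(
    "\nDisplacements are relative to the mean of all repetitions; values\n"
    "below ~0.6 mm (about one voxel) indicate negligible motion."
)
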