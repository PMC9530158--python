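"""Simulate a small cohort and rank echo combinations for segmentability.

Runs the full pipeline (phantom -> acquisition -> series grid -> masks ->
metrics) over simulated subjects with per-subject anatomy/noise jitter,
pools metrics across subjects, and ranks the nine echo series by WM/CSF
and GM/WM CNR at full averaging.
"""

import cordgre as cg

config = cg.StudyConfig(
    n_subjects=4,  # a quick demonstration; 10 reproduces the study scale
    base_seed=0,
    grid=cg.GridSpec(shape=(128, 128), n_slices=12),
)
result = cg.run_study(config)

for metric in ("cnr_wm_csf", "cnr_gm_wm"):
    ranked = cg.compare_series(result, metric, region="lse", nsa=8)
    print(f"\n{metric} (LSE stack, NSA = 8), across-subject mean +/- SD:")
    print(
        ranked[["series_id", "mean", "sd"]]
        .round(3)
        .to_string(index=False)
    )
    print(f"best series: {ranked.series_id.iloc[0]}")

print(
    "\nWM/CSF CNR (cord outline) is maximised by combining all 5 echoes.\n"
    "The phantom models thermal noise only, so GM/WM CNR also keeps rising\n"
    "with more echoes; in vivo the within-tissue SD includes anatomical\n"
    "variation, which caps the GM/WM optimum at 3-4 combined echoes and\n"
    "motivates the 3-echo recommendation for joint SC+GM segmentation."
)
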