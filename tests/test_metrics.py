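"""SNR/CNR/contrast metrics, slice selection, aggregation, and their
statistical behaviour on the noisy phantom."""

import math

import numpy as np
import pytest

import cordgre as cg
from cordgre.metrics import METRIC_NAMES, RegionDefinition, aggregate, slice_metrics, stack_slices


def mask_from(values_shape, coords, voxel_area=0.25, label="roi"):
    data = np.zeros(values_shape, dtype=bool)
    for c in coords:
        data[c] = True
    return cg.BinaryMask(data, label, voxel_area)


def image_with(values):
    """1-voxel-deep image whose flattened entries are `values`."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return arr


class TestClosedForms:
    def test_snr_two_voxel_example(self):
        img = image_with([8.0, 12.0])
        roi = mask_from((2, 1, 1), [(0, 0, 0), (1, 0, 0)])
        # mean 10, sample SD 2sqrt(2): SNR = 10 / 2.8284 = 3.5355
        assert cg.snr(img, roi) == pytest.approx(10 / (2 * math.sqrt(2)), rel=1e-12)

    def test_snr_degenerate_constant_roi(self, caplog):
        img = image_with([5.0, 5.0, 5.0])
        roi = mask_from((3, 1, 1), [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with caplog.at_level("WARNING"):
            assert cg.snr(img, roi) == float("inf")

    def test_cnr_closed_form(self):
        # means 10 and 6, sample SDs 3 and 4 -> 4 / 5 = 0.8
        d1 = 3 * math.sqrt(2) / 2
        d2 = 4 * math.sqrt(2) / 2
        img = image_with([10 - d1, 10 + d1, 6 - d2, 6 + d2])
        roi1 = mask_from((4, 1, 1), [(0, 0, 0), (1, 0, 0)])
        roi2 = mask_from((4, 1, 1), [(2, 0, 0), (3, 0, 0)])
        assert cg.cnr(img, roi1, roi2) == pytest.approx(0.8, rel=1e-12)

    def test_cnr_same_roi_is_zero(self):
        img = image_with([1.0, 2.0, 3.0])
        roi = mask_from((3, 1, 1), [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert cg.cnr(img, roi, roi) == 0.0

    def test_contrast_closed_form(self):
        img = image_with([3.0, 1.0])
        roi1 = mask_from((2, 1, 1), [(0, 0, 0)])
        roi2 = mask_from((2, 1, 1), [(1, 0, 0)])
        assert cg.contrast(img, roi1, roi2) == pytest.approx(1.0)
        assert cg.contrast(img, roi1, roi1) == 0.0

    def test_cnr_efficiency(self):
        assert cg.cnr_efficiency(6.0, 9.0) == pytest.approx(2.0)
        # quadrupling t while CNR doubles (sqrt-NSA law) leaves it unchanged
        assert cg.cnr_efficiency(2 * 6.0, 4 * 9.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            cg.cnr_efficiency(1.0, 0.0)


class TestSliceSelection:
    def test_lse_from_phantom(self, phantom_small, rois_small):
        assert cg.find_lse_slice(rois_small["sc"]) == phantom_small.lse_slice

    def test_tie_breaks_rostral(self):
        data = np.zeros((4, 4, 3), dtype=bool)
        data[:2, :2, :] = True  # same area everywhere
        mask = cg.BinaryMask(data, "sc", 0.25)
        assert cg.find_lse_slice(mask) == 2

    def test_matches_brute_force_argmax(self, rng):
        n = 9
        data = np.zeros((10, 10, n), dtype=bool)
        counts = rng.integers(1, 90, size=n)
        for s, c in enumerate(counts):
            data.reshape(100, n)[:c, s] = True
        mask = cg.BinaryMask(data, "sc", 0.25)
        best = max(range(n), key=lambda s: (counts[s], s))
        assert cg.find_lse_slice(mask) == best

    def test_empty_stack_rejected(self):
        mask = cg.BinaryMask(np.zeros((4, 4, 2), dtype=bool), "sc", 0.25)
        with pytest.raises(ValueError):
            cg.find_lse_slice(mask)

    def test_cm_slice_sources(self):
        assert cg.find_cm_slice(metadata={"cm_slice": 4}) == 4
        assert cg.find_cm_slice(metadata={"cm_slice": 4}, user_index=7) == 7
        with pytest.raises(ValueError):
            cg.find_cm_slice()


class TestAggregation:
    def test_examples(self):
        assert aggregate([5.0, 5.0, 5.0]) == 5.0
        assert aggregate([1.0, 2.0, 3.0]) == 2.0

    def test_mean_oracle(self, rng):
        vals = rng.uniform(0, 10, size=7)
        assert aggregate(vals) == pytest.approx(float(np.mean(vals)), rel=1e-15)

    def test_stack_truncated_at_volume_edge(self):
        with pytest.warns(UserWarning):
            slices = stack_slices(0, 1, 6)
        assert slices == [0, 1]


class TestOracleEquality:
    def test_metrics_equal_brute_force_recomputation(self, dataset_noisy, rois_small):
        """Every metric equals a from-scratch recomputation on raw voxel lists."""
        img = cg.rms_combine(dataset_noisy, 3, 0)
        s = 3
        vals = {}
        for label in ("gm", "wm", "csf"):
            m = rois_small[label]
            vals[label] = [
                float(img.data[i, j, s])
                for i, j in zip(*np.nonzero(m.data[:, :, s]))
            ]

        def mean(v):
            return sum(v) / len(v)

        def sd(v):
            mu = mean(v)
            return math.sqrt(sum((x - mu) ** 2 for x in v) / (len(v) - 1))

        got = slice_metrics(img, rois_small, s)
        assert got["snr_gm"] == pytest.approx(mean(vals["gm"]) / sd(vals["gm"]), abs=1e-12)
        assert got["snr_wm"] == pytest.approx(mean(vals["wm"]) / sd(vals["wm"]), abs=1e-12)
        assert got["cnr_wm_csf"] == pytest.approx(
            abs(mean(vals["wm"]) - mean(vals["csf"]))
            / math.sqrt(sd(vals["wm"]) ** 2 + sd(vals["csf"]) ** 2),
            abs=1e-12,
        )
        assert got["contrast_gm_wm"] == pytest.approx(
            abs(mean(vals["gm"]) - mean(vals["wm"]))
            / (0.5 * (mean(vals["gm"]) + mean(vals["wm"]))),
            abs=1e-12,
        )
        # area oracle
        area = cg.cross_sectional_area(rois_small["wm"], s)
        assert area == pytest.approx(len(vals["wm"]) * 0.25, abs=1e-12)

    def test_scale_invariance(self, dataset_noisy, rois_small):
        img = cg.rms_combine(dataset_noisy, 2, 0)
        scaled = cg.SeriesImage(
            data=4.2 * img.data, series_id=img.series_id, nsa=1,
            source_repetitions=(0,),
        )
        for name, value in slice_metrics(img, rois_small, 2).items():
            assert slice_metrics(scaled, rois_small, 2)[name] == pytest.approx(
                value, rel=1e-12
            ), name


@pytest.fixture(scope="module")
def nsa_curves(phantom_small, tissue, protocol_small, sigma_small, rois_small):
    """Across-seed means of the 3-echo-combination metrics vs NSA (LSE stack).

    Averaging over seeds brings the Monte-Carlo error of each curve point
    well below the tolerances asserted on it.
    """
    rd = RegionDefinition(phantom_small.lse_slice, phantom_small.cm_slice)
    slices = rd.slices("lse", protocol_small.n_slices)
    names = ("cnr_gm_wm", "cnr_wm_csf", "snr_wm", "contrast_gm_wm", "contrast_wm_csf")
    n_seeds = 8
    curves = {name: np.zeros(8) for name in names}
    for seed in range(n_seeds):
        ds = cg.simulate_dataset(
            phantom_small, tissue, protocol_small,
            cg.NoiseSpec(sigma=sigma_small, family="gaussian", seed=200 + seed),
        )
        reps = [cg.rms_combine(ds, 3, r) for r in range(8)]
        for n in range(1, 9):
            img = cg.average_repetitions(reps, n)
            per_slice = [slice_metrics(img, rois_small, s) for s in slices]
            for name in names:
                curves[name][n - 1] += np.mean([m[name] for m in per_slice])
    return {name: curve / n_seeds for name, curve in curves.items()}


class TestNoiseScaling:
    def test_snr_matches_signal_over_sigma(
        self, phantom_small, tissue, protocol_small, sigma_small, rois_small
    ):
        ds = cg.simulate_dataset(
            phantom_small, tissue, protocol_small,
            cg.NoiseSpec(sigma=sigma_small, family="gaussian", seed=5),
        )
        wm = rois_small["wm"]
        assert wm.n_voxels >= 1000
        s_wm = cg.spoiled_gre_signal(tissue.wm, protocol_small, 1)
        got = cg.snr(ds.data[:, :, :, 0, 0], wm)
        assert got == pytest.approx(s_wm / sigma_small, rel=0.03)

    def test_sqrt_nsa_growth_exponent(self, nsa_curves):
        """log-log slope of CNR and SNR vs NSA lies in [0.45, 0.55]."""
        nsa = np.arange(1, 9)
        for metric in ("cnr_gm_wm", "cnr_wm_csf", "snr_wm"):
            slope = np.polyfit(np.log(nsa), np.log(nsa_curves[metric]), 1)[0]
            assert 0.45 <= slope <= 0.55, (metric, slope)

    def test_contrast_independent_of_nsa(self, nsa_curves):
        for metric in ("contrast_gm_wm", "contrast_wm_csf"):
            curve = nsa_curves[metric]
            assert curve[-1] / curve[0] == pytest.approx(1.0, abs=0.05), metric

    def test_cnr_efficiency_flat_in_nsa(self, nsa_curves):
        # t is proportional to NSA, so CNR/sqrt(t) ~ CNR/sqrt(NSA) must be flat
        eff = nsa_curves["cnr_wm_csf"] / np.sqrt(np.arange(1, 9))
        assert eff[-1] / eff[0] == pytest.approx(1.0, abs=0.10)

    def test_combined_echoes_beat_first_echo_for_gm_wm_cnr(
        self, phantom_small, tissue, protocol_small, sigma_small, rois_small
    ):
        ds = cg.simulate_dataset(
            phantom_small, tissue, protocol_small,
            cg.NoiseSpec(sigma=sigma_small, family="gaussian", seed=21),
        )
        rd = RegionDefinition(phantom_small.lse_slice, phantom_small.cm_slice)
        images = [im for im in cg.build_grid(ds) if im.nsa == 8]
        table = cg.metrics_table(images, rois_small, rd, regions=("lse",))
        sel = table[table.metric == "cnr_gm_wm"].set_index("series_id").value
        for k in (2, 3, 4, 5):
            assert sel[f"echo1-{k}"] > sel["echo1"]

    def test_noiseless_contrast_matches_signal_equation(
        self, dataset_noiseless, rois_small, tissue, protocol_small, phantom_small
    ):
        """On pure-tissue ROIs of the noiseless phantom, the measured GM/WM
        contrast at echo 5 equals the closed-form prediction."""
        pure = {
            label: cg.BinaryMask(
                phantom_small.occupancy[label] >= 1 - 1e-6, label, 0.25
            )
            for label in ("gm", "wm")
        }
        img = dataset_noiseless.data[:, :, :, 4, 0]
        got = cg.contrast(img, pure["gm"], pure["wm"])
        s_gm = cg.spoiled_gre_signal(tissue.gm, protocol_small, 5)
        s_wm = cg.spoiled_gre_signal(tissue.wm, protocol_small, 5)
        assert got == pytest.approx(cg.contrast_from_signals(s_gm, s_wm), abs=1e-6)


def test_metrics_table_layout(dataset_noisy, rois_small, phantom_small):
    images = cg.build_grid(dataset_noisy)
    rd = RegionDefinition(phantom_small.lse_slice, phantom_small.cm_slice)
    table = cg.metrics_table(images, rois_small, rd, rep_time_s=134.5)
    assert set(table.metric) == set(METRIC_NAMES)
    # 72 images x 2 regions x 8 metrics
    assert len(table) == 72 * 2 * 8
    assert not table[table.metric.str.startswith("contrast")].degenerate.any()
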