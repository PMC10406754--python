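"""Agreement metrics against brute-force voxel-enumeration oracles."""

import math

import numpy as np
import pytest

from segsat import (
    LabelMap,
    LabelVolume,
    binary_counts,
    dice,
    evaluate_case,
    jaccard,
    label_volume_ml,
    mean_surface_distance,
    metrics_from_csv,
    metrics_to_csv,
    summarize_metrics,
    tpr,
)
from segsat.seg_metrics import boundary_mask, directed_surface_distances

from conftest import oracle_counts, oracle_msd, random_label_volume


def _mask_volume(mask, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(mask, dtype=np.int32), spacing)


class TestCounts:
    def test_direct_example(self):
        """4 reference voxels, 6 predicted, 3 shared -> (3, 3, 1)."""
        ref = np.zeros((4, 4, 4), dtype=np.int32)
        pred = np.zeros((4, 4, 4), dtype=np.int32)
        ref.flat[:4] = 1
        pred.flat[1:7] = 1
        assert binary_counts(_mask_volume(ref), _mask_volume(pred), 1) == (3, 3, 1)

    def test_identical_masks(self):
        vol = random_label_volume(5)
        n = int(np.count_nonzero(vol.voxels == 1))
        assert binary_counts(vol, vol, 1) == (n, 0, 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_triple_loop_oracle(self, seed, rng_volume_pair):
        ref, pred = rng_volume_pair(seed)
        for label in (0, 1, 2):
            assert binary_counts(ref, pred, label) == oracle_counts(ref, pred, label)

    def test_non_comparable_raises(self):
        a = _mask_volume(np.zeros((4, 4, 4)))
        b = _mask_volume(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            binary_counts(a, b, 1)


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [((3, 3, 1), 0.6), ((0, 0, 0), 1.0), ((0, 5, 7), 0.0)],
    )
    def test_dice_values(self, counts, expected):
        assert dice(*counts) == pytest.approx(expected, abs=1e-15)

    def test_jaccard_tpr_values(self):
        assert jaccard(3, 3, 1) == pytest.approx(3 / 7)
        assert tpr(3, 1) == pytest.approx(0.75)
        assert jaccard(5, 0, 0) == 1.0 and tpr(5, 0) == 1.0
        assert jaccard(0, 0, 0) == 1.0 and tpr(0, 0) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_jaccard_dice_identity(self, seed, rng_volume_pair):
        """J = D/(2-D) as an algebraic identity on random masks."""
        ref, pred = rng_volume_pair(seed)
        for label in (0, 1, 2):
            counts = binary_counts(ref, pred, label)
            d, j = dice(*counts), jaccard(*counts)
            assert abs(j - d / (2 - d)) < 1e-12

    def test_symmetry_and_tpr_asymmetry(self, rng_volume_pair):
        ref, pred = rng_volume_pair(17)
        c_fwd = binary_counts(ref, pred, 1)
        c_rev = binary_counts(pred, ref, 1)
        assert dice(*c_fwd) == dice(*c_rev)
        assert jaccard(*c_fwd) == jaccard(*c_rev)
        # TPR swaps FP and FN, so it is direction-dependent
        assert c_fwd[1] == c_rev[2] and c_fwd[2] == c_rev[1]


class TestSurfaceDistance:
    def test_identical_nonempty_masks_zero(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        vol = _mask_volume(mask)
        assert mean_surface_distance(vol, vol, 1) == 0.0

    def test_empty_mask_missing(self):
        ref = _mask_volume(np.zeros((4, 4, 4)))
        pred = np.zeros((4, 4, 4), dtype=np.int32)
        pred[1, 1, 1] = 1
        assert mean_surface_distance(ref, _mask_volume(pred), 1) is None
        assert mean_surface_distance(_mask_volume(pred), ref, 1) is None

    def test_offset_cubes_match_exhaustive_oracle(self):
        """Two 3x3x3 cubes offset by 4 voxels, 1 mm isotropic."""
        a = np.zeros((12, 8, 8), dtype=np.int32)
        b = np.zeros((12, 8, 8), dtype=np.int32)
        a[1:4, 2:5, 2:5] = 1
        b[5:8, 2:5, 2:5] = 1
        va, vb = _mask_volume(a), _mask_volume(b)
        assert mean_surface_distance(va, vb, 1) == pytest.approx(
            oracle_msd(va, vb, 1), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_random_volumes_match_oracle(self, seed, rng_volume_pair):
        ref, pred = rng_volume_pair(seed, shape=(6, 6, 6))
        for label in (1, 2):
            got = mean_surface_distance(ref, pred, label)
            want = oracle_msd(ref, pred, label)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_boundary_against_oracle(self):
        from conftest import oracle_boundary

        mask = random_label_volume(9, shape=(6, 6, 6)).mask(1)
        got = sorted(map(tuple, np.argwhere(boundary_mask(np.asarray(mask)))))
        assert got == sorted(oracle_boundary(np.asarray(mask)))

    def test_spacing_covariance(self, rng_volume_pair):
        """Scaling spacing by s scales MSD by s and volumes by s^3 exactly."""
        ref, pred = rng_volume_pair(23)
        s = 2.5
        ref_s = LabelVolume(ref.voxels, tuple(s * v for v in ref.spacing))
        pred_s = LabelVolume(pred.voxels, tuple(s * v for v in pred.spacing))
        msd1 = mean_surface_distance(ref, pred, 1)
        msd2 = mean_surface_distance(ref_s, pred_s, 1)
        assert msd2 == pytest.approx(s * msd1, rel=1e-12)
        assert label_volume_ml(ref_s, 1) == pytest.approx(
            s**3 * label_volume_ml(ref, 1), rel=1e-12
        )

    def test_directed_components_average_to_symmetric(self, rng_volume_pair):
        ref, pred = rng_volume_pair(31)
        d = directed_surface_distances(ref, pred, 1)
        assert mean_surface_distance(ref, pred, 1) == pytest.approx(
            0.5 * (d[0] + d[1])
        )


class TestVolumes:
    @pytest.mark.parametrize(
        "n,spacing,expected",
        [(1000, (1, 1, 1), 1.0), (0, (1, 1, 1), 0.0), (200, (1.5, 1.5, 5.0), 2.25)],
    )
    def test_volume_ml(self, n, spacing, expected):
        vox = np.zeros((12, 12, 12), dtype=np.int32)
        vox.flat[:n] = 1
        assert label_volume_ml(LabelVolume(vox, spacing), 1) == pytest.approx(expected)


class TestEvaluateCase:
    def test_self_comparison_perfect(self):
        from segsat import make_phantom

        vol = make_phantom()
        for rec in evaluate_case(vol, vol, LabelMap(), "self"):
            assert rec.dice == rec.jaccard == rec.tpr == 1.0
            assert rec.msd_mm == 0.0

    def test_all_background_prediction(self):
        from segsat import make_phantom

        vol = make_phantom()
        empty = LabelVolume(np.zeros_like(vol.voxels), vol.spacing)
        for rec in evaluate_case(vol, empty, LabelMap(), "bg"):
            assert rec.dice == 0.0
            assert rec.pred_empty and not rec.ref_empty
            assert rec.msd_mm is None

    def test_composition_matches_components(self, rng_volume_pair):
        """evaluate_case agrees with independent recomputation per metric."""
        ref, pred = rng_volume_pair(41)
        records = evaluate_case(ref, pred, LabelMap(), "comp")
        by_name = {r.label_name: r for r in records}
        for name, label in LabelMap().items():
            counts = binary_counts(ref, pred, label)
            assert by_name[name].dice == dice(*counts)
            assert by_name[name].jaccard == jaccard(*counts)
            assert by_name[name].tpr == tpr(counts[0], counts[2])
            assert by_name[name].msd_mm == mean_surface_distance(ref, pred, label)


class TestSummarize:
    def _record(self, case_id, d, msd=0.5):
        from segsat import CaseMetrics

        return CaseMetrics(case_id, "kidney", d, d / (2 - d), d, msd, 1.0, 1.0, False, False)

    def test_two_point_sd(self):
        summary = summarize_metrics([self._record("a", 0.8), self._record("b", 0.9)])
        row = summary.iloc[0]
        assert row["dice_mean"] == pytest.approx(0.85)
        assert row["dice_sd"] == pytest.approx(math.sqrt(0.005), abs=1e-12)

    def test_single_record_sd_zero(self):
        row = summarize_metrics([self._record("a", 0.8)]).iloc[0]
        assert row["dice_sd"] == 0.0 and row["dice_n"] == 1

    def test_missing_msd_excluded_and_counted(self):
        records = [self._record("a", 0.8), self._record("b", 0.9, msd=None)]
        row = summarize_metrics(records).iloc[0]
        assert row["msd_mm_mean"] == pytest.approx(0.5)
        assert row["msd_mm_n"] == 1 and row["msd_missing"] == 1

    def test_matches_streaming_oracle(self):
        """Mean/SD of 50 simulated records vs a Welford accumulator."""
        rng = np.random.default_rng(7)
        values = rng.uniform(0.3, 1.0, size=50)
        records = [self._record(f"c{i}", float(v)) for i, v in enumerate(values)]
        # Welford streaming mean/variance
        mean = m2 = 0.0
        for i, v in enumerate(values, start=1):
            delta = v - mean
            mean += delta / i
            m2 += delta * (v - mean)
        sd = math.sqrt(m2 / (len(values) - 1))
        row = summarize_metrics(records).iloc[0]
        assert row["dice_mean"] == pytest.approx(mean, abs=1e-12)
        assert row["dice_sd"] == pytest.approx(sd, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_metrics([])


class TestCsvRoundTrip:
    def test_missing_msd_serialises_as_empty_cell(self, tmp_path, rng_volume_pair):
        from segsat import make_phantom

        vol = make_phantom()
        empty = LabelVolume(np.zeros_like(vol.voxels), vol.spacing)
        records = evaluate_case(vol, empty, LabelMap(), "c1")
        path = tmp_path / "m.csv"
        metrics_to_csv(records, path)
        back = metrics_from_csv(path)
        assert back == records
        # the msd cell for the empty prediction really is empty text
        lines = path.read_text().splitlines()
        assert any(",,," in line or ",," in line for line in lines[1:])
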