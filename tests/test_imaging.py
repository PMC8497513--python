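"""Imaging statistics: PCC, masks, variance, partition, phase diagrams."""

import numpy as np
import pandas as pd
import pytest

from recolorpoly import (
    CellPhaseRecord,
    ChannelImage,
    RegionMasks,
    VarianceTrace,
    analysis_mask,
    assemble_phase_diagram,
    normalize_trace,
    partition_coefficient,
    pearson_cc,
    pixel_variance,
    region_mean_trace,
    variance_integral,
)


def pearson_double_loop(x, y, mask):
    """Literal two-pass, double-loop evaluation of the correlation formula."""
    xs, ys, n = 0.0, 0.0, 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                xs += x[i, j]
                ys += y[i, j]
                n += 1
    xbar, ybar = xs / n, ys / n
    num, dx2, dy2 = 0.0, 0.0, 0.0
    for i in range(h):
        for j in range(w):
            if mask[i, j]:
                num += (x[i, j] - xbar) * (y[i, j] - ybar)
                dx2 += (x[i, j] - xbar) ** 2
                dy2 += (y[i, j] - ybar) ** 2
    return num / np.sqrt(dx2) / np.sqrt(dy2)


def _img(arr):
    return ChannelImage(np.asarray(arr, dtype=float))


class TestPearson:
    def test_perfect_correlation_and_anticorrelation(self, rng):
        x = rng.uniform(0, 100, size=(16, 16))
        mask = np.ones((16, 16), bool)
        assert pearson_cc(_img(x), _img(x), mask) == pytest.approx(1.0)
        assert pearson_cc(_img(x), _img(200.0 - x), mask) == pytest.approx(-1.0)

    def test_hand_worked_four_pixel_example(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([[0.0, 1.0], [0.0, 1.0]])
        mask = np.ones((2, 2), bool)
        assert pearson_cc(_img(x), _img(y), mask) == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_loop_oracle_on_random_masked_images(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 1000, size=(24, 24))
            y = rng.uniform(0, 1000, size=(24, 24))
            mask = rng.random((24, 24)) < 0.6
            got = pearson_cc(_img(x), _img(y), mask)
            assert got == pytest.approx(pearson_double_loop(x, y, mask), abs=1e-12)
            assert -1.0 <= got <= 1.0

    def test_affine_rescaling_invariance(self, rng):
        x = rng.uniform(0, 100, size=(20, 20))
        y = rng.uniform(0, 100, size=(20, 20))
        mask = np.ones((20, 20), bool)
        base = pearson_cc(_img(x), _img(y), mask)
        assert pearson_cc(_img(3.7 * x + 12.0), _img(y), mask) == pytest.approx(base)
        assert pearson_cc(_img(x), _img(0.2 * y + 5.0), mask) == pytest.approx(base)

    def test_constant_channel_rejected(self):
        mask = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            pearson_cc(_img(np.ones((4, 4))), _img(np.arange(16.0).reshape(4, 4)), mask)


class TestAnalysisMask:
    def _masks(self):
        nucleus = np.zeros((10, 10), bool)
        nucleus[1:9, 1:9] = True
        nucleoli = np.zeros((10, 10), bool)
        nucleoli[2:4, 2:4] = True
        xi = np.zeros((10, 10), bool)
        xi[6:8, 6:8] = True
        return RegionMasks(nucleus=nucleus, nucleoli=nucleoli, xi=xi)

    def test_colocalization_excludes_nucleoli_and_xi(self):
        masks = self._masks()
        out = analysis_mask(masks, "colocalization")
        assert out.sum() == 64 - 4 - 4
        assert not (out & masks.nucleoli).any() and not (out & masks.xi).any()

    def test_coexpression_keeps_xi(self):
        masks = self._masks()
        out = analysis_mask(masks, "coexpression")
        assert (out & masks.xi).sum() == 4
        assert out.sum() == 64 - 4

    def test_variance_mode_matches_coexpression_region(self):
        masks = self._masks()
        np.testing.assert_array_equal(
            analysis_mask(masks, "variance"), analysis_mask(masks, "coexpression")
        )

    def test_empty_regions_and_unknown_mode(self):
        masks = self._masks()
        with pytest.raises(ValueError):
            analysis_mask(masks, "mystery")
        empty = RegionMasks(nucleus=np.zeros((5, 5), bool))
        with pytest.raises(ValueError):
            analysis_mask(empty, "colocalization")

    def test_mask_invariants_enforced(self):
        nucleus = np.zeros((5, 5), bool)
        nucleus[1:3, 1:3] = True
        bad = np.zeros((5, 5), bool)
        bad[4, 4] = True
        with pytest.raises(ValueError):
            RegionMasks(nucleus=nucleus, nucleoli=bad)


class TestPixelVariance:
    def test_constant_region_is_zero(self):
        img = _img(np.full((6, 6), 7.0))
        assert pixel_variance(img, np.ones((6, 6), bool)) == 0.0

    @pytest.mark.parametrize(
        "values, expected",
        [([0.0, 2.0], 2.0), ([1.0, 2.0, 3.0], 1.0)],
    )
    def test_hand_worked_sample_variance(self, values, expected):
        arr = np.zeros((1, len(values)))
        arr[0] = values
        mask = np.ones_like(arr, bool)
        assert pixel_variance(_img(arr), mask) == pytest.approx(expected)

    def test_matches_two_pass_formula(self, rng):
        arr = rng.uniform(0, 500, size=(30, 30))
        mask = rng.random((30, 30)) < 0.5
        vals = arr[mask]
        mu = vals.mean()
        expected = np.sum((vals - mu) ** 2) / (len(vals) - 1)
        assert pixel_variance(_img(arr), mask) == pytest.approx(expected, abs=1e-10)

    def test_single_pixel_rejected(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            pixel_variance(_img(np.ones((3, 3))), mask)


class TestTraces:
    def test_minmax_normalization_values(self):
        trace = VarianceTrace(times=np.arange(4.0), values=np.array([2.0, 5, 8, 14]))
        out = normalize_trace(trace)
        np.testing.assert_allclose(out.values, [0.0, 0.25, 0.5, 1.0])
        assert out.normalized

    def test_normalization_idempotent_and_spans_unit_interval(self, rng):
        trace = VarianceTrace(times=np.arange(20.0), values=rng.uniform(1, 9, 20))
        once = normalize_trace(trace)
        twice = normalize_trace(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert once.values.min() == 0.0 and once.values.max() == 1.0

    def test_constant_trace_rejected(self):
        trace = VarianceTrace(times=np.arange(3.0), values=np.full(3, 2.0))
        with pytest.raises(ValueError):
            normalize_trace(trace)

    def test_integral_of_unit_trace_equals_elapsed_time(self):
        trace = VarianceTrace(times=np.linspace(0, 7.0, 50), values=np.ones(50))
        out = variance_integral(trace)
        assert out.values[0] == 0.0
        assert out.values[-1] == pytest.approx(7.0)

    def test_integral_nondecreasing_for_nonnegative_traces(self, rng):
        trace = VarianceTrace(times=np.arange(30.0), values=rng.uniform(0, 4, 30))
        out = variance_integral(trace)
        assert np.all(np.diff(out.values) >= -1e-12)
        zero = variance_integral(
            VarianceTrace(times=np.arange(5.0), values=np.zeros(5))
        )
        assert np.all(zero.values == 0.0)

    def test_unordered_times_rejected(self):
        trace = VarianceTrace(times=np.array([0.0, 2.0, 1.0]), values=np.ones(3))
        with pytest.raises(ValueError):
            variance_integral(trace)


class TestPartitionCoefficient:
    def _build(self, xi_vals, other_vals):
        n = len(xi_vals) + len(other_vals)
        arr = np.zeros((1, n))
        arr[0, : len(xi_vals)] = xi_vals
        arr[0, len(xi_vals):] = other_vals
        xi = np.zeros((1, n), bool)
        xi[0, : len(xi_vals)] = True
        nucleus = np.ones((1, n), bool)
        return _img(arr), xi, nucleus

    def test_balanced_regions_give_unity(self):
        img, xi, nucleus = self._build([90, 110], [95, 105, 80, 120])
        assert partition_coefficient(img, xi, nucleus) == pytest.approx(1.0)

    def test_twofold_enrichment(self):
        img, xi, nucleus = self._build([90, 110, 100, 100], [40, 60, 50, 50, 45, 55])
        assert partition_coefficient(img, xi, nucleus) == pytest.approx(2.0)

    def test_uniform_image_and_scaling_invariance(self, rng):
        arr = np.full((8, 8), 37.0)
        xi = np.zeros((8, 8), bool)
        xi[2:4, 2:4] = True
        nucleus = np.ones((8, 8), bool)
        assert partition_coefficient(_img(arr), xi, nucleus) == pytest.approx(1.0)
        noisy = rng.uniform(10, 90, size=(8, 8))
        a = partition_coefficient(_img(noisy), xi, nucleus)
        b = partition_coefficient(_img(5.5 * noisy), xi, nucleus)
        assert a == pytest.approx(b)

    def test_empty_region_rejected(self):
        img, xi, nucleus = self._build([90], [100])
        with pytest.raises(ValueError):
            partition_coefficient(img, np.zeros_like(xi), nucleus)


class TestRegionTrace:
    def test_constant_stack_and_single_frame_mean(self):
        region = np.zeros((2, 2), bool)
        region[0] = True
        stack = [_img([[1.0, 3.0], [9.0, 9.0]])] * 4
        trace = region_mean_trace(stack, region)
        np.testing.assert_allclose(trace.values, 2.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_mean_trace([_img(np.ones((2, 2)))], np.zeros((2, 2), bool))


class TestPhaseDiagram:
    def test_empty_and_single_record(self):
        assert len(assemble_phase_diagram([])) == 0
        table = assemble_phase_diagram(
            [CellPhaseRecord(core_conc=0.1, sspb_conc=1.2, phase_separated=True)]
        )
        assert len(table) == 1
        assert table.loc[0, "valence"] == pytest.approx(12.0)

    def test_disagreement_rows_are_dropped(self):
        records = [
            CellPhaseRecord(0.1, 1.0, True, "a"),
            CellPhaseRecord(0.2, 1.0, False, "b"),
            CellPhaseRecord(0.3, 1.0, None, "c"),  # observers disagreed
        ]
        table = assemble_phase_diagram(records)
        assert list(table["cell_id"]) == ["a", "b"]

    def test_valence_consistency_enforced(self):
        with pytest.raises(ValueError):
            CellPhaseRecord(core_conc=0.1, sspb_conc=1.0, phase_separated=True,
                            valence=3.0)
        rec = CellPhaseRecord(core_conc=0.1, sspb_conc=1.0, phase_separated=True,
                              valence=10.0)
        assert rec.valence == pytest.approx(10.0)
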