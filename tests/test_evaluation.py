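"""Event-level metrics, Bland-Altman agreement, and cross-validation."""

import dataclasses

import numpy as np
import pytest

from bcgbeat import (EventSeries, KernelSpec, ModelConfig, SimConfig,
                     bland_altman, heart_rate, hr_mae, ibi_mae, make_dataset,
                     nad_sym)
from bcgbeat.evaluation import (METRIC_COLUMNS, PipelineSettings, evaluate_dsp,
                                grid_search, grouped_cv, hr_table)


def beat_train(mean_ibi=1.0, duration=120.0, start=1.0):
    return EventSeries(np.arange(start, duration, mean_ibi))


class TestHeartRate:
    def test_sixty_bpm(self):
        assert heart_rate(beat_train(1.0), 0, 60) == pytest.approx(60.0)

    def test_point_nine_two(self):
        assert heart_rate(beat_train(0.92), 0, 64) == pytest.approx(60 / 0.92, rel=1e-6)

    def test_undefined_sentinel(self):
        assert np.isnan(heart_rate(EventSeries([5.0]), 0, 64))
        assert np.isnan(heart_rate(beat_train(1.0), 3.2, 4.5))


class TestHrMae:
    def test_perfect_detection(self):
        ref = beat_train(1.0, 256.0)
        mae, _ = hr_mae(ref, ref, [0, 64, 128], 64.0, 64.0)
        assert mae == 0.0

    def test_every_second_beat_missed(self):
        ref = beat_train(1.0, 256.0)
        det = EventSeries(ref.times[::2])
        mae, _ = hr_mae(det, ref, [0, 64, 128], 64.0, 64.0)
        assert mae == pytest.approx(30.0, abs=0.5)

    def test_shift_invariance(self):
        """A uniform 50 ms detection delay leaves interval-based HR alone."""
        ref = beat_train(0.92, 256.0)
        det = ref.shift(0.05)
        mae, _ = hr_mae(det, ref, [0, 64, 128], 64.0, 8.0)
        assert mae < 0.6  # only boundary-crossing beats contribute


class TestNadSym:
    def test_zero_on_identical(self):
        ref = beat_train(0.92)
        assert nad_sym(ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_removed(self):
        ref = beat_train(0.92)
        assert nad_sym(ref.shift(0.05), ref) < 2.0

    def test_gaussian_jitter_folded_normal(self):
        """20 ms Gaussian jitter gives E|N(0,20ms)| = 20*sqrt(2/pi) ~ 16 ms."""
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            base = np.arange(1.0, 400.0, 0.92)
            jit = np.sort(base + rng.normal(0, 0.02, base.size))
            vals.append(nad_sym(EventSeries(jit), EventSeries(base)))
        expected = 20.0 * np.sqrt(2 / np.pi)
        assert np.mean(vals) == pytest.approx(expected, abs=2.0)


class TestIbiMae:
    def test_zero_on_identical(self):
        ref = beat_train(0.92)
        assert ibi_mae(ref, ref) == pytest.approx(0.0, abs=1e-6)

    def test_constant_shift(self):
        ref = beat_train(0.92)
        assert ibi_mae(ref.shift(0.3), ref) < 1.0

    def test_single_deletion_localized(self):
        """A missed beat doubles one interval; the step-function comparison
        confines the error to the grid points inside that interval."""
        ref = beat_train(1.0, 120.0)
        det_times = np.delete(ref.times, 60)
        det = EventSeries(det_times)
        got = ibi_mae(det, ref)
        # independent brute force on the 1 Hz grid
        lo = max(det.times[1], ref.times[1])
        hi = min(det.times[-1], ref.times[-1])
        grid = np.arange(np.ceil(lo), np.floor(hi) + 1)

        def step(times, g):
            i = np.clip(np.searchsorted(times, g), 1, len(times) - 1)
            return times[i] - times[i - 1]

        expected = np.mean(np.abs(step(det.times, grid) - step(ref.times, grid))) * 1e3
        assert got == pytest.approx(expected, abs=1.0)
        # sanity: roughly 2 affected grid points of ~1000 ms error each
        assert 0 < got < 3 * 2000.0 / grid.size

    def test_too_short_overlap_rejected(self):
        a = EventSeries([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="overlap"):
            ibi_mae(a, a)


class TestBlandAltman:
    def test_zero_residuals(self):
        pairs = np.column_stack([np.full(5, 60.0), np.full(5, 60.0)])
        stats = bland_altman(pairs)
        assert stats.bias == 0.0
        assert stats.loa_low == stats.loa_high == 0.0

    def test_two_point_closed_form(self):
        pairs = np.array([[61.0, 62.0], [61.0, 60.0]])  # residuals -1, +1
        stats = bland_altman(pairs)
        sd = np.std([-1.0, 1.0], ddof=1)  # sqrt(2)
        assert stats.bias == pytest.approx(0.0)
        assert stats.loa_high == pytest.approx(1.96 * sd)
        assert stats.loa_low == pytest.approx(-1.96 * sd)

    def test_missed_beats_quantized_residuals(self):
        """Whole missed beats produce discrete residual bands (8-s windows)."""
        ref = beat_train(1.0, 400.0)
        det_times = np.delete(ref.times, np.arange(10, 390, 25))
        tab = hr_table(EventSeries(det_times), ref,
                       np.arange(0, 384, 64.0), 64.0, 8.0)
        stats = bland_altman(tab)
        nonzero = stats.residuals[np.abs(stats.residuals) > 0.5]
        assert nonzero.size > 5
        assert np.all(np.abs(nonzero - np.median(nonzero)) < 2.0)
        assert np.median(nonzero) > 5.0  # one beat of 8 missing is > 5 bpm


TINY_MODEL = ModelConfig(arch="cnn", cnn_channels=(8, 8, 1), cnn_kernels=(5, 17, 33),
                         epochs=4, lr=1e-3, batch_size=8, seed=0)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset(SimConfig(n_subjects=4, night_duration=200.0, seed=5))


TINY_SETTINGS = PipelineSettings(train_stride_s=32.0, sync_segment_s=100.0)


class TestGroupedCv:
    def test_each_subject_validated_once_and_deterministic(self, tiny_dataset):
        reports = [
            grouped_cv(tiny_dataset, TINY_MODEL, KernelSpec("triangular", 0.8),
                       n_folds=2, settings=TINY_SETTINGS)
            for _ in range(2)
        ]
        for report in reports:
            counts = report.per_night.groupby("subject_id").size()
            assert sorted(counts.index) == ["s00", "s01", "s02", "s03"]
            assert (counts == 1).all()
        a, b = reports
        assert a.aggregates == b.aggregates

    def test_single_subject_requires_ungrouped(self, tiny_dataset):
        one = [n for n in tiny_dataset if n.subject_id == "s00"]
        with pytest.raises(ValueError, match="grouped"):
            grouped_cv(one, TINY_MODEL, KernelSpec("triangular", 0.8))

    def test_ungrouped_fits_no_worse_than_grouped(self, tiny_dataset):
        """Validating on seen subjects cannot be harder than on unseen ones."""
        kernel = KernelSpec("triangular", 0.8)
        grouped = grouped_cv(tiny_dataset, TINY_MODEL, kernel, n_folds=2,
                             settings=TINY_SETTINGS)
        with pytest.warns(UserWarning, match="intra-subject"):
            ungrouped = grouped_cv(tiny_dataset, TINY_MODEL, kernel,
                                   settings=TINY_SETTINGS, grouped=False)
        assert np.mean(ungrouped.fold_final_val_mse) <= np.mean(
            grouped.fold_final_val_mse) * 1.05

    def test_report_table_schema(self, tiny_dataset):
        report = evaluate_dsp(tiny_dataset, TINY_SETTINGS)
        table = report.render_table()
        for col in METRIC_COLUMNS:
            assert col in table
        assert "±" in table


class TestGridSearch:
    def test_grid_of_one_matches_single_cv(self, tiny_dataset):
        kernel = KernelSpec("triangular", 0.8)
        table = grid_search(tiny_dataset, [kernel], TINY_MODEL,
                            settings=TINY_SETTINGS, n_folds=2)
        single = grouped_cv(tiny_dataset, TINY_MODEL, kernel, n_folds=2,
                            settings=TINY_SETTINGS)
        assert len(table) == 1
        assert table.loc[0, "hr_mae_64"] == pytest.approx(
            single.aggregates["hr_mae_64"]["mean"])

    def test_row_per_grid_point(self, tiny_dataset):
        grid = [KernelSpec("triangular", 0.4), KernelSpec("triangular", 0.8),
                KernelSpec("rectangular", 0.8)]
        table = grid_search(tiny_dataset, grid, TINY_MODEL,
                            settings=TINY_SETTINGS, n_folds=2, epochs=1)
        assert len(table) == 3
        assert set(table["kernel_shape"]) == {"triangular", "rectangular"}
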