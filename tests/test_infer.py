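"""SNPI traces, pain-group mapping, timelines, and evaluation metrics."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from painrank import infer, nn
from painrank.infer import (
    GroupThresholds, build_timeline, calibrate_thresholds,
    evaluate_predictions, mae, map_to_group, pcc, rank_match, snpi_trace,
)
from painrank.pspi import PainGroup


@pytest.fixture(scope="module")
def model():
    return nn.init_model(nn.BranchSpec(n_conv_layers=3), seed=0)


class TestSnpiTrace:
    def test_constant_sequence_is_all_zero(self, model):
        frames = np.tile(np.linspace(0, 1, 64 * 64).reshape(64, 64), (5, 1, 1))
        np.testing.assert_allclose(snpi_trace(model, frames), 0.0, atol=1e-12)

    def test_reference_frame_value_is_zero(self, model, rng):
        frames = rng.random((6, 64, 64))
        assert snpi_trace(model, frames)[0] == 0.0
        assert snpi_trace(model, frames, reference=3)[3] == 0.0

    def test_causality_under_appended_frames(self, model, rng):
        frames = rng.random((8, 64, 64))
        full = snpi_trace(model, frames)
        truncated = snpi_trace(model, frames[:5])
        # values agree to numerical precision (batched BLAS reductions may
        # differ in the last bits between batch shapes)
        np.testing.assert_allclose(full[:5], truncated, rtol=1e-12, atol=1e-12)

    def test_previous_frame_delta_variant(self, model, rng):
        frames = rng.random((4, 64, 64))
        d = snpi_trace(model, frames, reference="previous")
        assert d[0] == 0.0
        emb = nn.embed(model, frames)
        assert d[2] == pytest.approx(np.linalg.norm(emb[2] - emb[1]))

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            snpi_trace(model, np.empty((0, 64, 64)))


class TestGroupMapping:
    thresholds = GroupThresholds((0.2, 0.4, 0.6, 0.8))

    def test_zero_snpi_is_pg1(self):
        assert map_to_group(np.array([0.0]), self.thresholds) == [PainGroup.PG1]

    def test_tie_at_cut_goes_up(self):
        assert map_to_group(np.array([0.4]), self.thresholds) == [PainGroup.PG3]

    def test_monotone_trace_gives_nondecreasing_groups(self):
        groups = map_to_group(np.linspace(0, 1, 21), self.thresholds)
        assert all(b.value >= a.value for a, b in zip(groups, groups[1:]))

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GroupThresholds((0.4, 0.2, 0.6, 0.8))

    def test_quantile_calibration_on_uniform_sample(self, rng):
        traces = [rng.random(500) for _ in range(4)]
        cuts = calibrate_thresholds(traces).cuts
        np.testing.assert_allclose(cuts, [0.2, 0.4, 0.6, 0.8], atol=0.03)

    def test_calibration_invariant_to_trace_order(self, rng):
        traces = [rng.random(100) for _ in range(3)]
        assert calibrate_thresholds(traces).cuts == calibrate_thresholds(traces[::-1]).cuts

    def test_degenerate_calibration_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            calibrate_thresholds([np.ones(10), np.ones(5)])


class TestTimeline:
    def test_single_group_single_segment(self):
        tl = build_timeline([PainGroup.PG1] * 6, frame_rate=3.0)
        assert len(tl.segments) == 1 and not tl.transitions
        assert tl.segments[0].duration_s == pytest.approx(2.0)

    def test_two_block_worked_example(self):
        groups = [PainGroup.PG1] * 4 + [PainGroup.PG3] * 4
        tl = build_timeline(groups, frame_rate=4.0, transition_interval_s=0.5)
        assert [(s.group, s.onset_s, s.duration_s) for s in tl.segments] == [
            (PainGroup.PG1, 0.0, 1.0), (PainGroup.PG3, 1.5, 1.0)]
        assert tl.transitions == [(PainGroup.PG1, PainGroup.PG3, 1.0)]
        assert tl.total_duration_s == pytest.approx(2.5)

    def test_transition_count_equals_group_changes(self, rng):
        groups = [PainGroup(int(v)) for v in rng.integers(1, 6, size=40)]
        tl = build_timeline(groups, frame_rate=4.0)
        changes = sum(a != b for a, b in zip(groups, groups[1:]))
        assert len(tl.transitions) == changes

    def test_rle_idempotence(self):
        groups = [PainGroup.PG2] * 3 + [PainGroup.PG5] * 2 + [PainGroup.PG2] * 4
        tl = build_timeline(groups, frame_rate=1.0)
        re_groups = [s.group for s in tl.segments for _ in range(int(s.duration_s))]
        tl2 = build_timeline(re_groups, frame_rate=1.0)
        assert [(s.group, s.duration_s) for s in tl.segments] == \
               [(s.group, s.duration_s) for s in tl2.segments]

    def test_nonpositive_frame_rate_rejected(self):
        with pytest.raises(ValueError):
            build_timeline([PainGroup.PG1], frame_rate=0.0)

    def test_json_export(self):
        tl = build_timeline([PainGroup.PG1, PainGroup.PG3], frame_rate=2.0)
        data = json.loads(tl.to_json())
        assert data["segments"][1]["group"] == "PG3"


def oracle_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))


class TestMetrics:
    def test_perfect_and_anti_correlation(self):
        a = np.array([1.0, 2.0, 5.0])
        assert pcc(a, a) == pytest.approx(1.0)
        assert mae(a, a) == 0.0
        assert pcc(a, -a) == pytest.approx(-1.0)

    def test_worked_example_matches_formula_oracle(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 7.0]
        assert pcc(a, b) == pytest.approx(oracle_pearson(a, b), rel=1e-12)
        assert mae(a, b) == pytest.approx((1 + 2 + 4) / 3, rel=1e-12)

    def test_random_vectors_match_oracle(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert pcc(a, b) == pytest.approx(oracle_pearson(a, b), rel=1e-12)
        assert mae(a, b) == pytest.approx(float(np.abs(a - b).mean()), rel=1e-12)

    def test_zero_variance_pcc_rejected(self):
        with pytest.raises(ValueError):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEvaluation:
    labels = np.array([0, 0, 1, 2, 3, 5, 7, 9], dtype=float)

    def test_perfect_oracle_predictor(self):
        report = evaluate_predictions(self.labels, self.labels)
        assert report.pcc == pytest.approx(1.0)
        assert report.mae == 0.0
        conf = report.confusion
        assert (conf.to_numpy().sum(axis=1) == np.diag(conf)).all()

    def test_constant_predictor_exercises_pcc_error_and_mae(self):
        with pytest.raises(ValueError):
            evaluate_predictions(np.full_like(self.labels, 2.0), self.labels)
        assert mae(np.full_like(self.labels, 2.0), self.labels) == \
            pytest.approx(np.abs(self.labels - 2.0).mean())

    def test_confusion_row_sums_equal_class_counts(self, rng):
        preds = rng.random(self.labels.size)
        report = evaluate_predictions(preds, self.labels)
        counts = pd.Series([infer.bin_pain_state(int(v)).value for v in self.labels]).value_counts()
        for state, n in counts.items():
            assert report.confusion.loc[state].sum() == n

    def test_rank_match_is_monotone_rescaling(self, rng):
        preds = rng.normal(size=30)
        labels = rng.integers(0, 16, size=30).astype(float)
        out = rank_match(preds, labels)
        assert sorted(out) == sorted(labels)
        order = np.argsort(preds, kind="stable")
        assert (np.diff(out[order]) >= 0).all()

    def test_end_to_end_evaluation_on_corpus(self, corpus, trained):
        report = infer.evaluate(trained["model"], corpus["manifest"],
                                frames=corpus["frames"])
        assert -1 <= report.pcc <= 1 and report.mae >= 0
        assert report.confusion.to_numpy().sum() == len(corpus["manifest"])
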