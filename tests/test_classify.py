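"""Classifier tests: similarity measures, the two-step decision rule, rhythm
fallback, template update rule, segment and long-term paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvckit.classify import (MatchScores, RhythmContext, ardiff,
                             classify_segment, covr, endiff, match_scores,
                             needs_template_update, rhythmic_rule,
                             step1_match, step2_resolve)
from pvckit.classify import SegmentResult
from pvckit.config import PipelineConfig
from pvckit.autoencoder import AEConfig
from pvckit.io import ECGRecord
from pvckit.synthetic import SynthConfig, generate_record
from pvckit.templates import Template


class TestSimilarityMeasures:
    def test_covr_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 0.5, 3.0])
        assert covr(x, x) == pytest.approx(1.0)
        assert covr(x, -x) == pytest.approx(-1.0)

    def test_covr_hand_value(self):
        # numerator 3, denominator sqrt(2)*sqrt(14/3)
        assert covr([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-4)

    def test_covr_constant_convention_and_symmetry(self):
        assert covr(np.ones(5), np.arange(5.0)) == 0.0
        x, y = np.array([1.0, 4.0, 2.0]), np.array([0.5, 1.0, 3.0])
        assert covr(x, y) == pytest.approx(covr(y, x))

    def test_ardiff_values(self):
        tw = np.array([1.0, 1.0, 1.0])
        assert ardiff(tw, tw) == 0.0
        assert ardiff(2 * tw, tw) == pytest.approx(100.0)
        assert ardiff([1.0, -1.0, 1.0], tw) == 0.0  # absolute sums equal

    def test_endiff_values(self):
        tw = np.array([1.0, 2.0])
        assert endiff(tw, tw) == 0.0
        assert endiff(np.zeros(2), tw) == pytest.approx(1.0)
        assert endiff([1.0, 1.0], [1.0, 2.0]) == pytest.approx(0.2)

    def test_zero_template_rejected(self):
        with pytest.raises(ValueError):
            ardiff([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            endiff([1.0, 1.0], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        for fn in (covr, ardiff, endiff):
            with pytest.raises(ValueError):
                fn([1.0, 2.0], [1.0, 2.0, 3.0])


class TestStepOneRule:
    @pytest.mark.parametrize("scores,expected", [
        ((0.95, 20.0, 5.0), True),    # first disjunct alone
        ((0.90, 99.0, 99.0), True),   # boundary: Covr >= 0.9 inclusive
        ((0.85, 5.0, 0.5), True),     # second disjunct
        ((0.85, 12.0, 0.5), False),   # ArDiff too large
        ((0.85, 5.0, 1.0), False),    # EnDiff boundary is strict
        ((0.85, 10.0, 0.5), False),   # ArDiff boundary is strict
        ((0.80, 0.0, 0.0), True),     # Covr lower bound inclusive
        ((0.79, 0.0, 0.0), False),
    ])
    def test_decision_table(self, scores, expected):
        assert step1_match(MatchScores(*scores)) is expected

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(0, 30),
           st.floats(0, 3))
    def test_monotone_in_covr(self, c1, c2, ar, en):
        lo, hi = sorted((c1, c2))
        if step1_match(MatchScores(lo, ar, en)):
            assert step1_match(MatchScores(hi, ar, en))


class TestRhythmRule:
    @pytest.mark.parametrize("pre,post,expected", [
        (0.7, 1.3, True),    # premature + compensatory pause
        (1.0, 1.0, False),   # on-time beat
        (0.7, 0.8, False),   # premature but no pause (interpolated)
    ])
    def test_cases(self, pre, post, expected):
        ctx = RhythmContext(rr_pre=pre, rr_post=post, rr_local=1.0)
        assert rhythmic_rule(ctx) is expected


class TestStepTwo:
    def _templates(self):
        t = np.linspace(0, 2 * np.pi, 50)
        sinus = Template(tw=np.sin(t), type="Non_PVC")
        ectopic = Template(tw=np.cos(t) * 2, type="PVC")
        return sinus, ectopic

    def test_adopts_type_of_best_matching_template(self):
        sinus, ectopic = self._templates()
        hw = ectopic.tw + 0.01  # near-perfect PVC-template match
        ctx = RhythmContext(1.0, 1.0, 1.0)
        label, prov, _ = step2_resolve(hw, [sinus, ectopic], ctx)
        assert label == "PVC" and prov == "step2_template"

    def test_higher_covr_wins_between_matching_templates(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 50))
        a = Template(tw=base, type="Non_PVC")
        b = Template(tw=base * 1.02, type="PVC")
        # hw correlates ~1 with both; tie broken by covr then endiff
        label, prov, _ = step2_resolve(base * 1.02, [a, b],
                                       RhythmContext(1.0, 1.0, 1.0))
        assert prov == "step2_template"
        assert label == "PVC"

    def test_rhythm_fallback_when_no_template_matches(self):
        sinus, ectopic = self._templates()
        rng = np.random.default_rng(0)
        hw = rng.normal(size=50)  # matches nothing
        pvc_ctx = RhythmContext(0.6, 1.4, 1.0)
        sin_ctx = RhythmContext(1.0, 1.0, 1.0)
        assert step2_resolve(hw, [sinus, ectopic], pvc_ctx)[0] == "PVC"
        label, prov, _ = step2_resolve(hw, [sinus, ectopic], sin_ctx)
        assert label == "Non_PVC" and prov == "step2_rhythm"

    def test_empty_template_list_rejected(self):
        with pytest.raises(ValueError):
            step2_resolve(np.ones(5), [], RhythmContext(1, 1, 1))


class TestTemplateUpdateRule:
    def _result(self, unknown, dom_covr):
        return SegmentResult(np.empty(0, int), [], [], np.empty(0), [],
                             step1_unknown_frac=unknown,
                             dominant_mean_covr=dom_covr)

    @pytest.mark.parametrize("unknown,covr_,expected", [
        (0.02, 0.96, False),
        (0.15, 0.96, True),
        (0.05, 0.85, True),
    ])
    def test_update_rule(self, unknown, covr_, expected):
        assert needs_template_update(self._result(unknown, covr_)) is expected


@pytest.fixture(scope="module")
def segment_run(short_record):
    record, truth, cfg = short_record
    pc = PipelineConfig(ae=AEConfig(epochs=50, seed=7))
    return classify_segment(record, None, pc), record, truth, pc


class TestClassifySegment:
    def test_every_beat_labelled_once_with_known_provenance(self, segment_run):
        res, record, truth, _ = segment_run
        assert len(res.labels) == len(res.r_samples) == len(res.provenance)
        assert set(res.provenance) <= {"step1", "step2_template",
                                       "step2_rhythm", "unscored"}
        assert set(res.labels) <= {"PVC", "Non_PVC"}

    def test_recovers_most_pvcs(self, segment_run):
        res, record, truth, _ = segment_run
        from pvckit.evaluation import compute_metrics, match_beats
        c = match_beats(res.r_samples, res.labels, truth.r_samples,
                        truth.labels, record.fs)
        m = compute_metrics(c)
        assert m.se >= 90.0 and m.pplus >= 90.0

    def test_deterministic_rerun(self, segment_run):
        res, record, truth, pc = segment_run
        res2 = classify_segment(record, None, pc)
        np.testing.assert_array_equal(res.r_samples, res2.r_samples)
        assert res.labels == res2.labels
        assert res.provenance == res2.provenance

    def test_reused_templates_path(self, segment_run):
        res, record, truth, pc = segment_run
        res2 = classify_segment(record, res.templates, pc, scale=res.scale)
        assert not res2.updated
        agree = np.mean([a == b for a, b in zip(res.labels, res2.labels)])
        assert agree > 0.98
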