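"""Exact-match metrics, MAEs, bootstrap and significance."""

import numpy as np
import pytest

from szfreq import (
    AnnotatedSegment,
    AttributeSet,
    AttributeSpan,
    AttributeType,
    MatchCounts,
    PhraseSet,
    RateMaeMetric,
    Span,
    SpanMatchMetric,
    StructuredFrequency,
    Sudep7MaeMetric,
    bootstrap,
    mae_rates,
    mae_sudep7,
    match_spans,
    match_structured,
    no_frequency_detection,
    prf,
    significance,
)
from szfreq.baseline import GoldReplayExtractor, apply_extractor
from szfreq.synthetic import GeneratorConfig, generate

T = AttributeType


class TestMatchSpans:
    def test_exact_match_counts(self, worked_phrases):
        counts = match_spans(worked_phrases, worked_phrases, typed=False)
        assert counts == MatchCounts(2, 2, 2)

    def test_boundary_mismatch_is_no_match(self):
        gold = PhraseSet((Span(0, 11),))  # "Few per hour"
        pred = PhraseSet((Span(0, 12),))  # "Few per hour." (with period)
        assert match_spans(pred, gold, typed=False) == MatchCounts(0, 1, 1)

    def test_empty_sets(self):
        assert match_spans(PhraseSet(), PhraseSet(), typed=False) == MatchCounts(0, 0, 0)

    def test_type_must_agree_when_typed(self):
        gold = AttributeSet((AttributeSpan(Span(0, 0), T.QUANTITY, "3"),))
        pred = AttributeSet((AttributeSpan(Span(0, 0), T.DURATION, "3"),))
        assert match_spans(pred, gold, typed=True).true_positive == 0
        assert match_spans(pred, gold, typed=False).true_positive == 1

    def test_symmetry_swaps_precision_and_recall(self, worked_attributes):
        pred = AttributeSet(worked_attributes.spans[:5])
        a = match_spans(pred, worked_attributes)
        b = match_spans(worked_attributes, pred)
        assert (a.predicted_total, a.gold_total) == (b.gold_total, b.predicted_total)
        assert a.true_positive == b.true_positive


class TestPrf:
    def test_printed_no_frequency_detection_numbers(self):
        assert prf(MatchCounts(98, 104, 99)) == (94.23, 98.99, 96.55)

    def test_perfect(self):
        assert prf(MatchCounts(5, 5, 5)) == (100.0, 100.0, 100.0)

    def test_zero_conventions(self):
        assert prf(MatchCounts(0, 0, 3)) == (0.0, 0.0, 0.0)
        assert prf(MatchCounts(0, 3, 0)) == (0.0, 0.0, 0.0)
        assert prf(MatchCounts(0, 0, 0)) == (100.0, 100.0, 100.0)

    def test_f1_zero_iff_tp_zero(self):
        assert prf(MatchCounts(0, 4, 4))[2] == 0.0
        assert prf(MatchCounts(1, 4, 4))[2] > 0.0

    def test_precision_equals_recall_when_totals_equal(self):
        p, r, _ = prf(MatchCounts(3, 7, 7))
        assert p == r


class TestMatchStructured:
    def _freq(self, *spans):
        attrs = tuple(AttributeSpan(Span(s, e), t, "x" * (e - s + 1)) for s, e, t in spans)
        lo = min(a.span.start for a in attrs)
        hi = max(a.span.end for a in attrs)
        return StructuredFrequency(Span(lo, hi), attrs)

    def test_exact_bundles_match(self, worked_phrases, worked_attributes):
        from szfreq import compose

        gold, _ = compose(worked_phrases, worked_attributes)
        assert match_structured(gold, gold) == MatchCounts(2, 2, 2)

    def test_one_attribute_off_by_one_fails_the_bundle(self):
        gold = self._freq((0, 2, T.QUANTITY), (4, 7, T.TEMPORAL_UNIT))
        pred = self._freq((0, 3, T.QUANTITY), (4, 7, T.TEMPORAL_UNIT))
        assert match_structured([pred], [gold]).true_positive == 0

    def test_phrase_boundary_difference_does_not_disqualify(self):
        attrs = (
            AttributeSpan(Span(0, 2), T.QUANTITY, "Few"),
            AttributeSpan(Span(8, 11), T.TEMPORAL_UNIT, "hour"),
        )
        gold = StructuredFrequency(Span(0, 11), attrs)  # "Few per hour"
        pred = StructuredFrequency(Span(0, 12), attrs)  # "Few per hour."
        assert match_structured([pred], [gold]).true_positive == 1
        assert match_structured([pred], [gold], strict_phrase=True).true_positive == 0

    def test_spurious_prediction_increments_total_only(self):
        gold = self._freq((0, 2, T.QUANTITY))
        extra = self._freq((5, 7, T.DURATION))
        counts = match_structured([gold, extra], [gold])
        assert counts == MatchCounts(1, 2, 1)

    def test_each_gold_matches_at_most_one_prediction(self):
        freq = self._freq((0, 2, T.QUANTITY))
        counts = match_structured([freq, freq], [freq])
        assert counts.true_positive == 1


def _seg(seg_id, n_pred_phrases, n_gold_phrases):
    width = 3
    needed = max(n_pred_phrases, n_gold_phrases) * (width + 1)
    text = "x" * max(needed, 1)
    spans = lambda n: PhraseSet(
        tuple(Span(i * (width + 1), i * (width + 1) + width - 1) for i in range(n))
    )
    return AnnotatedSegment(
        id=seg_id,
        text=text,
        gold_phrases=spans(n_gold_phrases),
        gold_attributes=AttributeSet(),
        predicted_phrases=spans(n_pred_phrases),
        predicted_attributes=AttributeSet(),
    )


class TestNoFrequencyDetection:
    def test_counts_match_construction(self):
        # 6 segments: pred empty in 4, gold empty in 3, both empty in 3
        segments = (
            [_seg(f"b{i}", 0, 0) for i in range(3)]
            + [_seg("p", 0, 1)]
            + [_seg("g2", 1, 1), _seg("g3", 2, 2)]
        )
        counts = no_frequency_detection(segments, segments)
        assert counts == MatchCounts(3, 4, 3)

    def test_all_have_frequencies(self):
        segments = [_seg("a", 1, 1), _seg("b", 2, 1)]
        assert no_frequency_detection(segments, segments) == MatchCounts(0, 0, 0)

    def test_model_never_silent_gold_has_empties(self):
        segments = [_seg(str(i), 1, 0) for i in range(10)]
        assert no_frequency_detection(segments, segments) == MatchCounts(0, 0, 10)

    def test_misaligned_lists_error(self):
        with pytest.raises(ValueError):
            no_frequency_detection([_seg("a", 0, 0)], [_seg("b", 0, 0)])


@pytest.fixture(scope="module")
def replayed_corpus():
    segments = generate(GeneratorConfig(size=120, seed=5))
    return apply_extractor(segments, GoldReplayExtractor())


class TestMae:
    def test_identical_extractions_zero(self, replayed_corpus):
        assert mae_rates(replayed_corpus, replayed_corpus, placeholder=0.1) == 0.0
        assert mae_sudep7(replayed_corpus, replayed_corpus, placeholder=0.1) == 0.0

    def test_single_segment_rate_difference(self):
        def seg(q, layer_pred_q):
            text = f"{q} per day, {layer_pred_q} per day"
            gold_attr = AttributeSet((
                AttributeSpan(Span(0, len(q) - 1), T.QUANTITY, q),
                AttributeSpan(Span(len(q) + 5, len(q) + 7), T.TEMPORAL_UNIT, "day"),
            ))
            s = AnnotatedSegment(
                id="m", text=text,
                gold_phrases=PhraseSet((Span(0, len(q) + 7),)),
                gold_attributes=gold_attr,
            )
            off = len(q) + 10  # past " per day, "
            s.predicted_phrases = PhraseSet((Span(off, off + len(layer_pred_q) + 7),))
            s.predicted_attributes = AttributeSet((
                AttributeSpan(Span(off, off + len(layer_pred_q) - 1), T.QUANTITY, layer_pred_q),
                AttributeSpan(
                    Span(off + len(layer_pred_q) + 5, off + len(layer_pred_q) + 7),
                    T.TEMPORAL_UNIT, "day"),
            ))
            return s

        s = seg("0.1", "0.2")
        assert mae_rates([s], [s], placeholder=0) == pytest.approx(0.1)

    def test_wrong_quantity_same_sudep7_contributes_zero(self):
        # "0.5 per month" gold vs "5 per month" predicted: both score 1
        text = "0.5 per month"
        gold = AttributeSet((
            AttributeSpan(Span(0, 2), T.QUANTITY, "0.5"),
            AttributeSpan(Span(8, 12), T.TEMPORAL_UNIT, "month"),
        ))
        pred = AttributeSet((
            AttributeSpan(Span(2, 2), T.QUANTITY, "5"),
            AttributeSpan(Span(8, 12), T.TEMPORAL_UNIT, "month"),
        ))
        seg = AnnotatedSegment(
            id="d", text=text,
            gold_phrases=PhraseSet((Span(0, 12),)), gold_attributes=gold,
            predicted_phrases=PhraseSet((Span(0, 12),)), predicted_attributes=pred,
        )
        assert mae_sudep7([seg], [seg], placeholder=0.0) == 0.0
        assert mae_rates([seg], [seg], placeholder=0.0) > 0  # rates do differ


class TestBootstrap:
    def test_same_seed_bit_identical(self, replayed_corpus):
        metric = SpanMatchMetric(task="attribute")
        a = bootstrap(metric, replayed_corpus, n_trials=200, sample_size=50, seed=9)
        b = bootstrap(metric, replayed_corpus, n_trials=200, sample_size=50, seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.indices, b.indices)
        c = bootstrap(metric, replayed_corpus, n_trials=200, sample_size=50, seed=10)
        assert not np.array_equal(a.indices, c.indices)

    def test_constant_metric_zero_sd(self, replayed_corpus):
        result = bootstrap(
            SpanMatchMetric(task="structured"), replayed_corpus,
            n_trials=100, sample_size=30, seed=0,
        )
        assert result.sd == 0.0 and result.mean == 100.0

    def test_single_trial_on_degenerate_corpus(self):
        seg = generate(GeneratorConfig(size=1, seed=3, freq_count_probs=(0, 1, 0, 0, 0)))
        apply_extractor(seg, GoldReplayExtractor())
        metric = SpanMatchMetric(task="attribute")
        result = bootstrap(metric, seg, n_trials=1, sample_size=1, seed=0)
        assert result.mean == metric(seg)

    def test_callable_slow_path_agrees_with_vectorized(self, replayed_corpus):
        metric = SpanMatchMetric(task="attribute", stat="precision")
        fast = bootstrap(metric, replayed_corpus, n_trials=50, sample_size=20, seed=2)
        slow = bootstrap(
            lambda segs: metric(segs), replayed_corpus,
            n_trials=50, sample_size=20, seed=2,
        )
        assert np.allclose(fast.values, slow.values)

    def test_empty_resample_hits_zero_convention_not_crash(self):
        # all-empty corpus: every resample has zero gold and zero predicted
        segments = generate(GeneratorConfig(size=5, seed=1, freq_count_probs=(1, 0, 0, 0, 0)))
        apply_extractor(segments, GoldReplayExtractor())
        result = bootstrap(
            SpanMatchMetric(task="attribute"), segments, n_trials=20, sample_size=5, seed=0
        )
        assert np.all(result.values == 100.0)

    def test_invalid_parameters(self, replayed_corpus):
        with pytest.raises(ValueError):
            bootstrap(SpanMatchMetric(), replayed_corpus, n_trials=0)


class TestSignificance:
    def test_identical_vectors_not_significant(self):
        v = np.arange(100.0)
        result = significance(v, v)
        assert result.proportion == 0.0 and not result.significant

    def test_uniform_dominance_significant(self):
        v = np.arange(100.0)
        result = significance(v + 1, v)
        assert result.proportion == 1.0 and result.significant

    def test_exactly_95_percent_is_not_significant(self):
        a = np.arange(1000.0)
        b = a.copy()
        b[:950] -= 1  # a > b in exactly 95.0% of trials
        result = significance(a, b)
        assert result.proportion == 0.95 and not result.significant

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            significance(np.zeros(3), np.zeros(4))
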