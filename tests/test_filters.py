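import itertools

import pytest
from hypothesis import given, settings, strategies as st

from fusemble.ensemble import overlap_calls, prioritize, reconcile_breakpoints
from fusemble.filters import (
    REASON_BELOW_CONSENSUS,
    REASON_HIGH_FREQUENCY,
    REASON_LOW_EVIDENCE,
    REASON_READTHROUGH,
    FilterConfig,
    apply_filters,
    is_high_frequency,
    is_low_evidence,
    is_readthrough,
)
from fusemble.freqdb import CohortFrequencyStore
from fusemble.knowledgebase import KnownFusionList
from fusemble.models import CALLERS, ConfigurationError, pair_key

from conftest import make_call

CFG = FilterConfig()
EMPTY_KNOWN = KnownFusionList.from_pairs([])


def _record(
    pair=("A", "B"),
    n_callers=3,
    reads=(10, 10, 10),
    chrom5="1",
    chrom3="2",
    pos5=1_000_000,
    pos3=5_000_000,
    strand5="+",
    strand3="+",
):
    calls = {}
    for caller, r in zip(CALLERS[:n_callers], reads):
        calls[caller] = [
            make_call(
                caller=caller,
                gene5=pair[0],
                gene3=pair[1],
                chrom5=chrom5,
                pos5=pos5,
                strand5=strand5,
                chrom3=chrom3,
                pos3=pos3,
                strand3=strand3,
                reads=r,
            )
        ]
    (record,) = overlap_calls(calls)
    return reconcile_breakpoints(record)


def _store(pair, frequency, denominator=1000):
    store = CohortFrequencyStore()
    n_obs = round(frequency * denominator)
    key = pair_key(*pair)
    for i in range(denominator):
        store.register_sample(f"s{i}", [key] if i < n_obs else [])
    assert store.frequency(key) == pytest.approx(frequency)
    return store


# -- read-through ----------------------------------------------------------


def test_readthrough_same_strand_below_threshold():
    rec = _record(chrom5="1", chrom3="1", pos5=1_000_000, pos3=1_150_000)
    assert is_readthrough(rec, CFG)


def test_readthrough_distance_225kb_retained():
    # intrachromosomal same-strand deletion spanning 225 kb is kept
    rec = _record(chrom5="1", chrom3="1", pos5=156_650_000, pos3=156_875_000)
    assert abs(rec.best_call.pos5 - rec.best_call.pos3) == 225_000
    assert not is_readthrough(rec, CFG)


def test_readthrough_interchromosomal_retained():
    rec = _record(chrom5="8", chrom3="7")
    assert not is_readthrough(rec, CFG)


def test_readthrough_opposite_strand_retained():
    rec = _record(chrom5="1", chrom3="1", pos5=100, pos3=500, strand5="+", strand3="-")
    assert not is_readthrough(rec, CFG)


def test_readthrough_unknown_strand_retained():
    rec = _record(chrom5="1", chrom3="1", pos5=100, pos3=500, strand5=".", strand3=".")
    assert not is_readthrough(rec, CFG)


def test_readthrough_distance_zero_filtered():
    rec = _record(chrom5="1", chrom3="1", pos5=100, pos3=100)
    assert is_readthrough(rec, CFG)


def test_readthrough_exact_threshold_retained():
    rec = _record(chrom5="1", chrom3="1", pos5=1, pos3=200_001)
    assert not is_readthrough(rec, CFG)  # strict: fewer than 200,000


# -- cohort frequency ------------------------------------------------------


def test_high_frequency_above_threshold():
    rec = _record(pair=("EML4", "ALK"))
    store = _store(("EML4", "ALK"), 7 / 22, denominator=22)
    assert store.frequency(rec.key) == pytest.approx(0.318, abs=5e-4)
    assert is_high_frequency(rec, store, CFG)


def test_low_frequency_retained():
    rec = _record()
    assert not is_high_frequency(rec, _store(("A", "B"), 0.05, 100), CFG)


def test_exactly_ten_percent_retained():
    rec = _record()
    assert not is_high_frequency(rec, _store(("A", "B"), 0.10, 20), CFG)


def test_unseen_pair_frequency_zero():
    rec = _record()
    assert not is_high_frequency(rec, CohortFrequencyStore(), CFG)


# -- evidence --------------------------------------------------------------


@pytest.mark.parametrize(
    "reads,expected",
    [((3, 2, 1), True), ((4, 1, 1), False), ((0,), True), ((4,), False)],
)
def test_low_evidence(reads, expected):
    rec = _record(n_callers=len(reads), reads=reads)
    assert is_low_evidence(rec, CFG) is expected


# -- apply_filters ----------------------------------------------------------


def test_known_pair_rescued_from_low_evidence():
    rec = _record(pair=("KIAA1549", "BRAF"), n_callers=3, reads=(2, 1, 1))
    known = KnownFusionList.from_pairs([("KIAA1549", "BRAF")])
    kept, decisions = apply_filters([rec], CohortFrequencyStore(), known, CFG)
    assert kept == [rec]
    (decision,) = decisions
    assert decision.rescued_by_known_list
    assert decision.reasons == {REASON_LOW_EVIDENCE}


def test_known_pair_rescued_from_high_frequency():
    rec = _record(pair=("EML4", "ALK"), n_callers=4, reads=(10, 9, 8, 7))
    known = KnownFusionList.from_pairs([("EML4", "ALK")])
    store = _store(("EML4", "ALK"), 7 / 22, 22)
    kept, decisions = apply_filters([rec], store, known, CFG)
    assert kept == [rec]
    assert decisions[0].rescued_by_known_list


def test_unlisted_two_caller_pair_removed_below_consensus():
    rec = _record(n_callers=2, reads=(50, 40))
    kept, decisions = apply_filters([rec], CohortFrequencyStore(), EMPTY_KNOWN, CFG)
    assert kept == []
    assert decisions[0].reasons == {REASON_BELOW_CONSENSUS}


def test_known_pair_needs_min_rescue_callers():
    rec = _record(pair=("KIAA1549", "BRAF"), n_callers=1, reads=(1,))
    known = KnownFusionList.from_pairs([("KIAA1549", "BRAF")])
    kept, _ = apply_filters([rec], CohortFrequencyStore(), known, CFG)
    assert kept == []  # single-caller known pairs go to the singleton channel


def test_clean_record_kept_with_no_reasons():
    rec = _record()
    kept, decisions = apply_filters([rec], CohortFrequencyStore(), EMPTY_KNOWN, CFG)
    assert kept == [rec]
    assert decisions[0].reasons == set()
    assert not decisions[0].rescued_by_known_list


def test_partition_and_reason_completeness():
    records = [
        _record(pair=("A", "B")),
        _record(pair=("C", "D"), n_callers=2),
        _record(pair=("E", "F"), reads=(1, 1, 1)),
        _record(pair=("G", "H"), chrom5="3", chrom3="3", pos5=10, pos3=50_000),
    ]
    kept, decisions = apply_filters(records, CohortFrequencyStore(), EMPTY_KNOWN, CFG)
    removed = [d.record for d in decisions if not d.kept]
    assert len(kept) + len(removed) == len(records)
    assert {id(r) for r in kept}.isdisjoint({id(r) for r in removed})
    for d in decisions:
        assert d.kept == (not d.reasons or d.rescued_by_known_list)


def test_reason_vocabulary():
    rec = _record(pair=("A", "B"), n_callers=2, reads=(1, 1), chrom5="1", chrom3="1",
                  pos5=100, pos3=200)
    store = _store(("A", "B"), 0.5, 10)
    _, decisions = apply_filters([rec], store, EMPTY_KNOWN, CFG)
    assert decisions[0].reasons == {
        REASON_BELOW_CONSENSUS,
        REASON_READTHROUGH,
        REASON_HIGH_FREQUENCY,
        REASON_LOW_EVIDENCE,
    }


def test_empty_known_list_kept_subset_of_consensus():
    records = [_record(pair=(f"G{i}", f"H{i}"), n_callers=1 + i % 5) for i in range(8)]
    kept, _ = apply_filters(records, CohortFrequencyStore(), EMPTY_KNOWN, CFG)
    assert all(r.caller_count >= 3 for r in kept)


def test_filter_config_validation():
    with pytest.raises(ConfigurationError):
        FilterConfig(min_reads=0)
    with pytest.raises(ConfigurationError):
        FilterConfig(min_callers=2, known_list_min_callers=3)


# -- monotonicity and commutation properties --------------------------------


@settings(max_examples=40, deadline=None)
@given(
    min_reads=st.integers(1, 10),
    min_callers_lo=st.integers(1, 6),
    data=st.data(),
)
def test_tightening_thresholds_never_grows_kept_set(min_reads, min_callers_lo, data):
    records = [
        _record(
            pair=(f"A{i}", f"B{i}"),
            n_callers=data.draw(st.integers(1, 7)),
            reads=tuple(data.draw(st.integers(0, 12)) for _ in range(7)),
        )
        for i in range(6)
    ]
    store = CohortFrequencyStore()
    loose = FilterConfig(min_callers=min_callers_lo, min_reads=min_reads,
                         known_list_min_callers=1)
    tight = FilterConfig(min_callers=min_callers_lo + 1, min_reads=min_reads + 1,
                         known_list_min_callers=1)
    kept_loose, _ = apply_filters(records, store, EMPTY_KNOWN, loose)
    kept_tight, _ = apply_filters(records, store, EMPTY_KNOWN, tight)
    assert {r.key for r in kept_tight} <= {r.key for r in kept_loose}


def test_lowering_frequency_threshold_never_grows_kept_set():
    rec = _record(pair=("A", "B"))
    store = _store(("A", "B"), 0.15, 20)
    kept_hi, _ = apply_filters([rec], store, EMPTY_KNOWN,
                               FilterConfig(max_cohort_frequency=0.20))
    kept_lo, _ = apply_filters([rec], store, EMPTY_KNOWN,
                               FilterConfig(max_cohort_frequency=0.10))
    assert {r.key for r in kept_lo} <= {r.key for r in kept_hi}


def test_boolean_filters_commute():
    """The kept set equals the conjunction of the three rules plus the
    consensus gate, independent of any evaluation order."""
    records = [
        _record(pair=("A", "B"), reads=(1, 2, 3)),
        _record(pair=("C", "D"), chrom5="2", chrom3="2", pos5=10, pos3=99_999),
        _record(pair=("E", "F")),
    ]
    store = _store(("E", "F"), 0.4, 10)
    kept, _ = apply_filters(records, store, EMPTY_KNOWN, CFG)
    for order in itertools.permutations(
        [
            lambda r: not is_readthrough(r, CFG),
            lambda r: not is_high_frequency(r, store, CFG),
            lambda r: not is_low_evidence(r, CFG),
            lambda r: r.caller_count >= CFG.min_callers,
        ]
    ):
        manual = [r for r in records if all(check(r) for check in order)]
        assert [r.key for r in manual] == [r.key for r in kept]
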