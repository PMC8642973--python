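import random

import pytest
from hypothesis import given, settings, strategies as st

from fusemble.ensemble import overlap_calls, prioritize, reconcile_breakpoints
from fusemble.models import CALLERS, ConfigurationError, pair_key

from conftest import make_call


# -- independent oracle: union-find over the pairwise same-pair relation ----


def _brute_force_groups(calls):
    """All-pairs grouping: two calls belong together iff their unordered
    gene sets are equal.  Deliberately quadratic and structurally unlike
    the dict-based implementation."""
    n = len(calls)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if {calls[i].gene5, calls[i].gene3} == {calls[j].gene5, calls[j].gene3}:
                parent[find(i)] = find(j)

    groups = {}
    for i, call in enumerate(calls):
        groups.setdefault(find(i), []).append(call)
    return {
        frozenset({g[0].gene5, g[0].gene3}): g for g in groups.values()
    }


def _random_instance(rng, n_callers=5, max_calls=30):
    genes = ["A", "B", "C", "D", "E", "F"]
    callers = list(CALLERS[:n_callers])
    calls_by_caller = {c: [] for c in callers}
    total = rng.randint(0, max_calls)
    for _ in range(total):
        caller = rng.choice(callers)
        g5, g3 = rng.sample(genes, 2)
        calls_by_caller[caller].append(
            make_call(
                caller=caller,
                gene5=g5,
                gene3=g3,
                chrom5=str(rng.randint(1, 5)),
                pos5=rng.randint(1, 10**6),
                chrom3=str(rng.randint(1, 5)),
                pos3=rng.randint(1, 10**6),
                reads=rng.randint(0, 40),
            )
        )
    return calls_by_caller


@pytest.mark.parametrize("seed", range(20))
def test_overlap_matches_brute_force_oracle(seed):
    rng = random.Random(seed)
    calls_by_caller = _random_instance(rng)
    records = overlap_calls(calls_by_caller)
    oracle = _brute_force_groups([c for v in calls_by_caller.values() for c in v])

    assert {frozenset(r.key) for r in records} == set(oracle)
    for record in records:
        group = oracle[frozenset(record.key)]
        assert sorted(record.calls(), key=repr) == sorted(group, key=repr)
        assert record.caller_count == len({c.caller for c in group})
        assert record.max_reads == max(c.reads for c in group)


def test_all_seven_callers_single_pair():
    calls = {
        c: [make_call(caller=c, gene5="RBPMS", gene3="MET", reads=i + 1)]
        for i, c in enumerate(CALLERS)
    }
    (record,) = overlap_calls(calls)
    assert record.caller_count == 7
    assert record.key == pair_key("RBPMS", "MET")


def test_five_of_seven_callers():
    calls = {c: [] for c in CALLERS}
    for c in CALLERS[:5]:
        calls[c] = [make_call(caller=c, gene5="BCAN", gene3="NTRK1", chrom5="1", chrom3="1")]
    (record,) = overlap_calls(calls)
    assert record.caller_count == 5


def test_reciprocal_orientations_merge():
    calls = {
        "arriba": [make_call(caller="arriba", gene5="A", gene3="B")],
        "jaffa": [make_call(caller="jaffa", gene5="B", gene3="A")],
    }
    (record,) = overlap_calls(calls)
    assert record.caller_count == 2
    assert record.orientations == {("A", "B"), ("B", "A")}


def test_multiple_isoforms_count_caller_once():
    calls = {
        "arriba": [
            make_call(caller="arriba", pos5=100, reads=9),
            make_call(caller="arriba", pos5=200, reads=5),
        ],
        "jaffa": [make_call(caller="jaffa", pos5=100, reads=2)],
    }
    (record,) = overlap_calls(calls)
    assert record.caller_count == 2
    assert len(list(record.calls())) == 3


def test_duplicate_caller_key_rejected():
    items = [("arriba", [make_call()]), ("arriba", [make_call()])]
    with pytest.raises(ConfigurationError, match="duplicate caller"):
        overlap_calls(items)


def test_mislabeled_call_rejected():
    with pytest.raises(ConfigurationError, match="filed under"):
        overlap_calls({"jaffa": [make_call(caller="arriba")]})


def test_conservation_every_call_in_exactly_one_record():
    rng = random.Random(42)
    calls_by_caller = _random_instance(rng, max_calls=25)
    all_calls = [c for v in calls_by_caller.values() for c in v]
    records = overlap_calls(calls_by_caller)
    grouped = [c for r in records for c in r.calls()]
    assert sorted(grouped, key=repr) == sorted(all_calls, key=repr)


# -- breakpoint reconciliation ---------------------------------------------


def test_reconcile_picks_max_reads():
    calls = {
        "arriba": [make_call(caller="arriba", pos5=111, reads=20)],
        "jaffa": [make_call(caller="jaffa", pos5=222, reads=5)],
    }
    (record,) = overlap_calls(calls)
    reconcile_breakpoints(record)
    assert record.best_call.pos5 == 111
    assert record.best_breakpoints[1] == 111


def test_reconcile_single_call():
    (record,) = overlap_calls({"cicero": [make_call(caller="cicero", pos5=77)]})
    reconcile_breakpoints(record)
    assert record.best_call.pos5 == 77


def test_reconcile_tie_broken_by_caller_support():
    # bp P: 10 reads (arriba) + 3 reads (jaffa) -> 2 supporting callers
    # bp Q: 10 reads (cicero) -> 1 supporting caller; tie on reads goes to P
    calls = {
        "arriba": [make_call(caller="arriba", pos5=100, reads=10)],
        "jaffa": [make_call(caller="jaffa", pos5=100, reads=3)],
        "cicero": [make_call(caller="cicero", pos5=900, reads=10)],
    }
    (record,) = overlap_calls(calls)
    reconcile_breakpoints(record)
    assert record.best_call.pos5 == 100


def test_reconcile_double_tie_lexicographic():
    calls = {
        "arriba": [make_call(caller="arriba", pos5=900, reads=10)],
        "cicero": [make_call(caller="cicero", pos5=100, reads=10)],
    }
    (record,) = overlap_calls(calls)
    reconcile_breakpoints(record)
    assert record.best_call.pos5 == 100  # smallest (chrom5,pos5,chrom3,pos3)


def test_best_breakpoints_belong_to_a_contained_call():
    rng = random.Random(7)
    for record in overlap_calls(_random_instance(rng, max_calls=30)):
        reconcile_breakpoints(record)
        assert record.best_call in list(record.calls())


# -- prioritization --------------------------------------------------------


def _record_with(caller_count, reads, pair=("A", "B")):
    calls = {
        c: [make_call(caller=c, gene5=pair[0], gene3=pair[1], reads=reads)]
        for c in CALLERS[:caller_count]
    }
    (record,) = overlap_calls(calls)
    return record


def test_prioritize_by_caller_count_then_reads():
    records = [_record_with(3, 5), _record_with(7, 1), _record_with(5, 9)]
    ordered = prioritize(records)
    assert [r.caller_count for r in ordered] == [7, 5, 3]

    same_count = [_record_with(3, 4, ("A", "B")), _record_with(3, 40, ("C", "D"))]
    assert [r.max_reads for r in prioritize(same_count)] == [40, 4]


def test_prioritize_full_tie_lexicographic_and_permutation_invariant():
    records = [
        _record_with(3, 10, ("Z", "Q")),
        _record_with(3, 10, ("A", "B")),
        _record_with(3, 10, ("M", "N")),
    ]
    expected = [("A", "B"), ("M", "N"), ("Q", "Z")]
    for seed in range(5):
        shuffled = records[:]
        random.Random(seed).shuffle(shuffled)
        assert [r.key for r in prioritize(shuffled)] == expected


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10**6), order_seed=st.integers(0, 10**6))
def test_overlap_permutation_invariance(seed, order_seed):
    rng = random.Random(seed)
    calls_by_caller = _random_instance(rng, max_calls=15)
    items = list(calls_by_caller.items())
    shuffled = items[:]
    random.Random(order_seed).shuffle(shuffled)
    for caller, calls in shuffled:
        random.Random(order_seed).shuffle(list(calls))

    a = prioritize([reconcile_breakpoints(r) for r in overlap_calls(items)])
    b = prioritize([reconcile_breakpoints(r) for r in overlap_calls(shuffled)])
    assert [(r.key, r.caller_count, r.max_reads, r.best_breakpoints) for r in a] == [
        (r.key, r.caller_count, r.max_reads, r.best_breakpoints) for r in b
    ]
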