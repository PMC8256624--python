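import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosemono import (
    DoseCombination,
    DoseOutcomeRecord,
    Ordering,
    build_series,
    compare_doses,
    make_analysis_series,
)


class TestCompareDoses:
    def test_crossed_pair_incomparable(self, worked_example_doses):
        d1, d2, _ = worked_example_doses
        assert compare_doses(d1, d2) is Ordering.INCOMPARABLE

    def test_dominated_pair_less(self, worked_example_doses):
        d1, d2, d3 = worked_example_doses
        assert compare_doses(d1, d3) is Ordering.LESS
        assert compare_doses(d2, d3) is Ordering.LESS
        assert compare_doses(d3, d1) is Ordering.GREATER

    def test_reflexive_equal(self, worked_example_doses):
        for d in worked_example_doses:
            assert compare_doses(d, d) is Ordering.EQUAL

    def test_missing_agent_counts_as_zero(self):
        mono = DoseCombination({"A": 10.0})
        combo = DoseCombination({"A": 10.0, "B": 5.0})
        assert compare_doses(mono, combo) is Ordering.LESS

    @given(st.data())
    @settings(deadline=None, max_examples=80)
    def test_antisymmetry_on_random_pairs(self, data):
        amounts = st.integers(0, 3).map(float)
        maps = st.dictionaries(st.sampled_from("AB"), amounts, min_size=1, max_size=2)
        a = DoseCombination(data.draw(maps))
        b = DoseCombination(data.draw(maps))
        ab, ba = compare_doses(a, b), compare_doses(b, a)
        flip = {Ordering.LESS: Ordering.GREATER, Ordering.GREATER: Ordering.LESS,
                Ordering.EQUAL: Ordering.EQUAL,
                Ordering.INCOMPARABLE: Ordering.INCOMPARABLE}
        assert ba is flip[ab]


def labels(chains):
    return [[d.label for d in chain] for chain in chains]


def brute_force_cover(doses):
    """Independent oracle: exhaustive search over the inclusion-maximal
    chains of the partial order for a cover that (i) contains a
    maximum-length chain, (ii) covers every dose, minimising
    (orphans, repetitions) in that order.  Series are never truncated —
    a series always absorbs every dose comparable with all its members —
    so only inclusion-maximal chains are candidates.
    Returns (max chain length, min orphans, min repetitions)."""
    n = len(doses)
    chains = []
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            seq = sorted(combo, key=lambda i: sum(doses[i].components.values()))
            if all(compare_doses(doses[seq[k]], doses[seq[k + 1]]) is Ordering.LESS
                   for k in range(len(seq) - 1)):
                chains.append(frozenset(combo))
    # keep inclusion-maximal chains only
    chains = [c for c in chains
              if not any(c < other for other in chains)]
    max_len = max(len(c) for c in chains)
    everything = frozenset(range(n))
    best = None
    for r in range(1, n + 1):
        for cover in itertools.combinations(chains, r):
            if frozenset().union(*cover) != everything:
                continue
            if max(len(c) for c in cover) != max_len:
                continue
            orphans = sum(1 for c in cover if len(c) == 1)
            reps = sum(len(c) for c in cover) - n
            cand = (orphans, reps)
            if best is None or cand < best:
                best = cand
        if best is not None and best[0] == 0:
            # adding more chains can only add repetitions
            break
    return max_len, best[0], best[1]


class TestBuildSeries:
    def test_worked_three_dose_example(self, worked_example_doses):
        chains = build_series(worked_example_doses)
        assert labels(chains) == [["d1", "d3"], ["d2", "d3"]]

    def test_totally_ordered_returns_single_chain(self):
        doses = [DoseCombination({"A": a}, label=f"d{i}")
                 for i, a in enumerate([10.0, 20.0, 30.0], 1)]
        assert labels(build_series(doses)) == [["d1", "d2", "d3"]]

    def test_diamond_repeats_endpoints(self):
        d1 = DoseCombination({"A": 1.0, "B": 1.0}, label="d1")
        d2 = DoseCombination({"A": 2.0, "B": 1.0}, label="d2")
        d3 = DoseCombination({"A": 1.0, "B": 2.0}, label="d3")
        d4 = DoseCombination({"A": 2.0, "B": 2.0}, label="d4")
        chains = build_series([d1, d2, d3, d4])
        assert labels(chains) == [["d1", "d2", "d4"], ["d1", "d3", "d4"]]

    def test_empty_input(self):
        assert build_series([]) == []

    def test_isolated_dose_is_flagged_singleton(self):
        a = DoseCombination({"A": 1.0}, label="a")
        b = DoseCombination({"A": 2.0}, label="b")
        c = DoseCombination({"B": 1.0}, label="c")  # incomparable to both? no: zero-fill
        # c has A=0 < a's A, but B=1 > a's B=0 -> incomparable to a and b
        chains = build_series([a, b, c])
        assert [["a", "b"], ["c"]] == labels(chains)

    def test_duplicate_doses_rejected(self):
        d = DoseCombination({"A": 1.0}, label="x")
        with pytest.raises(ValueError):
            build_series([d, DoseCombination({"A": 1.0}, label="y")])

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_on_random_posets(self, data):
        """Coverage, chain validity, longest-chain maximality and minimal
        orphan/repetition counts all agree with exhaustive search."""
        n = data.draw(st.integers(2, 6))
        seen, doses = set(), []
        for i in range(n):
            m = data.draw(st.tuples(st.integers(0, 3), st.integers(0, 3)))
            if m in seen:
                continue
            seen.add(m)
            doses.append(DoseCombination(
                {"A": float(m[0]), "B": float(m[1])}, label=f"d{i}"))
        if len(doses) < 2:
            return
        chains = build_series(doses)
        # coverage
        covered = {d for chain in chains for d in chain}
        assert covered == set(doses)
        # strict ascent
        for chain in chains:
            for lo, hi in zip(chain, chain[1:]):
                assert compare_doses(lo, hi) is Ordering.LESS
        max_len, orphans, reps = brute_force_cover(doses)
        assert max(len(c) for c in chains) == max_len
        assert sum(1 for c in chains if len(c) == 1) == orphans
        assert sum(len(c) for c in chains) - len(doses) == reps

    def test_deterministic(self, worked_example_doses):
        a = labels(build_series(worked_example_doses))
        b = labels(build_series(list(reversed(worked_example_doses))))
        assert a == b


def record(sid, label, components, n_dlt=(3, 1), n_or=None):
    kw = dict(study_id=sid, dose_label=label, dose_components=components)
    if n_dlt is not None:
        kw.update(n_evaluable_dlt=n_dlt[0], n_dlt=n_dlt[1])
    if n_or is not None:
        kw.update(n_evaluable_or=n_or[0], n_or=n_or[1])
    return DoseOutcomeRecord(**kw)


class TestMakeAnalysisSeries:
    def test_totally_ordered_single_series(self):
        recs = [record("S1", f"d{k}", {"A": 10.0 * k}, n_dlt=(3, k - 1))
                for k in (1, 2, 3)]
        series = make_analysis_series("S1", recs, "DLT")
        assert len(series) == 1
        assert series[0].levels == (1, 2, 3)
        assert [p.events for p in series[0].points] == [0, 1, 2]
        assert series[0].fittable

    def test_worked_example_shares_top_dose_counts(self, worked_example_doses):
        recs = [record("S1", d.label, dict(d.components), n_dlt=(6, i))
                for i, d in enumerate(worked_example_doses)]
        series = make_analysis_series("S1", recs, "DLT")
        assert len(series) == 2
        assert all(s.n_levels == 2 for s in series)
        top_counts = {s.points[-1].events for s in series}
        assert top_counts == {2}  # dose 3's events feature in both series

    def test_outcome_reported_on_subset_of_doses(self):
        recs = [
            record("S1", "d1", {"A": 10.0}, n_dlt=(3, 0), n_or=(3, 1)),
            record("S1", "d2", {"A": 20.0}, n_dlt=(3, 1)),
            record("S1", "d3", {"A": 30.0}, n_dlt=(3, 1)),
            record("S1", "d4", {"A": 40.0}, n_dlt=(6, 2), n_or=(6, 2)),
        ]
        or_series = make_analysis_series("S1", recs, "OR")
        assert len(or_series) == 1
        assert or_series[0].levels == (1, 2)
        assert [p.dose.label for p in or_series[0].points] == ["d1", "d4"]

    def test_no_outcome_returns_empty(self):
        recs = [record("S1", "d1", {"A": 10.0}, n_dlt=(3, 0))]
        assert make_analysis_series("S1", recs, "OR") == []

    def test_foreign_records_rejected(self):
        recs = [record("S2", "d1", {"A": 10.0})]
        with pytest.raises(ValueError, match="study"):
            make_analysis_series("S1", recs, "DLT")
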