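"""Interval arithmetic against a per-base brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genclock.intervals import (
    BedParseError,
    IntervalSet,
    classify_individual_fragments,
    downsample_individuals,
    intersect_total,
    merge_intervals,
    read_bed,
    window_frequency,
    write_bed,
)

# -- brute-force oracle: everything via explicit base-position sets ---------


def covered_bases(ivs):
    cov = {}
    for chrom, start, end in ivs:
        cov.setdefault(chrom, set()).update(range(start, end))
    return cov


def bases_to_runs(cov):
    out = []
    for chrom, bases in cov.items():
        run_start = None
        prev = None
        for b in sorted(bases):
            if run_start is None:
                run_start = b
            elif b != prev + 1:
                out.append((chrom, run_start, prev + 1))
                run_start = b
            prev = b
        if run_start is not None:
            out.append((chrom, run_start, prev + 1))
    return sorted(out)


def interval_strategy(max_chroms=5, max_intervals=50, max_coord=1000):
    interval = st.tuples(
        st.integers(1, max_chroms).map(lambda i: f"c{i}"),
        st.integers(0, max_coord - 1),
        st.integers(1, 60),
    ).map(lambda t: (t[0], t[1], t[1] + t[2]))
    return st.lists(interval, max_size=max_intervals).map(IntervalSet.from_tuples)


@settings(max_examples=120, derandomize=True)
@given(interval_strategy(), interval_strategy())
def test_merge_and_intersect_match_brute_force(a, b):
    merged = merge_intervals(a, b)
    cov = covered_bases(list(a) + list(b))
    assert sorted((iv.chrom, iv.start, iv.end) for iv in merged) == bases_to_runs(cov)
    ma, mb = merge_intervals(a), merge_intervals(b)
    inter, shared = intersect_total(ma, mb)
    cov_a, cov_b = covered_bases(list(a)), covered_bases(list(b))
    cov_inter = {c: cov_a[c] & cov_b.get(c, set()) for c in cov_a}
    cov_inter = {c: s for c, s in cov_inter.items() if s}
    assert shared == sum(len(s) for s in cov_inter.values())
    assert sorted((iv.chrom, iv.start, iv.end) for iv in inter) == bases_to_runs(cov_inter)
    # symmetry and the total = shared + private identity
    assert intersect_total(mb, ma)[1] == shared
    assert ma.total_bp - shared >= 0 and mb.total_bp - shared >= 0


@settings(max_examples=80, derandomize=True)
@given(interval_strategy(max_intervals=20), interval_strategy(max_intervals=20))
def test_classification_matches_brute_force(ind, other):
    joined = merge_intervals(other)
    shared, private = classify_individual_fragments(ind, joined)
    cov_other = covered_bases(list(other))
    for iv in ind:
        overlaps = bool(cov_other.get(iv.chrom, set()) & set(range(iv.start, iv.end)))
        in_shared = any(jv == iv for jv in shared)
        in_private = any(jv == iv for jv in private)
        assert in_shared == overlaps and in_private != overlaps
    assert len(shared) + len(private) == len(ind)


@settings(max_examples=60, derandomize=True)
@given(st.lists(interval_strategy(max_chroms=3, max_intervals=10), min_size=1, max_size=5),
       st.integers(1, 40))
def test_window_frequency_matches_brute_force(individuals, window_bp):
    joined = merge_intervals(*individuals)
    freq = window_frequency(joined, individuals, window_bp)
    covs = [covered_bases(list(ind)) for ind in individuals]
    for row in freq.itertuples(index=False):
        wbases = set(range(row.start, row.end))
        expected = sum(1 for cov in covs if cov.get(row.chrom, set()) & wbases)
        assert row.count == expected
    assert ((freq["count"] >= 1) & (freq["count"] <= len(individuals))).all()


def test_merge_examples():
    assert list(merge_intervals(IntervalSet())) == []
    got = merge_intervals(IntervalSet.from_tuples([("1", 0, 100), ("1", 50, 150)]))
    assert [(iv.start, iv.end) for iv in got] == [(0, 150)]
    # book-ended intervals coalesce, as the merge tool's default does
    got = merge_intervals(IntervalSet.from_tuples([("1", 0, 100), ("1", 100, 200)]))
    assert [(iv.start, iv.end) for iv in got] == [(0, 200)]


def test_intersect_identity_and_disjoint():
    a = merge_intervals(IntervalSet.from_tuples([("1", 10, 60), ("2", 0, 5)]))
    inter, shared = intersect_total(a, a)
    assert shared == a.total_bp and inter == a
    b = merge_intervals(IntervalSet.from_tuples([("1", 60, 100)]))
    assert intersect_total(a, b)[1] == 0  # book-ended is not overlap


def test_classification_edge_semantics():
    frag = IntervalSet.from_tuples([("1", 0, 100)])
    shared, private = classify_individual_fragments(
        frag, merge_intervals(IntervalSet.from_tuples([("1", 99, 200)])))
    assert len(shared) == 1 and len(private) == 0  # 1 bp overlap qualifies
    shared, private = classify_individual_fragments(
        frag, merge_intervals(IntervalSet.from_tuples([("1", 100, 200)])))
    assert len(shared) == 0 and len(private) == 1  # half-open: book-ended is private
    shared, private = classify_individual_fragments(frag, IntervalSet())
    assert len(private) == 1


def test_window_frequency_distinct_individual_rule():
    # an individual with two fragments touching one window counts once ...
    ind = IntervalSet.from_tuples([("1", 0, 200), ("1", 700, 900)])
    joined = merge_intervals(ind)
    freq = window_frequency(joined, [ind], window_bp=1000)
    assert freq["count"].tolist() == [1, 1]
    # ... unless raw overlap events are requested
    joined_one = merge_intervals(IntervalSet.from_tuples([("1", 0, 1000)]))
    freq = window_frequency(joined_one, [ind], window_bp=1000, count="overlaps")
    assert freq["count"].tolist() == [2]


def test_window_frequency_rejects_bad_width():
    with pytest.raises(ValueError):
        window_frequency(IntervalSet(), [], window_bp=0)


def test_malformed_interval_is_named():
    with pytest.raises(BedParseError, match="5-5"):
        IntervalSet.from_tuples([("1", 5, 5)])


def test_bed_roundtrip(tmp_path):
    ivs = IntervalSet.from_tuples([("chr2", 10, 500), ("chr1", 0, 1000)])
    path = tmp_path / "x.bed"
    write_bed(ivs, path)
    assert read_bed(path) == ivs


def test_downsample_is_seeded_and_uniform():
    sets = {f"i{k}": IntervalSet.from_tuples([("1", k, k + 1)]) for k in range(10)}
    a = downsample_individuals(sets, 4, seed=5)
    b = downsample_individuals(sets, 4, seed=5)
    assert list(a) == list(b) and len(a) == 4
    assert list(downsample_individuals(sets, 4, seed=6)) != list(a) or True  # may coincide
    with pytest.raises(ValueError):
        downsample_individuals(sets, 11, seed=0)
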