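from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from privrisk import (
    k_anonymity_classes,
    k_histogram,
    kl_profile,
    risk_sweep,
    satisfies_kl,
    uniqueness_fraction,
)
from privrisk.microdata import SchemaError

from conftest import make_names_table
from _oracle import brute_force_k_values

words = st.text(alphabet="abcd", max_size=6)


class TestKAnonymityClasses:
    def test_counts_equivalence_classes(self, small_table):
        classes = k_anonymity_classes(small_table, ["gender", "location", "age"])
        assert classes == [(("F", "Town", 30), 2), (("M", "Town", 41), 1)]

    def test_all_distinct(self, names_table):
        md = names_table(["a", "b", "c"])
        assert [size for _, size in k_anonymity_classes(md, ["name"])] == [1, 1, 1]

    def test_empty_dataset(self, names_table):
        assert k_anonymity_classes(names_table([]), ["name"]) == []

    def test_unknown_attribute(self, small_table):
        with pytest.raises(SchemaError):
            k_anonymity_classes(small_table, ["zipcode"])


class TestKLProfile:
    def test_neighbors_within_one_edit(self, names_table):
        prof = kl_profile(names_table(["ann", "anne", "bob"]), "name", 1)
        assert [prof.k_values[f"r{i}"] for i in range(3)] == [2, 2, 1]

    def test_l0_equals_exact_match_class_sizes(self, names_table):
        md = names_table(["ann", "ann", "bob"])
        prof = kl_profile(md, "name", 0)
        assert [prof.k_values[f"r{i}"] for i in range(3)] == [2, 2, 1]

    def test_huge_l_gives_k_equal_n(self, names_table):
        md = names_table(["a", "bcdef", "xy"])
        prof = kl_profile(md, "name", 10)
        assert set(prof.k_values.values()) == {3}

    @given(st.lists(words, min_size=1, max_size=30), st.integers(0, 3))
    def test_matches_brute_force(self, values, l):
        md = make_names_table(values)
        prof = kl_profile(md, "name", l, policy=None)
        pairs = [(r.record_id, r["name"]) for r in md]
        assert dict(prof.k_values) == brute_force_k_values(pairs, l)

    @given(st.lists(words, min_size=1, max_size=25), st.integers(0, 3))
    def test_k_non_decreasing_in_l(self, values, l):
        md = make_names_table(values)
        lo = kl_profile(md, "name", l, policy=None)
        hi = kl_profile(md, "name", l + 1, policy=None)
        assert all(hi.k_values[r] >= lo.k_values[r] for r in lo.k_values)

    @given(st.lists(words, min_size=1, max_size=25))
    def test_l0_reduction_randomized(self, values):
        md = make_names_table(values)
        prof = kl_profile(md, "name", 0, policy=None)
        sizes = dict()
        for t, size in k_anonymity_classes(md, ["name"]):
            sizes[t[0]] = size
        assert all(prof.k_values[r.record_id] == sizes[r["name"]] for r in md)


class TestSatisfiesKL:
    def test_k1_always_true(self, names_table):
        assert satisfies_kl(names_table(["x", "y"]), "name", 1, 0)

    def test_all_unique_fails_k2_at_l0(self, names_table):
        assert not satisfies_kl(names_table(["a", "b", "c"]), "name", 2, 0)

    def test_near_names_satisfy_k2_at_l1(self, names_table):
        # every name has >= 1 neighbor within one edit
        assert satisfies_kl(names_table(["ann", "anne", "ana"]), "name", 2, 1)

    def test_invalid_k_rejected(self, names_table):
        with pytest.raises(ValueError):
            satisfies_kl(names_table(["x"]), "name", 0, 0)


class TestKHistogram:
    def test_counts_and_unique_fraction(self, names_table):
        prof = kl_profile(names_table(["ann", "anne", "bob"]), "name", 1)
        hist = k_histogram(prof)
        assert hist.counts == {1: 1, 2: 2}
        assert hist.unique_fraction == pytest.approx(1 / 3)
        assert hist.frac_at_most(2) == 1.0

    def test_all_unique(self, names_table):
        hist = k_histogram(kl_profile(names_table(["a", "be", "cef"]), "name", 0))
        assert hist.counts == {1: 3}
        assert hist.unique_fraction == 1.0

    def test_empty_profile_rejected(self, names_table):
        from privrisk import AnonymityProfile

        with pytest.raises(ValueError):
            k_histogram(AnonymityProfile(field="name", l=0, k_values={}))

    @given(st.lists(words, min_size=1, max_size=30), st.integers(0, 2))
    def test_conservation(self, values, l):
        hist = k_histogram(kl_profile(make_names_table(values), "name", l))
        assert hist.n == len(values)


class TestUniquenessFraction:
    def test_examples(self, small_table, names_table):
        assert uniqueness_fraction(small_table, ["gender", "location", "age"]) \
            == pytest.approx(1 / 3)
        assert uniqueness_fraction(names_table(["a", "b"]), ["name"]) == 1.0
        assert uniqueness_fraction(names_table(["a", "a"]), ["name"]) == 0.0

    def test_empty_dataset_rejected(self, names_table):
        with pytest.raises(ValueError):
            uniqueness_fraction(names_table([]), ["name"])


class TestRiskSweep:
    def test_unique_fractions_follow_pair_structure(self, names_table):
        md = names_table(["ann", "anne", "bob"])
        sweep = risk_sweep(md, "name", [0, 1, 2])
        assert [sweep[l].unique_fraction for l in (0, 1, 2)] == \
            pytest.approx([1.0, 1 / 3, 1 / 3])

    def test_duplicate_l_deduplicated(self, names_table):
        sweep = risk_sweep(names_table(["a", "b"]), "name", [1, 1, 0])
        assert sorted(sweep) == [0, 1]

    def test_empty_l_values_rejected(self, names_table):
        with pytest.raises(ValueError):
            risk_sweep(names_table(["a"]), "name", [])

    def test_matches_per_l_profiles(self, names_table):
        md = names_table(["ann", "ana", "bob", "rob", "roberta"])
        sweep = risk_sweep(md, "name", [0, 1, 2, 3])
        for l in (0, 1, 2, 3):
            assert sweep[l].counts == k_histogram(kl_profile(md, "name", l)).counts

    @given(st.lists(words, min_size=1, max_size=25))
    def test_unique_fraction_non_increasing(self, values):
        sweep = risk_sweep(make_names_table(values), "name", [0, 1, 2, 3])
        fracs = [sweep[l].unique_fraction for l in (0, 1, 2, 3)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
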