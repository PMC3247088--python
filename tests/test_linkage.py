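from __future__ import annotations

import dataclasses
import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from privrisk import (
    Evidence,
    LinkConfig,
    Profile,
    aggregate,
    dossier_report,
    five_profile_fixture,
    infer_attributes,
    link_all,
    link_confidence,
    match_strong,
    match_weak,
    pairwise_precision_recall,
)

REF = dt.date(2011, 11, 24)


def prof(pid, source="s", **attrs):
    return Profile(profile_id=pid, source=source, attrs=attrs)


class TestInference:
    def test_spouse_term_implies_gender(self):
        p = infer_attributes(prof("a", free_text="… my husband and I …"))
        assert p.get("gender") == "female"
        q = infer_attributes(prof("b", free_text="My Wife's doctor"))
        assert q.get("gender") == "male"

    def test_birthdate_yields_age_at_reference_date(self):
        p = infer_attributes(prof("a", birthdate="1962-03-14"),
                             reference_date=REF)
        assert p.get("age") == 49
        # day before the birthday: one year younger
        q = infer_attributes(prof("b", birthdate="1962-11-25"),
                             reference_date=REF)
        assert q.get("age") == 48

    def test_never_overwrites_explicit_attribute(self):
        p = infer_attributes(prof("a", gender="male", free_text="my husband"))
        assert p.get("gender") == "male"

    def test_no_rule_matches_returns_profile_unchanged(self):
        p = prof("a", username="x")
        assert infer_attributes(p) is p

    def test_malformed_rule_rejected_at_load(self):
        from privrisk.linkage import InferenceRule

        with pytest.raises(ValueError):
            InferenceRule("", "gender", "female")


class TestMatchStrong:
    def test_shared_email_only(self):
        ev = match_strong(prof("a", email="X@y.z"), prof("b", email="x@Y.Z"))
        assert [e.attribute for e in ev] == ["email"]
        assert ev[0].kind == "strong"

    def test_phone_and_username_two_evidences(self):
        ev = match_strong(
            prof("a", phone="814-555-0137", username="Jm62"),
            prof("b", cell_phone="(814) 555 0137", username="jm62"))
        assert sorted(e.attribute for e in ev) == ["phone", "username"]

    def test_no_shared_identifiers(self):
        assert match_strong(prof("a", email="a@b.c"),
                            prof("b", phone="1234")) == []


class TestMatchWeak:
    def test_three_consistency_checks(self):
        ev = match_weak(
            prof("a", gender="F", location="State College, PA",
                 birthdate="1962-03-14"),
            prof("b", gender="f", location="state college pa", age=49),
            reference_date=REF)
        assert sorted(e.attribute for e in ev) == ["age", "gender", "location"]
        assert all(e.kind == "weak" for e in ev)

    def test_conflicting_gender_contributes_nothing(self):
        ev = match_weak(prof("a", gender="F"), prof("b", gender="M"))
        assert ev == []

    def test_missing_attributes_contribute_nothing(self):
        assert match_weak(prof("a", username="x"), prof("b", username="y")) == []

    def test_age_slack(self):
        a = prof("a", age=49)
        assert match_weak(a, prof("b", age=50)) != []
        assert match_weak(a, prof("b", age=51)) == []
        assert match_weak(a, prof("b", age=51), age_slack_years=2) != []


class TestLinkConfidence:
    def test_noisy_or_closed_forms(self):
        w = lambda x: Evidence("weak", "gender", "", x)
        assert link_confidence([]) == 0.0
        assert link_confidence([w(0.9)]) == pytest.approx(0.9)
        assert link_confidence([w(0.9), w(0.5)]) == pytest.approx(0.95)

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValueError):
            Evidence("weak", "gender", "", 1.5)

    @given(st.lists(st.floats(0.01, 1.0), max_size=6),
           st.floats(0.01, 1.0))
    def test_monotone_in_added_evidence(self, weights, extra):
        evs = [Evidence("weak", "x", "", w) for w in weights]
        assert link_confidence(evs + [Evidence("weak", "x", "", extra)]) \
            >= link_confidence(evs)


class TestLinkAll:
    def test_shared_email_links(self):
        links = link_all([prof("a", email="x@y.z"), prof("b", email="x@y.z")])
        assert len(links) == 1
        assert links[0].pair == ("a", "b")
        assert links[0].confidence == pytest.approx(0.95)

    def test_weak_only_below_threshold_excluded(self):
        links = link_all(
            [prof("a", gender="F"), prof("b", gender="F")],
            LinkConfig(threshold=0.5))
        assert links == []

    def test_duplicate_profile_ids_rejected(self):
        with pytest.raises(ValueError):
            link_all([prof("a", email="x@y"), prof("a", email="x@y")])

    def test_symmetric_in_profile_order(self):
        ps = [prof("a", email="x@y.z", gender="F", location="T"),
              prof("b", email="x@y.z", gender="F", location="T")]
        fwd = link_all(ps)
        rev = link_all(ps[::-1])
        assert [(l.pair, l.confidence) for l in fwd] == \
            [(l.pair, l.confidence) for l in rev]


class TestAggregate:
    def test_transitive_merge(self):
        ps = [prof("a", email="1@x"), prof("b", email="1@x", phone="555"),
              prof("c", phone="555")]
        merged = aggregate(ps, link_all(ps))
        assert [m.members for m in merged] == [("a", "b", "c")]

    def test_no_links_all_singletons(self):
        ps = [prof("a", username="u1"), prof("b", username="u2")]
        merged = aggregate(ps, link_all(ps))
        assert [m.members for m in merged] == [("a",), ("b",)]

    def test_partition_at_every_threshold(self):
        ps = [prof("a", email="1@x", gender="F"),
              prof("b", email="1@x", phone="555"),
              prof("c", phone="555", username="u"),
              prof("d", username="u")]
        links = link_all(ps, LinkConfig(threshold=0.0))
        all_ids = {p.profile_id for p in ps}
        prev_components = None
        for thr in (0.0, 0.3, 0.6, 0.8, 0.99):
            merged = aggregate(ps, links, threshold=thr)
            members = [set(m.members) for m in merged]
            assert set().union(*members) == all_ids
            assert sum(len(m) for m in members) == len(all_ids)
            if prev_components is not None:
                # raising the threshold refines the partition
                for comp in members:
                    assert any(comp <= old for old in prev_components)
            prev_components = members

    def test_conflicts_recorded_with_priority_order(self):
        ps = [prof("a", "osn", email="1@x", location="Smallville"),
              prof("b", "directory", email="1@x", location="Bigtown")]
        cfg = LinkConfig(source_priority=("osn", "directory"))
        merged = aggregate(ps, link_all(ps, cfg), config=cfg)
        m = merged[0]
        assert m.attrs["location"] == "Smallville"  # priority source wins
        assert m.conflicts == [("location", ["Smallville", "Bigtown"])]
        assert m.provenance["email"] == ["osn"]


class TestFiveProfileScenario:
    def test_five_profiles_merge_into_one_dossier(self):
        profiles, expected = five_profile_fixture()
        links = link_all(profiles)
        merged = aggregate(profiles, links)
        assert len(merged) == 1
        assert set(merged[0].members) == expected
        report = dossier_report(merged[0], links)
        for attr in ("full_name", "birthdate", "spouse", "address",
                     "cell_phone", "home_phone", "email", "occupation"):
            assert attr in report["recovered_attribute_types"]
        assert len(merged[0].attrs["email"]) == 2  # two distinct addresses

    def test_report_provenance_and_determinism(self):
        profiles, _ = five_profile_fixture()
        links = link_all(profiles)
        merged = aggregate(profiles, links)
        r1 = dossier_report(merged[0], links)
        r2 = dossier_report(merged[0], links)
        assert r1 == r2
        assert r1["attributes"]["spouse"]["sources"] == ["phonebook"]

    def test_email_ablation_splits_component(self):
        profiles, _ = five_profile_fixture()
        p1 = profiles[0]
        profiles[0] = dataclasses.replace(
            p1, attrs={k: v for k, v in p1.attrs.items() if k != "email"})
        merged = aggregate(profiles, link_all(profiles))
        assert sorted(m.members for m in merged) == [
            ("profile1", "profile2"), ("profile3", "profile4", "profile5")]

    def test_singleton_dossier(self):
        p = prof("solo", "osn", username="u", gender="F")
        merged = aggregate([p], [])
        report = dossier_report(merged[0])
        assert report["members"] == ["solo"]
        assert all(v["sources"] == ["osn"]
                   for v in report["attributes"].values())


class TestPrecisionRecall:
    def test_perfect_merge(self):
        merged = aggregate(
            [prof("s1:p0", email="a@x"), prof("s2:p0", email="a@x")],
            link_all([prof("s1:p0", email="a@x"), prof("s2:p0", email="a@x")]))
        p, r = pairwise_precision_recall(
            merged, {"s1:p0": "p0", "s2:p0": "p0"})
        assert (p, r) == (1.0, 1.0)

    def test_under_and_over_merge(self):
        ps = [prof("s1:p0", username="u0"), prof("s2:p0", username="z9"),
              prof("s1:p1", email="b@x"), prof("s2:p1", email="b@x")]
        merged = aggregate(ps, link_all(ps))
        imap = {"s1:p0": "p0", "s2:p0": "p0", "s1:p1": "p1", "s2:p1": "p1"}
        p, r = pairwise_precision_recall(merged, imap)
        assert p == 1.0 and r == 0.5
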