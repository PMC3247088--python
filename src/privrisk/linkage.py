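"""Cross-source profile linkage: attribution, inference, aggregation.

An adversary who collects public profiles of the same person from several
sources — medical social networks, web search results, directories,
phonebooks — can reconstruct a dossier far richer than any single source.
The attack has three stages:

* **attribution** — extract attributes (username, email, phone, gender,
  location, birthdate, occupation, …) from each source's profiles;
* **inference** — derive further attributes by logical rules, e.g. a
  free-text mention of "my husband" implies the owner is female, a
  birthdate plus a reference date yields an age;
* **aggregation** — score every profile pair on matching evidence, link
  pairs above a confidence threshold, and merge the connected components
  of the link graph into per-person dossiers.

Evidence is *strong* (exact match on an identifier-class attribute:
email, phone, username) or *weak* (consistency of quasi-identifiers:
gender, location, age/birthdate). Pair confidence combines evidence
weights by noisy-or, 1 − Π(1 − wᵢ): independent imperfect witnesses, any
one of which may suffice.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import yaml

from .microdata import Microdata
from .strdist import NormalizationPolicy

__all__ = [
    "Profile",
    "Evidence",
    "LinkResult",
    "MergedProfile",
    "LinkConfig",
    "QIFrequencyTable",
    "InferenceRule",
    "DEFAULT_RULES",
    "infer_attributes",
    "match_strong",
    "match_weak",
    "link_confidence",
    "link_all",
    "aggregate",
    "dossier_report",
    "pairwise_precision_recall",
]

#: identifier-class attributes compared exactly for strong evidence;
#: phone-like keys are pooled so a cell number matches whichever column
#: a source stored it under
#: location strings match exactly after case-folding and stripping all
#: punctuation ("State College, PA" == "state college pa"); no gazetteer
LOCATION_POLICY = NormalizationPolicy(strip_chars="'\u2019-.,;:()")

STRONG_ATTRIBUTE_GROUPS: dict[str, tuple[str, ...]] = {
    "email": ("email",),
    "phone": ("phone", "cell_phone", "home_phone"),
    "username": ("username",),
}

#: attributes for which several distinct values are normal in a merged
#: dossier (a person has many phone numbers), not a conflict
MULTI_VALUE_ATTRIBUTES = frozenset({"email", "username"})


@dataclass(frozen=True)
class Profile:
    """One source's view of a person: an attribute map, mostly incomplete."""

    profile_id: str
    source: str
    attrs: Mapping[str, Any]

    def __post_init__(self) -> None:
        present = {k for k, v in self.attrs.items() if v not in (None, "")}
        if not present:
            raise ValueError(
                f"profile {self.profile_id!r} has no attributes")

    def get(self, attr: str) -> Any:
        v = self.attrs.get(attr)
        return None if v == "" else v


@dataclass(frozen=True)
class Evidence:
    kind: str  # "strong" | "weak"
    attribute: str
    detail: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(
                f"evidence weight must be in (0, 1], got {self.weight}")
        if self.kind not in ("strong", "weak"):
            raise ValueError(f"unknown evidence kind {self.kind!r}")


@dataclass(frozen=True)
class LinkResult:
    pair: tuple[str, str]  # profile ids, lexicographically ordered
    evidences: tuple[Evidence, ...]
    confidence: float


@dataclass
class MergedProfile:
    """A reconstructed dossier: one connected component of the link graph."""

    members: tuple[str, ...]
    attrs: dict[str, Any]
    provenance: dict[str, list[str]]  # attribute -> sources that supplied it
    conflicts: list[tuple[str, list[Any]]]


@dataclass(frozen=True)
class InferenceRule:
    """Logical rule: a free-text pattern implies an attribute value."""

    pattern: str  # substring matched case-insensitively in free_text
    attribute: str
    value: Any

    def __post_init__(self) -> None:
        if not self.pattern or not self.attribute:
            raise ValueError("inference rule needs a pattern and an attribute")


#: spouse-term rules: a profile mentioning "my husband" belongs to a woman,
#: "my wife" to a man (the heteronormative reading such public-records
#: inference attacks historically rely on)
DEFAULT_RULES: tuple[InferenceRule, ...] = (
    InferenceRule("my husband", "gender", "female"),
    InferenceRule("my wife", "gender", "male"),
)


@dataclass
class LinkConfig:
    """Evidence weights, confidence threshold and matching tolerances.

    Defaults rank email and phone as near-unique identifiers, a shared
    username as relatively unique, and each quasi-identifier consistency
    check as weak corroboration. The threshold and weights are policy
    knobs, not estimated quantities.
    """

    strong_weights: dict[str, float] = field(default_factory=lambda: {
        "email": 0.95, "phone": 0.95, "username": 0.7})
    weak_weight: float = 0.3
    use_weak: bool = True
    threshold: float = 0.5
    age_slack_years: int = 1
    reference_date: _dt.date = _dt.date(2011, 11, 24)
    source_priority: tuple[str, ...] = ()
    rules: tuple[InferenceRule, ...] = DEFAULT_RULES
    apply_inference: bool = True
    #: optional small-town weighting: scale weak-evidence weight by the
    #: reciprocal frequency of the pair's (gender, location, age) tuple in
    #: a reference population — a match in a town of 15k says more than a
    #: match in a metropolis
    reference_population: "Microdata | QIFrequencyTable | None" = None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "LinkConfig":
        kw: dict[str, Any] = {}
        if "strong_weights" in d:
            kw["strong_weights"] = dict(d["strong_weights"])
        for key in ("weak_weight", "use_weak", "threshold",
                    "age_slack_years"):
            if key in d:
                kw[key] = d[key]
        if "reference_date" in d:
            kw["reference_date"] = _dt.date.fromisoformat(
                str(d["reference_date"]))
        if "source_priority" in d:
            kw["source_priority"] = tuple(d["source_priority"])
        if "rules" in d:
            kw["rules"] = tuple(
                InferenceRule(r["pattern"], r["attribute"], r["value"])
                for r in d["rules"])
        if "apply_inference" in d:
            kw["apply_inference"] = bool(d["apply_inference"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "LinkConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# inference


def _age_on(birthdate: str, on: _dt.date) -> int:
    b = _dt.date.fromisoformat(str(birthdate))
    return on.year - b.year - ((on.month, on.day) < (b.month, b.day))


def infer_attributes(
    p: Profile,
    rules: Iterable[InferenceRule] = DEFAULT_RULES,
    reference_date: _dt.date = _dt.date(2011, 11, 24),
) -> Profile:
    """Augment a profile by logical reasoning; never overwrites a present value.

    Applies the free-text rules to ``free_text`` and derives ``age`` from
    ``birthdate`` relative to the reference date.
    """
    derived: dict[str, Any] = {}
    text = p.get("free_text")
    if text is not None:
        lowered = str(text).casefold()
        for rule in rules:
            if rule.pattern.casefold() in lowered:
                derived.setdefault(rule.attribute, rule.value)
    if p.get("birthdate") is not None:
        derived["age"] = _age_on(p.get("birthdate"), reference_date)
    derived = {k: v for k, v in derived.items() if p.get(k) is None}
    if not derived:
        return p
    return replace(p, attrs={**p.attrs, **derived})


# ---------------------------------------------------------------------------
# matching

_NON_DIGIT = re.compile(r"\D")


def _norm_email(v: Any) -> str:
    return str(v).strip().casefold()


def _norm_phone(v: Any) -> str:
    return _NON_DIGIT.sub("", str(v))


def _norm_username(v: Any) -> str:
    return str(v).strip().casefold()


_STRONG_NORMALIZERS = {
    "email": _norm_email,
    "phone": _norm_phone,
    "username": _norm_username,
}


def _strong_values(p: Profile, group: str) -> set[str]:
    norm = _STRONG_NORMALIZERS[group]
    vals = set()
    for attr in STRONG_ATTRIBUTE_GROUPS[group]:
        v = p.get(attr)
        if v is not None:
            vals.add(norm(v))
    return vals


def match_strong(
    p: Profile,
    q: Profile,
    weights: Mapping[str, float] | None = None,
) -> list[Evidence]:
    """Strong evidence: exact matches on identifier-class attributes.

    One Evidence per identifier group (email / phone / username) whose
    normalized values intersect across the two profiles.
    """
    if weights is None:
        weights = LinkConfig().strong_weights
    out = []
    for group in STRONG_ATTRIBUTE_GROUPS:
        shared = _strong_values(p, group) & _strong_values(q, group)
        if shared:
            out.append(Evidence(
                kind="strong", attribute=group,
                detail=f"shared {group}: {sorted(shared)[0]}",
                weight=weights[group]))
    return out


class QIFrequencyTable:
    """Frequencies of quasi-identifier combinations in a reference population.

    Backs the small-town weighting of weak evidence: a quasi-identifier
    combination shared by f residents is worth 1/f of the base weight, so
    agreement on a combination unique in town keeps full strength while
    agreement on a common one (every man of roughly the same age, say)
    decays to nothing. Ages come from the reference's ``birthdate``
    column (evaluated at the reference date) or an ``age`` column.
    """

    def __init__(self, ref: Microdata,
                 reference_date: _dt.date = _dt.date(2011, 11, 24),
                 policy: NormalizationPolicy = LOCATION_POLICY):
        from collections import Counter

        self._policy = policy
        # one Counter per subset of {gender, location, age}; age kept as
        # the tuple's last component so windowed queries can sum over it
        self._counters: dict[frozenset, Counter] = {
            frozenset(s): Counter()
            for s in (("gender",), ("location",), ("age",),
                      ("gender", "location"), ("gender", "age"),
                      ("location", "age"), ("gender", "location", "age"))
        }
        has_birthdate = "birthdate" in ref.schema
        has_age = "age" in ref.schema
        for r in ref.records:
            g = (str(r["gender"]).casefold()
                 if "gender" in ref.schema and r["gender"] is not None
                 else None)
            loc = (policy.apply(str(r["location"]))
                   if "location" in ref.schema and r["location"] is not None
                   else None)
            age: int | None = None
            if has_birthdate and r["birthdate"] is not None:
                age = _age_on(r["birthdate"], reference_date)
            elif has_age and r["age"] is not None:
                age = int(r["age"])
            fields = {"gender": g, "location": loc, "age": age}
            for subset, counter in self._counters.items():
                if any(fields[f] is None for f in subset):
                    continue
                key = tuple(fields[f] for f in ("gender", "location")
                            if f in subset)
                if "age" in subset:
                    key = key + (age,)
                counter[key] += 1

    def frequency(self, gender: Any = None, location: Any = None,
                  age_window: tuple[int, int] | None = None) -> int:
        """Residents matching the conjunction of the given attributes.

        ``age_window`` is an inclusive age range; pass the span of the two
        compared ages — it is symmetric in the pair, and any two distinct
        residents consistent with the pair both fall inside it.
        """
        subset = frozenset(
            name for name, v in (
                ("gender", gender), ("location", location),
                ("age", age_window)) if v is not None)
        if not subset:
            return sum(self._counters[frozenset(("gender",))].values())
        counter = self._counters[subset]
        key: tuple = ()
        if gender is not None:
            key += (str(gender).casefold(),)
        if location is not None:
            key += (self._policy.apply(str(location)),)
        if age_window is not None:
            lo, hi = age_window
            return sum(counter.get(key + (a,), 0) for a in range(lo, hi + 1))
        return counter.get(key, 0)


def match_weak(
    p: Profile,
    q: Profile,
    *,
    weight: float = 0.3,
    age_slack_years: int = 1,
    reference_date: _dt.date = _dt.date(2011, 11, 24),
    policy: NormalizationPolicy = LOCATION_POLICY,
    reference_population: "Microdata | QIFrequencyTable | None" = None,
) -> list[Evidence]:
    """Weak evidence: quasi-identifier consistency between two profiles.

    Checks gender agreement, normalized-location equality, and
    age/birthdate consistency (ages compared at the reference date, within
    the slack — self-reported ages lag by up to a year). An attribute
    missing on either side contributes nothing; a disagreement contributes
    nothing (callers see disagreements again as conflicts at merge time).
    """
    out = []
    g1, g2 = p.get("gender"), q.get("gender")
    gender_match = (
        g1 is not None and g2 is not None
        and str(g1).casefold() == str(g2).casefold())
    loc1, loc2 = p.get("location"), q.get("location")
    loc_match = (
        loc1 is not None and loc2 is not None
        and policy.apply(str(loc1)) == policy.apply(str(loc2)))

    def _age(profile: Profile) -> int | None:
        if profile.get("birthdate") is not None:
            return _age_on(profile.get("birthdate"), reference_date)
        if profile.get("age") is not None:
            return int(profile.get("age"))
        return None

    a1, a2 = _age(p), _age(q)
    age_match = a1 is not None and a2 is not None and abs(a1 - a2) <= age_slack_years

    w = weight
    if reference_population is not None and (
            gender_match or loc_match or age_match):
        # small-town weighting: divide by the multiplicity, in the
        # reference population, of the conjunction of whatever matched —
        # a combination unique in town keeps full weight, a common one
        # decays with the number of residents it fits
        table = (reference_population
                 if isinstance(reference_population, QIFrequencyTable)
                 else QIFrequencyTable(reference_population, reference_date))
        freq = table.frequency(
            gender=g1 if gender_match else None,
            location=loc1 if loc_match else None,
            age_window=(min(a1, a2), max(a1, a2)) if age_match else None)
        w = max(weight / max(freq, 1), 1e-6)
    if gender_match:
        out.append(Evidence("weak", "gender", f"gender={g1}", w))
    if loc_match:
        out.append(Evidence(
            "weak", "location", f"location={policy.apply(str(loc1))}", w))
    if age_match:
        out.append(Evidence("weak", "age", f"age≈{a1}", w))
    return out


def link_confidence(evidences: Sequence[Evidence]) -> float:
    """Noisy-or combination 1 − Π(1 − wᵢ); 0 for no evidence.

    Monotone non-decreasing in added evidence.
    """
    conf = 1.0
    for e in evidences:
        if not 0.0 < e.weight <= 1.0:
            raise ValueError(f"evidence weight out of range: {e.weight}")
        conf *= 1.0 - e.weight
    return 1.0 - conf


def _score_pair(
    p: Profile, q: Profile, config: LinkConfig,
    reference: "QIFrequencyTable | Microdata | None" = None,
) -> LinkResult:
    evidences = list(match_strong(p, q, config.strong_weights))
    if config.use_weak:
        evidences += match_weak(
            p, q,
            weight=config.weak_weight,
            age_slack_years=config.age_slack_years,
            reference_date=config.reference_date,
            reference_population=reference,
        )
    pair = tuple(sorted((p.profile_id, q.profile_id)))
    return LinkResult(
        pair=pair,
        evidences=tuple(evidences),
        confidence=link_confidence(evidences),
    )


def link_all(
    profiles: Sequence[Profile], config: LinkConfig | None = None
) -> list[LinkResult]:
    """Score all unordered profile pairs; keep those above the threshold.

    Inference runs first on every profile (when enabled), so derived
    attributes take part in matching. Output ordering is deterministic:
    confidence descending, then pair ids.
    """
    if config is None:
        config = LinkConfig()
    ids = [p.profile_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate profile ids: {dupes}")
    if config.apply_inference:
        profiles = [
            infer_attributes(p, config.rules, config.reference_date)
            for p in profiles
        ]
    reference = config.reference_population
    if isinstance(reference, Microdata):  # build the frequency table once
        reference = QIFrequencyTable(reference, config.reference_date)
    results = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            r = _score_pair(profiles[i], profiles[j], config, reference)
            if r.confidence >= config.threshold:
                results.append(r)
    results.sort(key=lambda r: (-r.confidence, r.pair))
    return results


# ---------------------------------------------------------------------------
# aggregation


def _source_rank(source: str, priority: Sequence[str]) -> tuple[int, str]:
    try:
        return (priority.index(source), source)
    except ValueError:
        return (len(priority), source)


def aggregate(
    profiles: Sequence[Profile],
    links: Sequence[LinkResult],
    threshold: float | None = None,
    *,
    config: LinkConfig | None = None,
) -> list[MergedProfile]:
    """Merge profiles along links: connected components become dossiers.

    Components partition the input profiles at every threshold; raising
    the threshold only removes edges, so it can only refine the partition.
    Within a component, attribute values are unioned. For single-valued
    attributes the highest-priority source (config.source_priority order,
    then source name) supplies the primary value and any differing values
    are recorded as conflicts; email and username are treated as
    legitimately multi-valued.
    """
    if config is None:
        config = LinkConfig()
    if threshold is None:
        threshold = config.threshold
    g: nx.Graph = nx.Graph()
    by_id = {p.profile_id: p for p in profiles}
    g.add_nodes_from(by_id)
    for link in links:
        if link.confidence >= threshold:
            g.add_edge(*link.pair)
    merged = []
    for component in nx.connected_components(g):
        members = tuple(sorted(component))
        ranked = sorted(
            (by_id[m] for m in members),
            key=lambda p: _source_rank(p.source, config.source_priority))
        attrs: dict[str, Any] = {}
        provenance: dict[str, list[str]] = {}
        conflicts: dict[str, list[Any]] = {}
        for p in ranked:
            for attr in sorted(p.attrs):
                v = p.get(attr)
                if v is None:
                    continue
                if attr not in attrs:
                    attrs[attr] = [v] if attr in MULTI_VALUE_ATTRIBUTES else v
                    provenance[attr] = [p.source]
                else:
                    if attr in MULTI_VALUE_ATTRIBUTES:
                        if v not in attrs[attr]:
                            attrs[attr].append(v)
                            provenance[attr].append(p.source)
                    elif v != attrs[attr]:
                        conflicts.setdefault(attr, [attrs[attr]])
                        if v not in conflicts[attr]:
                            conflicts[attr].append(v)
                        if p.source not in provenance[attr]:
                            provenance[attr].append(p.source)
                    elif p.source not in provenance[attr]:
                        provenance[attr].append(p.source)
        merged.append(MergedProfile(
            members=members,
            attrs=attrs,
            provenance=provenance,
            conflicts=sorted(conflicts.items()),
        ))
    merged.sort(key=lambda m: m.members)
    return merged


def dossier_report(
    m: MergedProfile, links: Sequence[LinkResult] = ()
) -> dict[str, Any]:
    """Deterministic, JSON-serialisable account of one reconstructed dossier:
    which attribute types were recovered, their values, which source
    supplied each, recorded conflicts, and the link evidence inside the
    component."""
    member_set = set(m.members)
    component_links = [
        {
            "pair": list(link.pair),
            "confidence": round(link.confidence, 6),
            "evidence": [
                {"kind": e.kind, "attribute": e.attribute,
                 "detail": e.detail, "weight": e.weight}
                for e in link.evidences
            ],
        }
        for link in links
        if set(link.pair) <= member_set
    ]
    return {
        "members": list(m.members),
        "recovered_attribute_types": sorted(m.attrs),
        "attributes": {
            a: {"value": m.attrs[a], "sources": m.provenance[a]}
            for a in sorted(m.attrs)
        },
        "conflicts": [
            {"attribute": a, "values": vs} for a, vs in m.conflicts
        ],
        "links": component_links,
    }


# ---------------------------------------------------------------------------
# evaluation against ground truth


def pairwise_precision_recall(
    merged: Sequence[MergedProfile],
    identity_map: Mapping[str, str],
) -> tuple[float, float]:
    """Pairwise precision/recall of a merge against a ground-truth identity map.

    A profile pair is a true co-reference when both map to the same
    person; a predicted co-reference when both land in the same merged
    component. Conventions: precision is 1.0 when nothing is predicted,
    recall 1.0 when no true pair exists.
    """
    from collections import defaultdict
    from itertools import combinations

    true_pairs: set[tuple[str, str]] = set()
    by_person: dict[str, list[str]] = defaultdict(list)
    for pid in sorted(identity_map):
        by_person[identity_map[pid]].append(pid)
    for pids in by_person.values():
        true_pairs.update(combinations(sorted(pids), 2))
    pred_pairs: set[tuple[str, str]] = set()
    for m in merged:
        pred_pairs.update(combinations(sorted(m.members), 2))
    tp = len(true_pairs & pred_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall
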