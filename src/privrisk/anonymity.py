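"""k-anonymity, k-l-anonymity profiles, histograms and QI uniqueness.

Classic k-anonymity asks how many records share a record's exact
quasi-identifier tuple. The approximate variant measured here —
*k-l-anonymity* — relaxes exact equality to proximity under an edit
distance: a record has anonymity level k when there are k − 1 *other*
records whose identifier value lies within l edits of its own. At l = 0
this reduces exactly to k-anonymity on that field. The per-record k values
summarise how well a population's names protect it against an adversary
who knows a name only approximately: the fraction of records with k = 1
("uniquely identifiable") is the headline risk number, and it can only
shrink as l grows.

Conventions: k counts the record itself (k = 1 + neighbors), so k = 1
means no other record is confusable with it. Two records with identical
values are each other's neighbors at any l.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .microdata import Microdata, SchemaError, project
from .strdist import (
    DEFAULT_POLICY,
    NormalizationPolicy,
    levenshtein_within,
)

__all__ = [
    "AnonymityProfile",
    "KHistogram",
    "k_anonymity_classes",
    "kl_profile",
    "satisfies_kl",
    "k_histogram",
    "uniqueness_fraction",
    "risk_sweep",
]


@dataclass(frozen=True)
class AnonymityProfile:
    """Per-record anonymity levels for one field at one threshold l."""

    field: str
    l: int
    k_values: Mapping[str, int]  # record_id -> k, k >= 1

    def __len__(self) -> int:
        return len(self.k_values)

    def min_k(self) -> int:
        return min(self.k_values.values())


@dataclass(frozen=True)
class KHistogram:
    """Distribution of per-record k values; the risk report's histogram."""

    counts: Mapping[int, int]  # k -> number of records

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_fraction(self) -> float:
        """Fraction of records with k = 1, i.e. uniquely identifiable."""
        return self.counts.get(1, 0) / self.n

    def frac_at_most(self, m: int) -> float:
        """Fraction of records whose k is at most m."""
        return sum(c for k, c in self.counts.items() if k <= m) / self.n

    def to_dict(self) -> dict:
        return {
            "counts": {str(k): self.counts[k] for k in sorted(self.counts)},
            "n": self.n,
            "unique_fraction": self.unique_fraction,
        }


def k_anonymity_classes(
    md: Microdata, qi_attrs: Sequence[str]
) -> list[tuple[tuple, int]]:
    """Equivalence classes under exact equality of the projected QI tuple.

    Returns (tuple, class size) pairs in first-occurrence order; sizes sum
    to len(md). This is the l = 0 base case of the approximate metric.
    """
    tuples = project(md, qi_attrs)
    counts = Counter(tuples)
    seen: set[tuple] = set()
    out: list[tuple[tuple, int]] = []
    for t in tuples:
        if t not in seen:
            seen.add(t)
            out.append((t, counts[t]))
    return out


def _unique_value_neighbor_counts(
    values: Sequence[str], multiplicity: Sequence[int], max_l: int
) -> list[list[int]]:
    """For each unique value, number of records at each distance 1..max_l.

    Returns ``nbr`` with ``nbr[i][d]`` = total multiplicity of *other*
    unique values at distance exactly d from values[i]. Pairs are pruned by
    the length lower bound before the thresholded distance computation.
    """
    nbr = [[0] * (max_l + 1) for _ in values]
    if max_l == 0:
        return nbr
    by_len: dict[int, list[int]] = {}
    for i, v in enumerate(values):
        by_len.setdefault(len(v), []).append(i)
    lengths = sorted(by_len)
    for length in lengths:
        for other in lengths:
            if other < length or other > length + max_l:
                continue
            for i in by_len[length]:
                for j in by_len[other]:
                    if other == length and j <= i:
                        continue
                    d = levenshtein_within(values[i], values[j], max_l)
                    if d is not None and d > 0:
                        nbr[i][d] += multiplicity[j]
                        nbr[j][d] += multiplicity[i]
    return nbr


def _field_strings(
    md: Microdata, field: str, policy: NormalizationPolicy | None
) -> list[str]:
    raw = md.column(field)
    out = []
    for v in raw:
        s = "" if v is None else str(v)
        out.append(policy.apply(s) if policy is not None else s)
    return out


def _profiles_for_sweep(
    md: Microdata,
    field: str,
    l_values: Sequence[int],
    policy: NormalizationPolicy | None,
) -> dict[int, AnonymityProfile]:
    """One AnonymityProfile per distinct l, computing pair distances once.

    Distances between unique values are evaluated a single time with the
    largest requested threshold as cutoff; each profile then accumulates
    neighbor counts up to its own l.
    """
    for l in l_values:
        if l < 0:
            raise ValueError("distance threshold l must be >= 0")
    ls = sorted(set(l_values))
    strings = _field_strings(md, field, policy)
    mult = Counter(strings)
    uniq = list(mult)
    pos = {v: i for i, v in enumerate(uniq)}
    max_l = ls[-1] if ls else 0
    nbr = _unique_value_neighbor_counts(uniq, [mult[v] for v in uniq], max_l)
    profiles: dict[int, AnonymityProfile] = {}
    for l in ls:
        k_by_value = [
            mult[v] + sum(nbr[i][1 : l + 1]) for i, v in enumerate(uniq)
        ]
        k_values = {
            r.record_id: k_by_value[pos[s]]
            for r, s in zip(md.records, strings)
        }
        profiles[l] = AnonymityProfile(field=field, l=l, k_values=k_values)
    return profiles


def kl_profile(
    md: Microdata,
    field: str,
    l: int,
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
) -> AnonymityProfile:
    """Anonymity level k(r) = 1 + |{x ≠ r : dist(value(r), value(x)) ≤ l}|.

    Values are normalized with `policy` first (None to compare raw). At
    l = 0 the k values equal exact-match equivalence-class sizes on the
    field.
    """
    return _profiles_for_sweep(md, field, [l], policy)[l]


def satisfies_kl(
    md: Microdata,
    field: str,
    k: int,
    l: int,
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
) -> bool:
    """Whether every record has at least k − 1 neighbors within l edits.

    The dataset-level property quantifies over all records; k = 1 is
    vacuously satisfied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1 or not md.records:
        return True
    profile = kl_profile(md, field, l, policy)
    return profile.min_k() >= k


def k_histogram(profile: AnonymityProfile) -> KHistogram:
    """Histogram of k values: counts[k] = number of records at level k."""
    if not profile.k_values:
        raise ValueError("cannot build a histogram from an empty profile")
    return KHistogram(counts=dict(Counter(profile.k_values.values())))


def uniqueness_fraction(md: Microdata, qi_attrs: Sequence[str]) -> float:
    """Fraction of records whose quasi-identifier tuple occurs exactly once.

    The classic population-uniqueness statistic for an attribute set such
    as {gender, location, age}.
    """
    if not md.records:
        raise ValueError("uniqueness is undefined on an empty dataset")
    tuples = project(md, qi_attrs)
    counts = Counter(tuples)
    return sum(1 for t in tuples if counts[t] == 1) / len(tuples)


def risk_sweep(
    md: Microdata,
    field: str,
    l_values: Sequence[int],
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
) -> dict[int, KHistogram]:
    """k histograms for several thresholds at once (duplicates deduplicated).

    Pairwise distances are computed once at the largest l. As l grows every
    record's k can only grow, so the unique fraction is non-increasing.
    """
    if not len(l_values):
        raise ValueError("l_values must be non-empty")
    profiles = _profiles_for_sweep(md, field, l_values, policy)
    return {l: k_histogram(p) for l, p in profiles.items()}
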