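"""Levenshtein distance and edit-distance neighborhood search.

The anonymity model in this package generalises k-anonymity by asking, for
each record, how many *other* records carry an identifier value within ``l``
single-character edits (insertions, deletions, substitutions). This module
supplies that distance function and a :class:`NeighborIndex` that answers
"which records lie within distance l of this query string" without a full
pairwise scan.

Distances are computed by ``edlib`` (a banded Myers bit-vector aligner) on
Unicode code points; the index prunes candidates by string length
(``|len(a) - len(b)|`` is a lower bound on the distance) and passes the
threshold to edlib as an early-exit cutoff. Correctness of the index is
defined solely as equality with a linear brute-force scan, which the test
suite checks against an independent dynamic-programming oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import edlib

from .microdata import Microdata, SchemaError

__all__ = [
    "levenshtein",
    "levenshtein_within",
    "NormalizationPolicy",
    "normalize_name",
    "NeighborIndex",
    "build_index",
    "query_within",
]


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two strings (unit cost, code-point edits)."""
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_within(a: str, b: str, k: int) -> int | None:
    """Edit distance if it is ≤ k, else None (early-exit computation)."""
    if abs(len(a) - len(b)) > k:
        return None
    if a == b:
        return 0
    d = edlib.align(a, b, task="distance", k=k)["editDistance"]
    return None if d < 0 else d


@dataclass(frozen=True)
class NormalizationPolicy:
    """How raw name strings are cleaned before distance computation.

    Defaults: case-fold, strip apostrophes/hyphens/periods, collapse runs
    of whitespace to a single space and trim the ends. Phonebook and
    profile names vary mostly in punctuation and case, which are almost
    never the edits an adversary's error model is about.
    """

    casefold: bool = True
    strip_chars: str = "'’-."
    collapse_whitespace: bool = True

    def apply(self, raw: str) -> str:
        s = raw
        if self.casefold:
            s = s.casefold()
        if self.strip_chars:
            s = s.translate({ord(c): None for c in self.strip_chars})
        if self.collapse_whitespace:
            s = " ".join(s.split())
        return s


DEFAULT_POLICY = NormalizationPolicy()


def normalize_name(raw: str, policy: NormalizationPolicy = DEFAULT_POLICY) -> str:
    """Normalize a name per the policy; idempotent by construction."""
    return policy.apply(raw)


@dataclass
class NeighborIndex:
    """Edit-distance neighborhood index over one attribute of a Microdata.

    Internally: unique values grouped by length (a ``|len diff| <= l``
    candidate filter), each unique value mapping to the record_ids that
    carry it. The contract is extensional — ``query_within`` returns
    exactly what a full scan would.
    """

    field_name: str
    _ids_by_value: dict[str, list[str]] = field(default_factory=dict)
    _values_by_len: dict[int, list[str]] = field(default_factory=dict)
    _value_by_id: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ids_by_value.values())

    @property
    def unique_values(self) -> list[str]:
        return list(self._ids_by_value)

    def add(self, value: str, record_id: str) -> None:
        if value not in self._ids_by_value:
            self._ids_by_value[value] = []
            self._values_by_len.setdefault(len(value), []).append(value)
        self._ids_by_value[value].append(record_id)
        self._value_by_id[record_id] = value

    def record_ids(self, value: str) -> list[str]:
        return list(self._ids_by_value.get(value, ()))

    def value_of(self, record_id: str) -> str:
        return self._value_by_id[record_id]

    def query_within(self, query: str, l: int) -> set[str]:
        """Record ids whose indexed value is within l edits of the query."""
        if l < 0:
            raise ValueError("distance threshold l must be >= 0")
        out: set[str] = set()
        qlen = len(query)
        for length in range(max(0, qlen - l), qlen + l + 1):
            for value in self._values_by_len.get(length, ()):
                if levenshtein_within(query, value, l) is not None:
                    out.update(self._ids_by_value[value])
        return out


def build_index(
    md: Microdata,
    field: str,
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
) -> NeighborIndex:
    """Index all records' values of one attribute for neighborhood queries.

    Values are normalized with `policy` before indexing (pass ``None`` to
    index raw strings); missing values index as the empty string.
    Construction is deterministic in record order.
    """
    if field not in md.schema:
        raise SchemaError(f"unknown attribute {field!r}")
    idx = NeighborIndex(field_name=field)
    for r in md.records:
        v = r[field]
        s = "" if v is None else str(v)
        if policy is not None:
            s = policy.apply(s)
        idx.add(s, r.record_id)
    return idx


def query_within(idx: NeighborIndex, query: str, l: int) -> set[str]:
    """Functional form of :meth:`NeighborIndex.query_within`."""
    return idx.query_within(query, l)
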