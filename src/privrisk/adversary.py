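"""Approximate-knowledge attack simulation.

Threat model: an eavesdropping adversary learns a target's identifying
string imperfectly — e edit errors, e.g. a misheard or misread name — and
searches a reference dataset (a phonebook) for every record within l edits
of the corrupted string. The simulation measures how often the true target
survives in that candidate set (the recovery rate) and how small the
candidate sets are, i.e. how much of the search space the adversary must
still examine by hand.

Perturbations have Levenshtein distance *exactly* e from the original
(verified on every draw), which makes the triangle-inequality guarantee
provable: whenever e ≤ l the true record is always retrieved, so the
recovery rate is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .microdata import Microdata
from .strdist import (
    DEFAULT_POLICY,
    NeighborIndex,
    NormalizationPolicy,
    build_index,
    levenshtein,
)

__all__ = [
    "PerturbationSpec",
    "RecoveryStats",
    "perturb",
    "attack_once",
    "recovery_experiment",
]

ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_MAX_REJECTION_ATTEMPTS = 10_000


class PerturbationError(RuntimeError):
    """No string at the exact requested distance was found."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Exactly e edit errors, reproducible from the seed."""

    e: int
    seed: int
    substitution_only: bool = False

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError("number of edit errors e must be >= 0")


@dataclass
class RecoveryStats:
    """Aggregated outcomes of repeated attack trials."""

    n_trials: int
    recovery_rate: float
    candidate_size_dist: Mapping[int, int] = field(default_factory=dict)

    def frac_at_most(self, m: int) -> float:
        """Fraction of trials where the adversary faced at most m candidates."""
        return (
            sum(c for size, c in self.candidate_size_dist.items() if size <= m)
            / self.n_trials
        )

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "recovery_rate": self.recovery_rate,
            "candidate_size_dist": {
                str(k): self.candidate_size_dist[k]
                for k in sorted(self.candidate_size_dist)
            },
        }


def _apply_random_edits(
    name: str, e: int, rng: np.random.Generator, substitution_only: bool
) -> str:
    s = list(name)
    ops = ("substitute",) if substitution_only else (
        "insert", "delete", "substitute")
    for _ in range(e):
        avail = [
            op for op in ops
            if not (op in ("delete", "substitute") and not s)
        ]
        if not avail:
            avail = ["insert"]
        op = avail[int(rng.integers(len(avail)))]
        if op == "insert":
            pos = int(rng.integers(len(s) + 1))
            s.insert(pos, ALPHABET[int(rng.integers(len(ALPHABET)))])
        elif op == "delete":
            pos = int(rng.integers(len(s)))
            del s[pos]
        else:
            pos = int(rng.integers(len(s)))
            s[pos] = ALPHABET[int(rng.integers(len(ALPHABET)))]
    return "".join(s)


def perturb(name: str, spec: PerturbationSpec) -> str:
    """A string at Levenshtein distance exactly ``spec.e`` from ``name``.

    Each of e steps applies one random edit (uniform operation, uniform
    position, uniform lowercase character); because random edits can cancel
    or coincide, the result is rejection-resampled until its distance,
    re-verified with the full distance computation, equals e. Deterministic
    given the spec's seed.
    """
    if spec.e == 0:
        return name
    if not name and spec.substitution_only:
        raise PerturbationError(
            "cannot reach a positive distance from an empty string "
            "with substitutions only")
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        candidate = _apply_random_edits(
            name, spec.e, rng, spec.substitution_only)
        if levenshtein(name, candidate) == spec.e:
            return candidate
    raise PerturbationError(
        f"no string at distance exactly {spec.e} from {name!r} found after "
        f"{_MAX_REJECTION_ATTEMPTS} attempts")


def attack_once(
    md: Microdata,
    field: str,
    target: str,
    e: int,
    l: int,
    seed: int,
    *,
    index: NeighborIndex | None = None,
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
    substitution_only: bool = False,
) -> tuple[list[str], bool]:
    """One simulated attack against one record.

    The target's field value is corrupted to exact distance e, the dataset
    searched within l, and the (deterministically ordered: ascending
    distance to the corrupted string, then record_id) candidate list
    returned together with whether the true target is in it. By the
    triangle inequality, e ≤ l forces a hit.
    """
    record = md.record(target)  # raises KeyError for an unknown target
    if index is None:
        index = build_index(md, field, policy)
    value = record[field]
    s = "" if value is None else str(value)
    if policy is not None:
        s = policy.apply(s)
    noisy = perturb(s, PerturbationSpec(e=e, seed=seed,
                                        substitution_only=substitution_only))
    candidates = index.query_within(noisy, l)
    ordered = sorted(
        candidates,
        key=lambda rid: (levenshtein(noisy, index.value_of(rid)), rid))
    return ordered, target in candidates


def recovery_experiment(
    md: Microdata,
    field: str,
    e: int,
    l: int,
    n_trials: int,
    seed: int,
    *,
    policy: NormalizationPolicy | None = DEFAULT_POLICY,
    substitution_only: bool = False,
) -> RecoveryStats:
    """Monte-Carlo recovery experiment over uniformly sampled targets.

    Targets are drawn with replacement; each trial runs ``attack_once``
    with a per-trial seed derived from the experiment seed. Fully
    deterministic given (dataset, parameters, seed).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not md.records:
        raise ValueError("cannot attack an empty dataset")
    rng = np.random.default_rng(seed)
    index = build_index(md, field, policy)
    ids = [r.record_id for r in md.records]
    hits = 0
    size_dist: dict[int, int] = {}
    for _ in range(n_trials):
        target = ids[int(rng.integers(len(ids)))]
        trial_seed = int(rng.integers(2**31))
        candidates, hit = attack_once(
            md, field, target, e, l, trial_seed,
            index=index, policy=policy, substitution_only=substitution_only)
        hits += hit
        size_dist[len(candidates)] = size_dist.get(len(candidates), 0) + 1
    return RecoveryStats(
        n_trials=n_trials,
        recovery_rate=hits / n_trials,
        candidate_size_dist=size_dist,
    )
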