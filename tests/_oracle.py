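"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive and written from the definitions —
a full Wagner–Fischer dynamic program, O(n²) linear scans, exhaustive
enumeration of single edits — so the package's optimised implementations
can be checked against code that shares none of their machinery.
"""

from __future__ import annotations

from functools import lru_cache

ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def levenshtein_dp(a: str, b: str) -> int:
    """Full dynamic-programming edit distance (two-row Wagner–Fischer)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


@lru_cache(maxsize=1_000_000)
def _cached_dp(a: str, b: str) -> int:
    if a > b:
        a, b = b, a
    return levenshtein_dp(a, b)


def brute_force_query(pairs, query: str, l: int) -> set:
    """Linear scan: ids of (id, value) pairs with dp distance <= l."""
    return {rid for rid, v in pairs if _cached_dp(query, v) <= l}


def brute_force_k_values(pairs, l: int) -> dict:
    """k(r) = 1 + #other records within l, by full pairwise DP scan."""
    ks = {rid: 1 for rid, _ in pairs}
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            if _cached_dp(pairs[i][1], pairs[j][1]) <= l:
                ks[pairs[i][0]] += 1
                ks[pairs[j][0]] += 1
    return ks


def single_edit_pmf(s: str) -> dict[str, float]:
    """Outcome distribution of one uniform random edit, conditioned on the
    result being at distance exactly 1 (same-letter substitutions are
    rejected and resampled).

    Mirrors the adversary's sampler: operation uniform over
    {insert, delete, substitute}, position uniform, character uniform over
    the lowercase alphabet.
    """
    weights: dict[str, float] = {}
    n = len(s)
    ops = 3 if n else 1  # empty string: only insertion is available
    if n:
        for pos in range(n):  # delete
            out = s[:pos] + s[pos + 1:]
            weights[out] = weights.get(out, 0.0) + (1 / ops) * (1 / n)
        for pos in range(n):  # substitute (same char rejected)
            for c in ALPHABET:
                if c == s[pos]:
                    continue
                out = s[:pos] + c + s[pos + 1:]
                weights[out] = weights.get(out, 0.0) + (
                    (1 / ops) * (1 / n) * (1 / 26))
    for pos in range(n + 1):  # insert
        for c in ALPHABET:
            out = s[:pos] + c + s[pos:]
            weights[out] = weights.get(out, 0.0) + (
                (1 / ops) * (1 / (n + 1)) * (1 / 26))
    total = sum(weights.values())
    return {out: w / total for out, w in weights.items()}
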