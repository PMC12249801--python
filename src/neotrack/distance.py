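"""Capped, banded Levenshtein distance on amino-acid strings.

Specificity matching only ever needs to know whether two CDR3s are
within one (occasionally two) edits of each other, so the full dynamic
program is wasteful: the computation is restricted to a diagonal band of
half-width ``cap`` and abandoned as soon as every cell in the current
row exceeds the cap. Strings whose lengths differ by more than the cap
are rejected immediately.
"""

from __future__ import annotations

EXCEEDS_CAP = None
"""Sentinel returned when the distance is known to exceed the cap."""


def bounded_levenshtein(a: str, b: str, cap: int = 1) -> int | None:
    """Levenshtein distance between ``a`` and ``b`` if it is <= ``cap``.

    Returns the exact distance when it does not exceed ``cap``, otherwise
    :data:`EXCEEDS_CAP` (``None``). Symmetric in its arguments. Insertions,
    deletions and substitutions all cost 1.

    Raises ``ValueError`` for empty strings or a negative cap.
    """
    if not a or not b:
        raise ValueError("bounded_levenshtein requires non-empty strings")
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if a == b:
        return 0
    if cap == 0:
        return EXCEEDS_CAP
    la, lb = len(a), len(b)
    if abs(la - lb) > cap:
        return EXCEEDS_CAP
    if la > lb:  # keep the inner loop over the shorter string
        a, b, la, lb = b, a, lb, la

    big = cap + 1
    prev = list(range(la + 1))
    for j in range(1, lb + 1):
        cj = b[j - 1]
        cur = [big] * (la + 1)
        cur[0] = j if j <= cap else big
        lo = max(1, j - cap)
        hi = min(la, j + cap)
        row_min = cur[0] if lo == 1 else big
        for i in range(lo, hi + 1):
            cost = 0 if a[i - 1] == cj else 1
            val = prev[i - 1] + cost
            if prev[i] + 1 < val:
                val = prev[i] + 1
            if cur[i - 1] + 1 < val:
                val = cur[i - 1] + 1
            if val > cap:
                val = big
            cur[i] = val
            if val < row_min:
                row_min = val
        if row_min > cap:
            return EXCEEDS_CAP
        prev = cur
    d = prev[la]
    return d if d <= cap else EXCEEDS_CAP


def deletion_variants(s: str) -> list[str]:
    """All strings obtained from ``s`` by deleting exactly one character."""
    return [s[:i] + s[i + 1 :] for i in range(len(s))]
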