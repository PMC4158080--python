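"""Independent brute-force oracles used across the test suite.

Deliberately naive implementations, kept separate from the package code
paths they validate: per-position set membership for motif scoring,
substring enumeration for ATG counting, full combination enumeration for
exact Mann-Whitney p-values, and rank-then-Pearson for Spearman.
"""

from __future__ import annotations

import itertools
import math

_ALLOWED = {
    "A": {"A"},
    "C": {"C"},
    "G": {"G"},
    "T": {"T"},
    "W": {"A", "T"},
    "R": {"A", "G"},
    "Y": {"C", "T"},
    "S": {"C", "G"},
    "K": {"G", "T"},
    "M": {"A", "C"},
    "B": {"C", "G", "T"},
    "D": {"A", "G", "T"},
    "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def brute_mismatches(window: str, pattern: str) -> int:
    """Positionwise mismatch count; N in the window never matches."""
    assert len(window) == len(pattern)
    total = 0
    for w, p in zip(window.upper(), pattern.upper()):
        if w == "N" or w not in _ALLOWED[p]:
            total += 1
    return total


def brute_scan(window: str, pattern: str = "TATAWAG", max_mismatch: int = 1) -> tuple[str, int]:
    """Exhaustive sub-window scan; returns (class, min mismatches)."""
    k = len(pattern)
    best = min(
        brute_mismatches(window[i : i + k], pattern) for i in range(len(window) - k + 1)
    )
    if best == 0:
        cls = "canonical"
    elif best <= max_mismatch:
        cls = "one_mismatch"
    else:
        cls = "tata_less"
    return cls, best


def brute_atg_count(seq: str) -> list[int]:
    """Every index i with seq[i:i+3] == 'ATG', by direct enumeration."""
    s = seq.upper()
    return [i for i in range(len(s) - 2) if s[i : i + 3] == "ATG"]


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = mid
        i = j + 1
    return ranks


def exact_mwu_p(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all C(n1+n2, n1)
    assignments of the pooled midranks; returns (U_x, p)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = _midranks(pooled)
    mu = n1 * len(y) / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    dev = abs(u_obs - mu)
    total = extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def rank_pearson(x: list[float], y: list[float]) -> float:
    """Spearman rho as Pearson correlation of midranks, from scratch."""
    rx, ry = _midranks(list(x)), _midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
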