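"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately implemented from first principles (integer
enumeration, naive scans) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_upper_tail_enum(a: int, b: int, c: int, d: int) -> float:
    """Exact P(X >= a) by full hypergeometric enumeration (integer comb)."""
    n = a + b + c + d
    r1 = a + b  # SCP column total
    c1 = a + c  # gene row total
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    num = sum(math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(max(a, lo), hi + 1))
    return num / math.comb(n, r1)


def fisher_sweep(max_margin: int = 40):
    """Yield (a, b, c, d, exact_p) for every table with all margins <= max_margin."""
    for r1 in range(0, max_margin + 1):
        for c1 in range(0, max_margin + 1):
            lo_n = max(r1, c1, 1)
            hi_n = min(r1 + max_margin, c1 + max_margin, 2 * max_margin)
            for n in range(lo_n, hi_n + 1):
                lo = max(0, r1 + c1 - n)
                hi = min(r1, c1)
                if hi < lo:
                    continue
                denom = math.comb(n, c1)
                terms = [
                    math.comb(r1, k) * math.comb(n - r1, c1 - k)
                    for k in range(lo, hi + 1)
                ]
                suffix = 0
                for i in range(hi - lo, -1, -1):
                    suffix += terms[i]
                    a = lo + i
                    b = r1 - a
                    c = c1 - a
                    d = n - a - b - c
                    yield a, b, c, d, suffix / denom


def largest_gap_oracle(values: list[tuple]) -> set:
    """Evaluate every cut position explicitly; pick the maximal (topmost) gap."""
    vals = sorted(values, key=lambda t: (-t[1], t[0]))
    if len(vals) <= 1:
        return {s for s, _ in vals}
    best_gap, best_cut = -1.0, None
    for cut in range(len(vals) - 1):
        gap = vals[cut][1] - vals[cut + 1][1]
        if gap > best_gap:  # strict: first (topmost) maximal gap wins
            best_gap, best_cut = gap, cut
    if best_gap <= 0:
        return {s for s, _ in vals}
    return {s for s, _ in vals[: best_cut + 1]}


def matcher_oracle(entries, text: str, stop_terms=()) -> set:
    """Naive longest-match token scan over a dictionary list (no trie).

    Reimplements the matcher contract: whole-token case-insensitive matching,
    longest term wins at each position, non-gene classes suppress identical
    gene terms, all-lowercase stop terms only count when not spelled
    lowercase in the text.
    """
    import re

    tok = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")
    toks = tok.findall(text)
    low = [t.lower() for t in toks]
    keyed: dict[tuple, list] = {}
    for e in entries:
        key = tuple(t.lower() for t in tok.findall(e.term))
        keyed.setdefault(key, []).append(e)
    stop = {s.lower() for s in stop_terms}
    hits = set()
    i = 0
    while i < len(toks):
        best = None
        for key in keyed:
            if low[i : i + len(key)] == list(key):
                if best is None or len(key) > len(best):
                    best = key
        if best is None:
            i += 1
            continue
        group = keyed[best]
        surface = " ".join(toks[i : i + len(best)])
        suppressed = any(e.entity_class != "genes and proteins" for e in group) or (
            surface.lower() in stop and surface == surface.lower()
        )
        if not suppressed:
            hits |= {e.entity_id for e in group if e.entity_class == "genes and proteins"}
        i += len(best)
    return hits


def pearson_oracle(x, y) -> float:
    """Direct covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def ks_statistic_oracle(a, b) -> float:
    """D = sup |ECDF_a - ECDF_b| by brute-force sweep over all sample points."""
    a = sorted(a)
    b = sorted(b)
    points = sorted(set(a) | set(b))
    d = 0.0
    for t in points:
        fa = sum(1 for v in a if v <= t) / len(a)
        fb = sum(1 for v in b if v <= t) / len(b)
        d = max(d, abs(fa - fb))
    return d
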