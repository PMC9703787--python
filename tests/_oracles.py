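"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations they
check: the repeat oracle enumerates all substrings per length, the
aligner oracle is a quadratic dynamic program, and the correlation
oracle evaluates the textbook formulas directly.
"""

from __future__ import annotations

import math

import numpy as np

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def brute_force_repeats(seqs, min_len: int, tandem_gap: int = 0):
    """All interspersed maximal repeat families by exhaustive enumeration.

    Builds the same doubled text (sequences + reverse complements with
    unique separators), collects every substring of every length with
    >= 2 occurrences, and keeps those whose occurrences have >= 2
    distinct left characters and >= 2 distinct right characters.
    Returns sorted (canonical unit, copies) pairs, copies as
    (seq_id, start, end, strand).
    """
    text_parts, layout = [], []
    sep_i = 0
    for rec in seqs:
        for strand, s in (("+", rec.sequence), ("-", rc(rec.sequence))):
            layout.append((rec.id, strand, sum(len(t) for t in text_parts), len(s)))
            text_parts.append(s)
            text_parts.append(chr(1000 + sep_i))
            sep_i += 1
    text = "".join(text_parts)
    n = len(text)
    seq_by_id = {r.id: r.sequence for r in seqs}

    fams: dict[str, dict[tuple[str, int, int], str]] = {}
    L = min_len
    while True:
        pos: dict[str, list[int]] = {}
        for i in range(n - L + 1):
            sub = text[i : i + L]
            if any(ord(c) > 200 for c in sub):
                continue
            pos.setdefault(sub, []).append(i)
        groups = {u: p for u, p in pos.items() if len(p) >= 2}
        if not groups:
            break
        for u, p in groups.items():
            lefts = {text[i - 1] if i > 0 else chr(999) for i in p}
            rights = {text[i + L] if i + L < n else chr(998) for i in p}
            if len(lefts) >= 2 and len(rights) >= 2:
                canon = min(u, rc(u))
                occ = fams.setdefault(canon, {})
                for i in p:
                    for sid, strand, off, ln in layout:
                        if off <= i and i + L <= off + ln:
                            pp = i - off
                            iv = (pp, pp + L) if strand == "+" else (ln - pp - L, ln - pp)
                            gen = seq_by_id[sid][iv[0] : iv[1]]
                            occ[(sid, iv[0], iv[1])] = "+" if gen == canon else "-"
        L += 1

    out = []
    for canon, occ in fams.items():
        copies = sorted((sid, s, e, st) for (sid, s, e), st in occ.items())
        if len(copies) < 2:
            continue
        runs, prev = 0, None
        for c in copies:
            if prev is not None and c[0] == prev[0] and c[1] - prev[2] <= tandem_gap:
                prev = c
                continue
            runs += 1
            prev = c
        if runs >= 2:
            out.append((canon, tuple(copies)))
    return sorted(out)


def edit_distance_dp(a: str, b: str) -> int:
    """Quadratic Levenshtein distance (numpy row recurrence)."""
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    m = len(b)
    idx = np.arange(m + 1, dtype=np.int32)
    prev = idx.copy()
    for i, ca in enumerate(a.encode(), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (bb != ca), prev[1:] + 1)
        # insertion chain: cur[j] = min_{k<=j} cur[k] + (j - k)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def pearson_formula(xs, ys) -> tuple[float, float]:
    """Textbook product-moment r and two-sided p from the t transform."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as tdist

    p = 2.0 * tdist.sf(abs(t), n - 2)
    return r, p
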