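"""Brute-force, pure-Python tandem-repeat oracle.

Implements the documented detection algorithm (periodic self-match seeding,
consensus-guided edge refinement, harmonic suppression, span/period/position
overlap resolution) with plain loops and lists — no numpy — as an independent
cross-check of the vectorised implementation on short sequences.
"""

from __future__ import annotations


def consensus_unit(region: str, period: int) -> str:
    n_full = len(region) // period
    if n_full == 0:
        return region[:period]
    cols = []
    for j in range(period):
        column = [region[i * period + j] for i in range(n_full)]
        best = min(set(column), key=lambda b: (-column.count(b), b))
        cols.append(best)
    return "".join(cols)


def phase_consensus(sequence: str, a: int, span: int, p: int) -> str:
    if span >= 3 * p:
        return consensus_unit(sequence[a + p:a + span - p], p)
    return consensus_unit(sequence[a:a + span], p)


def consensus_identity(region: str, consensus: str) -> float:
    p = len(consensus)
    return sum(b == consensus[i % p] for i, b in enumerate(region)) / len(region)


def refine_edges(sequence: str, a: int, span: int, p: int,
                 consensus: str) -> tuple[int, int]:
    n = len(sequence)

    def agree(i: int) -> bool:
        return sequence[i] == consensus[(i - a) % p]

    def walk(start: int, step: int) -> int:
        edge, best, score, i = start, 0, 0, start
        while 0 <= i < n:
            if agree(i):
                score += 2
                if score >= best:
                    best, edge = score, i
            else:
                score -= 3
                if best - score >= 12:
                    break
            i += step
        return edge

    anchor = a + (span // (2 * p)) * p
    anchor = min(max(anchor, a), a + span - 1)
    left = walk(anchor, -1)
    right = walk(anchor, +1)
    return left, right - left + 1


def is_harmonic(sequence: str, a: int, span: int, p: int,
                min_identity: float, min_period: int) -> bool:
    region = sequence[a:a + span]
    for q in range(min_period, p):
        if p % q != 0 or len(region) <= q:
            continue
        if consensus_identity(region, consensus_unit(region, q)) >= min_identity:
            return True
    return False


def oracle_repeats(sequence: str, min_period: int = 5, max_period: int = 200,
                   min_copies: float = 2.5, min_identity: float = 0.85):
    """All accepted repeat regions as (start, stop, period, copy_number,
    consensus, mean_identity) tuples, 1-based inclusive coordinates."""
    n = len(sequence)
    candidates = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        m = [sequence[i] == sequence[i + p] for i in range(n - p)]
        if len(m) < p:
            continue
        wins = [sum(m[j:j + p]) for j in range(len(m) - p + 1)]
        seeds = [j for j, w in enumerate(wins) if w >= min_identity * p]
        if not seeds:
            continue
        groups = [[seeds[0]]]
        for j in seeds[1:]:
            if j - groups[-1][-1] > 2 * p:
                groups.append([])
            groups[-1].append(j)
        for g in groups:
            a, b = g[0], g[-1] + p - 1
            e = min(8, p)
            while b - a + 1 >= e and sum(m[a:a + e]) / e < 0.75:
                a += 1
            while b - a + 1 >= e and sum(m[b - e + 1:b + 1]) / e < 0.75:
                b -= 1
            while a <= b and not m[a]:
                a += 1
            while b >= a and not m[b]:
                b -= 1
            while a > 0 and m[a - 1]:
                a -= 1
            while b + 1 < len(m) and m[b + 1]:
                b += 1
            if b < a:
                continue
            span = (b + p) - a + 1
            cons = phase_consensus(sequence, a, span, p)
            a, span = refine_edges(sequence, a, span, p, cons)
            copies = round(span / p, 1)
            if copies < min_copies:
                continue
            if span <= p:
                continue
            cons = phase_consensus(sequence, a, span, p)
            ident = consensus_identity(sequence[a:a + span], cons)
            if ident < min_identity:
                continue
            if is_harmonic(sequence, a, span, p, min_identity, min_period):
                continue
            candidates.append((a + 1, a + span, p, copies, cons, ident))

    candidates.sort(key=lambda c: (-(c[1] - c[0] + 1), c[2], c[0]))
    accepted = []
    for cand in candidates:
        if any(cand[0] <= acc[1] and acc[0] <= cand[1] for acc in accepted):
            continue
        accepted.append(cand)
    accepted.sort()
    return accepted
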