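"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
enumeration, full dynamic programming) and share no code with the package
paths they check.
"""

import numpy as np


def candidate_oracle(hits_packed, n_windows, t, max_candidates=10**9):
    """Exhaustive interval-enumeration candidate selection.

    Enumerates every window interval of length <= n_windows per target,
    counts contained hits, keeps intervals with >= t hits, tightens each to
    its first/last contained hit, merges overlapping tight placements
    keeping the best (count desc, leftmost, shortest), and ranks like the
    production path.
    """
    hits = sorted((int(h) >> 32, int(h) & 0xFFFFFFFF) for h in np.asarray(hits_packed))
    out = []
    targets = sorted({t_ for t_, _ in hits})
    for tid in targets:
        wins = sorted(w for t_, w in hits if t_ == tid)
        placements = set()
        lo, hi = wins[0], wins[-1]
        for a in range(lo - n_windows + 1, hi + 1):
            b = a + n_windows - 1
            inside = [w for w in wins if a <= w <= b]
            if len(inside) >= t:
                placements.add((inside[0], inside[-1], len(inside)))
        # merge overlapping placements
        placements = sorted(placements)
        chains = []
        for p in placements:
            if chains and p[0] <= chains[-1][0]:
                chain = chains[-1]
                chain[0] = max(chain[0], p[1])
                if (-p[2], p[0], p[1]) < (-chain[1][2], chain[1][0], chain[1][1]):
                    chain[1] = p
            else:
                chains.append([p[1], p])
        out.extend((tid, c[1][0], c[1][1], c[1][2]) for c in chains)
    out.sort(key=lambda x: (-x[3], x[0], x[1]))
    return out[:max_candidates]


def dp_semiglobal_distance(query, region):
    """Full O(nm) edit distance with free leading/trailing region gaps."""
    m, n = len(query), len(region)
    prev = [0] * (n + 1)  # free leading gaps in the region
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            sub = prev[j - 1] + (query[i - 1] != region[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free trailing gaps
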