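"""Independent oracles used by the test suite.

These deliberately re-derive quantities with the simplest possible code
(per-base walks, exhaustive enumeration) and share no logic with the
package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

_CONSUME_Q = {0: True, 1: True, 4: True, 7: True, 8: True}
_CONSUME_R = {0: True, 2: True, 3: True, 7: True, 8: True}


def naive_pileup(reads, ref_len):
    """Per-base CIGAR re-walk into plain dictionaries.

    ``reads`` are (ref_start, cigartuples, query). Returns dicts keyed by
    position: base calls {pos: {base: n}}, deletions, insertion starts,
    read starts/ends.
    """
    base_calls: dict[int, dict[str, int]] = {}
    dels: dict[int, int] = {}
    ins: dict[int, int] = {}
    starts: dict[int, int] = {}
    ends: dict[int, int] = {}
    for ref_start, cig, query in reads:
        rpos, qpos = ref_start, 0
        for op, ln in cig:
            for _ in range(ln):
                if op in (0, 7, 8):
                    b = query[qpos]
                    if b in "ACGT":
                        base_calls.setdefault(rpos, {}).setdefault(b, 0)
                        base_calls[rpos][b] += 1
                    rpos += 1
                    qpos += 1
                elif op == 2:
                    dels[rpos] = dels.get(rpos, 0) + 1
                    rpos += 1
                elif op == 1:
                    qpos += 1
                elif op == 4:
                    qpos += 1
                elif op == 3:
                    rpos += 1
        # insertion events: one per I run, at the preceding ref position
        r = ref_start
        for op, ln in cig:
            if op == 1:
                ins[r - 1] = ins.get(r - 1, 0) + 1
            if _CONSUME_R.get(op):
                r += ln
        last = r - 1
        starts[ref_start] = starts.get(ref_start, 0) + 1
        ends[last] = ends.get(last, 0) + 1
    return base_calls, dels, ins, starts, ends


def random_read(rng, ref_seq, max_len=40, p_mismatch=0.1):
    """One random alignment with a random (valid) CIGAR over ``ref_seq``.

    Alignments start and end with an M run; D/I/S appear with moderate
    probability; query bases are reference with random mismatches.
    """
    L = len(ref_seq)
    start = int(rng.integers(0, L - 10))
    cig = []
    rpos = start
    query = []

    def m_run(n):
        nonlocal rpos
        n = min(n, L - rpos)
        if n <= 0:
            return False
        for i in range(n):
            b = ref_seq[rpos + i]
            if rng.random() < p_mismatch:
                b = "ACGT"[(("ACGT".index(b)) + int(rng.integers(1, 4))) % 4]
            query.append(b)
        cig.append((0, n))
        rpos += n
        return True

    if rng.random() < 0.3:
        ns = int(rng.integers(1, 5))
        cig.append((4, ns))
        query.extend(rng.choice(list("ACGT"), size=ns))
    m_run(int(rng.integers(3, 12)))
    for _ in range(int(rng.integers(0, 3))):
        r = rng.random()
        if r < 0.4 and rpos + 2 < L:  # deletion
            nd = int(rng.integers(1, 3))
            nd = min(nd, L - rpos - 2)
            cig.append((2, nd))
            rpos += nd
            if not m_run(int(rng.integers(2, 8))):
                break
        elif r < 0.8:  # insertion
            ni = int(rng.integers(1, 4))
            cig.append((1, ni))
            query.extend(rng.choice(list("ACGT"), size=ni))
            if not m_run(int(rng.integers(2, 8))):
                break
    if rng.random() < 0.3:
        ns = int(rng.integers(1, 5))
        cig.append((4, ns))
        query.extend(rng.choice(list("ACGT"), size=ns))
    # merge adjacent same-op runs (keeps the CIGAR canonical)
    merged = []
    for op, ln in cig:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return start, merged, "".join(query)


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration (no ties assumed).

    Enumerates every assignment of the pooled sample into groups of the
    observed sizes, computes the Mann-Whitney U of the first group, and
    returns min(1, 2 * P(U >= max(U_obs, nm - U_obs))).
    """
    x = list(x)
    y = list(y)
    n, m = len(x), len(y)
    pooled = x + y
    order = sorted(range(n + m), key=lambda i: pooled[i])
    ranks = [0] * (n + m)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    u_obs = sum(ranks[:n]) - n * (n + 1) / 2
    u_big = max(u_obs, n * m - u_obs)
    count = 0
    total = comb(n + m, n)
    all_ranks = list(range(1, n + m + 1))
    for combo in itertools.combinations(all_ranks, n):
        u = sum(combo) - n * (n + 1) / 2
        if u >= u_big:
            count += 1
    return min(1.0, 2.0 * count / total)
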