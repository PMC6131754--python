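"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a pipeline quantity directly from its definition
(naive loops, full enumeration) without sharing code paths with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from enhancer_rewire.formats_io import AlignmentChain, GenomicInterval


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.seq_id != b.seq_id:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def project_per_base(
    iv: GenomicInterval, chains: Sequence[AlignmentChain]
) -> Optional[Tuple[GenomicInterval, int]]:
    """Per-base projection: choose the chain exactly as the spec dictates
    (max score, then lower ref start, then chain id), then map every base."""
    best = None
    best_key = None
    for ch in chains:
        if ch.ref_seq != iv.seq_id:
            continue
        n_aligned = sum(
            1 for pos in range(iv.start, iv.end) if ch.map_base(pos) is not None
        )
        if n_aligned == 0:
            continue
        key = (-ch.score, ch.ref_start, ch.chain_id)
        if best is None or key < best_key:
            best, best_key = ch, key
    if best is None:
        return None
    mapped = [best.map_base(pos) for pos in range(iv.start, iv.end)]
    mapped = [m for m in mapped if m is not None]
    return GenomicInterval(best.query_seq, min(mapped), max(mapped) + 1), len(mapped)


def brute_force_tissue_pair(
    a_src, b_src, a_dst, b_dst, chains, min_overlap=50
) -> Dict[str, str]:
    """Naive re-derivation of the tissue-pair set algebra.

    Returns {enhancer_id: category} for every source enhancer surviving the
    within-species overlap removal step.
    """

    def ov(x, y):
        return overlap_bp(x, y) >= min_overlap

    a1 = [r for r in a_src if not any(ov(r.interval, s.interval) for s in b_src)]
    b1 = [r for r in b_src if not any(ov(r.interval, s.interval) for s in a_src)]
    a1m = [m for m in a_dst if not any(ov(m, x) for x in b_dst)]
    b1m = [m for m in b_dst if not any(ov(m, x) for x in a_dst)]

    cats: Dict[str, str] = {}

    def one_side(src, own_m, other_pool_fn):
        projected = {}
        for r in src:
            p = project_per_base(r.interval, chains)
            if p is None:
                cats[r.enhancer_id] = "EG"
            else:
                projected[r.enhancer_id] = (r, p[0])
        matched = set()
        remaining = {}
        for rid, (r, piv) in projected.items():
            hit = [i for i, m in enumerate(own_m) if ov(piv, m)]
            if hit:
                cats[rid] = "FCE"
                matched.update(hit)
            else:
                remaining[rid] = piv
        pool = [m for i, m in enumerate(own_m) if i not in matched]
        return remaining, pool

    rem_a, pool_a = one_side(a1, a1m, None)
    rem_b, pool_b = one_side(b1, b1m, None)
    for rid, piv in rem_a.items():
        cats[rid] = "RPE" if any(ov(piv, m) for m in pool_b) else "EG"
    for rid, piv in rem_b.items():
        cats[rid] = "RPE" if any(ov(piv, m) for m in pool_a) else "EG"
    return cats


def enumerate_scan(
    seq: str, motif, p_threshold: float, resolution: float = 1e-3
) -> List[Tuple[int, str, int]]:
    """All-words enumeration scanner: (start, strand, int_score) hits.

    Scores live on the same integer grid as the implementation (grid
    rounding is part of the scoring definition); p-values come from full
    enumeration of all 4**w words instead of convolution.
    """
    lo = motif.log_odds()
    ints = np.rint(lo / resolution).astype(int)
    w = motif.width
    bg = motif.background
    # exact tail by enumeration
    word_scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = sum(ints[i, b] for i, b in enumerate(word))
        p = math.prod(bg[b] for b in word)
        word_scores[s] = word_scores.get(s, 0.0) + p
    scores_sorted = sorted(word_scores, reverse=True)
    tail = {}
    acc = 0.0
    for s in scores_sorted:
        acc += word_scores[s]
        tail[s] = acc

    def pval(s):
        vals = [t for t in scores_sorted if t >= s]
        return tail[vals[-1]] if vals else 1.0

    code = {c: i for i, c in enumerate("ACGT")}
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start : start + w].upper()
        if any(c not in code for c in window):
            continue
        fwd = [code[c] for c in window]
        rev = [comp[b] for b in reversed(fwd)]
        for strand, word in (("+", fwd), ("-", rev)):
            s = sum(ints[i, b] for i, b in enumerate(word))
            if pval(s) <= p_threshold:
                hits.append((start, strand, s))
    return hits


def exact_rank_sum_p_greater(x: Sequence[float], y: Sequence[float]) -> float:
    """P(rank-sum of x >= observed) by full enumeration of group labels."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    total = 0
    ge = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        s = sum(sorted(ranks.values())[i] for i in combo)
        total += 1
        if s >= obs:
            ge += 1
    return ge / total


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def pmf(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = pmf(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def poisson_upper_tail(obs: int, lam: float) -> float:
    """P(X >= obs) for X ~ Poisson(lam), by direct summation."""
    if obs <= 0:
        return 1.0
    below = sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(obs))
    return 1.0 - below
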