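"""Enhancer filtering, cross-species projection, and FCE/RPE/EG classification.

An enhancer active in one species is compared with the enhancer landscape at
its orthologous location in a second species and labelled:

* ``FCE`` — functionally conserved: the orthologous region is an enhancer in
  the same tissue(s);
* ``RPE`` — reprogrammed: the orthologous region is an enhancer in at least
  one tissue in which the source enhancer is not active;
* ``EG``  — enhancer gain: no alignable ortholog, or the ortholog shows no
  enhancer activity at all.

Orthology is established by projecting intervals through pairwise alignment
chains; "did not align" means zero projected bases (an enhancer projecting a
single base proceeds to overlap testing, where the 50 bp intersection rule
governs functional overlap — no separate aligned-fraction threshold is
introduced).  RPE takes precedence over FCE when the ortholog is active both
in shared and in novel tissues, since reprogramming is defined by a
partially or fully different tissue set.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formats_io import AlignmentChain, GenomicInterval, repeat_fraction

__all__ = [
    "EnhancerRecord",
    "Projection",
    "TissuePairResult",
    "center_to_fixed_width",
    "filter_enhancers",
    "overlaps",
    "project",
    "classify_genome_wide",
    "classify_tissue_pair",
    "reprogramming_rate",
    "IntervalIndex",
]

DEFAULT_MIN_OVERLAP = 50
DEFAULT_MAX_LENGTH = 3000
DEFAULT_MAX_REPEAT = 0.75

FCE = "FCE"
RPE = "RPE"
EG = "EG"


@dataclass
class EnhancerRecord:
    """An enhancer interval, its tissue activity and (after classification)
    its conservation category and ortholog projection."""

    interval: GenomicInterval
    species: str = ""
    tissues: frozenset = frozenset()
    enhancer_id: Optional[str] = None
    ortholog: Optional[GenomicInterval] = None
    aligned_bases: int = 0
    category: Optional[str] = None
    reprogrammed_to: frozenset = frozenset()
    clipped: bool = False

    def __post_init__(self) -> None:
        self.tissues = frozenset(self.tissues)
        self.reprogrammed_to = frozenset(self.reprogrammed_to)


@dataclass(frozen=True)
class Projection:
    """Result of projecting an interval through a chain: the minimal query
    interval spanning all projected bases, and how many bases projected."""

    interval: GenomicInterval
    aligned_bases: int
    chain_id: str


def center_to_fixed_width(
    peak: GenomicInterval, width: int, seq_length: Optional[int] = None
) -> Tuple[GenomicInterval, bool]:
    """Re-centre a peak to a fixed width (e.g. 1 kb around the peak centre).

    Returns ``(interval, clipped)``; the interval is clipped at the sequence
    boundaries, in which case its length may fall short of ``width``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    center = (peak.start + peak.end) // 2
    start = center - width // 2
    end = start + width
    clipped = False
    if start < 0:
        end += -start  # keep the requested width where possible
        start = 0
        clipped = True
    if seq_length is not None and end > seq_length:
        end = seq_length
        clipped = True
    if end - start > width:
        end = start + width
    return GenomicInterval(peak.seq_id, start, end, peak.strand), clipped


def filter_enhancers(
    records: Iterable[EnhancerRecord],
    genome: Dict[str, str],
    max_length: int = DEFAULT_MAX_LENGTH,
    max_repeat_fraction: float = DEFAULT_MAX_REPEAT,
) -> Tuple[List[EnhancerRecord], List[Tuple[EnhancerRecord, str]]]:
    """Drop enhancers longer than ``max_length`` or with a repeat fraction
    exceeding ``max_repeat_fraction`` (both thresholds inclusive: a record
    exactly at the limit is kept, since only strict exceedance removes).

    Returns ``(kept, rejected)`` where each rejection carries the rule that
    fired.  Repeat content is the soft-masked (lowercase) fraction.
    """
    kept: List[EnhancerRecord] = []
    rejected: List[Tuple[EnhancerRecord, str]] = []
    for rec in records:
        iv = rec.interval
        if iv.seq_id not in genome:
            raise ValueError(f"sequence {iv.seq_id!r} not in genome")
        seq = genome[iv.seq_id]
        if iv.end > len(seq):
            raise ValueError(
                f"interval {iv} extends beyond sequence end ({len(seq)})"
            )
        if iv.length > max_length:
            rejected.append((rec, f"length {iv.length} > {max_length}"))
            continue
        rf = repeat_fraction(seq[iv.start : iv.end])
        if rf > max_repeat_fraction:
            rejected.append((rec, f"repeat fraction {rf:.3f} > {max_repeat_fraction}"))
            continue
        kept.append(rec)
    return kept, rejected


def overlaps(
    a: GenomicInterval, b: GenomicInterval, min_bp: int = DEFAULT_MIN_OVERLAP
) -> bool:
    """True iff the two intervals share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return a.overlap_length(b) >= min_bp


class IntervalIndex:
    """Sorted-start lookup of intervals on named sequences.

    Supports "any interval overlapping the query by >= min_bp" queries in
    O(log n + k).  Items may carry an arbitrary payload.
    """

    def __init__(self, items: Iterable[Tuple[GenomicInterval, object]]):
        by_seq: Dict[str, List[Tuple[int, int, object]]] = {}
        for iv, payload in items:
            by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end, payload))
        self._by_seq = {}
        self._max_len = {}
        for seq, lst in by_seq.items():
            lst.sort(key=lambda t: (t[0], t[1]))
            self._by_seq[seq] = lst
            self._max_len[seq] = max(e - s for s, e, _ in lst)

    def overlapping(
        self, query: GenomicInterval, min_bp: int = 1
    ) -> List[Tuple[GenomicInterval, object]]:
        lst = self._by_seq.get(query.seq_id)
        if not lst:
            return []
        max_len = self._max_len[query.seq_id]
        starts = [s for s, _, _ in lst]
        lo = bisect_right(starts, query.start - max_len)
        hi = bisect_right(starts, query.end - 1)
        out = []
        for s, e, payload in lst[lo:hi]:
            if min(e, query.end) - max(s, query.start) >= min_bp:
                out.append((GenomicInterval(query.seq_id, s, e), payload))
        return out


def _chains_by_ref(chains: Iterable[AlignmentChain]) -> Dict[str, List[AlignmentChain]]:
    out: Dict[str, List[AlignmentChain]] = {}
    for ch in chains:
        out.setdefault(ch.ref_seq, []).append(ch)
    return out


def project(
    interval: GenomicInterval, chains: Iterable[AlignmentChain]
) -> Optional[Projection]:
    """Project an interval into the other species through alignment chains.

    Among chains overlapping the interval, the highest-scoring one is used
    (ties broken by lower reference start, then chain id — no chain
    stitching).  Every reference base falling in an aligned block is
    projected; the result is the minimal query interval spanning the
    projected bases.  ``None`` when no base projects.
    """
    if isinstance(chains, dict):
        candidates = chains.get(interval.seq_id, [])
    else:
        candidates = [ch for ch in chains if ch.ref_seq == interval.seq_id]
    best: Optional[AlignmentChain] = None
    best_aligned = 0
    best_key = None
    for ch in candidates:
        aligned = 0
        for r, _, s in ch.blocks:
            if r >= interval.end:
                break
            aligned += max(0, min(r + s, interval.end) - max(r, interval.start))
        if aligned == 0:
            continue
        key = (-ch.score, ch.ref_start, ch.chain_id)
        if best is None or key < best_key:
            best, best_aligned, best_key = ch, aligned, key
    if best is None:
        return None
    lo = None
    hi = None
    for r, q, s in best.blocks:
        if r >= interval.end:
            break
        ov_start = max(r, interval.start)
        ov_end = min(r + s, interval.end)
        if ov_end <= ov_start:
            continue
        if best.query_reversed:
            q_lo = q + (s - (ov_end - r))
            q_hi = q + (s - (ov_start - r))
        else:
            q_lo = q + (ov_start - r)
            q_hi = q + (ov_end - r)
        lo = q_lo if lo is None else min(lo, q_lo)
        hi = q_hi if hi is None else max(hi, q_hi)
    return Projection(
        GenomicInterval(best.query_seq, lo, hi), best_aligned, best.chain_id
    )


def classify_genome_wide(
    records: Sequence[EnhancerRecord],
    dst_sets: Dict[str, Sequence[GenomicInterval]],
    chains: Iterable[AlignmentChain],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> List[EnhancerRecord]:
    """Genome-wide FCE/RPE/EG classification of source-species enhancers.

    ``dst_sets`` maps each tissue to the destination-species enhancer
    intervals active in that tissue.  Precedence per record:

    1. no projected base                                     -> EG
    2. projection overlaps (>= min_overlap) a destination enhancer in >= 1
       tissue *not* in the record's own tissue set           -> RPE
    3. projection overlaps destination enhancers only in shared tissues
                                                             -> FCE
    4. projection overlaps no destination enhancer           -> EG
    """
    missing = set().union(*(r.tissues for r in records)) - set(dst_sets) if records else set()
    if missing:
        raise ValueError(
            f"tissues present in records but absent from destination sets: "
            f"{sorted(missing)}"
        )
    chain_index = chains if isinstance(chains, dict) else _chains_by_ref(chains)
    index = IntervalIndex(
        (iv, tissue) for tissue, ivs in dst_sets.items() for iv in ivs
    )
    out: List[EnhancerRecord] = []
    for rec in records:
        proj = project(rec.interval, chain_index)
        if proj is None:
            out.append(replace(rec, category=EG, ortholog=None, aligned_bases=0,
                               reprogrammed_to=frozenset()))
            continue
        hit_tissues = {
            tissue for _, tissue in index.overlapping(proj.interval, min_overlap)
        }
        novel = frozenset(hit_tissues - rec.tissues)
        if novel:
            cat, rep = RPE, novel
        elif hit_tissues:
            cat, rep = FCE, frozenset()
        else:
            cat, rep = EG, frozenset()
        out.append(
            replace(rec, category=cat, ortholog=proj.interval,
                    aligned_bases=proj.aligned_bases, reprogrammed_to=rep)
        )
    return out


@dataclass
class TissuePairResult:
    """Outcome of the tissue-pair set algebra.

    Human-side input tissues A and B are reduced to their non-overlapping
    subsets (A1/B1), projected to the other species (A2/B2), intersected
    with the other species' non-overlapping subsets to find functionally
    conserved enhancers, and the remainders crossed to find reprogramming
    events in both directions.  Set membership is by record identity of the
    source-side records.
    """

    tissue_a: str
    tissue_b: str
    a1_src: List[EnhancerRecord] = field(default_factory=list)
    b1_src: List[EnhancerRecord] = field(default_factory=list)
    a1_dst: List[GenomicInterval] = field(default_factory=list)
    b1_dst: List[GenomicInterval] = field(default_factory=list)
    a2_src: List[EnhancerRecord] = field(default_factory=list)
    b2_src: List[EnhancerRecord] = field(default_factory=list)
    fce_a: List[EnhancerRecord] = field(default_factory=list)
    fce_b: List[EnhancerRecord] = field(default_factory=list)
    reprogrammed_a_to_b: List[EnhancerRecord] = field(default_factory=list)
    reprogrammed_b_to_a: List[EnhancerRecord] = field(default_factory=list)
    eg_a: List[EnhancerRecord] = field(default_factory=list)
    eg_b: List[EnhancerRecord] = field(default_factory=list)


def _non_overlapping(
    primary: Sequence, other: Sequence, min_overlap: int, key=lambda x: x
) -> List:
    """Members of ``primary`` overlapping no member of ``other`` >= min_overlap."""
    if not other:
        return list(primary)
    index = IntervalIndex((key(o), None) for o in other)
    return [p for p in primary if not index.overlapping(key(p), min_overlap)]


def classify_tissue_pair(
    a_src: Sequence[EnhancerRecord],
    b_src: Sequence[EnhancerRecord],
    a_dst: Sequence[GenomicInterval],
    b_dst: Sequence[GenomicInterval],
    chains: Iterable[AlignmentChain],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    tissue_a: Optional[str] = None,
    tissue_b: Optional[str] = None,
) -> TissuePairResult:
    """Tissue-pair categorisation by explicit set algebra.

    Steps: (i) within each species drop enhancers shared between tissues A
    and B; (ii) project the source-species subsets through the chains
    (failures -> EG); (iii) source enhancers whose projection overlaps the
    same-tissue destination subset are FCEs; (iv) destination enhancers not
    matched in (iii) form the candidate pools; (v) source-A projections
    overlapping the destination-B pool are reprogramming events A->B, and
    symmetrically; (vi) the leftovers join the EGs.
    """
    if tissue_a is None:
        tissue_a = sorted(a_src[0].tissues)[0] if a_src and a_src[0].tissues else "A"
    if tissue_b is None:
        tissue_b = sorted(b_src[0].tissues)[0] if b_src and b_src[0].tissues else "B"
    res = TissuePairResult(tissue_a=str(tissue_a), tissue_b=str(tissue_b))
    chain_index = chains if isinstance(chains, dict) else _chains_by_ref(chains)

    # (i) non-overlapping subsets within each species
    a1_src = _non_overlapping(a_src, b_src, min_overlap, key=lambda r: r.interval)
    b1_src = _non_overlapping(b_src, a_src, min_overlap, key=lambda r: r.interval)
    a1_dst = _non_overlapping(a_dst, b_dst, min_overlap)
    b1_dst = _non_overlapping(b_dst, a_dst, min_overlap)
    res.a1_src, res.b1_src = a1_src, b1_src
    res.a1_dst, res.b1_dst = a1_dst, b1_dst

    def side(src_recs, own_dst, fce_out, eg_out):
        projected = []  # (record, projection)
        for rec in src_recs:
            proj = project(rec.interval, chain_index)
            if proj is None:
                eg_out.append(replace(rec, category=EG, ortholog=None,
                                      aligned_bases=0))
            else:
                projected.append((rec, proj))
        # (iii) FCE: projection overlaps own-tissue destination subset
        own_index = IntervalIndex((iv, i) for i, iv in enumerate(own_dst))
        matched_dst: set = set()
        remaining = []
        for rec, proj in projected:
            hits = own_index.overlapping(proj.interval, min_overlap)
            if hits:
                matched_dst.update(i for _, i in hits)
                fce_out.append(replace(rec, category=FCE, ortholog=proj.interval,
                                       aligned_bases=proj.aligned_bases))
            else:
                remaining.append((rec, proj))
        # (iv) destination pool not matched as FCE
        pool = [iv for i, iv in enumerate(own_dst) if i not in matched_dst]
        return remaining, pool

    remaining_a, pool_a_dst = side(a1_src, a1_dst, res.fce_a, res.eg_a)
    remaining_b, pool_b_dst = side(b1_src, b1_dst, res.fce_b, res.eg_b)

    # (v) cross overlaps: A-source projections against the B destination pool
    pool_b_index = IntervalIndex((iv, None) for iv in pool_b_dst)
    for rec, proj in remaining_a:
        if pool_b_index.overlapping(proj.interval, min_overlap):
            res.reprogrammed_a_to_b.append(
                replace(rec, category=RPE, ortholog=proj.interval,
                        aligned_bases=proj.aligned_bases,
                        reprogrammed_to=frozenset({res.tissue_b}))
            )
        else:
            res.eg_a.append(replace(rec, category=EG, ortholog=proj.interval,
                                    aligned_bases=proj.aligned_bases))
    pool_a_index = IntervalIndex((iv, None) for iv in pool_a_dst)
    for rec, proj in remaining_b:
        if pool_a_index.overlapping(proj.interval, min_overlap):
            res.reprogrammed_b_to_a.append(
                replace(rec, category=RPE, ortholog=proj.interval,
                        aligned_bases=proj.aligned_bases,
                        reprogrammed_to=frozenset({res.tissue_a}))
            )
        else:
            res.eg_b.append(replace(rec, category=EG, ortholog=proj.interval,
                                    aligned_bases=proj.aligned_bases))
    return res


def reprogramming_rate(
    records: Sequence[EnhancerRecord], tissue: str
) -> Optional[float]:
    """Fraction of the tissue's enhancers categorised as reprogrammed.

    ``None`` when no record is active in the tissue.
    """
    active = [r for r in records if tissue in r.tissues]
    if not active:
        return None
    return sum(r.category == RPE for r in active) / len(active)
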