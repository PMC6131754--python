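"""PWM motif scanning and TFBS overrepresentation statistics.

Scanning scores every window on both strands with the motif's log2-odds
matrix and converts scores to exact word-probability p-values computed from
the full score distribution under the background model.  The distribution
is obtained by position-wise convolution on a discretised score grid
(resolution 1e-3 bits): per-position scores are rounded once to grid units
and every window is scored *on that grid*, so scan scores and the null
distribution live on the same lattice and the p-value of a score is exact
for the discretised matrix.

Overrepresentation of a motif in a region set is tested against random
control regions matched for length, GC and repeat content: with lambda the
control hit count rescaled to the region base count, the p-value is the
Poisson upper tail P(X >= observed), Bonferroni-corrected over the number
of motifs tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .formats_io import (
    GenomicInterval,
    MotifModel,
    gc_fraction,
    repeat_fraction,
)

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "ScoreTable",
    "scan",
    "scan_regions",
    "matched_controls",
    "enrichment",
    "tfbs_overlap_percentage",
]

SCORE_RESOLUTION = 1e-3  # bits per grid unit
LAMBDA_FLOOR = 1e-9

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes (A=0..T=3, anything else -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    """One PWM occurrence; the interval has exactly the motif's width."""

    interval: GenomicInterval
    motif_id: str
    strand: str
    score: float  # log2-odds, bits
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    observed_count: int
    expected_count: float
    p_value: float
    p_adjusted: float
    enriched: bool
    lambda_floored: bool = False


class ScoreTable:
    """Integer-grid scoring table and exact null tail for one motif."""

    def __init__(self, motif: MotifModel, resolution: float = SCORE_RESOLUTION):
        self.motif = motif
        self.resolution = resolution
        lo = motif.log_odds()  # (w, 4) in bits
        self.int_scores = np.rint(lo / resolution).astype(np.int64)
        # reverse-complement view: reversed positions, complemented bases
        self.int_scores_rc = self.int_scores[::-1, ::-1].copy()
        self._tail, self._offset = self._null_tail()

    def _null_tail(self) -> Tuple[np.ndarray, int]:
        """P(score >= s) over all words under the motif background."""
        bg = self.motif.background
        w = self.motif.width
        mins = self.int_scores.min(axis=1)
        maxs = self.int_scores.max(axis=1)
        offset = int(mins.sum())
        size = int((maxs - mins).sum()) + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        span = 0
        for i in range(w):
            new = np.zeros(size)
            for b in range(4):
                shift = int(self.int_scores[i, b] - mins[i])
                new[shift : shift + span + 1] += bg[b] * dist[: span + 1]
            span += int(maxs[i] - mins[i])
            dist = new
        tail = np.cumsum(dist[::-1])[::-1]
        return tail, offset

    def p_value(self, int_score: int) -> float:
        idx = int_score - self._offset
        if idx < 0:
            return 1.0
        if idx >= len(self._tail):
            return float(self._tail[-1]) if len(self._tail) else 1.0
        return float(min(1.0, self._tail[idx]))

    def window_scores(self, codes: np.ndarray, rc: bool = False) -> np.ndarray:
        """Integer score of every window; invalid (N-containing) -> minimal."""
        w = self.motif.width
        n = len(codes) - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        table = self.int_scores_rc if rc else self.int_scores
        safe = np.where(codes < 0, 0, codes)
        total = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for i in range(w):
            total += table[i, safe[i : i + n]]
            bad |= codes[i : i + n] < 0
        total[bad] = np.iinfo(np.int64).min
        return total


def scan(
    sequence: str,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    seq_id: str = "seq",
    offset: int = 0,
    both_strands: bool = True,
    table: Optional[ScoreTable] = None,
) -> List[MotifHit]:
    """All motif occurrences with p-value <= ``p_threshold``.

    Both strands are scanned by default; windows containing N are skipped.
    A palindromic motif therefore yields two hits (same interval, opposite
    strands) at a matching position — deduplication is deliberately off.
    ``offset`` shifts reported coordinates (for scanning sub-sequences).
    """
    if table is None:
        table = ScoreTable(motif)
    w = motif.width
    codes = encode(sequence)
    if len(codes) < w:
        return []
    hits: List[MotifHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        scores = table.window_scores(codes, rc=(strand == "-"))
        for pos in np.nonzero(scores > np.iinfo(np.int64).min)[0]:
            p = table.p_value(int(scores[pos]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        GenomicInterval(seq_id, offset + int(pos), offset + int(pos) + w),
                        motif.motif_id,
                        strand,
                        float(scores[pos]) * table.resolution,
                        p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_regions(
    regions: Sequence[Tuple[str, GenomicInterval]],
    genome: Dict[str, str],
    motifs: Sequence[MotifModel],
    p_threshold: float = 1e-4,
) -> Dict[str, List[MotifHit]]:
    """Scan genome slices for every motif; keyed by region label."""
    tables = {m.motif_id: ScoreTable(m) for m in motifs}
    out: Dict[str, List[MotifHit]] = {}
    for label, iv in regions:
        seq = genome[iv.seq_id][iv.start : iv.end]
        hits: List[MotifHit] = []
        for m in motifs:
            hits.extend(
                scan(seq, m, p_threshold, seq_id=iv.seq_id, offset=iv.start,
                     table=tables[m.motif_id])
            )
        out[label] = hits
    return out


def matched_controls(
    regions: Sequence[GenomicInterval],
    genome: Dict[str, str],
    n_per_region: int = 1,
    gc_tol: float = 0.02,
    repeat_tol: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 1000,
    max_relaxations: int = 5,
) -> List[GenomicInterval]:
    """Random regions matched for length, GC and repeat content.

    For each input region, ``n_per_region`` controls of identical length
    are drawn by rejection sampling anywhere in the genome outside the
    input regions, accepting placements with GC within ``gc_tol`` and
    repeat (lowercase) fraction within ``repeat_tol`` of the target.  After
    ``max_attempts`` rejections both tolerances are doubled (at most
    ``max_relaxations`` times) before giving up with an error naming the
    region.
    """
    if rng is None:
        rng = np.random.default_rng()
    seq_ids = sorted(genome)
    lengths = np.array([len(genome[s]) for s in seq_ids], dtype=float)
    weights = lengths / lengths.sum()
    # prefix sums for O(1) GC / repeat queries
    gc_prefix: Dict[str, np.ndarray] = {}
    rep_prefix: Dict[str, np.ndarray] = {}
    for s in seq_ids:
        arr = np.frombuffer(genome[s].encode("ascii"), dtype=np.uint8)
        is_gc = np.isin(arr, np.frombuffer(b"GCgc", dtype=np.uint8))
        is_low = (arr >= 97) & (arr <= 122)
        gc_prefix[s] = np.concatenate([[0], np.cumsum(is_gc)])
        rep_prefix[s] = np.concatenate([[0], np.cumsum(is_low)])
    forbidden: Dict[str, List[Tuple[int, int]]] = {}
    for iv in regions:
        forbidden.setdefault(iv.seq_id, []).append((iv.start, iv.end))

    controls: List[GenomicInterval] = []
    for iv in regions:
        target_gc = gc_fraction(genome[iv.seq_id][iv.start : iv.end])
        target_rep = repeat_fraction(genome[iv.seq_id][iv.start : iv.end])
        for _ in range(n_per_region):
            tol_gc, tol_rep = gc_tol, repeat_tol
            placed = None
            for _relax in range(max_relaxations + 1):
                for _att in range(max_attempts):
                    si = rng.choice(len(seq_ids), p=weights)
                    s = seq_ids[si]
                    limit = len(genome[s]) - iv.length
                    if limit <= 0:
                        continue
                    start = int(rng.integers(0, limit))
                    end = start + iv.length
                    if any(
                        min(end, fe) - max(start, fs) > 0
                        for fs, fe in forbidden.get(s, [])
                    ):
                        continue
                    gc = (gc_prefix[s][end] - gc_prefix[s][start]) / iv.length
                    rep = (rep_prefix[s][end] - rep_prefix[s][start]) / iv.length
                    if abs(gc - target_gc) <= tol_gc and abs(rep - target_rep) <= tol_rep:
                        placed = GenomicInterval(s, start, end)
                        break
                if placed is not None:
                    break
                tol_gc *= 2
                tol_rep *= 2
            if placed is None:
                raise RuntimeError(
                    f"could not place a matched control for region {iv} "
                    f"after {max_relaxations} tolerance relaxations"
                )
            controls.append(placed)
    return controls


def enrichment(
    region_seqs: Sequence[str],
    control_seqs: Sequence[str],
    motifs: Sequence[MotifModel],
    alpha: float = 0.05,
    p_threshold: float = 1e-4,
) -> List[EnrichmentResult]:
    """Per-motif Poisson overrepresentation test of regions vs controls.

    observed = total hits across regions; lambda = control hits scaled by
    total region bp / total control bp; p = P(X >= observed) for
    X ~ Poisson(lambda), Bonferroni-corrected over all motifs tested.
    A zero lambda with positive observed count is floored at 1e-9 and
    flagged.  Overlapping hits of the same motif count individually.
    """
    region_bp = sum(len(s) for s in region_seqs)
    control_bp = sum(len(s) for s in control_seqs)
    if control_bp == 0:
        raise ValueError("no control sequence provided")
    n_motifs = len(motifs)
    results: List[EnrichmentResult] = []
    for m in motifs:
        table = ScoreTable(m)
        obs = sum(
            len(scan(s, m, p_threshold, table=table)) for s in region_seqs
        )
        ctrl = sum(
            len(scan(s, m, p_threshold, table=table)) for s in control_seqs
        )
        lam = ctrl * (region_bp / control_bp)
        floored = False
        if lam == 0.0 and obs > 0:
            lam = LAMBDA_FLOOR
            floored = True
        if obs == 0:
            p = 1.0
        else:
            p = float(stats.poisson.sf(obs - 1, lam))
        p_adj = min(1.0, p * n_motifs)
        results.append(
            EnrichmentResult(m.motif_id, obs, lam, p, p_adj, p_adj <= alpha, floored)
        )
    return results


def tfbs_overlap_percentage(
    enriched_rpe: Iterable[str], enriched_ref: Iterable[str]
) -> Optional[float]:
    """Percentage of RPE-overrepresented motifs also overrepresented in the
    reference set; ``None`` when the RPE set is empty."""
    rpe = set(enriched_rpe)
    if not rpe:
        return None
    return 100.0 * len(rpe & set(enriched_ref)) / len(rpe)
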