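"""Gene locus construction and the expression consequences of reprogramming.

A gene's locus is the genomic territory bounded at the midpoints of the
intergenic gaps to its neighbours (first/last loci run to the sequence
ends), so loci tile each sequence.  Enhancers are assigned to loci with the
same >= 50 bp overlap rule used everywhere else; an enhancer straddling a
boundary goes to the locus with the larger overlap (ties to the
lower-coordinate locus).

The reprogramming shift test asks whether genes whose loci contain
reprogrammed enhancers of a given tissue pair are expressed higher in the
tissue the enhancers are active in than in the partner tissue: the
statistic is the ratio of median (median-normalised) expressions and a
one-sided Wilcoxon rank-sum p-value (exact enumeration for small samples,
normal approximation with continuity correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enhancer_classify import EnhancerRecord
from .formats_io import GenomicInterval

__all__ = [
    "GeneLocus",
    "build_loci",
    "assign_enhancers_to_loci",
    "normalize_expression",
    "ShiftResult",
    "rpe_expression_shift",
    "bin_by_enhancer_count",
    "seloci_test",
]

EXACT_WILCOXON_MAX_N = 8


@dataclass
class GeneLocus:
    gene_id: str
    gene: GenomicInterval
    locus: GenomicInterval
    enhancers: List[EnhancerRecord] = field(default_factory=list)


def build_loci(
    genes: Sequence[Tuple[str, GenomicInterval]],
    sequence_lengths: Dict[str, int],
) -> List[GeneLocus]:
    """Tile each sequence into gene loci bounded at intergenic midpoints.

    For consecutive genes the boundary sits at the midpoint of the gap
    between them; overlapping genes get the midpoint of their overlap (the
    same arithmetic).  The first locus starts at 0 and the last ends at the
    sequence length.
    """
    by_seq: Dict[str, List[Tuple[str, GenomicInterval]]] = {}
    for gid, iv in genes:
        if iv.seq_id not in sequence_lengths:
            raise ValueError(f"gene {gid}: unknown sequence {iv.seq_id!r}")
        if iv.end > sequence_lengths[iv.seq_id]:
            raise ValueError(
                f"gene {gid} at {iv} extends beyond sequence length "
                f"{sequence_lengths[iv.seq_id]}"
            )
        by_seq.setdefault(iv.seq_id, []).append((gid, iv))
    loci: List[GeneLocus] = []
    for seq_id in sorted(by_seq):
        lst = sorted(by_seq[seq_id], key=lambda t: (t[1].start, t[1].end))
        length = sequence_lengths[seq_id]
        bounds = [0]
        for (_, prev), (_, nxt) in zip(lst, lst[1:]):
            bounds.append((prev.end + nxt.start) // 2)
        bounds.append(length)
        for (gid, iv), lo, hi in zip(lst, bounds, bounds[1:]):
            loci.append(GeneLocus(gid, iv, GenomicInterval(seq_id, lo, hi)))
    return loci


def assign_enhancers_to_loci(
    loci: Sequence[GeneLocus],
    records: Iterable[EnhancerRecord],
    min_overlap: int = 50,
) -> None:
    """Attach each enhancer to the locus it overlaps by >= ``min_overlap``.

    A straddling enhancer goes to the locus with the larger overlap; exact
    ties go to the lower-coordinate locus.  Enhancers overlapping no locus
    sufficiently are left unassigned.
    """
    by_seq: Dict[str, List[GeneLocus]] = {}
    for loc in loci:
        loc.enhancers = []
        by_seq.setdefault(loc.locus.seq_id, []).append(loc)
    for lst in by_seq.values():
        lst.sort(key=lambda l: l.locus.start)
    for rec in records:
        candidates = by_seq.get(rec.interval.seq_id, [])
        best = None
        best_key = None
        for loc in candidates:
            ov = loc.locus.overlap_length(rec.interval)
            if ov >= min_overlap:
                key = (-ov, loc.locus.start)
                if best is None or key < best_key:
                    best, best_key = loc, key
        if best is not None:
            best.enhancers.append(rec)


def normalize_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each tissue column by its median over all genes."""
    if table.empty:
        raise ValueError("empty expression table")
    out = table.copy()
    for col in table.columns:
        med = table[col].median(skipna=True)
        if not np.isfinite(med) or med == 0:
            raise ValueError(f"tissue {col!r} has zero or undefined median expression")
        out[col] = table[col] / med
    return out


@dataclass(frozen=True)
class ShiftResult:
    fold_change: float  # median(tissue_b) / median(tissue_a)
    p_value: float
    n_genes: int
    tissue_a: str
    tissue_b: str
    reliable: bool  # False when < 2 genes were available
    genes: tuple = ()


def rpe_expression_shift(
    rpe_records: Sequence[EnhancerRecord],
    loci: Sequence[GeneLocus],
    expression: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    min_overlap: int = 50,
) -> ShiftResult:
    """Expression shift at genes flanking a tissue-pair's reprogrammed set.

    Selects genes whose locus contains >= 1 enhancer of ``rpe_records``
    and compares their expression in ``tissue_b`` (where the enhancers are
    active in this species) against ``tissue_a`` (the partner tissue):
    fold change of medians plus a one-sided Wilcoxon rank-sum p-value for
    tissue_b > tissue_a.
    """
    for t in (tissue_a, tissue_b):
        if t not in expression.columns:
            raise ValueError(f"tissue {t!r} not in expression table")
    assign_enhancers_to_loci(loci, rpe_records, min_overlap=min_overlap)
    genes = sorted(
        {loc.gene_id for loc in loci if loc.enhancers} & set(expression.index)
    )
    vals = expression.loc[genes, [tissue_a, tissue_b]].dropna()
    a = vals[tissue_a].to_numpy()
    b = vals[tissue_b].to_numpy()
    n = len(vals)
    if n == 0:
        return ShiftResult(float("nan"), float("nan"), 0, tissue_a, tissue_b, False)
    fold = float(np.median(b) / np.median(a))
    if n == 1:
        return ShiftResult(fold, 1.0, 1, tissue_a, tissue_b, False, tuple(vals.index))
    p = wilcoxon_rank_sum_greater(b, a)
    return ShiftResult(fold, p, n, tissue_a, tissue_b, n >= 2, tuple(vals.index))


def wilcoxon_rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum P(x shifted above y).

    Exact enumeration (no ties) up to 8 per group, else the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (
        len(x) <= EXACT_WILCOXON_MAX_N
        and len(y) <= EXACT_WILCOXON_MAX_N
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def bin_by_enhancer_count(
    loci: Sequence[GeneLocus],
    expression: Optional[pd.DataFrame] = None,
    tissue: Optional[str] = None,
    max_bin: int = 20,
) -> pd.DataFrame:
    """Summarise gene loci binned by how many enhancers they contain.

    Per bin: number of genes, median normalised expression (when an
    expression table and tissue are given), and the FCE/RPE/EG fractions of
    the bin's enhancers.  Bins above ``max_bin`` are pooled.  Enhancers
    must already be assigned to loci.
    """
    rows = []
    bins: Dict[int, List[GeneLocus]] = {}
    for loc in loci:
        b = min(len(loc.enhancers), max_bin)
        bins.setdefault(b, []).append(loc)
    for b in sorted(bins):
        members = bins[b]
        recs = [r for loc in members for r in loc.enhancers]
        n_enh = len(recs)
        row = {
            "bin": b,
            "n_genes": len(members),
            "n_enhancers": n_enh,
        }
        if expression is not None and tissue is not None:
            gene_ids = [loc.gene_id for loc in members if loc.gene_id in expression.index]
            row["median_expression"] = (
                float(expression.loc[gene_ids, tissue].median()) if gene_ids else float("nan")
            )
        for cat in ("FCE", "RPE", "EG"):
            row[f"frac_{cat}"] = (
                sum(r.category == cat for r in recs) / n_enh if n_enh else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def seloci_test(loci: Sequence[GeneLocus]) -> Optional[pd.DataFrame]:
    """Category make-up of single-enhancer loci (seLoci) versus the rest.

    For each category a 2x2 table (enhancer in a seLocus vs in a
    multi-enhancer locus) x (category vs not) is tested with a two-sided
    Fisher exact test.  The observed fraction in seLoci is reported next
    to the overall fraction ("expected by chance" if categories were
    spread uniformly across loci).  ``None`` when there is no seLocus.
    """
    se_recs = [r for loc in loci if len(loc.enhancers) == 1 for r in loc.enhancers]
    multi_recs = [r for loc in loci if len(loc.enhancers) > 1 for r in loc.enhancers]
    if not se_recs:
        return None
    all_recs = se_recs + multi_recs
    rows = []
    for cat in ("FCE", "RPE", "EG"):
        a = sum(r.category == cat for r in se_recs)
        b = len(se_recs) - a
        c = sum(r.category == cat for r in multi_recs)
        d = len(multi_recs) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "n_seloci_cat": a,
                "n_seloci": len(se_recs),
                "frac_seloci": a / len(se_recs),
                "frac_all": sum(r.category == cat for r in all_recs) / len(all_recs),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("category")
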