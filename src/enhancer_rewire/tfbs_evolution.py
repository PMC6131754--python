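"""Evolutionary categorisation of TFBSs within orthologous enhancer pairs.

Each motif occurrence on the source (reference) side of an orthologous
enhancer pair is labelled by what happened to it across the alignment:

* ``TFBSC`` (conserved)  — the site maps through the alignment onto an
  occurrence of the *same* motif in the other species;
* ``TFBSR`` (reused)     — the site maps, but onto an occurrence of a
  *different* motif (mutations rewired the site for a different factor);
* ``TFBSH`` (reshuffled) — the site does not map positionally, yet the same
  motif occurs elsewhere in the counterpart enhancer;
* ``TFBSG`` (gained)     — the site has no counterpart of any kind.

"Maps" means at least ``min_mapped_fraction`` of the site's bases project
through the chain (default 0.5).  Precedence is exactly
C > R > H > G: mapping evidence outranks mere presence.  "Same TF" is
operationalised as same motif identifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .enhancer_classify import project
from .formats_io import AlignmentChain, GenomicInterval
from .motif_analysis import MotifHit

__all__ = [
    "SITE_CATEGORIES",
    "CategorizedSite",
    "categorize_sites",
    "density",
    "compare_rpe_fce",
    "DensityComparison",
]

TFBSC = "TFBSC"
TFBSH = "TFBSH"
TFBSG = "TFBSG"
TFBSR = "TFBSR"
SITE_CATEGORIES = (TFBSC, TFBSH, TFBSG, TFBSR)


@dataclass(frozen=True)
class CategorizedSite:
    hit: MotifHit
    category: str
    projected: Optional[GenomicInterval]
    mapped_fraction: float


def categorize_sites(
    hits_src: Sequence[MotifHit],
    hits_dst: Sequence[MotifHit],
    chains: Iterable[AlignmentChain],
    min_mapped_fraction: float = 0.5,
    enhancer_src: Optional[GenomicInterval] = None,
) -> List[CategorizedSite]:
    """Assign each source-side hit exactly one of the four site categories.

    ``hits_src``/``hits_dst`` must be restricted to one orthologous
    enhancer pair; the chains must cover that pair.  Output order follows
    a canonical sort of the input hits, so categorisation is independent
    of input ordering.
    """
    if enhancer_src is not None:
        for h in hits_src:
            if h.interval.overlap_length(enhancer_src) < h.interval.length:
                raise ValueError(
                    f"hit {h.interval} lies outside the source enhancer {enhancer_src}"
                )
    dst_motifs = {h.motif_id for h in hits_dst}
    ordered = sorted(hits_src, key=lambda h: (h.interval, h.motif_id, h.strand))
    out: List[CategorizedSite] = []
    for h in ordered:
        proj = project(h.interval, chains)
        frac = (proj.aligned_bases / h.interval.length) if proj else 0.0
        mapped = frac >= min_mapped_fraction
        category = TFBSG
        projected = proj.interval if proj else None
        if mapped:
            same = any(
                d.motif_id == h.motif_id and d.interval.overlap_length(proj.interval) >= 1
                for d in hits_dst
            )
            if same:
                category = TFBSC
            else:
                other = any(
                    d.motif_id != h.motif_id
                    and d.interval.overlap_length(proj.interval) >= 1
                    for d in hits_dst
                )
                if other:
                    category = TFBSR
                elif h.motif_id in dst_motifs:
                    category = TFBSH
        elif h.motif_id in dst_motifs:
            category = TFBSH
        out.append(CategorizedSite(h, category, projected, frac))
    return out


def density(hits_in_category: Sequence, enhancer_length: int) -> float:
    """Sites per kilobase."""
    if enhancer_length <= 0:
        raise ValueError("enhancer_length must be > 0")
    n = hits_in_category if isinstance(hits_in_category, int) else len(hits_in_category)
    return 1000.0 * n / enhancer_length


@dataclass(frozen=True)
class DensityComparison:
    """Per tissue pair: RPE vs FCE site density and a verdict per category."""

    tissue_pair: str
    rpe_density: Dict[str, float]
    fce_density: Dict[str, float]
    verdict: Dict[str, str]  # higher / lower / equal


def _verdict(rpe: float, fce: float, tolerance: float) -> str:
    if fce == 0.0 and rpe == 0.0:
        return "equal"
    ref = fce if fce != 0.0 else rpe
    if abs(rpe - fce) <= tolerance * abs(ref):
        return "equal"
    return "higher" if rpe > fce else "lower"


def compare_rpe_fce(
    rpe_densities: Dict[str, Dict[str, float]],
    fce_densities: Dict[str, Dict[str, float]],
    tolerance: float = 0.01,
) -> Tuple[List[DensityComparison], pd.DataFrame]:
    """Compare per-category TFBS densities between RPEs and matched FCEs.

    Inputs map tissue-pair id -> {category -> density (sites/kb)}.  A pair
    missing from the FCE side is skipped.  Densities within a relative
    ``tolerance`` (default 1%) are called "equal" — without a band,
    equality would be measure-zero for continuous densities.

    Returns the per-pair comparisons and a summary table with, per
    category, the fraction of tissue pairs in each verdict.
    """
    comparisons: List[DensityComparison] = []
    for pair in sorted(rpe_densities):
        if pair not in fce_densities:
            continue
        rpe = rpe_densities[pair]
        fce = fce_densities[pair]
        verdicts = {
            cat: _verdict(rpe.get(cat, 0.0), fce.get(cat, 0.0), tolerance)
            for cat in SITE_CATEGORIES
        }
        comparisons.append(DensityComparison(pair, dict(rpe), dict(fce), verdicts))
    rows = []
    n = len(comparisons)
    for cat in SITE_CATEGORIES:
        counts = {"higher": 0, "lower": 0, "equal": 0}
        for c in comparisons:
            counts[c.verdict[cat]] += 1
        rows.append(
            {
                "category": cat,
                "n_pairs": n,
                **{k: (v / n if n else float("nan")) for k, v in counts.items()},
            }
        )
    return comparisons, pd.DataFrame(rows).set_index("category")
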