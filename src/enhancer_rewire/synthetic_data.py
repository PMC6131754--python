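"""Two-species toy dataset generator with planted ground truth.

The generator emits everything the pipeline consumes — two soft-masked
genomes, a UCSC chain linking them, per-tissue enhancer sets for both
species, a motif library with planted occurrences, gene annotations and
expression tables — together with a truth table for every planted label, so
every downstream stage can be scored against known answers.

Construction is unit-based: each enhancer (or small group of enhancers
sharing a gene locus) occupies one *unit* consisting of an optional
species-A-only gap, an optional species-B-only gap, and an aligned segment
holding flanking pads, the enhancer(s) and a gene body.  Aligned segments
are copied from A to B with per-base substitutions and short indels; the
chain blocks fall out of that copy.  Planted categories:

* FCE  — ortholog present in B, active in the identical tissue set;
* RPE  — ortholog present in B, active in at least one tissue absent from
  the A-side set (half fully switched, half partially, by default);
* EG   — either placed in an A-only gap (unalignable) or aligned but with
  no enhancer annotated on the B side (50/50 split; all-aligned when
  alignment coverage is 1).

Motif sites are planted per orthologous enhancer pair in the four
evolutionary flavours (conserved / gained / reshuffled / reused), editing
consensus strings directly into the assembled sequences, and expression
tables carry a planted fold-change at genes flanking reprogrammed
enhancers in the tissue where the local enhancer copy is active.

A single RNG stream seeded from the config drives every draw in documented
order, so a given config reproduces its outputs byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .enhancer_classify import EnhancerRecord
from .formats_io import (
    AlignmentChain,
    GenomicInterval,
    MotifModel,
    write_bed,
    write_chain,
    write_expression,
    write_fasta,
    write_meme,
)
from .motif_analysis import MotifHit

__all__ = ["ScenarioConfig", "SyntheticDataset", "simulate", "plant_expression",
           "make_motif_library"]

_PAD = 150          # aligned pad flanking each unit, bp
_MID = 100          # gap between enhancer and gene body, bp
_GENE_LEN = 300     # gene body length, bp
_SLOT_GAP = 6       # spacing between planted motif sites, bp
_SITE_CAT = {"conserved": "TFBSC", "gained": "TFBSG",
             "reshuffled": "TFBSH", "reused": "TFBSR"}


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic scenario."""

    seed: int = 0
    n_sequences: int = 2
    sequence_length: int = 300_000
    n_tissues: int = 4
    n_enhancers: int = 200
    category_fractions: Tuple[float, float, float] = (0.02, 0.42, 0.56)  # FCE, RPE, EG
    enhancer_length_range: Tuple[int, int] = (200, 800)
    alignment_coverage: float = 0.7
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    repeat_fraction: float = 0.2
    motif_events_per_enhancer: Dict[str, int] = field(
        default_factory=lambda: {"conserved": 1, "gained": 1, "reshuffled": 1, "reused": 1}
    )
    # optional per-category overrides (e.g. plant extra gained sites only in
    # RPEs to emulate reprogramming through TFBS acquisition)
    motif_events_rpe: Optional[Dict[str, int]] = None
    motif_events_fce: Optional[Dict[str, int]] = None
    n_motifs: int = 6
    motif_width: int = 8
    expression_fold_change: float = 1.4
    expression_noise_sd: float = 0.5
    expression_baseline: float = 100.0
    multi_tissue_fraction: float = 0.1
    partial_reprogram_fraction: float = 0.5
    enhancers_per_locus_range: Tuple[int, int] = (1, 1)
    rpe_bias_by_locus_size: bool = False

    def validate(self) -> None:
        if abs(sum(self.category_fractions) - 1.0) > 1e-6:
            raise ValueError("category_fractions must sum to 1")
        if not (0.0 < self.alignment_coverage <= 1.0):
            raise ValueError("alignment_coverage must be in (0, 1]")
        if self.n_tissues < 2 and self.category_fractions[1] > 0:
            raise ValueError("reprogramming requires at least 2 tissues")
        lo, hi = self.enhancer_length_range
        if lo < 100 or hi < lo:
            raise ValueError("enhancer_length_range must satisfy 100 <= lo <= hi")
        for d in (self.motif_events_per_enhancer, self.motif_events_rpe,
                  self.motif_events_fce):
            unknown = set(d or {}) - set(_SITE_CAT)
            if unknown:
                raise ValueError(f"unknown motif event kinds: {sorted(unknown)}")


def _apportion(fractions: Sequence[float], n: int) -> List[int]:
    """Integer counts summing to n, largest-remainder rounding."""
    raw = [f * n for f in fractions]
    base = [int(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def make_motif_library(
    n_motifs: int, width: int, rng: np.random.Generator,
    consensus_prob: float = 0.97,
) -> List[MotifModel]:
    """Sharp-consensus motifs with mutually distant consensi.

    Consensi are drawn until pairwise Hamming distance >= 3 holds against
    every earlier consensus and its reverse complement (so no palindromes
    or near-duplicates sneak in).
    """
    consensi: List[np.ndarray] = []
    while len(consensi) < n_motifs:
        cand = rng.integers(0, 4, width)
        rc = (3 - cand)[::-1]
        if np.sum(cand != rc) < 3:
            continue
        ok = True
        for prev in consensi:
            if np.sum(cand != prev) < 3 or np.sum(rc != prev) < 3:
                ok = False
                break
        if ok:
            consensi.append(cand)
    off = (1.0 - consensus_prob) / 3.0
    motifs = []
    for i, cons in enumerate(consensi):
        mat = np.full((width, 4), off)
        mat[np.arange(width), cons] = consensus_prob
        motifs.append(MotifModel(f"M{i + 1}", mat))
    return motifs


def _diverge(
    a_seg: np.ndarray, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> Tuple[np.ndarray, List[Tuple[int, int, int]]]:
    """Copy a segment with substitutions and short indels.

    Returns the query-side segment and (ref_off, query_off, size) blocks
    relative to the segment starts.
    """
    n = len(a_seg)

    def _subst(chunk: np.ndarray) -> np.ndarray:
        chunk = chunk.copy()
        if sub_rate > 0 and len(chunk):
            m = rng.random(len(chunk)) < sub_rate
            k = int(m.sum())
            if k:
                chunk[m] = (chunk[m] + rng.integers(1, 4, k)) % 4
        return chunk

    if indel_rate <= 0:
        return _subst(a_seg), [(0, 0, n)]
    k = int(rng.binomial(n, indel_rate))
    if k == 0:
        return _subst(a_seg), [(0, 0, n)]
    pos = np.sort(rng.choice(n, size=k, replace=False))
    is_del = rng.random(k) < 0.5
    lens = np.minimum(rng.geometric(0.5, k), 5)
    parts: List[np.ndarray] = []
    blocks: List[Tuple[int, int, int]] = []
    prev = 0
    b_off = 0
    for p, d, L in zip(pos, is_del, lens):
        p = int(p)
        if p < prev:
            continue
        if p > prev:
            parts.append(_subst(a_seg[prev:p]))
            blocks.append((prev, b_off, p - prev))
            b_off += p - prev
        if d:
            prev = min(p + int(L), n)
        else:
            parts.append(rng.integers(0, 4, int(L)))
            b_off += int(L)
            prev = p
    if prev < n:
        parts.append(_subst(a_seg[prev:]))
        blocks.append((prev, b_off, n - prev))
    b_seg = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    return b_seg, blocks


def _span(
    blocks: Sequence[Tuple[int, int, int]], start: int, end: int
) -> Optional[Tuple[int, int, int]]:
    """Query span (lo, hi, aligned_bases) of ref range [start, end)."""
    lo = hi = None
    aligned = 0
    for r, q, s in blocks:
        ov_s, ov_e = max(r, start), min(r + s, end)
        if ov_e <= ov_s:
            continue
        aligned += ov_e - ov_s
        q_lo = q + (ov_s - r)
        q_hi = q + (ov_e - r)
        lo = q_lo if lo is None else min(lo, q_lo)
        hi = q_hi if hi is None else max(hi, q_hi)
    if lo is None:
        return None
    return lo, hi, aligned


def _merge_blocks(blocks: List[Tuple[int, int, int]]) -> List[Tuple[int, int, int]]:
    out: List[Tuple[int, int, int]] = []
    for r, q, s in blocks:
        if out and out[-1][0] + out[-1][2] == r and out[-1][1] + out[-1][2] == q:
            pr, pq, ps = out[-1]
            out[-1] = (pr, pq, ps + s)
        else:
            out.append((r, q, s))
    return out


def _decode(arr: np.ndarray, lower_mask: np.ndarray) -> str:
    upper = np.array(list("ACGT"), dtype="<U1")[arr]
    lower = np.array(list("acgt"), dtype="<U1")[arr]
    return "".join(np.where(lower_mask, lower, upper).tolist())


def _repeat_run(mask: np.ndarray, start: int, length: int,
                fraction: float, rng: np.random.Generator) -> None:
    """Mark one lowercase run covering ~fraction of [start, start+length)."""
    run = int(round(fraction * length))
    if run <= 0 or length <= 0:
        return
    off = int(rng.integers(0, max(1, length - run + 1)))
    mask[start + off : start + off + run] = True


@dataclass
class _Unit:
    """One gene locus under construction (1..k enhancers + gene body)."""

    seq_index: int
    enh_ids: List[int]


@dataclass
class SyntheticDataset:
    """In-memory bundle of a simulated scenario plus its ground truth."""

    config: ScenarioConfig
    sequences_a: Dict[str, str]
    sequences_b: Dict[str, str]
    chains: List[AlignmentChain]
    motifs: List[MotifModel]
    truth: pd.DataFrame                 # one row per species-A enhancer
    motif_sites: pd.DataFrame           # planted site truth, both species
    genes_a: List[Tuple[str, GenomicInterval]]
    genes_b: List[Tuple[str, GenomicInterval]]
    genes_truth: pd.DataFrame
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    skipped_motif_events: int = 0

    # -- convenience views -------------------------------------------------
    @property
    def tissues(self) -> List[str]:
        return [f"T{i + 1}" for i in range(self.config.n_tissues)]

    def records(self, species: str) -> List[EnhancerRecord]:
        """Planted enhancers of one species as EnhancerRecord objects."""
        out = []
        for row in self.truth.itertuples():
            if species == "A":
                tissues = row.tissues_a.split(",")
                iv = GenomicInterval(row.seq, row.start, row.end)
            else:
                if row.category == "EG":
                    continue
                tissues = row.tissues_b.split(",")
                iv = GenomicInterval(row.seq, row.b_start, row.b_end)
            out.append(
                EnhancerRecord(iv, species=species, tissues=frozenset(tissues),
                               enhancer_id=f"{row.enhancer_id}")
            )
        return out

    def tissue_sets(self, species: str) -> Dict[str, List[GenomicInterval]]:
        sets: Dict[str, List[GenomicInterval]] = {t: [] for t in self.tissues}
        for rec in self.records(species):
            for t in rec.tissues:
                sets[t].append(rec.interval)
        return sets

    def planted_hits(self, enhancer_id: int, species: str) -> List[MotifHit]:
        """Planted motif sites of one enhancer as MotifHit objects."""
        sub = self.motif_sites[
            (self.motif_sites.enhancer_id == enhancer_id)
            & (self.motif_sites.species == species)
        ]
        return [
            MotifHit(GenomicInterval(r.seq, r.start, r.end), r.motif_id, "+",
                     0.0, 1e-9)
            for r in sub.itertuples()
        ]

    def write(self, outdir) -> Dict[str, Path]:
        """Write the full bundle to disk in the pipeline's standard formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}

        def _p(name: str) -> Path:
            paths[name] = outdir / name
            return paths[name]

        write_fasta(_p("speciesA.fa"), self.sequences_a)
        write_fasta(_p("speciesB.fa"), self.sequences_b)
        write_chain(_p("A_to_B.chain"), self.chains)
        write_meme(_p("motifs.meme"), self.motifs)
        for species in ("A", "B"):
            sets = self.tissue_sets(species)
            for tissue in self.tissues:
                ivs = sorted(sets[tissue])
                write_bed(_p(f"enhancers_{species}_{tissue}.bed"),
                          [(iv, tissue) for iv in ivs])
        write_bed(_p("genes_A.bed"), [(iv, gid) for gid, iv in self.genes_a])
        write_bed(_p("genes_B.bed"), [(iv, gid) for gid, iv in self.genes_b])
        write_expression(_p("expression_A.tsv"), self.expression_a)
        write_expression(_p("expression_B.tsv"), self.expression_b)
        self.truth.to_csv(_p("truth.tsv"), sep="\t", index=False)
        self.motif_sites.to_csv(_p("motif_sites.tsv"), sep="\t", index=False)
        self.genes_truth.to_csv(_p("genes_truth.tsv"), sep="\t", index=False)
        with open(_p("scenario.yaml"), "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)
        return paths


def plant_expression(
    genes_truth: pd.DataFrame,
    tissues: Sequence[str],
    fold_change: float,
    noise_sd: float,
    rng: np.random.Generator,
    baseline: float = 100.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Expression tables with the planted fold-change.

    Every gene starts from a common baseline; in each species the gene is
    multiplied by ``fold_change`` in the tissues where its locus enhancer
    is active in that species, then log-normal noise of scale ``noise_sd``
    is applied.  With ``noise_sd = 0`` and ``fold_change = 1`` all tissues
    are identical per gene.
    """
    gene_ids = genes_truth.gene_id.tolist()
    tables = {}
    for species, col in (("A", "elevated_a"), ("B", "elevated_b")):
        values = np.full((len(gene_ids), len(tissues)), float(baseline))
        for gi, elev in enumerate(genes_truth[col]):
            if isinstance(elev, str) and elev:
                for t in elev.split(","):
                    values[gi, tissues.index(t)] *= fold_change
        if noise_sd > 0:
            values *= np.exp(rng.normal(0.0, noise_sd, size=values.shape))
        tables[species] = pd.DataFrame(values, index=gene_ids, columns=list(tissues))
        tables[species].index.name = "gene_id"
    return tables["A"], tables["B"]


def _plant_motif_events(
    runs: List[Tuple[int, int, int]],
    a_enh: Tuple[int, int],
    motifs: List[MotifModel],
    counts: Dict[str, int],
    rng: np.random.Generator,
    arr_a: np.ndarray,
    arr_b: np.ndarray,
) -> Tuple[List[Tuple[str, int, int, str, str]], int]:
    """Plant the four flavours of motif site into one enhancer pair.

    ``runs`` are (a_abs, b_abs, size) aligned runs within the pair.
    Returns ``(sites, skipped)`` with sites as
    (species, start, end, motif_id, planted_kind) tuples.
    """
    width = motifs[0].width
    events: List[str] = []
    for kind in ("conserved", "reused", "reshuffled", "gained"):
        events.extend([kind] * counts.get(kind, 0))
    needed = sum(2 if k == "reused" else 1 for k in events)
    skipped = 0
    while needed > len(motifs):
        events.pop()
        skipped += 1
        needed = sum(2 if k == "reused" else 1 for k in events)
    order = rng.permutation(len(motifs))
    motif_iter = iter(order)

    # slot allocator over aligned runs
    slots: List[Tuple[int, int]] = []
    for a0, b0, size in sorted(runs):
        off = 0
        while off + width <= size:
            slots.append((a0 + off, b0 + off))
            off += width + _SLOT_GAP
    slot_iter = iter(slots)

    sites: List[Tuple[str, int, int, str, str]] = []

    def consensus(m: MotifModel) -> np.ndarray:
        return m.matrix.argmax(axis=1)

    for kind in events:
        try:
            if kind == "reshuffled":
                a_slot = next(slot_iter)
                b_slot = next(slot_iter)
            else:
                a_slot = next(slot_iter)
        except StopIteration:
            skipped += 1
            continue
        if kind == "conserved":
            m = motifs[next(motif_iter)]
            arr_a[a_slot[0] : a_slot[0] + width] = consensus(m)
            arr_b[a_slot[1] : a_slot[1] + width] = consensus(m)
            sites.append(("A", a_slot[0], a_slot[0] + width, m.motif_id, kind))
            sites.append(("B", a_slot[1], a_slot[1] + width, m.motif_id, kind))
        elif kind == "reused":
            m1 = motifs[next(motif_iter)]
            m2 = motifs[next(motif_iter)]
            arr_a[a_slot[0] : a_slot[0] + width] = consensus(m1)
            arr_b[a_slot[1] : a_slot[1] + width] = consensus(m2)
            sites.append(("A", a_slot[0], a_slot[0] + width, m1.motif_id, kind))
            sites.append(("B", a_slot[1], a_slot[1] + width, m2.motif_id, kind))
        elif kind == "reshuffled":
            m = motifs[next(motif_iter)]
            arr_a[a_slot[0] : a_slot[0] + width] = consensus(m)
            arr_b[b_slot[1] : b_slot[1] + width] = consensus(m)
            sites.append(("A", a_slot[0], a_slot[0] + width, m.motif_id, kind))
            sites.append(("B", b_slot[1], b_slot[1] + width, m.motif_id, kind))
        else:  # gained: species A only
            m = motifs[next(motif_iter)]
            arr_a[a_slot[0] : a_slot[0] + width] = consensus(m)
            sites.append(("A", a_slot[0], a_slot[0] + width, m.motif_id, kind))
    return sites, skipped


def simulate(config: ScenarioConfig, outdir=None) -> SyntheticDataset:
    """Generate a full scenario; optionally write it to ``outdir``.

    Deterministic given ``config.seed``: rerunning with the same config
    yields byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = [f"T{i + 1}" for i in range(config.n_tissues)]
    n = config.n_enhancers
    lmin, lmax = config.enhancer_length_range
    cov = config.alignment_coverage

    # --- per-enhancer category / tissue assignment ------------------------
    n_fce, n_rpe, n_eg = _apportion(config.category_fractions, n)
    categories = ["FCE"] * n_fce + ["RPE"] * n_rpe + ["EG"] * n_eg
    eg_modes_pool = ["gap"] * (n_eg - n_eg // 2) + ["aligned"] * (n_eg // 2)
    if cov >= 1.0:
        eg_modes_pool = ["aligned"] * n_eg

    # --- group enhancers into units (gene loci) ---------------------------
    k_lo, k_hi = config.enhancers_per_locus_range
    unit_sizes: List[int] = []
    left = n
    while left > 0:
        k = int(rng.integers(k_lo, k_hi + 1)) if k_hi > k_lo else k_lo
        k = min(k, left)
        unit_sizes.append(k)
        left -= k
    if config.rpe_bias_by_locus_size:
        # put RPEs preferentially into large units: order slots by unit
        # size ascending and hand out EG/FCE before RPE
        unit_order = sorted(range(len(unit_sizes)), key=lambda i: (unit_sizes[i], i))
        ordered_cats = (
            ["EG"] * n_eg + ["FCE"] * n_fce + ["RPE"] * n_rpe
        )
    else:
        unit_order = list(range(len(unit_sizes)))
        ordered_cats = [categories[i] for i in rng.permutation(n)]
    rng.shuffle(eg_modes_pool)
    eg_mode_iter = iter(eg_modes_pool)

    units: List[_Unit] = []
    enh_cat: List[str] = [""] * n
    slot = 0
    assignment: List[List[int]] = [[] for _ in unit_sizes]
    for ui in unit_order:
        for _ in range(unit_sizes[ui]):
            assignment[ui].append(slot)
            slot += 1
    # enhancer ids are global, in unit order
    enh_id = 0
    id_map: List[List[int]] = []
    cat_per_unit: List[List[str]] = []
    for ui in range(len(unit_sizes)):
        ids = []
        cats = []
        for s in assignment[ui]:
            ids.append(enh_id)
            cats.append(ordered_cats[s])
            enh_id += 1
        id_map.append(ids)
        cat_per_unit.append(cats)
        units.append(_Unit(seq_index=ui % config.n_sequences, enh_ids=ids))

    # per-enhancer attributes, drawn in id order
    enh_len: List[int] = [0] * n
    tissues_a: List[frozenset] = [frozenset()] * n
    tissues_b: List[Optional[frozenset]] = [None] * n
    eg_mode: List[str] = [""] * n
    for ui, unit in enumerate(units):
        for j, eid in enumerate(unit.enh_ids):
            cat = cat_per_unit[ui][j]
            enh_cat[eid] = cat
            enh_len[eid] = int(rng.integers(lmin, lmax + 1))
            t = tissues[int(rng.integers(0, len(tissues)))]
            tset = {t}
            if (
                config.multi_tissue_fraction > 0
                and len(tissues) > 2
                and rng.random() < config.multi_tissue_fraction
            ):
                others = [x for x in tissues if x not in tset]
                tset.add(others[int(rng.integers(0, len(others)))])
            tissues_a[eid] = frozenset(tset)
            if cat == "FCE":
                tissues_b[eid] = frozenset(tset)
            elif cat == "RPE":
                novel_pool = [x for x in tissues if x not in tset]
                t_new = novel_pool[int(rng.integers(0, len(novel_pool)))]
                if rng.random() < config.partial_reprogram_fraction:
                    tissues_b[eid] = frozenset(tset | {t_new})
                else:
                    tissues_b[eid] = frozenset({t_new})
            else:
                eg_mode[eid] = next(eg_mode_iter)

    # --- assemble sequences, chain and coordinates ------------------------
    seq_names = [f"chr{i + 1}" for i in range(config.n_sequences)]
    seqs_a: Dict[str, str] = {}
    seqs_b: Dict[str, str] = {}
    chains: List[AlignmentChain] = []
    coords: Dict[int, dict] = {}          # per enhancer id
    gene_coords: List[dict] = []          # per unit
    arrs_a: Dict[str, np.ndarray] = {}
    arrs_b: Dict[str, np.ndarray] = {}
    masks_a: Dict[str, np.ndarray] = {}
    masks_b: Dict[str, np.ndarray] = {}
    pair_runs: Dict[int, List[Tuple[int, int, int]]] = {}

    for si, seq in enumerate(seq_names):
        a_parts: List[np.ndarray] = []
        b_parts: List[np.ndarray] = []
        am_parts: List[np.ndarray] = []
        bm_parts: List[np.ndarray] = []
        blocks_abs: List[Tuple[int, int, int]] = []
        a_pos = b_pos = 0
        for ui, unit in enumerate(units):
            if unit.seq_index != si:
                continue
            ids = unit.enh_ids
            gap_ids = [e for e in ids if enh_cat[e] == "EG" and eg_mode[e] == "gap"]
            aligned_ids = [e for e in ids if e not in gap_ids]
            # layout keeps every enhancer inside its own gene's locus: the
            # gene body comes first, its enhancers follow, and a mirror-length
            # desert pad pushes the midpoint boundary past the last enhancer
            enh_block = sum(enh_len[e] + _MID for e in aligned_ids)
            desert = _PAD + enh_block + _MID
            aligned_len = _PAD + _GENE_LEN + _MID + enh_block + desert
            ga_base = int(round(aligned_len * (1.0 - cov) / cov))
            ga = ga_base
            gap_needed = sum(enh_len[e] + 40 for e in gap_ids)
            if gap_ids:
                ga = max(ga, 2 * gap_needed + 400)
            gb = int(round(ga_base * rng.uniform(0.5, 1.5))) if ga_base > 0 else 0

            # A-only gap (hosts gap-mode EG enhancers near its tail, so they
            # stay on the downstream gene's side of the locus boundary)
            if ga > 0:
                gap_arr = rng.integers(0, 4, ga)
                gap_mask = np.zeros(ga, dtype=bool)
                off = ga - gap_needed
                for e in gap_ids:
                    coords[e] = {"seq": seq, "start": a_pos + off,
                                 "end": a_pos + off + enh_len[e]}
                    off += enh_len[e] + 40
                if not gap_ids:
                    _repeat_run(gap_mask, 0, ga, config.repeat_fraction, rng)
                a_parts.append(gap_arr)
                am_parts.append(gap_mask)
                a_pos += ga
            # B-only gap
            if gb > 0:
                b_arr = rng.integers(0, 4, gb)
                b_mask = np.zeros(gb, dtype=bool)
                _repeat_run(b_mask, 0, gb, config.repeat_fraction, rng)
                b_parts.append(b_arr)
                bm_parts.append(b_mask)
                b_pos += gb

            # aligned segment
            a_seg = rng.integers(0, 4, aligned_len)
            seg_mask = np.zeros(aligned_len, dtype=bool)
            _repeat_run(seg_mask, 0, _PAD, config.repeat_fraction, rng)
            _repeat_run(seg_mask, aligned_len - _PAD, _PAD,
                        config.repeat_fraction, rng)
            b_seg, seg_blocks = _diverge(
                a_seg, config.substitution_rate, config.indel_rate, rng
            )
            g_start = _PAD
            off = _PAD + _GENE_LEN + _MID
            for e in aligned_ids:
                a_start, a_end = a_pos + off, a_pos + off + enh_len[e]
                coords[e] = {"seq": seq, "start": a_start, "end": a_end}
                span = _span(seg_blocks, off, off + enh_len[e])
                if span is not None and enh_cat[e] != "EG":
                    b_lo, b_hi, _ = span
                    coords[e]["b_start"] = b_pos + b_lo
                    coords[e]["b_end"] = b_pos + b_hi
                    pair_runs[e] = [
                        (a_pos + max(r, off),
                         b_pos + q + (max(r, off) - r),
                         min(r + s, off + enh_len[e]) - max(r, off))
                        for r, q, s in seg_blocks
                        if min(r + s, off + enh_len[e]) - max(r, off) > 0
                    ]
                off += enh_len[e] + _MID
            g_span = _span(seg_blocks, g_start, g_start + _GENE_LEN)
            gene_coords.append(
                {
                    "unit": ui,
                    "seq": seq,
                    "a_start": a_pos + g_start,
                    "a_end": a_pos + g_start + _GENE_LEN,
                    "b_start": (b_pos + g_span[0]) if g_span else None,
                    "b_end": (b_pos + g_span[1]) if g_span else None,
                }
            )
            blocks_abs.extend(
                (a_pos + r, b_pos + q, s) for r, q, s in seg_blocks
            )
            a_parts.append(a_seg)
            am_parts.append(seg_mask)
            b_parts.append(b_seg)
            bm_parts.append(np.zeros(len(b_seg), dtype=bool))
            a_pos += aligned_len
            b_pos += len(b_seg)

        if a_pos > config.sequence_length:
            raise ValueError(
                f"infeasible packing: sequence {seq} needs {a_pos} bp but "
                f"sequence_length is {config.sequence_length}; reduce "
                f"n_enhancers or increase sequence_length"
            )
        tail_a = config.sequence_length - a_pos
        if tail_a > 0:
            a_parts.append(rng.integers(0, 4, tail_a))
            am_parts.append(np.zeros(tail_a, dtype=bool))
            a_pos += tail_a
        tail_b = max(200, tail_a)
        b_parts.append(rng.integers(0, 4, tail_b))
        bm_parts.append(np.zeros(tail_b, dtype=bool))
        b_pos += tail_b

        arrs_a[seq] = np.concatenate(a_parts) if a_parts else np.empty(0, np.int64)
        arrs_b[seq] = np.concatenate(b_parts) if b_parts else np.empty(0, np.int64)
        masks_a[seq] = np.concatenate(am_parts) if am_parts else np.empty(0, bool)
        masks_b[seq] = np.concatenate(bm_parts) if bm_parts else np.empty(0, bool)
        merged = _merge_blocks(blocks_abs)
        if merged:
            chains.append(
                AlignmentChain(
                    chain_id=str(si + 1),
                    score=float(sum(s for _, _, s in merged)),
                    ref_seq=seq,
                    ref_size=a_pos,
                    query_seq=seq,
                    query_size=b_pos,
                    blocks=tuple(merged),
                )
            )

    # --- motif library and planted sites ----------------------------------
    motifs = make_motif_library(config.n_motifs, config.motif_width, rng)
    site_rows: List[dict] = []
    skipped_total = 0
    for eid in range(n):
        if enh_cat[eid] == "EG" or eid not in pair_runs:
            continue
        seq = coords[eid]["seq"]
        if enh_cat[eid] == "RPE" and config.motif_events_rpe is not None:
            counts = config.motif_events_rpe
        elif enh_cat[eid] == "FCE" and config.motif_events_fce is not None:
            counts = config.motif_events_fce
        else:
            counts = config.motif_events_per_enhancer
        sites, skipped = _plant_motif_events(
            pair_runs[eid],
            (coords[eid]["start"], coords[eid]["end"]),
            motifs,
            counts,
            rng,
            arrs_a[seq],
            arrs_b[seq],
        )
        skipped_total += skipped
        for species, s0, s1, motif_id, kind in sites:
            site_rows.append(
                {
                    "enhancer_id": eid,
                    "species": species,
                    "seq": seq,
                    "start": s0,
                    "end": s1,
                    "motif_id": motif_id,
                    "planted_kind": kind,
                    "category": _SITE_CAT[kind],
                }
            )
    if skipped_total:
        warnings.warn(f"{skipped_total} motif events skipped (no room)")
    motif_sites = pd.DataFrame(
        site_rows,
        columns=["enhancer_id", "species", "seq", "start", "end", "motif_id",
                 "planted_kind", "category"],
    )

    # planted sites must stay uppercase
    for r in site_rows:
        mask = masks_a if r["species"] == "A" else masks_b
        mask[r["seq"]][r["start"] : r["end"]] = False

    seqs_a = {s: _decode(arrs_a[s], masks_a[s]) for s in seq_names}
    seqs_b = {s: _decode(arrs_b[s], masks_b[s]) for s in seq_names}

    # --- enhancer truth table ---------------------------------------------
    rows = []
    for ui, unit in enumerate(units):
        gene_id = f"g{ui:04d}"
        for eid in unit.enh_ids:
            c = coords[eid]
            has_ortholog = "b_start" in c
            rows.append(
                {
                    "enhancer_id": eid,
                    "seq": c["seq"],
                    "start": c["start"],
                    "end": c["end"],
                    "category": enh_cat[eid],
                    "eg_mode": eg_mode[eid],
                    "tissues_a": ",".join(sorted(tissues_a[eid])),
                    "tissues_b": ",".join(sorted(tissues_b[eid]))
                    if tissues_b[eid] else "",
                    "b_start": c.get("b_start", -1),
                    "b_end": c.get("b_end", -1),
                    "gene_id": gene_id,
                    "category_b": (
                        ""
                        if not has_ortholog or enh_cat[eid] == "EG"
                        else ("RPE" if tissues_a[eid] - tissues_b[eid] else "FCE")
                    ),
                }
            )
    truth = pd.DataFrame(rows).sort_values("enhancer_id").reset_index(drop=True)

    # --- genes and expression ---------------------------------------------
    genes_a: List[Tuple[str, GenomicInterval]] = []
    genes_b: List[Tuple[str, GenomicInterval]] = []
    gene_rows = []
    for gc in gene_coords:
        ui = gc["unit"]
        gene_id = f"g{ui:04d}"
        genes_a.append((gene_id, GenomicInterval(gc["seq"], gc["a_start"], gc["a_end"])))
        if gc["b_start"] is not None and gc["b_end"] > gc["b_start"]:
            genes_b.append(
                (gene_id, GenomicInterval(gc["seq"], gc["b_start"], gc["b_end"]))
            )
        elev_a: set = set()
        elev_b: set = set()
        for eid in units[ui].enh_ids:
            elev_a |= set(tissues_a[eid])
            if tissues_b[eid]:
                elev_b |= set(tissues_b[eid])
        gene_rows.append(
            {
                "gene_id": gene_id,
                "elevated_a": ",".join(sorted(elev_a)),
                "elevated_b": ",".join(sorted(elev_b)),
                "n_enhancers": len(units[ui].enh_ids),
                "has_rpe": any(enh_cat[e] == "RPE" for e in units[ui].enh_ids),
            }
        )
    genes_truth = pd.DataFrame(gene_rows)
    expr_a, expr_b = plant_expression(
        genes_truth,
        tissues,
        config.expression_fold_change,
        config.expression_noise_sd,
        rng,
        baseline=config.expression_baseline,
    )

    ds = SyntheticDataset(
        config=config,
        sequences_a=seqs_a,
        sequences_b=seqs_b,
        chains=chains,
        motifs=motifs,
        truth=truth,
        motif_sites=motif_sites,
        genes_a=genes_a,
        genes_b=genes_b,
        genes_truth=genes_truth,
        expression_a=expr_a,
        expression_b=expr_b,
        skipped_motif_events=skipped_total,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
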