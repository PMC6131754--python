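"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based, half-open, on the forward strand,
regardless of the source dialect; conversions happen only at the I/O
boundary.  In particular, UCSC chain records with a ``-`` query strand are
flipped to forward-strand query coordinates at parse time (the flip is
recorded on the chain so the record can be written back verbatim).

Soft-masking (lowercase bases) in FASTA is treated as the repeat signal:
the repeat fraction of an interval is simply its lowercase fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "AlignmentChain",
    "MotifModel",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_chain",
    "write_chain",
    "read_meme",
    "write_meme",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "read_genes_bed",
    "gc_fraction",
    "repeat_fraction",
]

BASES = "ACGT"


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open, 0-based span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when on different sequences."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.seq_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AlignmentChain:
    """An ordered list of ungapped blocks mapping reference to query.

    ``blocks`` are ``(ref_start, query_start, size)`` triples with both
    coordinates on the forward strand.  When ``query_reversed`` is set the
    original chain had a ``-`` query strand: within each block reference
    base ``ref_start + k`` pairs with query base ``query_start + size-1-k``,
    and blocks run in decreasing query order as reference increases.
    """

    chain_id: str
    score: float
    ref_seq: str
    ref_size: int
    query_seq: str
    query_size: int
    blocks: tuple
    query_reversed: bool = False

    def __post_init__(self) -> None:
        prev_r = prev_q = None
        for r, q, s in self.blocks:
            if s < 1:
                raise ValueError(f"chain {self.chain_id}: block size {s} < 1")
            if prev_r is not None:
                if r < prev_r:
                    raise ValueError(f"chain {self.chain_id}: blocks not sorted by ref")
                if not self.query_reversed and q < prev_q:
                    raise ValueError(f"chain {self.chain_id}: query blocks not increasing")
                if self.query_reversed and q > prev_q:
                    raise ValueError(f"chain {self.chain_id}: reversed query blocks not decreasing")
            prev_r, prev_q = r + s, q

    @property
    def ref_start(self) -> int:
        return self.blocks[0][0]

    @property
    def ref_end(self) -> int:
        r, _, s = self.blocks[-1]
        return r + s

    def aligned_bases(self) -> int:
        return sum(s for _, _, s in self.blocks)

    def map_base(self, ref_pos: int) -> Optional[int]:
        """Forward-strand query position paired with ``ref_pos``, or None."""
        for r, q, s in self.blocks:
            if r <= ref_pos < r + s:
                k = ref_pos - r
                return q + (s - 1 - k) if self.query_reversed else q + k
        return None

    def invert(self) -> "AlignmentChain":
        """The same alignment with reference and query roles swapped."""
        inv = [(q, r, s) for r, q, s in self.blocks]
        inv.sort(key=lambda b: b[0])
        return AlignmentChain(
            chain_id=self.chain_id,
            score=self.score,
            ref_seq=self.query_seq,
            ref_size=self.query_size,
            query_seq=self.ref_seq,
            query_size=self.ref_size,
            blocks=tuple(inv),
            query_reversed=self.query_reversed,
        )


@dataclass(frozen=True)
class MotifModel:
    """A position probability matrix over A/C/G/T with a background model."""

    motif_id: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be width x 4")
        if m.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: width {m.shape[0]} < 4")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id}: row {bad} sums to {sums[bad]:.8f}, not 1"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Per-position log2-odds scores after pseudocount regularisation."""
        pc = self.pseudocount
        adj = (self.matrix + pc * self.background[None, :]) / (1.0 + pc)
        return np.log2(adj / self.background[None, :])


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list:
    """Read BED3/BED4 into ``(GenomicInterval, name-or-None)`` tuples.

    Coordinates are taken verbatim (BED is already 0-based half-open);
    records come back in file order.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            out.append((iv, name))
    return out


def write_bed(path, records: Iterable) -> None:
    """Write ``(interval, name)`` tuples (or bare intervals) as BED."""
    with open(path, "w") as fh:
        for rec in records:
            iv, name = rec if isinstance(rec, tuple) else (rec, None)
            if name is None:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\n")


def read_genes_bed(path) -> list:
    """Read a gene BED (name column required) as ``(gene_id, interval)``."""
    genes = []
    for iv, name in read_bed(path):
        if name is None:
            raise FormatError(f"{path}: gene BED requires a name column")
        genes.append((name, iv))
    return genes


# ---------------------------------------------------------------------------
# UCSC chain

def read_chain(path) -> list:
    """Parse a UCSC chain file into :class:`AlignmentChain` objects.

    Blocks are reconstructed by accumulating the dt/dq gap offsets;
    negative query strands are converted to forward-strand coordinates.
    """
    chains = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise FormatError(f"{path}:{i}: expected chain header, got {line!r}")
        parts = line.split()
        if len(parts) != 13:
            raise FormatError(f"{path}:{i}: chain header needs 13 fields")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        if t_strand != "+":
            raise FormatError(f"{path}:{i}: reference strand must be '+'")
        reversed_q = q_strand == "-"
        blocks_local = []
        t_pos, q_pos = t_start, q_start
        while i < n:
            dat = lines[i].strip()
            i += 1
            if not dat:
                break
            nums = dat.split()
            size = int(nums[0])
            blocks_local.append((t_pos, q_pos, size))
            if len(nums) == 3:
                t_pos += size + int(nums[1])
                q_pos += size + int(nums[2])
            elif len(nums) == 1:
                t_pos += size
                q_pos += size
                break
            else:
                raise FormatError(f"{path}:{i}: bad alignment data line {dat!r}")
        if t_pos != t_end or q_pos != q_end:
            raise FormatError(
                f"{path}: chain {chain_id}: block sizes inconsistent with header span "
                f"(ref ends {t_pos} vs {t_end}, query ends {q_pos} vs {q_end})"
            )
        if reversed_q:
            blocks = tuple(
                (t, q_size - (q + s), s) for t, q, s in blocks_local
            )
        else:
            blocks = tuple(blocks_local)
        chains.append(
            AlignmentChain(
                chain_id=chain_id,
                score=float(score),
                ref_seq=t_name,
                ref_size=t_size,
                query_seq=q_name,
                query_size=q_size,
                blocks=blocks,
                query_reversed=reversed_q,
            )
        )
    return chains


def write_chain(path, chains: Sequence[AlignmentChain]) -> None:
    """Write chains in UCSC chain format (restoring the original strand)."""
    with open(path, "w") as fh:
        for ch in chains:
            if ch.query_reversed:
                local = [(r, ch.query_size - (q + s), s) for r, q, s in ch.blocks]
                q_strand = "-"
            else:
                local = list(ch.blocks)
                q_strand = "+"
            t_start, q_start = local[0][0], local[0][1]
            t_end = local[-1][0] + local[-1][2]
            q_end = local[-1][1] + local[-1][2]
            score = int(ch.score) if float(ch.score).is_integer() else ch.score
            fh.write(
                f"chain {score} {ch.ref_seq} {ch.ref_size} + {t_start} {t_end} "
                f"{ch.query_seq} {ch.query_size} {q_strand} {q_start} {q_end} {ch.chain_id}\n"
            )
            for j, (r, q, s) in enumerate(local):
                if j + 1 < len(local):
                    nr, nq, _ = local[j + 1]
                    fh.write(f"{s}\t{nr - (r + s)}\t{nq - (q + s)}\n")
                else:
                    fh.write(f"{s}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format

def read_meme(path) -> list:
    """Read a MEME minimal-format motif library.

    The background letter frequencies line is honoured when present,
    otherwise a uniform background is used.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    motifs = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            vals = lines[i].split()
            freq = {vals[j]: float(vals[j + 1]) for j in range(0, len(vals), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
            i += 1
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            i += 1
            # find letter-probability header
            while i < n and not lines[i].strip().startswith("letter-probability"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
            i += 1
            rows = []
            while i < n:
                row = lines[i].strip()
                if not row or row.startswith(("MOTIF", "URL", "Background")):
                    break
                vals = [float(x) for x in row.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: expected 4 columns")
                if abs(sum(vals) - 1.0) > 1e-5:
                    raise ValueError(
                        f"{path}: motif {motif_id}: probability row sums to "
                        f"{sum(vals):.6f}, not 1"
                    )
                rows.append(vals)
                i += 1
            motifs.append(MotifModel(motif_id, np.array(rows), background=background))
            continue
        i += 1
    return motifs


def write_meme(path, motifs: Sequence[MotifModel]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[j]:.5f}" for j, b in enumerate(BASES)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA (soft-masked)

def read_fasta(path) -> dict:
    """Read FASTA into ``{seq_id: sequence string}``, preserving case."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict, line_width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def gc_fraction(seq: str) -> float:
    """Case-insensitive G+C fraction of a sequence."""
    if not seq:
        return 0.0
    up = seq.upper()
    return (up.count("G") + up.count("C")) / len(seq)


def repeat_fraction(seq: str) -> float:
    """Soft-masked (lowercase) fraction of a sequence."""
    if not seq:
        return 0.0
    return sum(c.islower() for c in seq) / len(seq)


# ---------------------------------------------------------------------------
# Expression tables

def read_expression(path) -> pd.DataFrame:
    """Read a gene-by-tissue expression TSV.

    The first column holds gene ids, the header row tissue names.  Missing
    values (empty or NA) stay missing; they are never coerced to zero.
    Duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene ids: {', '.join(map(str, dups))}")
    return df.astype(float)


def write_expression(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g", na_rep="NA")
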