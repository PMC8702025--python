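"""Concatenated codon-partitioned supermatrices for tree inference.

Builds PCG123 (all codon positions) and PCG12 (first + second positions)
datasets from per-gene, codon-aligned FASTA alignments, with partition
definitions in 1-based closed coordinates and exports to relaxed PHYLIP,
NEXUS (charset block) and RAxML-style partition text.

Gene alignments are assumed codon-aligned upstream (codon-aware aligners
keep frame); every operation here preserves frame, so a codon-position
subset of a filtered matrix remains meaningful.  Alignment itself and
heuristic block filtering (Gblocks-style) are out of scope — the column
filter used here is a transparent, parameterized simplification that
drops whole codon triplets.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from itertools import groupby
from typing import Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Partition",
    "Supermatrix",
    "filter_columns",
    "concatenate",
    "codon_subset",
    "to_phylip",
    "to_nexus",
    "to_raxml_partitions",
    "read_fasta_alignment",
    "CANONICAL_PCG_ORDER",
]

#: The 13 protein-coding genes in ancestral genome order.
CANONICAL_PCG_ORDER = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

_GAP_CHARS = set("-?NnXx.")


@dataclass(frozen=True)
class Partition:
    """A charset: columns ``start..end`` (1-based closed) with ``stride``
    (3 for a codon-position class inside an interleaved gene range)."""

    gene: str
    position_class: int | None  # 1, 2, 3 or None for a whole-gene range
    start: int
    end: int
    stride: int = 1

    def columns(self) -> range:
        return range(self.start, self.end + 1, self.stride)

    @property
    def label(self) -> str:
        suffix = f"_pos{self.position_class}" if self.position_class else ""
        return f"{self.gene}{suffix}"


@dataclass
class Supermatrix:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]              # aligned sequences, same order as taxa
    partitions: tuple[Partition, ...]
    dataset_label: str = "PCG123"

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.rows))

    def partition_cover(self) -> list[int]:
        """How many partitions claim each column (tiling ⇔ all ones)."""
        cover = [0] * self.length
        for p in self.partitions:
            for col in p.columns():
                cover[col - 1] += 1
        return cover


def read_fasta_alignment(source) -> dict:
    """Aligned FASTA -> ordered {taxon: sequence} map."""
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise ValueError("empty FASTA alignment")
    return {r.id: str(r.seq).upper() for r in records}


# ---------------------------------------------------------------------------
# Column filtering (frame-preserving)
# ---------------------------------------------------------------------------

def filter_columns(alignment: Mapping[str, str], max_gap_frac: float = 0.5,
                   min_conserved_frac: float = 0.5):
    """Drop poorly supported columns, whole codon triplets at a time.

    A column fails when its gap fraction exceeds ``max_gap_frac`` or the
    most common non-gap base falls below ``min_conserved_frac`` agreement
    among non-gap rows; if any column of a codon triplet fails, the whole
    triplet is dropped (frame preservation).  Thresholds (1.0, 0.0) are
    the identity filter.  Returns ``(filtered alignment, kept 1-based
    column indices)``; raises if nothing survives.
    """
    taxa = list(alignment)
    seqs = [alignment[t].upper() for t in taxa]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment rows have unequal lengths")
    if length % 3:
        raise ValueError(f"alignment length {length} not divisible by 3")
    n = len(seqs)

    def column_ok(i: int) -> bool:
        col = [s[i] for s in seqs]
        bases = [c for c in col if c not in _GAP_CHARS]
        gap_frac = 1 - len(bases) / n
        if gap_frac > max_gap_frac:
            return False
        if not bases:
            return min_conserved_frac <= 0
        top = max(bases.count(b) for b in set(bases))
        return top / len(bases) >= min_conserved_frac

    kept: list[int] = []
    for codon_start in range(0, length, 3):
        cols = [codon_start, codon_start + 1, codon_start + 2]
        if all(column_ok(i) for i in cols):
            kept.extend(cols)
    if not kept:
        raise ValueError(
            "no columns kept; relax max_gap_frac / min_conserved_frac")
    filtered = {t: "".join(s[i] for i in kept) for t, s in zip(taxa, seqs)}
    return filtered, [i + 1 for i in kept]


# ---------------------------------------------------------------------------
# Concatenation and codon-position subsets
# ---------------------------------------------------------------------------

def concatenate(per_gene_alignments: Mapping[str, Mapping[str, str]],
                gene_order: Sequence[str] | None = None,
                allow_missing: bool = False,
                dataset_label: str = "PCG123") -> Supermatrix:
    """Join per-gene alignments into one matrix with codon partitions.

    Genes are joined in ``gene_order`` (default: the canonical order for
    the genes supplied).  All alignments must share one taxon set unless
    ``allow_missing`` is set, in which case absent taxa are gap-filled.
    Each gene contributes three codon-position partitions.
    """
    if not per_gene_alignments:
        raise ValueError("no gene alignments supplied")
    if gene_order is None:
        canon = [g for g in CANONICAL_PCG_ORDER if g in per_gene_alignments]
        extra = [g for g in per_gene_alignments if g not in CANONICAL_PCG_ORDER]
        gene_order = canon + sorted(extra)
    missing = [g for g in gene_order if g not in per_gene_alignments]
    if missing:
        raise ValueError(f"gene_order names absent genes: {', '.join(missing)}")

    all_taxa: list[str] = []
    for aln in per_gene_alignments.values():
        for t in aln:
            if t not in all_taxa:
                all_taxa.append(t)
    if not allow_missing:
        for g in gene_order:
            absent = [t for t in all_taxa if t not in per_gene_alignments[g]]
            if absent:
                raise ValueError(
                    f"{g}: taxa missing from alignment: {', '.join(absent)} "
                    "(pass allow_missing=True to gap-fill)")

    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in all_taxa}
    offset = 0
    for g in gene_order:
        aln = per_gene_alignments[g]
        glen = len(next(iter(aln.values())))
        if glen % 3:
            raise ValueError(f"{g}: alignment length {glen} not divisible by 3")
        if any(len(s) != glen for s in aln.values()):
            raise ValueError(f"{g}: rows have unequal lengths")
        for t in all_taxa:
            chunks[t].append(aln.get(t, "-" * glen))
        for pos in (1, 2, 3):
            parts.append(Partition(g, pos, offset + pos, offset + glen, stride=3))
        offset += glen
    return Supermatrix(
        taxa=tuple(all_taxa),
        rows=tuple("".join(chunks[t]) for t in all_taxa),
        partitions=tuple(parts),
        dataset_label=dataset_label,
    )


def codon_subset(sm: Supermatrix, positions) -> Supermatrix:
    """Keep only the requested codon positions (subset of {1, 2, 3}).

    Operates per gene through the partition table, so the result stays
    frame-consistent and carries rebuilt contiguous-stride partitions.
    ``positions={1,2,3}`` is the identity.
    """
    positions = sorted(set(positions))
    if not positions or any(p not in (1, 2, 3) for p in positions):
        raise ValueError("positions must be a non-empty subset of {1, 2, 3}")
    by_gene = {}
    for p in sm.partitions:
        if p.position_class is None:
            raise ValueError("matrix lacks codon-position partitions")
        by_gene.setdefault(p.gene, {})[p.position_class] = p
    # preserve gene order by first column
    genes = sorted(by_gene, key=lambda g: min(p.start for p in by_gene[g].values()))

    keep_cols: list[int] = []   # 0-based
    parts: list[Partition] = []
    offset = 0
    k = len(positions)
    for g in genes:
        gene_parts = by_gene[g]
        if set(gene_parts) != {1, 2, 3}:
            raise ValueError(f"{g}: expected partitions for codon positions 1-3")
        start = gene_parts[1].start
        end = gene_parts[3].end
        n_codons = (end - start + 1) // 3
        for codon in range(n_codons):
            for pos in positions:
                keep_cols.append(start - 1 + codon * 3 + pos - 1)
        glen = n_codons * k
        for i, pos in enumerate(positions, start=1):
            parts.append(Partition(g, pos, offset + i, offset + glen, stride=k))
        offset += glen
    label = "PCG" + "".join(str(p) for p in positions)
    return Supermatrix(
        taxa=sm.taxa,
        rows=tuple("".join(r[i] for i in keep_cols) for r in sm.rows),
        partitions=tuple(parts),
        dataset_label=label,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def sanitize_labels(taxa: Sequence[str]):
    """Whitespace-free, unique labels plus the renaming map."""
    mapping = {}
    used = set()
    for t in taxa:
        clean = re.sub(r"\s+", "_", t.strip())
        candidate, k = clean, 1
        while candidate in used:
            k += 1
            candidate = f"{clean}_{k}"
        used.add(candidate)
        mapping[t] = candidate
    return mapping


def _msa(sm: Supermatrix) -> MultipleSeqAlignment:
    labels = sanitize_labels(sm.taxa)
    return MultipleSeqAlignment(
        SeqRecord(Seq(row), id=labels[t], description="")
        for t, row in zip(sm.taxa, sm.rows)
    )


def to_phylip(sm: Supermatrix) -> str:
    """Relaxed PHYLIP serialization (byte-stable for identical input)."""
    out = io.StringIO()
    AlignIO.write(_msa(sm), out, "phylip-relaxed")
    return out.getvalue()


def _charset_ranges(p: Partition) -> str:
    if p.stride == 1:
        return f"{p.start}-{p.end}"
    return f"{p.start}-{p.end}\\{p.stride}"


def to_nexus(sm: Supermatrix) -> str:
    """NEXUS with a data block and a sets block of charset definitions."""
    if not sm.partitions:
        raise ValueError("supermatrix has no partitions")
    labels = sanitize_labels(sm.taxa)
    width = max(len(v) for v in labels.values())
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.length};",
        "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "  MATRIX",
    ]
    for t, row in zip(sm.taxa, sm.rows):
        lines.append(f"    {labels[t]:<{width}}  {row}")
    lines += ["  ;", "END;", "", "BEGIN SETS;"]
    for p in sm.partitions:
        lines.append(f"  CHARSET {p.label} = {_charset_ranges(p)};")
    lines += ["END;", ""]
    return "\n".join(lines)


def to_raxml_partitions(sm: Supermatrix) -> str:
    """RAxML-style partition file text (one DNA model line per charset)."""
    if not sm.partitions:
        raise ValueError("supermatrix has no partitions")
    return "\n".join(
        f"DNA, {p.label} = {_charset_ranges(p)}" for p in sm.partitions
    ) + "\n"
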