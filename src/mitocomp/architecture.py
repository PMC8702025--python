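"""Gene architecture: junction spacers/overlaps, size accounting, gene order.

The signed *spacer* at a junction is defined exactly as mitogenome feature
tables print their "intergenic nucleotides" column:

    spacer = start(downstream) - end(upstream) - 1

so a positive value is an intergenic spacer (IGS), a negative value is an
overlap, and 0 means the genes abut.  For a circular molecule the junction
between the last feature and the first is reported as well, and — because
the control region is accounted for separately from intergenic spacers —
junctions flanking the CR are excluded from IGS totals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .annotation import GeneFeature, MitogenomeAnnotation, PCG_NAMES

__all__ = [
    "JunctionRecord",
    "ArchitectureSummary",
    "GeneOrderSignature",
    "junction_table",
    "overlap_summary",
    "igs_summary",
    "architecture_summary",
    "gene_order_signature",
    "ancestral_insect_signature",
    "compare_gene_order",
    "length_conservation_check",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class JunctionRecord:
    upstream: str
    downstream: str
    spacer: int
    circular: bool = False  # true for the wrap-around junction


@dataclass(frozen=True)
class ArchitectureSummary:
    organism: str
    genome_length: int
    pcg_total_bp: int
    pcg_fraction_of_genome: float
    rrnL_bp: int | None
    rrnS_bp: int | None
    trna_min_bp: int | None
    trna_max_bp: int | None
    trna_min_genes: tuple[str, ...]
    trna_max_genes: tuple[str, ...]
    cr_bp: int | None
    igs_count: int
    igs_total_bp: int
    igs_max: tuple[str, str, int] | None
    overlap_count: int
    overlap_total_bp: int
    max_overlap: tuple[str, str, int] | None


@dataclass(frozen=True)
class GeneOrderSignature:
    """Circular signed gene order, rotated to start at trnI."""

    order: tuple[tuple[str, int], ...]  # (gene, +1 majority / -1 minority)
    reference_label: str = ""

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.order)


def junction_table(ann: MitogenomeAnnotation) -> list[JunctionRecord]:
    """Signed spacer for every adjacent feature pair in genome order.

    Reproduces the printed intergenic-nucleotides column row-for-row; for a
    circular genome the final record is the wrap-around junction from the
    last feature back to the first.
    """
    feats = ann.features
    if not feats or (len(feats) < 2 and not ann.circular):
        raise ValueError("need at least 2 features for a junction table")
    if any(feats[i].start > feats[i + 1].start for i in range(len(feats) - 1)):
        raise ValueError("features must be sorted by start")
    records = [
        JunctionRecord(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    ]
    if ann.circular:
        last, first = feats[-1], feats[0]
        records.append(
            JunctionRecord(last.name, first.name,
                           ann.genome_length - last.end + first.start - 1,
                           circular=True)
        )
    return records


def _is_cr_junction(rec: JunctionRecord) -> bool:
    return rec.upstream == "CR" or rec.downstream == "CR" or rec.circular


def overlap_summary(ann: MitogenomeAnnotation):
    """(count, total bp, (upstream, downstream, bp) of the largest overlap)."""
    negs = [r for r in junction_table(ann) if r.spacer < 0]
    if not negs:
        return 0, 0, None
    biggest = min(negs, key=lambda r: r.spacer)
    return len(negs), sum(-r.spacer for r in negs), (
        biggest.upstream, biggest.downstream, -biggest.spacer)


def igs_summary(ann: MitogenomeAnnotation):
    """(count, total bp, (upstream, downstream, bp) of the largest IGS).

    Junctions flanking the control region (including the circular wrap)
    are excluded: the CR is accounted for as its own region, not as
    intergenic sequence.
    """
    pos = [r for r in junction_table(ann)
           if r.spacer > 0 and not _is_cr_junction(r)]
    if not pos:
        return 0, 0, None
    biggest = max(pos, key=lambda r: r.spacer)
    return len(pos), sum(r.spacer for r in pos), (
        biggest.upstream, biggest.downstream, biggest.spacer)


def architecture_summary(ann: MitogenomeAnnotation) -> ArchitectureSummary:
    """Size accounting over a complete annotation (coordinates only)."""
    pcg_total = sum(f.length for f in ann.pcgs)
    trnas = ann.by_kind("tRNA")
    trna_lengths = sorted(f.length for f in trnas) if trnas else []

    def _len_of(name: str) -> int | None:
        try:
            return ann[name].length
        except KeyError:
            return None

    crs = ann.by_kind("CR")
    igs_count, igs_total, igs_max = igs_summary(ann)
    ov_count, ov_total, ov_max = overlap_summary(ann)
    return ArchitectureSummary(
        organism=ann.organism,
        genome_length=ann.genome_length,
        pcg_total_bp=pcg_total,
        pcg_fraction_of_genome=pcg_total / ann.genome_length,
        rrnL_bp=_len_of("rrnL"),
        rrnS_bp=_len_of("rrnS"),
        trna_min_bp=trna_lengths[0] if trna_lengths else None,
        trna_max_bp=trna_lengths[-1] if trna_lengths else None,
        trna_min_genes=tuple(f.name for f in trnas if trna_lengths and f.length == trna_lengths[0]),
        trna_max_genes=tuple(f.name for f in trnas if trna_lengths and f.length == trna_lengths[-1]),
        cr_bp=crs[0].length if crs else None,
        igs_count=igs_count,
        igs_total_bp=igs_total,
        igs_max=igs_max,
        overlap_count=ov_count,
        overlap_total_bp=ov_total,
        max_overlap=ov_max,
    )


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

def gene_order_signature(ann: MitogenomeAnnotation,
                         label: str | None = None) -> GeneOrderSignature:
    """Signed circular gene order over the 37 genes, anchored at trnI.

    The control region is excluded (it is not a gene); strand sign is +1
    for majority, -1 for minority.  Raises if trnI is absent.
    """
    genes = [(f.name, 1 if f.strand == "majority" else -1)
             for f in ann.features if f.kind != "CR"]
    names = [g for g, _ in genes]
    if "trnI" not in names:
        raise ValueError("gene order signature requires trnI as the anchor gene")
    i = names.index("trnI")
    return GeneOrderSignature(tuple(genes[i:] + genes[:i]),
                              label if label is not None else ann.organism)


def ancestral_insect_signature() -> GeneOrderSignature:
    """The packaged putative ancestral insect (Drosophila-type) gene order."""
    with open(_DATA_DIR / "ancestral_insect_order.tsv") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    order = tuple((r["gene"], 1 if r["strand"] == "J" else -1) for r in rows)
    return GeneOrderSignature(order, "ancestral-insect")


def _adjacency_set(sig: GeneOrderSignature) -> set:
    """Canonicalized signed adjacencies of the circular order.

    The adjacency a→b with signs (sa, sb) is equivalent to reading the
    molecule backwards, b→a with signs (-sb, -sa); each adjacency is stored
    under the lexicographically smaller of the two encodings.
    """
    adj = set()
    order = sig.order
    for (a, sa), (b, sb) in zip(order, order[1:] + order[:1]):
        fwd = (a, sa, b, sb)
        rev = (b, -sb, a, -sa)
        adj.add(min(fwd, rev))
    return adj


def compare_gene_order(sig_a: GeneOrderSignature, sig_b: GeneOrderSignature):
    """(identical, breakpoint count) between two circular signed orders.

    Breakpoints are adjacencies (with strand signs, orientation-insensitive)
    present in ``sig_a`` but not in ``sig_b``.  Both signatures must cover
    the same gene set.
    """
    if sig_a.genes() != sig_b.genes():
        diff = sorted(sig_a.genes() ^ sig_b.genes())
        raise ValueError(f"gene sets differ: {', '.join(diff)}")
    a, b = _adjacency_set(sig_a), _adjacency_set(sig_b)
    breakpoints = len(a - b)
    return breakpoints == 0, breakpoints


# ---------------------------------------------------------------------------
# Conservation identity
# ---------------------------------------------------------------------------

def length_conservation_check(ann: MitogenomeAnnotation) -> bool:
    """True iff the coordinate bookkeeping closes the circle.

    Σ feature lengths + Σ signed junction spacers (including the circular
    wrap) must equal the genome length, every feature must lie within
    1..genome_length, and starts must be strictly increasing.  This ties
    the junction table, the overlap/IGS summaries and the per-gene lengths
    to one mutually consistent coordinate system.
    """
    feats = ann.features
    if not feats:
        return False
    starts = [f.start for f in feats]
    if starts != sorted(starts) or len(set(starts)) != len(starts):
        return False
    if any(f.end > ann.genome_length or f.start < 1 for f in feats):
        return False
    total = sum(f.length for f in feats)
    total += sum(r.spacer for r in junction_table(ann))
    return total == ann.genome_length
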