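"""Region-partitioned nucleotide composition and strand-asymmetry skews.

Skews follow the standard definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed over unambiguous bases only.  A skew whose denominator is zero is
reported as absent (``None``), distinguishable from a true zero.

Region conventions
------------------
* ``PCGs123`` concatenates each protein-coding gene's coding-sense
  sequence (minority-strand genes reverse-complemented) in genome order,
  including stop codons — composition of coding regions is strand-
  sensitive, and this is the convention under which PCG AT-skew is
  strongly negative while GC-skew is positive.
* ``PCGs12`` / ``PCGs3`` select codon positions 1-2 / 3 within each gene
  independently, over the codons that encode amino acids: terminal stop
  codons and the incomplete trailing T are excluded.  Hence
  ``len(PCGs3)`` equals the genome's amino-acid total and
  ``len(PCGs12) = 2 * len(PCGs3)``.
* ``rRNAs`` / ``tRNAs`` concatenate each gene on its sense strand; ``CR``
  is taken from the majority strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation import MitogenomeAnnotation, reverse_complement
from .codons import extract_codons
from .genetic_code import invertebrate_mito_code

__all__ = [
    "CompositionProfile",
    "base_composition",
    "region_partition",
    "composition_report",
    "REGION_LABELS",
]

REGION_LABELS = ("whole", "PCGs123", "PCGs12", "PCGs3", "rRNAs", "tRNAs", "CR")


@dataclass(frozen=True)
class CompositionProfile:
    region_label: str
    length: int                 # countable (unambiguous) bases
    ambiguous: int              # excluded IUPAC-ambiguity bases
    frac_A: float               # percentages of countable bases
    frac_T: float
    frac_G: float
    frac_C: float
    at_content: float
    gc_content: float
    at_skew: float | None       # None when A + T = 0
    gc_skew: float | None       # None when G + C = 0


def base_composition(seq: str, region_label: str = "whole") -> CompositionProfile:
    """Composition and skews of one nucleotide string.

    Ambiguous IUPAC bases are excluded from every numerator and
    denominator but their count is surfaced.  Raises on an empty sequence
    or one with no countable bases.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, t = s.count("A"), s.count("T")
    g, c = s.count("G"), s.count("C")
    n = a + t + g + c
    if n == 0:
        raise ValueError("no countable bases (all ambiguous)")
    return CompositionProfile(
        region_label=region_label,
        length=n,
        ambiguous=len(s) - n,
        frac_A=100 * a / n,
        frac_T=100 * t / n,
        frac_G=100 * g / n,
        frac_C=100 * c / n,
        at_content=100 * (a + t) / n,
        gc_content=100 * (g + c) / n,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def region_partition(ann: MitogenomeAnnotation) -> dict:
    """Concatenated sequence for each composition region of one genome.

    Returns a ``region_label -> sequence`` map (regions with no features
    are omitted).  Requires the annotation to carry its sequence; raises
    if a PCG's length is ≡ 2 (mod 3) (neither a whole number of codons nor
    an incomplete-stop frame), naming the gene.
    """
    if ann.sequence is None:
        raise ValueError(f"{ann.organism}: annotation carries no sequence")
    code = invertebrate_mito_code()
    seq = ann.sequence
    pcg123, pcg12, pcg3 = [], [], []
    for f in ann.pcgs:
        sense = f.sense_sequence(seq)
        pcg123.append(sense)
        try:
            ext = extract_codons(sense, f.stop_codon, code)
        except ValueError as exc:
            raise ValueError(f"{f.name}: {exc}") from exc
        for codon in ext.counted_codons:
            pcg12.append(codon[:2])
            pcg3.append(codon[2])
    regions = {
        "whole": seq,
        "PCGs123": "".join(pcg123),
        "PCGs12": "".join(pcg12),
        "PCGs3": "".join(pcg3),
    }
    rrnas = [f.sense_sequence(seq) for f in ann.by_kind("rRNA")]
    trnas = [f.sense_sequence(seq) for f in ann.by_kind("tRNA")]
    crs = [seq[f.start - 1:f.end] for f in ann.by_kind("CR")]
    if rrnas:
        regions["rRNAs"] = "".join(rrnas)
    if trnas:
        regions["tRNAs"] = "".join(trnas)
    if crs:
        regions["CR"] = "".join(crs)
    return {k: v for k, v in regions.items() if v}


def composition_report(anns: list[MitogenomeAnnotation]) -> pd.DataFrame:
    """One row per species x region, in the conventional table layout.

    Annotations without a sequence are skipped with a warning.
    """
    rows = []
    for ann in anns:
        if ann.sequence is None:
            warnings.warn(f"{ann.organism}: no sequence, skipped", stacklevel=2)
            continue
        parts = region_partition(ann)
        for label in REGION_LABELS:
            part = parts.get(label)
            if part is None:
                continue
            p = base_composition(part, label)
            rows.append({
                "species": ann.organism,
                "region": p.region_label,
                "size_bp": p.length + p.ambiguous,
                "T_pct": p.frac_T,
                "C_pct": p.frac_C,
                "A_pct": p.frac_A,
                "G_pct": p.frac_G,
                "AT_pct": p.at_content,
                "GC_pct": p.gc_content,
                "AT_skew": p.at_skew,
                "GC_skew": p.gc_skew,
            })
    return pd.DataFrame(rows)
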