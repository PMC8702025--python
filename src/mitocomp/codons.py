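"""Codon extraction, translation, RSCU and amino-acid usage profiles.

All protein-coding genes are handled under the invertebrate mitochondrial
code (translation table 5).  Several mitochondrial PCGs end on the
incomplete stop codon ``T`` — a single thymine completed to UAA by
post-transcriptional polyadenylation — which is never counted as a codon.
Terminal complete stop codons (TAA/TAG) are extracted but excluded from
usage counts, so amino-acid totals are "without the termination codons".

RSCU (relative synonymous codon usage) for codon *c* in a synonymous
family of size *k* with counts *n*:

    RSCU(c) = n_c * k / sum over the family of n_c'

i.e. observed use relative to uniform use of the family.  A codon that is
unused while its family is observed has RSCU 0; a wholly unobserved family
has no RSCU values (absent, not 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation import MitogenomeAnnotation
from .genetic_code import GeneticCode, invertebrate_mito_code

__all__ = [
    "CodonExtraction",
    "CodonUsageTable",
    "extract_codons",
    "translate_codon",
    "amino_acid_total",
    "rscu",
    "codon_usage_table",
    "codon_usage_report",
    "AA_SUBFAMILY_LABELS",
]

#: Field-convention labels splitting the two leucine/serine codon families:
#: Leu2 = UUR, Leu1 = CUN, Ser1 = AGN, Ser2 = UCN.
AA_SUBFAMILY_LABELS = {
    ("L", "TT"): "Leu2", ("L", "CT"): "Leu1",
    ("S", "AG"): "Ser1", ("S", "TC"): "Ser2",
}

_ONE_TO_THREE = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


@dataclass(frozen=True)
class CodonExtraction:
    codons: tuple[str, ...]          # all complete codons, coding order
    terminal_stop: str | None        # TAA/TAG if the last codon is a stop
    trailing_partial: str | None     # the lone 'T' of an incomplete stop

    @property
    def counted_codons(self) -> tuple[str, ...]:
        """Codons entering usage statistics: terminal stop excluded."""
        return self.codons[:-1] if self.terminal_stop else self.codons


def extract_codons(gene_seq: str, stop_codon: str | None = None,
                   code: GeneticCode | None = None) -> CodonExtraction:
    """Split a coding-sense gene sequence into codons.

    Accepts length ≡ 0 (mod 3), or ≡ 1 (mod 3) when the annotated stop is
    the incomplete ``T``.  Length ≡ 2 (mod 3) is a frame error.  A
    terminal TAA/TAG is returned but flagged, so callers can exclude it
    from counts; internal stops raise a warning (misannotation is common),
    not an error.
    """
    code = code or invertebrate_mito_code()
    seq = gene_seq.upper().replace("U", "T")
    rem = len(seq) % 3
    if rem == 2:
        raise ValueError(f"frame error: gene length {len(seq)} ≡ 2 (mod 3)")
    partial = None
    if rem == 1:
        if stop_codon != "T":
            raise ValueError(
                f"gene length {len(seq)} ≡ 1 (mod 3) but annotated stop is "
                f"{stop_codon!r}, not the incomplete 'T'"
            )
        partial = seq[-1]
        seq = seq[:-1]
    codons = tuple(seq[i:i + 3] for i in range(0, len(seq), 3))
    terminal = codons[-1] if codons and code.is_stop(codons[-1]) else None
    internal_stops = [i for i, c in enumerate(codons[:-1]) if code.is_stop(c)]
    if internal_stops:
        warnings.warn(
            f"{len(internal_stops)} internal stop codon(s) at codon "
            f"position(s) {internal_stops[:5]}", stacklevel=2)
    return CodonExtraction(codons, terminal, partial)


def translate_codon(codon: str, code: GeneticCode | None = None) -> str:
    """Amino acid under the active code ('*' stop, 'X' ambiguous)."""
    return (code or invertebrate_mito_code()).translate(codon)


def amino_acid_total(ann: MitogenomeAnnotation) -> int:
    """Total encoded amino acids over all PCGs, termination codons excluded.

    Works in coordinate-only mode from lengths and annotated stop codons:
    a complete-stop gene of length L contributes L/3 - 1, an
    incomplete-stop gene (L - 1)/3.  Frame violations raise, naming the
    offending gene.
    """
    total = 0
    for f in ann.pcgs:
        if f.stop_codon == "T":
            if f.length % 3 != 1:
                raise ValueError(f"{f.name}: length {f.length} ≢ 1 (mod 3) with stop T")
            total += (f.length - 1) // 3
        else:
            if f.length % 3 != 0:
                raise ValueError(f"{f.name}: length {f.length} not divisible by 3")
            total += f.length // 3 - 1
    return total


def rscu(counts: dict, code: GeneticCode | None = None) -> dict:
    """RSCU values for a codon-count table (DNA or RNA alphabet keys).

    Families follow the genetic code's synonymous sets (6-fold Leu, 8-fold
    Ser under table 5).  Counts containing stop codons are rejected.
    Returned keys use the DNA alphabet.
    """
    code = code or invertebrate_mito_code()
    norm = {k.upper().replace("U", "T"): v for k, v in counts.items()}
    stops = [c for c in norm if code.is_stop(c)]
    if stops:
        raise ValueError(f"stop codons in usage counts: {', '.join(sorted(stops))}")
    unknown = [c for c in norm if c not in code.table]
    if unknown:
        raise ValueError(f"unknown codons: {', '.join(sorted(unknown))}")
    values: dict[str, float] = {}
    for aa, family in code.families().items():
        fam_total = sum(norm.get(c, 0) for c in family)
        if fam_total == 0:
            continue  # wholly unobserved family: absent, not zero
        k = len(family)
        for c in family:
            values[c] = norm.get(c, 0) * k / fam_total
    return values


@dataclass
class CodonUsageTable:
    """Per-genome codon usage: raw counts, RSCU, amino-acid totals."""

    organism: str
    counts: dict
    rscu: dict
    aa_totals: dict
    total_aa: int
    code_label: str

    def aa_profile(self) -> dict:
        """Amino-acid usage with Leu and Ser split into their two codon
        sub-families (Leu1/Leu2, Ser1/Ser2), as codon-usage figures are
        conventionally drawn."""
        code = invertebrate_mito_code()
        profile: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = code.translate(codon)
            label = AA_SUBFAMILY_LABELS.get((aa, codon[:2]), _ONE_TO_THREE.get(aa, aa))
            profile[label] = profile.get(label, 0) + n
        return profile

    def top_codons(self, n: int = 4) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def codon_usage_table(ann: MitogenomeAnnotation,
                      code: GeneticCode | None = None) -> CodonUsageTable:
    """Count codon usage over all PCGs of a sequenced annotation.

    Every non-terminal codon is counted, including each gene's initiation
    codon; terminal stops and the incomplete trailing T are excluded.
    """
    if ann.sequence is None:
        raise ValueError(f"{ann.organism}: annotation carries no sequence")
    code = code or invertebrate_mito_code()
    counts: dict[str, int] = {}
    for f in ann.pcgs:
        ext = extract_codons(f.sense_sequence(ann.sequence), f.stop_codon, code)
        for c in ext.counted_codons:
            if c not in code.table or code.is_stop(c):
                # ambiguous codon, or internal stop (warned upstream): skip
                continue
            counts[c] = counts.get(c, 0) + 1
    aa_totals: dict[str, int] = {}
    for c, n in counts.items():
        aa = code.translate(c)
        aa_totals[aa] = aa_totals.get(aa, 0) + n
    return CodonUsageTable(
        organism=ann.organism,
        counts=counts,
        rscu=rscu(counts, code),
        aa_totals=aa_totals,
        total_aa=sum(counts.values()),
        code_label=code.label,
    )


def codon_usage_report(anns: list[MitogenomeAnnotation],
                       code: GeneticCode | None = None):
    """Per-species usage tables plus a cross-species amino-acid matrix.

    Returns ``(tables, aa_matrix)`` where ``aa_matrix`` is a DataFrame of
    amino-acid counts (Leu/Ser split) with one row per species.
    """
    tables = [codon_usage_table(a, code) for a in anns]
    aa_matrix = pd.DataFrame(
        [t.aa_profile() for t in tables],
        index=[t.organism for t in tables],
    ).fillna(0).astype(int)
    return tables, aa_matrix


def usage_frame(table: CodonUsageTable) -> pd.DataFrame:
    """Tidy per-codon table (RNA-alphabet codons) for TSV export."""
    code = invertebrate_mito_code()
    rows = []
    for codon in sorted(code.sense_codons):
        n = table.counts.get(codon, 0)
        rows.append({
            "codon": codon.replace("T", "U"),
            "aa": code.translate(codon),
            "count": n,
            "rscu": table.rscu.get(codon),
        })
    return pd.DataFrame(rows)
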