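"""Genetic code tables (packaged as data so further codes can be added).

The default is NCBI translation table 5, the invertebrate mitochondrial
code: AGA/AGG encode Ser, ATA encodes Met and TGA encodes Trp; TAA/TAG are
the only stops.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

__all__ = ["GeneticCode", "invertebrate_mito_code", "DNA_BASES"]

_DATA_DIR = Path(__file__).parent / "data"

DNA_BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    label: str
    table: dict  # codon (DNA alphabet) -> one-letter amino acid, '*' = stop

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in self.table.items() if aa != "*")

    def families(self) -> dict:
        """Synonymous families: amino acid -> tuple of its sense codons."""
        fams: dict[str, list[str]] = {}
        for codon, aa in self.table.items():
            if aa != "*":
                fams.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}

    def translate(self, codon: str) -> str:
        """One-letter amino acid, '*' for stop, 'X' for any ambiguity."""
        c = codon.upper().replace("U", "T")
        return self.table.get(c, "X")

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == "*"


@lru_cache(maxsize=None)
def invertebrate_mito_code() -> GeneticCode:
    with open(_DATA_DIR / "transl_table_5.tsv") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return GeneticCode("transl_table_5", {r["codon"]: r["aa"] for r in rows})
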