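"""Reading, writing and validating annotated mitochondrial genomes.

The central container is :class:`MitogenomeAnnotation`: a circular molecule
with an ordered list of :class:`GeneFeature` records (13 protein-coding
genes, 22 tRNAs, 2 rRNAs and one control region when complete) and,
optionally, the majority-strand nucleotide sequence.

Coordinate convention
---------------------
All coordinates are 1-based, fully closed intervals, exactly as printed in
mitogenome feature tables: a gene spanning positions ``start..end`` has
length ``end - start + 1``.  Origin-spanning features are not supported;
both strands are represented relative to the majority (H) strand, with
``strand`` being ``"majority"`` or ``"minority"``.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "MitogenomeAnnotation",
    "Issue",
    "CANONICAL_GENES",
    "PCG_NAMES",
    "parse_feature_table",
    "write_feature_table",
    "parse_genbank",
    "write_genbank",
    "validate_annotation",
    "normalize_gene_name",
]

_DATA_DIR = Path(__file__).parent / "data"

#: The 13 protein-coding genes of the animal mitogenome.
PCG_NAMES = frozenset(
    {"ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
     "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB"}
)

_TRNA_NAMES = frozenset(
    {f"trn{aa}" for aa in "ACDEFGHIKMNPQRTVWY"} | {"trnL1", "trnL2", "trnS1", "trnS2"}
)

#: Canonical 37-gene complement (control region excluded).
CANONICAL_GENES = PCG_NAMES | _TRNA_NAMES | {"rrnL", "rrnS"}

_STRAND_ALIASES = {
    "J": "majority", "H": "majority", "+": "majority", "MAJORITY": "majority",
    "N": "minority", "L": "minority", "-": "minority", "MINORITY": "minority",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (uppercased)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _load_synonyms() -> dict:
    with open(_DATA_DIR / "gene_synonyms.yaml") as fh:
        raw = yaml.safe_load(fh)
    return {str(k).upper().replace("-", "").replace("_", ""): v for k, v in raw.items()}


_SYNONYMS = _load_synonyms()


def normalize_gene_name(name: str) -> str:
    """Map a gene symbol from any common dialect to the canonical symbol.

    ``COX1 -> COI``, ``NAD2 -> ND2``, ``l-rRNA -> rrnL`` etc.  tRNA names
    like ``trnM``/``tRNA-Met`` are normalized to ``trnX`` one-letter form.
    Unknown names are returned stripped but otherwise untouched.
    """
    key = name.strip()
    squashed = key.upper().replace("-", "").replace("_", "")
    if squashed in _SYNONYMS:
        return _SYNONYMS[squashed]
    m = re.fullmatch(r"TRNA?([A-Z])([12])?", squashed)
    if m:
        base = f"trn{m.group(1)}"
        return base + (m.group(2) or "")
    m = re.fullmatch(r"TRNA?(ALA|ARG|ASN|ASP|CYS|GLN|GLU|GLY|HIS|ILE|LEU|LYS|MET|PHE|PRO|SER|THR|TRP|TYR|VAL)([12])?", squashed)
    if m:
        three_to_one = {
            "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
            "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
            "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
            "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
        }
        return f"trn{three_to_one[m.group(1)]}" + (m.group(2) or "")
    return key


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a mitogenome.

    ``kind`` is one of ``PCG``, ``tRNA``, ``rRNA``, ``CR``; ``strand`` is
    ``majority`` (printed "J") or ``minority`` ("N"); coordinates are 1-based
    closed.  ``stop_codon`` may be the single letter ``T`` for the incomplete
    stop completed by polyadenylation.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    start_codon: str | None = None
    stop_codon: str | None = None
    anticodon: str | None = None

    def __post_init__(self):
        if self.kind not in ("PCG", "tRNA", "rRNA", "CR"):
            raise ValueError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("majority", "minority"):
            raise ValueError(f"{self.name}: strand must be majority/minority, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.name}: bad coordinates {self.start}..{self.end} "
                "(1-based closed, end >= start; origin-spanning features unsupported)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sense_sequence(self, genome_seq: str) -> str:
        """Coding-sense sequence of this feature given the majority strand."""
        sub = genome_seq[self.start - 1 : self.end].upper()
        return reverse_complement(sub) if self.strand == "minority" else sub


@dataclass
class MitogenomeAnnotation:
    """An annotated (optionally sequenced) circular mitogenome."""

    organism: str
    genome_length: int
    features: list[GeneFeature]
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"{self.organism}: sequence length {len(self.sequence)} "
                    f"!= genome_length {self.genome_length}"
                )

    def __getitem__(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.by_kind("PCG")

    def with_sequence(self, sequence: str) -> "MitogenomeAnnotation":
        return MitogenomeAnnotation(
            organism=self.organism,
            genome_length=self.genome_length,
            features=list(self.features),
            circular=self.circular,
            sequence=sequence,
        )


@dataclass(frozen=True)
class Issue:
    """A validation finding; ``severity`` is ``error`` or ``warning``."""

    severity: str
    code: str
    message: str


# ---------------------------------------------------------------------------
# TSV feature tables
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("gene", "kind", "strand", "start", "end",
                "start_codon", "stop_codon", "anticodon")


def parse_feature_table(
    tsv_text: str,
    organism: str = "unknown",
    genome_length: int | None = None,
    circular: bool = True,
    validate: bool = True,
) -> MitogenomeAnnotation:
    """Parse a tab-delimited feature table into an annotation.

    The table requires a header with at least ``gene, kind, strand, start,
    end``; optional columns are ``start_codon, stop_codon, anticodon``.
    Strand accepts ``J``/``N`` (majority/minority) and common aliases.
    ``genome_length`` defaults to the maximum ``end``.

    Raises ``ValueError`` (with the offending line number) on malformed
    rows, duplicate identically-named overlapping features, or an empty
    table.
    """
    reader = csv.reader(io.StringIO(tsv_text), delimiter="\t")
    rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise ValueError("no features: empty feature table")
    header = [h.strip().lower() for h in rows[0]]
    missing = [c for c in ("gene", "kind", "strand", "start", "end") if c not in header]
    if missing:
        raise ValueError(f"feature table header missing columns: {', '.join(missing)}")
    idx = {c: header.index(c) for c in header}

    def cell(row, col):
        i = idx.get(col)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    features: list[GeneFeature] = []
    for lineno, row in enumerate(rows[1:], start=2):
        name = cell(row, "gene")
        if not name:
            raise ValueError(f"line {lineno}: missing gene name")
        raw = {c: cell(row, c) for c in _TSV_COLUMNS}
        try:
            start = int(raw["start"].replace(",", ""))
            end = int(raw["end"].replace(",", ""))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coordinate for {name}") from exc
        strand = _STRAND_ALIASES.get(raw["strand"].upper() or raw["strand"])
        if strand is None:
            raise ValueError(f"line {lineno}: unknown strand {raw['strand']!r} for {name}")
        if end < start:
            raise ValueError(f"line {lineno}: start > end for {name}")
        features.append(
            GeneFeature(
                name=name,
                kind=raw["kind"],
                strand=strand,
                start=start,
                end=end,
                start_codon=raw["start_codon"] or None,
                stop_codon=raw["stop_codon"] or None,
                anticodon=raw["anticodon"] or None,
            )
        )

    if not features:
        raise ValueError("no features: table has a header but no rows")
    _reject_duplicate_overlaps(features)
    length = genome_length if genome_length is not None else max(f.end for f in features)
    ann = MitogenomeAnnotation(
        organism=organism, genome_length=length, features=features, circular=circular
    )
    if validate:
        errors = [i for i in validate_annotation(ann) if i.severity == "error"]
        if errors:
            raise ValueError(
                "invalid annotation: " + "; ".join(i.message for i in errors)
            )
    return ann


def _reject_duplicate_overlaps(features: Sequence[GeneFeature]) -> None:
    seen: dict[str, GeneFeature] = {}
    for f in features:
        other = seen.get(f.name)
        if other is not None and not (f.end < other.start or f.start > other.end):
            raise ValueError(f"overlapping features share the name {f.name!r}")
        seen[f.name] = f


def write_feature_table(ann: MitogenomeAnnotation) -> str:
    """Serialize an annotation to the normalized TSV dialect (inverse of
    :func:`parse_feature_table`)."""
    strand_code = {"majority": "J", "minority": "N"}
    out = io.StringIO()
    w = csv.writer(out, delimiter="\t", lineterminator="\n")
    w.writerow(_TSV_COLUMNS)
    for f in ann.features:
        w.writerow([
            f.name, f.kind, strand_code[f.strand], f.start, f.end,
            f.start_codon or "", f.stop_codon or "", f.anticodon or "",
        ])
    return out.getvalue()


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GB_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
            "misc_feature": "CR", "D-loop": "CR"}


def parse_genbank(source, validate: bool = False) -> MitogenomeAnnotation:
    """Read a GenBank flat file (path or handle) into an annotation.

    CDS records become PCGs, tRNA/rRNA records keep their kind, and
    D-loop/misc_feature records annotated as the control region become CR.
    Gene names are normalized through the packaged synonym map.  Compound
    (join/complement-spanning-origin) locations are rejected; a record
    without an ORIGIN sequence yields an annotation-only result.
    """
    record = SeqIO.read(source, "genbank")
    features: list[GeneFeature] = []
    trna_seen: dict[str, int] = {}
    for feat in record.features:
        kind = _GB_KIND.get(feat.type)
        if kind is None:
            continue
        if len(feat.location.parts) > 1:
            raise ValueError(
                f"compound location {feat.location} unsupported "
                "(origin-spanning features are a documented limitation)"
            )
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or ["?"])[0]
        if kind == "CR" and "control" not in label.lower() and feat.type != "D-loop" \
                and label not in ("CR", "?"):
            continue
        name = "CR" if kind == "CR" else normalize_gene_name(label)
        if kind == "tRNA" and name in ("trnL", "trnS"):
            # Disambiguate the duplicated leucine/serine tRNAs by anticodon
            # when given, else by order of appearance.
            anticodon = (quals.get("anticodon") or [""])[0].upper().replace("T", "U")
            by_ac = {"UAA": "trnL2", "UAG": "trnL1", "GCU": "trnS1", "UGA": "trnS2"}
            if anticodon in by_ac:
                name = by_ac[anticodon]
            else:
                trna_seen[name] = trna_seen.get(name, 0) + 1
                name = f"{name}{trna_seen[name]}"
        anticodon = quals.get("anticodon", [None])[0]
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                strand="minority" if feat.location.strand == -1 else "majority",
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                start_codon=(quals.get("start_codon") or [None])[0],
                stop_codon=(quals.get("stop_codon") or [None])[0],
                anticodon=anticodon.upper().replace("T", "U") if anticodon else None,
            )
        )
    seq = str(record.seq).upper() if len(record.seq) else None
    if seq is not None and set(seq) <= {"N"}:
        seq = None  # placeholder ORIGIN (annotation-only record)
    length = len(record.seq) if seq else max((f.end for f in features), default=0)
    ann = MitogenomeAnnotation(
        organism=record.annotations.get("organism", record.id or "unknown"),
        genome_length=length,
        features=features,
        circular=record.annotations.get("topology", "circular") == "circular",
        sequence=seq,
    )
    if validate:
        errors = [i for i in validate_annotation(ann) if i.severity == "error"]
        if errors:
            raise ValueError("invalid annotation: " + "; ".join(i.message for i in errors))
    return ann


def write_genbank(ann: MitogenomeAnnotation, handle) -> None:
    """Write an annotation (and sequence, if present) as a GenBank flat file."""
    seq = Seq(ann.sequence if ann.sequence is not None else "N" * ann.genome_length)
    accession = re.sub(r"\W+", "_", ann.organism)[:16] or "MITO"
    record = SeqRecord(seq, id=accession, name=accession,
                       description=f"{ann.organism} mitochondrion, complete genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if ann.circular else "linear"
    record.annotations["organism"] = ann.organism
    gb_type = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    for f in ann.features:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "minority" else 1)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        if f.name == "CR":
            quals["note"] = ["control region"]
        record.features.append(SeqFeature(loc, type=gb_type[f.kind], qualifiers=quals))
    SeqIO.write(record, handle, "genbank")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_annotation(ann: MitogenomeAnnotation) -> list[Issue]:
    """Structural integrity checks; returns issues instead of raising.

    An empty list means a valid, complete record: the canonical 37 genes
    plus exactly one control region, strictly increasing starts, coordinates
    within the genome, PCGs with a start codon and a frame-consistent stop
    (length divisible by 3 with a complete TAA/TAG stop, or length ≡ 1
    mod 3 with the incomplete stop ``T``), and tRNAs with anticodons.
    """
    issues: list[Issue] = []
    names = [f.name for f in ann.features]
    present = set(names)

    for gene in sorted(CANONICAL_GENES - present):
        issues.append(Issue("error", "missing-gene", f"missing gene {gene}"))
    n_cr = sum(1 for f in ann.features if f.kind == "CR")
    if n_cr == 0:
        issues.append(Issue("error", "missing-cr", "no control region annotated"))
    elif n_cr > 1:
        issues.append(Issue("error", "multiple-cr", f"{n_cr} control regions annotated"))

    prev_start = 0
    for f in ann.features:
        if f.start <= prev_start:
            issues.append(Issue("error", "unsorted",
                                f"{f.name}: feature starts not strictly increasing"))
        prev_start = f.start
        if f.end > ann.genome_length:
            issues.append(Issue("error", "out-of-range",
                                f"{f.name}: end {f.end} > genome length {ann.genome_length}"))
        if f.kind == "PCG":
            if not f.start_codon:
                issues.append(Issue("error", "missing-start-codon",
                                    f"{f.name}: PCG without start codon"))
            rem = f.length % 3
            if f.stop_codon == "T":
                if rem != 1:
                    issues.append(Issue("error", "frame",
                                        f"{f.name}: incomplete stop T requires length ≡ 1 mod 3 "
                                        f"(length {f.length})"))
            elif rem != 0:
                issues.append(Issue("error", "frame",
                                    f"{f.name}: length {f.length} not divisible by 3 and "
                                    "stop codon is not the incomplete T"))
        if f.kind == "tRNA" and not f.anticodon:
            issues.append(Issue("error", "missing-anticodon",
                                f"{f.name}: tRNA without anticodon"))

    dupes = {n for n in names if names.count(n) > 1}
    for n in sorted(dupes):
        issues.append(Issue("error", "duplicate", f"gene name {n} appears more than once"))
    if ann.sequence is not None and len(ann.sequence) != ann.genome_length:
        issues.append(Issue("error", "sequence-length",
                            "sequence length differs from genome_length"))
    return issues
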