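"""Nucleotide diversity (π) and Nei–Gojobori Ka/Ks with Jukes–Cantor correction.

π is the mean proportion of differing sites over all unordered sequence
pairs of an alignment, after *complete deletion*: every column containing
a gap or ambiguous base in any sequence is removed before counting, as
DnaSP does by default.

Ka/Ks follows the classic counting method of Nei & Gojobori (1986):

* every codon position contributes synonymous/nonsynonymous *site*
  fractions according to the fraction of its possible single-nucleotide
  changes that are synonymous, with changes to stop codons excluded from
  the denominator (each codon therefore contributes exactly 3 sites);
* observed codon differences are partitioned by averaging, with equal
  weight, over all minimal mutational pathways between the two codons;
  pathways passing through a stop codon are discarded (if every pathway
  does, all are kept as a fallback);
* proportions are corrected for multiple hits with the Jukes–Cantor
  formula d = -(3/4)·ln(1 - 4p/3); p ≥ 3/4 is reported as saturated.

Tools differ in their stop-codon and pathway-weighting conventions, so
third-decimal disagreement with other NG86 implementations is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import DNA_BASES, GeneticCode, invertebrate_mito_code

__all__ = [
    "DiversityTrack",
    "NG86Pair",
    "PairwiseSelection",
    "pairwise_pi",
    "sliding_window_pi",
    "ng86_site_counts",
    "ng86_pairwise",
    "gene_kaks",
    "jukes_cantor",
]


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def _as_matrix(alignment) -> np.ndarray:
    """Alignment (mapping or sequence of equal-length strings) -> byte matrix."""
    if isinstance(alignment, Mapping):
        seqs = [str(s) for s in alignment.values()]
    else:
        seqs = [str(s) for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned (lengths {sorted(lengths)})")
    return np.array([list(s.upper()) for s in seqs], dtype="U1")


def _complete_deletion(mat: np.ndarray) -> np.ndarray:
    """Drop every column containing a gap or ambiguous base in any row."""
    ok = np.isin(mat, list(DNA_BASES)).all(axis=0)
    return mat[:, ok]


def pairwise_pi(alignment) -> float:
    """Nucleotide diversity of an alignment (complete deletion).

    Mean over all unordered sequence pairs of the per-site difference
    proportion.  Raises with fewer than 2 sequences or when no column
    survives complete deletion.
    """
    mat = _complete_deletion(_as_matrix(alignment))
    n, ncols = mat.shape
    if ncols == 0:
        raise ValueError("no comparable columns after complete deletion")
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += np.count_nonzero(mat[i] != mat[j]) / ncols
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class DiversityTrack:
    window_size: int
    step: int
    windows: tuple[tuple[int, int, float], ...]  # (start, end, pi), 1-based closed
    n_sequences: int
    sites_used_policy: str = "complete-deletion"


def sliding_window_pi(alignment, window: int = 100, step: int = 25) -> DiversityTrack:
    """Windowed π along an alignment (defaults: 100 bp window, 25 bp step).

    Complete deletion is applied to the whole alignment first; window
    coordinates refer to the post-deletion alignment.  Windows are
    anchored at position 1 and advance by ``step``; a final partial window
    is dropped.
    """
    if window < 2:
        raise ValueError("window must be at least 2 bp")
    if step < 1:
        raise ValueError("step must be positive")
    mat = _complete_deletion(_as_matrix(alignment))
    n, ncols = mat.shape
    if ncols < window:
        raise ValueError(f"alignment ({ncols} comparable sites) shorter than window {window}")
    pairs = list(combinations(range(n), 2))
    diff_cols = np.zeros(ncols)
    for i, j in pairs:
        diff_cols += mat[i] != mat[j]
    windows = []
    for start in range(0, ncols - window + 1, step):
        pi = diff_cols[start:start + window].sum() / (window * len(pairs))
        windows.append((start + 1, start + window, float(pi)))
    return DiversityTrack(window, step, tuple(windows), n)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986
# ---------------------------------------------------------------------------

_SITE_CACHE: dict[tuple[str, str], tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[str, str, str], tuple[float, float]] = {}


def ng86_site_counts(codon: str, code: GeneticCode | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the number of synonymous
    single-base changes divided by the number of non-stop changes; the
    three positions always sum to 3.0 sites.  Stop codons are rejected.
    """
    code = code or invertebrate_mito_code()
    c = codon.upper().replace("U", "T")
    key = (code.label, c)
    if key in _SITE_CACHE:
        return _SITE_CACHE[key]
    if any(b not in DNA_BASES for b in c) or len(c) != 3:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    aa = code.translate(c)
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in DNA_BASES:
            if b == c[pos]:
                continue
            alt = c[:pos] + b + c[pos + 1:]
            alt_aa = code.translate(alt)
            if alt_aa == "*":
                continue  # excluded from the denominator
            n_valid += 1
            if alt_aa == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    result = (syn, 3.0 - syn)
    _SITE_CACHE[key] = result
    return result


def _diff_partition(a: str, b: str, code: GeneticCode) -> tuple[float, float]:
    """(syn, nonsyn) observed differences between two sense codons,
    averaged over minimal mutational pathways (equal weight, stop-free
    pathways preferred)."""
    key = (code.label, a, b)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]

    diff_pos = [i for i in range(3) if a[i] != b[i]]

    def walk(current: str, remaining: list[int]) -> list[tuple[int, int, bool]]:
        # returns (syn_steps, nonsyn_steps, passed_through_stop) per pathway
        if not remaining:
            return [(0, 0, False)]
        out = []
        for pos in remaining:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            step_syn = int(code.translate(nxt) == code.translate(current)
                           and code.translate(nxt) != "*" and code.translate(current) != "*")
            is_stop = code.translate(nxt) == "*"
            rest = [p for p in remaining if p != pos]
            for s, n, stop in walk(nxt, rest):
                out.append((s + step_syn, n + (1 - step_syn), stop or is_stop))
        return out

    pathways = walk(a, diff_pos)
    clean = [p for p in pathways if not p[2]]
    used = clean if clean else pathways
    syn = sum(p[0] for p in used) / len(used)
    nonsyn = sum(p[1] for p in used) / len(used)
    _DIFF_CACHE[key] = (syn, nonsyn)
    return syn, nonsyn


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor distance; None when saturated (p ≥ 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class NG86Pair:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    pS: float | None
    pN: float | None
    dS: float | None      # None = saturated (or undefined sites)
    dN: float | None
    codons_used: int


def ng86_pairwise(cds_a: str, cds_b: str,
                  code: GeneticCode | None = None) -> NG86Pair:
    """NG86 proportions and JC-corrected rates for one coding sequence pair.

    Both sequences must share a length divisible by 3.  Codon pairs
    containing gaps or ambiguous bases are skipped; stop codons raise
    (strip terminal stops first).  Site totals are averaged across the two
    sequences.
    """
    code = code or invertebrate_mito_code()
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} not divisible by 3")
    S = N = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if any(ch not in DNA_BASES for ch in ca + cb):
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            raise ValueError(f"stop codon at codon {i // 3 + 1}: {ca}/{cb}")
        sa = ng86_site_counts(ca, code)
        sb = ng86_site_counts(cb, code)
        S += (sa[0] + sb[0]) / 2
        N += (sa[1] + sb[1]) / 2
        if ca != cb:
            ds_, dn_ = _diff_partition(ca, cb, code)
            Sd += ds_
            Nd += dn_
        used += 1
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    return NG86Pair(
        syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd,
        pS=pS, pN=pN,
        dS=jukes_cantor(pS) if pS is not None else None,
        dN=jukes_cantor(pN) if pN is not None else None,
        codons_used=used,
    )


@dataclass(frozen=True)
class PairwiseSelection:
    gene: str
    n_pairs: int
    mean_ka: float | None
    mean_ks: float | None
    ratio: float | None            # mean_ka / mean_ks
    saturated_pairs: int
    per_pair: tuple                # ((taxon_a, taxon_b, NG86Pair), ...)


def gene_kaks(per_gene_alignments: Mapping[str, Mapping[str, str]],
              code: GeneticCode | None = None) -> list[PairwiseSelection]:
    """Per-gene Ka/Ks over all unordered taxon pairs.

    ``per_gene_alignments`` maps gene name -> {taxon -> gap-free codon
    alignment}.  The gene-level ratio is mean(dN)/mean(dS) over pairs with
    defined rates — more stable than averaging per-pair ratios when some
    pair's dS is near zero.  A gene whose pairs are all saturated (or with
    mean dS = 0) gets ``ratio=None``.
    """
    code = code or invertebrate_mito_code()
    results = []
    for gene, taxa in per_gene_alignments.items():
        names = list(taxa)
        if len(names) < 2:
            raise ValueError(f"{gene}: need at least 2 taxa")
        per_pair = []
        dns, dss = [], []
        saturated = 0
        for ta, tb in combinations(names, 2):
            pair = ng86_pairwise(taxa[ta], taxa[tb], code)
            per_pair.append((ta, tb, pair))
            if pair.dN is None or pair.dS is None:
                saturated += 1
            else:
                dns.append(pair.dN)
                dss.append(pair.dS)
        mean_ka = float(np.mean(dns)) if dns else None
        mean_ks = float(np.mean(dss)) if dss else None
        ratio = (mean_ka / mean_ks
                 if mean_ka is not None and mean_ks not in (None, 0.0) else None)
        results.append(PairwiseSelection(
            gene=gene, n_pairs=len(per_pair), mean_ka=mean_ka,
            mean_ks=mean_ks, ratio=ratio, saturated_pairs=saturated,
            per_pair=tuple(per_pair),
        ))
    return results
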