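"""Independent brute-force oracle for Nei–Gojobori counting.

Deliberately written from the method's definition with no code shared
with the implementation under test: translation comes from Biopython's
codon table 5, pathway averaging enumerates explicit permutations via
itertools, and site fractions are recomputed from scratch per call.
"""

from itertools import permutations

from Bio.Data import CodonTable

_T5 = CodonTable.unambiguous_dna_by_id[5]
BASES = "ACGT"


def oracle_translate(codon: str) -> str:
    return "*" if codon in _T5.stop_codons else _T5.forward_table[codon]


def oracle_site_counts(codon: str):
    """Synonymous/nonsynonymous site fractions; per position the fraction
    of non-stop single-base changes that are synonymous."""
    aa = oracle_translate(codon)
    assert aa != "*"
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:]
                for b in BASES if b != codon[pos]]
        alts = [a for a in alts if oracle_translate(a) != "*"]
        if alts:
            syn += sum(oracle_translate(a) == aa for a in alts) / len(alts)
    return syn, 3.0 - syn


def oracle_diff_partition(a: str, b: str):
    """Mean (syn, nonsyn) step counts over minimal mutational pathways,
    stop-free pathways preferred, equal weights."""
    positions = [i for i in range(3) if a[i] != b[i]]
    outcomes = []
    for order in permutations(positions):
        cur, syn, nonsyn, hits_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            ta, tb_ = oracle_translate(cur), oracle_translate(nxt)
            if tb_ == "*":
                hits_stop = True
            if ta == tb_ and ta != "*" and tb_ != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        outcomes.append((syn, nonsyn, hits_stop))
    clean = [o for o in outcomes if not o[2]]
    used = clean if clean else outcomes
    return (sum(o[0] for o in used) / len(used),
            sum(o[1] for o in used) / len(used))
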