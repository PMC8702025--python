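# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates, annotations and validation

All coordinates are 1-based, fully closed intervals on the majority (H)
strand, exactly as mitogenome feature tables print them; a feature's
length is `end − start + 1`. Strand labels `J`/`N` (and `H`/`L`, `+`/`−`)
normalize to `majority`/`minority`. Origin-spanning features are rejected:
in the genomes this package was built around, the control region is the
last feature, so circularity matters only at the junction between the last
feature and position 1, which the architecture module reports explicitly.
The duplicated leucine and serine tRNAs are disambiguated as
`trnL1` (CUN, anticodon UAG) / `trnL2` (UUR, UAA) and `trnS1` (AGN, GCU) /
`trnS2` (UCN, UGA), by anticodon when available and by order of appearance
otherwise. Gene-name dialects (COX1, NAD2, l-rRNA, tRNA-Met, …) are mapped
to canonical symbols through a packaged YAML synonym table — data, not
code, so new dialects need no edits.

A *complete* record holds the canonical 37 genes (13 PCGs, 22 tRNAs,
2 rRNAs) plus exactly one control region. `validate_annotation` returns
issue records rather than raising: completeness, strictly increasing
starts, coordinate bounds, PCG frame consistency (length ≡ 0 mod 3 with a
complete TAA/TAG stop, or ≡ 1 mod 3 with the incomplete stop `T`), start
codons on PCGs, anticodons on tRNAs.

## Junction accounting and the conservation identity

The signed spacer at a junction is `start(downstream) − end(upstream) − 1`:
positive = intergenic spacer (IGS), negative = overlap, 0 = abutting. The
junction table reproduces a published "intergenic nucleotides" column
row-for-row, making the printed table itself the test fixture. Junctions
flanking the control region (including the circular wrap) are excluded
from IGS totals, because the CR is accounted for as its own region.
Overlap totals consider every junction.

The conservation check requires Σ feature lengths + Σ signed spacers
(including the circular junction) to equal the genome length. On a sorted
circular layout this sum telescopes, so the check's discriminating power
comes from the structural constraints enforced alongside it: strictly
increasing starts and `1 ≤ start ≤ end ≤ genome_length`. It ties the
junction table, the overlap/IGS summaries and per-gene lengths to one
consistent coordinate system, and it must hold for every simulated genome.

## Gene order

Gene order is compared as a circular *signed* permutation over the 37
genes (CR excluded), anchored at trnI. The metric is the breakpoint
count: adjacencies `(a, s_a) → (b, s_b)` present in one order but not the
other, where an adjacency is equivalent to its reverse reading
`(b, −s_b) → (a, −s_a)`. Under this convention an adjacent transposition
of same-strand genes costs 3 breakpoints and a signed block reversal
costs 2 (only the flanks break). Breakpoint distance was chosen because
it is brute-force verifiable by enumerating adjacencies; inversion/TDRL
event inference is out of scope.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed over
unambiguous bases; ambiguous IUPAC bases are excluded from numerator and
denominator and their count surfaced. A skew whose denominator is zero is
reported as absent (`None`), distinguishable from a true zero.

Region conventions:

* `PCGs123` concatenates each PCG's *coding-sense* sequence (minority-
  strand genes reverse-complemented) in genome order, stop codons
  included. Coding-strand composition is the convention under which PCG
  AT-skew is strongly negative and GC-skew positive; computing on the
  majority strand throughout would wash this signal out.
* `PCGs12`/`PCGs3` select codon positions within each gene independently,
  over amino-acid-encoding codons only: terminal complete stops and the
  incomplete trailing `T` are excluded. Consequently
  `len(PCGs3) = total amino acids` and `len(PCGs12) = 2·len(PCGs3)`,
  matching how published composition tables size these partitions; the
  sum `len(PCGs12) + len(PCGs3)` falls short of `len(PCGs123)` by exactly
  the stop-codon bases.
* `rRNAs`/`tRNAs` concatenate sense-strand sequences; `CR` is read from
  the majority strand.

## Codon usage and RSCU

Translation uses NCBI table 5 (invertebrate mitochondrial: AGA/AGG = Ser,
ATA = Met, TGA = Trp), shipped as a packaged data table so further codes
can be added; the test suite checks all 64 codons against Biopython's
table as an independent oracle.

Usage counts include every non-terminal codon of every PCG — including
each gene's initiation codon, which shifts totals by at most 13 per
genome — and exclude terminal stops and the trailing `T`, so amino-acid
totals are "without the termination codons". In coordinate-only mode the
same total is computed arithmetically: `L/3 − 1` per complete-stop gene,
`(L − 1)/3` per incomplete-stop gene. Internal stop codons trigger a
warning, not an error, because terminus misannotation is common; they are
skipped in usage counts.

RSCU families follow the genetic code's synonymous sets (6-fold Leu,
8-fold Ser under table 5). An unused codon in an observed family has
RSCU 0; a wholly unobserved family is absent, not 0. For amino-acid
profiles the Leu and Ser families are split into the conventional
Leu1 (CUN) / Leu2 (UUR) and Ser1 (AGN) / Ser2 (UCN) sub-families.

## Nucleotide diversity

π is the mean, over all unordered sequence pairs, of the proportion of
differing sites. *Complete deletion* is applied first — every column with
a gap or ambiguity in any sequence is dropped — matching the default of
the standard desktop tool for this analysis. Sliding windows (default
100 bp window, 25 bp step) are anchored at position 1 of the
post-deletion alignment, advance by the step, and a final partial window
is dropped; per-window π equals an independent recomputation of π on the
same slice, which the tests assert.

## Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction)

Sites: each position of a sense codon contributes the fraction of its
possible single-nucleotide changes that are synonymous, with changes to
stop codons excluded from the denominator; each codon therefore
contributes exactly 3 sites, and per-pair site totals are averaged across
the two sequences. Differences: the observed changes within a codon pair
are partitioned by averaging, with equal weight, over all minimal
mutational pathways (up to 6 orderings for a 3-difference pair); pathways
passing through a stop codon are discarded, and if every pathway does,
all are kept as a fallback. Proportions p are corrected with
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported as saturated (`None`), never
as a number.

The gene-level ratio is mean(dN)/mean(dS) over defined pairs rather than
the mean of per-pair ratios, which is unstable when any pair's dS ≈ 0;
per-pair values are still emitted. Codon pairs containing gaps or
ambiguity are skipped. Tools differ in pathway weighting and stop-codon
conventions, so third-decimal disagreement with other NG86
implementations is expected; the implementation is instead held to exact
agreement with a brute-force pathway-enumeration oracle over all sense
codon pairs.

## Supermatrices

Per-gene codon alignments are concatenated in the canonical 13-PCG order
with three codon-position partitions per gene (recorded as 1-based closed
ranges with stride 3, the `start-end\3` charset idiom). Position subsets
(e.g. PCG12) are taken per gene through the partition table, so frame is
preserved end-to-end and partitions always tile the matrix exactly.

Heuristic conserved-block selection is replaced by a transparent,
parameterized column filter: a column fails if its gap fraction exceeds
`max_gap_frac` or the majority base among non-gap rows falls below
`min_conserved_frac`; any failing column removes its whole codon triplet.
Thresholds (1.0, 0.0) are the identity. The defaults (0.5, 0.5) are
deliberately mild; the filter exists for reproducibility, not to mimic a
specific tool's internal heuristic. Exports: relaxed PHYLIP (via
Biopython), NEXUS with a charset block (hand-written, round-trip-checked
against dendropy), RAxML partition text. Taxon labels are sanitized to
whitespace-free unique names with the mapping returned.

## Synthetic data

`simulate_annotation` lays out coordinates from a template — gene order,
lengths, strands, signed spacers, start/stop codons — whose default
mirrors the packaged 15,274 bp study genome, so overlap/IGS totals
round-trip exactly through the architecture analyses. Sequence is then
written gene by gene: PCGs as ATN start + sense codons sampled from
calibrated weights + TAA/TAG or incomplete-T stop; tRNA/rRNA as A+T-
biased noise; the control region ~9 points more A+T-rich, as real
control regions are. Codon weights are products of per-base
probabilities with the four dominant mitogenome codons (TTA/TTT/ATT/ATA)
boosted ×3 and the per-base A+T mass calibrated by bisection so the
expected coding composition equals `at_target` (default 0.73).

At genuine overlaps one gene's bases must win: protein-coding genes take
precedence over RNA genes (their reading frames carry the analysis
constraints), and between two overlapping PCGs the downstream gene wins.
An overlapped PCG terminus is therefore *nominal* — exactly as in real
mitogenomes, where ATP8's stop lies inside ATP6 — and in the default
template this touches ATP8's stop and ND4's start only; codon analyses
warn and skip the occasional resulting internal-stop codon. The test
suite asserts exact frame consistency on an overlap-free template and
documented tolerance on the default one.

`evolve_cds` diverges stop-free CDSs on a star tree at codon level:
Poisson(divergence) proposed events per codon per branch, positions
uniform, target bases weighted κ for transitions, proposals creating
stops rejected (consuming the event), nonsynonymous proposals accepted
with relative weight ω versus 1. This accept/reject scheme was chosen
over substitution-matrix exponentiation because it is fully auditable
and sufficient for what the analyses need: recovered NG86 ratios
approximate ω (≈1 under neutrality with κ = 1) and preserve rankings
across ω classes. Note that κ > 1 biases NG86 ratios downward — a known
property of the counting method, since transitions are
disproportionately synonymous — so absolute recovery is only asserted at
κ = 1, ranking recovery at the default κ = 2. `divergence` counts
*proposed* events; realized substitutions are fewer after thinning.

What the generator does not emulate: indels and alignment error (gap
handling is exercised by injecting gap columns into fixtures instead),
tRNA secondary structure, control-region repeats, among-site rate
variation, non-star topologies, and sequencing error. Passing recovery
tests therefore demonstrates correctness of the estimators under the
model's assumptions, not robustness to real-data artifacts.

## Validation scales

The packaged study fixtures are analyzed in full (< 1 s). Simulation-based
checks use: 20 seeds for the conservation identity; 15,274 bp genomes for
composition recovery (binomial noise at that length is ≈ ±0.4 points, the
tolerance asserted is ±2); and for ω-ranking recovery, 50 replicates of
13 genes × 80 codons × 10 taxa with ω cycling through
{0.075, 0.3, 0.67} — the purifying-selection range reported across
mitochondrial PCGs — at divergence 0.3 and κ = 2, requiring the class-mean
ordering to be preserved in ≥ 95% of replicates. These sizes keep the
whole suite fast while leaving comfortable statistical separation between
the ω classes.

## Known limitations

* Origin-spanning features are unsupported (documented rejection).
* π window coordinates refer to the post-deletion alignment, not the
  input alignment.
* The column filter is not a reimplementation of any published block-
  selection heuristic; site counts from pipelines using such tools are
  not expected to match.
* NG86 is a counting method; for publication-grade selection inference a
  likelihood method (codeml-style) should be used downstream. Maximum-
  likelihood dN/dS, site and branch models are out of scope.
* De novo annotation, assembly and tree inference are out of scope; the
  package consumes annotations and alignments and produces inference-
  ready matrices.
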