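# Methods

This note documents the models and procedures crisprpam implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic benchmarks do and do not demonstrate.

## Protospacer search

A protospacer candidate is a target subsequence matching a CRISPR spacer at
≥ 90 % identity on either strand. We implement the match as a
**semi-global alignment**: the spacer is aligned end to end inside a window
of the target, window overhangs are free, scoring is match +1 / mismatch
−2 and a gap run of length *g* costs 5 + 2*g*. Identity is anchored to the
spacer, `matches / len(spacer)` — this is stricter and less ambiguous than
identity over a local alignment span, and it makes the 90 % threshold an
exact statement (a 20 nt spacer tolerates 2 mismatches at 0.90 and fails
at 3 with 0.85). Alignments admit at most 2 gap columns by default
(`max_gaps`); ties in score are broken toward more matches, then fewer
gaps, then the leftmost span, so output is deterministic. The DP packs the
lexicographic objective (score, matches, −gaps) into a single integer per
cell, which keeps the three-state affine recurrence exact without a
traceback.

Candidate windows come from a **pigeonhole seed filter**: for edit budget
e = ⌊(1 − min_identity)·L⌋ + max_gaps the spacer is split into e + 1
contiguous exact chunks; any hit within budget must contain at least one
chunk verbatim, so exact-substring lookups of the chunks (with a ±(e+1)
window pad) enumerate a superset of all true hit locations, each then
verified by the full DP. Overlapping hits of the same spacer on a target
are deduplicated to the best-scoring span (ties leftmost). Matches falling
inside declared CRISPR-array intervals can be masked out, since a spacer
matching its own array is not a protospacer.

Hits can be labelled `phage` / `plasmid` / `genome` / `unknown` from a
target-metadata table. Genome-class hits are retained and kept separable:
a chromosomally located protospacer can persist precisely because its
flank deviates from the functional PAM (self-tolerance), and that
difference is informative downstream.

## PAM inference

The PAM of a type II system lies in the **10 nt immediately 3′ of the
protospacer, read on the non-target strand** — the strand on which the
spacer sequence itself occurs. For a plus-strand hit ending at *e* the
flank is `target[e : e+10]`; for a minus-strand hit starting at *s* it is
the reverse complement of `target[s−10 : s]`. Flanks shorter than the full
width (contig edge) are dropped, not padded, because padding would bias
terminal positions.

Flanks are fixed width, so "alignment" is positional stacking into a
position frequency matrix (counts over A/C/G/T per position; ambiguous
bases tallied separately in `skipped`, preserving the invariant
`counts + skipped = n` per position). Information content is
IC = 2 − H bits with H the base-2 Shannon entropy of the column's base
fractions; the Schneider small-sample correction e(n) = 3/(2·n·ln 2) is
available but off by default — at the small n typical of this analysis it
would null out genuinely weak signals, and the IC floor below already
handles noise. Logo data are exported as heights `freq × IC`, which sum to
the column IC.

The degenerate consensus uses a **cumulative-coverage rule**: per position,
bases are included in descending frequency — frequency ties included
together — until the included fraction reaches 0.8, and the IUPAC letter of
the included set is emitted. A 50/50 A/C position therefore reads `M`,
surfacing an ambiguity that only a cleavage experiment can resolve, and a
position split between genome-derived and phage-derived evidence shows up
when profiles are partitioned by source class. Two guards temper the rule:

* **IC floor** (`min_ic`, default 0.25 bits): a position below the floor is
  written `N`. A uniform column's IC is not exactly 0 at finite n — its
  sampling noise is ≈ 3/(2·n·ln 2) bits (≈ 0.04 at n = 50), and the
  coverage rule alone would render it as a spurious three-letter code.
  0.25 bits sits an order of magnitude above that noise yet safely below
  the 2 − log₂3 ≈ 0.415 bits of a genuinely three-base position, so truly
  degenerate letters (W, M, V, …) survive while noise reads `N`.
* **Minimum support** (`min_support`, default 3 flanks): with fewer flanks
  the caller refuses and suggests pooling spacers from closely related
  strains of the same species — the standard fallback when a species' own
  arrays yield no protospacers.

Identical (protospacer, flank) pairs within a group are deduplicated by
default (near-identical phages would otherwise multiply-count one event);
`dedup_flanks=false` keeps all. Loci sharing a group label pool their
flanks into one profile.

## Ortholog clustering

Proteins shorter than 800 aa are discarded as fragments (full-length Cas9s
run roughly 1000–1650 aa). All remaining pairs are aligned locally with
BLOSUM62, gap open −11 / extend −1 (extension priced from the second
gapped position, the aligner's native convention); `X` is accepted but
scores 0 against everything. Raw scores map to bits via the gapped
Karlin–Altschul transform bits = (λ·S − ln K)/ln 2 with the standard
protein-search constants λ = 0.267, K = 0.041 — declared constants, not
fitted ones; since score coverage divides bits by alignment length, their
exact values shift all edges together, and the audit edge table exposes
the raw numbers for anyone re-thresholding.

Two proteins are linked when the aligned span covers ≥ 0.8 of **both**
sequences and bit score / alignment length ≥ 0.8; clusters are connected
components (single linkage). Both coverages symmetric is deliberate — a
domain-only match to a longer multi-domain protein should not merge
clusters. Raising either threshold can only delete edges, hence only
refine the partition. All-vs-all is O(n²) alignments, acceptable at the
intended scale of a few hundred sequences.

## Tree building and concordance

Likelihood tree inference is a published-tool territory; what this package
needs from a tree is **grouping**, and for grouping a transparent
distance method suffices and is testable. Columns of the input MSA are
first filtered to "informative" ones — gap fraction ≤ 0.5 and at least two
distinct non-gap residues (both thresholds exposed; this is a declared
approximation of curated block selection, not a reconstruction of it).
Distances are p-distance or the Poisson correction d = −ln(1 − p), capped
(with a warning) at 10 as p → 1. Neighbor joining follows the Saitou–Nei
Q criterion with labels pre-sorted so input order is irrelevant, ties
broken toward the first pair in sorted order, negative branch lengths
clamped to 0, and the final three lineages joined at a root trifurcation
with the closed-form lengths, so the unrooted tree is binary. NJ is exact
on additive matrices — topology and path lengths — which is the property
the test suite enforces.

Bootstrap supports resample informative columns with replacement B times,
re-join each replicate, and attach to each point-tree edge the fraction of
replicates displaying its bipartition. Monophyly of a leaf set means some
edge bipartition equals it exactly (singletons and the full leaf set are
trivially monophyletic). The cluster/tree report lists, per sequence
cluster, whether its members are monophyletic — the concordance between
sequence-space clustering and tree grouping.

When no MSA is given and the retained proteins happen to be equal length
(the substitution-only synthetic families), they are treated as
positionally aligned; unequal-length inputs require an MSA, produced by
any standard aligner.

## Duplex scoring

The repeat:anti-repeat duplex scorer is a base-pair-weighted antiparallel
alignment: GC = 3, AU = 2, GU wobble = 1, opposed non-complementary bases
−1, bulged in-duplex positions −2, computed as a local alignment of strand
1 against the reversed strand 2 (so pairs are non-crossing and
antiparallel by construction, and the empty duplex scoring 0 makes the
optimum non-negative). This is explicitly **not** an energy model: it
ranks duplex extent for comparing loci, nothing more. Thermodynamic
co-folding, ensembles and intra-strand structure are out of scope.

## Synthetic corpora

The generator emulates the statistical structure of a database search, not
its biology: i.i.d. background genomes at a chosen GC; spacer copies
planted without overlap on uniformly chosen strands, each base substituted
independently at `mutation_rate`; a concrete flank drawn uniformly within
each IUPAC base set of the true PAM (N → uniform over four, W → uniform
over {A, T}), then mutated at the same rate; and a manifest recording every
placement, mutation count and realised flank. Each operation consumes its
own seeded stream, so adding placements never changes background bases.
Default study conditions for recovery runs: one 9 kb genome, 5 spacers of
30 nt, 50 placements, mutation rate 0.02, flank width 10 — enough planted
evidence for a stable logo while keeping a full 20-replicate recovery run
in seconds. Protein families default to 3 ancestors × 5 members of 900 aa,
within-family divergence 0.05, between-family 0.7 (rejection-enforced).

What passing these benchmarks shows: the search loses no hit above
threshold, the flank/consensus machinery recovers a planted motif at the
stated noise, clustering recovers well-separated families, NJ is exact on
additive inputs. What it does not show: behaviour on real genomes with
repeats and shared phage content, PAM inference from the tiny and biased
protospacer counts of real species (the minimum-support guard exists for a
reason), robustness of clustering near the coverage thresholds, or any
branch-length realism of the NJ stand-in.

## Degenerate inputs and edge behaviour

Empty FASTA yields an empty record list; malformed records fail naming the
line. Spacers must be plain ACGT (ambiguity codes rejected) so identity
arithmetic is exact; targets may carry IUPAC codes, which never count as
matches and are skipped in PFMs. Array orientation is an experimental
input — `unknown` is accepted but flagged, because the non-target strand
is undefined without it. Saturated distances, all-gap column pairs, < 3
taxa, empty flank sets and no-hit runs all fail with targeted messages
rather than degraded output; CLI exit codes are 0 / 2 (usage or config) /
3 (empty result).
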