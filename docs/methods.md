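# Methods

## Scope and design

`sasrfuse` implements a desk-scale fusion-discovery pipeline for base-space
paired-end RNA-Seq against an annotated gene model. It does not attempt to
be a production aligner: the genomic/junction/exon/filter mapping stage is a
deliberately small seed-and-extend mapper sized for the package's synthetic
fixtures, and users with real data can supply their own alignments and use
the SASR aligner, evidence graph, and bias test on top of them. Color-space
reads, indels, and novel (unannotated) exon boundaries are out of scope; to
find junctions at novel boundaries, add the novel exons to the gene model
first.

## Gene model

Internal coordinates are 0-based half-open; GTF input (1-based inclusive)
is converted at the boundary, BED12 is native. Exon `rank` is 1-based in
transcription order, so rank 1 on the minus strand is the highest-coordinate
exon. Overlapping transcripts of one gene are flattened to the set of
distinct `(start, end)` exon intervals, ranked on the flattened set: the
evidence graph operates on exons, not transcripts. Gene length is the
span from the start of the first exon to the end of the last exon, introns
included; this is the normalizer used by the bias test.

The junction reference enumerates, per gene, all ordered exon pairs
`(rank i, rank j)` with `i < j`: adjacent pairs are "known" junctions,
rank-skipping pairs "putative". There is no cap on `j − i` by default
(`max_rank_skip` exists for very exon-rich annotations). Each entry
concatenates the donor's 3′ flank and the acceptor's 5′ flank, truncated
when an exon is shorter than the flank; the default flank is
`read_length − 10` so a read spanning the boundary always retains at least
a decamer on its short side.

The filter reference (rRNA, repeats, adaptors, homopolymers in real use)
defaults to the four homopolymers; any read with a confident filter hit is
subtracted from all alignment sets before pairing.

## Suffix-array spliced-read (SASR) aligner

Two tables index every exon's ends: donor entries are the last `L` bases of
the exon (transcription orientation) for `L` in `[min_len, max_len]`
(default 10 to `read_length − 10`); acceptor entries are the first `L`
bases *keyed reversed*, so the read's terminal decamer can be
binary-searched after reversal with the same O(log n) machinery. Entries
are compact `(exon_index, length)` pairs; key strings are materialized
lazily during comparisons. Entries whose key contains a non-ACGT symbol are
excluded (they cannot anchor-match). The alphabet order is A<C<G<T; ties
between identical keys break by exon index for determinism.

Queries take the read's first and last decamers, matched exactly. Anchor
hits are extended over the stored exon end; substitutions are counted only
in the extension region, at most 2 per side by default. A hit requires the
donor map length plus the acceptor map length to equal the (effective) read
length. Clip totals c = 0..10 are tried in order; each total is split over
the two read ends (ascending left clip), all splits of a total are
searched, and the scan stops at the first productive total. The emitted hit
set is independent of the split enumeration order because all splits of a
total are searched before stopping.

Admission to SASR (the criteria are a reconstruction): a read is a
splice-candidate iff it is at least two anchors long, has no confident
prior placement (unmapped, or pairing quality ≤ 10), and its
base-composition Shannon entropy is ≥ 1 bit (rejecting homopolymers and
other low-complexity reads that would anchor promiscuously).

A read is kept only if all its hits name one junction after collapsing
exons with identical boundary coordinates (overlapping annotation);
otherwise it is discarded as ambiguous.

## Mapping and pairing

Four reference classes are aligned in one pass: genome, junction, exon
(used for the short reverse mates), and filter. Seeds are the first 25
bases with per-class seed mismatch budgets (genome/junction 2, exon 3);
candidate diagonals come from exact 8-mers of the seed (pigeonhole over
three chunks), and the full read is scored match +1 / mismatch −2. Each
class also caps total mismatches (genome/junction 4, exon 5): a read whose
best placement would exceed the cap is reported unmapped for that class
rather than as a frayed alignment — this is what routes breakpoint-spanning
reads (whose tails cross into a different gene) into SASR instead of
letting a partial genomic alignment claim them. An unmapped mate whose
partner is anchored inside a gene is rescued by realigning it within the
downstream exons of that gene with up to six mismatches.

Exon- and junction-reference alignments that lie entirely on one side of
the boundary are projected back to genome coordinates and deduplicated
against direct genomic placements before pairing, so the same physical
placement found through two references never competes with itself in the
pairing posterior. Junction-crossing alignments cannot be projected; they
are kept in junction coordinates and become SPAN evidence when they overlap
the boundary by at least 10 bases on each side.

The pairing quality value is a reconstruction with the published observable
behavior (a phred-like, thresholdable 0–40 scale). All (forward, reverse)
placement combinations are candidates; candidate `i` is weighted
`w_i = 10^(score_i/10) · d_i` where `d_i` is the normal insert-size density
(default mean 150, sd 25, matching a 100–200 bp gel-selected library) for
concordant candidates and a small constant background (1e−9) otherwise.
The best candidate is primary with
`PQV = min(40, round(−10·log₁₀(1 − w_best/Σw)))`. The background term is
what lets a *uniquely placed* discordant pair — the signature of a
fusion-bridging fragment — earn PQV 40 while still losing to any plausible
concordant explanation. RPKM uses primary pairs above the PQV threshold:
`reads_in_gene · 10⁹ / (total_confident · exonic_length)`.

## Evidence graph, JCV, calling

Exons are nodes; SPAN and BRIDGE evidences are edges keyed by the exon
pair. BRIDGE edges require primary pairings with PQV strictly greater than
10 and both mates assigned to exons; a mate whose interval overlaps exons
of more than one gene is ambiguous and the pair contributes to no
candidate. Uniqueness of evidence is uniqueness of start points: SPAN
evidences by their offset from the donor boundary, BRIDGE evidences by the
forward mate's leftmost coordinate, so PCR duplicates collapse.

Candidates are the exon pairs carrying at least one SPAN edge. BRIDGE
support for a candidate (donor D, acceptor A) aggregates bridge edges whose
forward-mate exon is in gene(D) at or upstream of D and whose reverse-mate
exon is in gene(A) at or downstream of A — bridging fragments land on the
exons flanking the junction, not necessarily exactly on D and A.

The JCV formula is a reconstruction of a score described only by its
properties (0–100 range, mass at 0 and 100, BRIDGE quantity/quality versus
an expression-driven error expectation). Effective evidence
`k_eff = Σ(1 − 10^(−PQV/10))`; null rate `λ = max(10⁻⁶, ρ·r_X·r_Y/N)` with
`r_X, r_Y` the exons' confident read counts, `N` the total primary pairs,
and ρ the random-mispairing rate (default 10⁻³, configurable for
calibration); `p_null = P(Poisson(λ) ≥ k_eff)` via the regularized lower
incomplete gamma `P(k_eff, λ)`; `JCV = clamp(round(−10·log₁₀ p_null), 0,
100)`. JCV is monotone in evidence and anti-monotone in λ by construction.

Calling thresholds are pairs (min unique SPAN, min unique BRIDGE): (1,1)
for same-gene junctions, (2,2) for fusions, with an optional JCV floor
applied afterwards. Same-gene calls sharing a donor or acceptor boundary
with at least two distinct partners are flagged as alternative splices.
Fusion classification: inter-chromosomal when the partner genes' chromosomes
differ; inverted when same chromosome, opposite strands; same-strand
otherwise, with `signed_distance` measured from the donor exon's 3′
boundary to the acceptor exon's 5′ boundary along the donor gene's
transcription direction (negative when the acceptor partner lies upstream —
the convention that reproduces the printed sign for reverse-order
intra-chromosomal fusions). `in_frame` is reported only when CDS annotation
is present (the synthetic models carry none, so it is empty there).

## Breakpoint-bias bootstrap

The breakpoint of a fusion is modeled at the midpoint of the intron
following the last retained exon of the 5′ gene (mirrored on the minus
strand) and normalized by gene length measured from the transcription
start. The null draws each gene's location uniform(0,1) over the gene span
(not intronic positions only); `n_sims` sets of `n_genes` locations are
drawn, and the p-value is the fraction of simulated set means *strictly
below* the observed mean. Under the null the set mean has expectation 0.5
and standard deviation `1/√(12·n)` (0.0602 for n = 23), and the simulated
p-value agrees with the Irwin–Hall closed form; both are property-tested.
The generator seed is recorded in the result for reproducibility.

## Synthetic data

The generator emulates a strand-specific paired-end RNA-Seq library:
asymmetric read lengths (50 bp forward / 25 bp reverse by default), inserts
normal(150, 25) — a 100–200 bp gel selection band, log-normal transcript
abundances (μ=1, σ=1), and i.i.d. substitution errors (default 0.5 %).
Genomes are uniform-random ACGT (3 × 120 kb), genes non-overlapping with
3–6 exons of 80–200 bp and introns of 200–800 bp, strands alternating
within a chromosome so all three fusion classes have candidate gene pairs.
Fusion transcripts join exons 1..r of a 5′ gene to exons s..end of a 3′
gene with r, s drawn uniformly; classes follow a configurable mix
(default one third each). Besides abundance-driven fragments, the generator
emits a small number of deterministic fragments per fusion with distinct
start points (default 3 spanning + 3 bridging) so that recovery tests state
their coverage precondition explicitly rather than relying on sampling
luck; these fragments pass through the same error model.

What the generator does *not* emulate: repeat families and homology between
genes (the main source of real-data false positives), base-quality
structure, coverage bias along transcripts, indels, and PCR duplication
beyond identical start points. Passing recovery tests on this data
therefore demonstrates the correctness of the machinery — anchoring,
extension, sum rule, pairing, thresholds — not real-data specificity, which
is governed by the filter reference, the ambiguity rule, and JCV
calibration (ρ) on real alignments.

## Numerical and problem-size choices

- Poisson upper tails via `scipy.special.gammainc` at real-valued `k_eff`;
  p floored at 10⁻³⁰⁰ before the log; JCV/PQV rounded half-even by Python's
  `round`.
- PQV posterior guard: `1 − p < 10⁻¹²` reports the 40 cap directly.
- Suffix tables sort by materialized key with `(exon_index, length)`
  tie-breaks; all pipeline outputs are sorted deterministically, and
  rerunning with the same seed is byte-identical.
- Test problem sizes: oracle-equivalence runs use ≤50 exons and ~200 reads;
  end-to-end recovery uses 45 genes / 21 fusions / 2,500 fragments; the
  bootstrap runs at its published 100,000 × 23 operating point. These sizes
  make the whole suite run in seconds while exercising every stage at the
  published operating thresholds.

## Known limitations

- The PQV and JCV formulas and the SASR admission criteria are
  reconstructions from described behavior, not transcriptions; their
  thresholdable semantics (0–40 and 0–100 scales, PQV>10 confidence) are
  preserved but individual values need not match any other implementation.
- The seed-and-extend mapper trades sensitivity for size: reads whose first
  25 bases contain errors in all three seed chunks are missed, and scoring
  is not base-quality aware.
- BRIDGE direction relies on the strand-specific library convention
  (forward mate = sense); non-strand-specific chemistries would need the
  orientation convention relaxed.
- `in_frame` requires CDS annotation; GTF CDS records are not currently
  parsed, so frame is reported only as absent.
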