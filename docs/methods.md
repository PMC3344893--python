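# Methods

## Scope and model of the data

The package operates on ortholog cohorts for a single locus: one promoter
or 3′-UTR sequence per species, optionally a multiple alignment of them,
a rooted species tree, mature miRNA sequences, and element consensus
sequences. It identifies regulatory elements the way a footprinting study
does — short motifs conserved as patches against a diverged background —
and characterises lineage-restricted retroelement insertions. It does not
retrieve sequences, compute multiple alignments (they are ingested
verbatim), score motifs probabilistically, or model thermodynamics of
RNA duplexes.

## Coordinate conventions

All internal sequence coordinates are 1-based closed; conversion to
0-based half-open happens only at BED export. Promoter positions relative
to a transcription start site use the no-zero genetics convention
(…, −2, −1, +1, +2, …), so an interval spanning the TSS such as
(−197, +107) contains |−197| + 107 = 304 positions. UTR position 1 is the
first nucleotide after the stop codon, and a miRNA site's position is the
5′-most base of its target word. The internal alphabet is DNA; RNA input
is converted U→T on load, flagged, and rendered back as RNA on output.
This keeps one scanning code path for promoter DNA and miRNA-derived
words.

## Motif scanning

A window matches an IUPAC consensus when every window base lies in the
base set of the corresponding consensus code. An ambiguity code in the
*scanned* sequence matches only a consensus position whose set contains
its full set — so an N in a draft genome never satisfies a concrete
consensus position (conservative calling). Minus-strand hits are found by
matching the reverse-complemented consensus and are reported in
plus-strand coordinates; a site matched on both strands at the same span
(the NRF1 consensus is near-palindromic) is collapsed to one + hit
flagged `both_strands`.

The NRF1 rule: consensus `YGCGCANGCGCR`, half-sites at positions 2–5 and
8–11 (both `GCGC`). The degenerate flanking positions (1, 6, 7, 12) must
always match their sets; at most one mismatch is tolerated and it must
fall inside a single half-site. This is the stricter of the two possible
readings (the tolerated mismatch could conceivably also fall on a
degenerate position); we use the literal half-site reading. Hits are
classed `perfect` (0 mismatches) or `tolerated`.

Overlapping hits are all reported in exports. For *counting sites*,
`nonoverlapping_hits` reduces overlapping calls to distinct footprints
(greedy, perfect class first, then leftmost): a 12-bp site binds one
dimer, and a perfect match shadowed by a tolerated call one step away is
the same site.

Duplication finding reports maximal pairs of exact repeats (length ≥ 8 by
default). Periodic regions generate derivative pairs at multiples of the
fundamental period; a pair whose combined span is contained in the span
of a smaller-offset pair is suppressed, so a homopolymer run yields the
single offset-1 block. This is a deterministic tie-break, not a claim
about repeat biology.

## Conservation

Identity counting only, no phylogenetic weighting: the data this serves
are small cohorts where the published analyses count species. A column is
`*` when all rows agree and no row has a gap (gaps count in the
denominator and block `*`), `^` when the majority base reaches
`high_threshold` without invariance. The default threshold 0.89 is chosen
so that both a 17/19 column (0.895) and a 35/38 column (0.921) — the two
"~90%" cases the annotation style is used for — fall in the high tier.
Majority ties break alphabetically for deterministic output. Deviating
species are treated the same whether they carry a substitution or a gap.

## miRNA seed matching

Seed classes follow the canonical definitions: 8mer = reverse complement
of miRNA positions 2–8 followed by an adenine opposite position 1;
7mer-m8 = positions 2–8; 7mer-A1 = positions 2–7 plus the adenine. The
adenine is required as a literal A in the target regardless of miRNA
position 1 (the standard convention; A1 recognition is by the silencing
complex, not by pairing). Classification is strict Watson–Crick — a G:U
wobble never rescues a seed match — while duplex diagrams display wobbles
as a distinct pair type and can count them as paired.

At one start position only the highest class is reported
(8mer > 7mer-m8 > 7mer-A1), and a site whose word lies entirely inside a
higher-class site's word is suppressed: every 8mer contains a 7mer-A1 as
its suffix, and reporting it separately would double-count one physical
site. The test suite checks this against an exhaustive oracle that
classifies every 8-nt frame by direct pairing.

Cross-species conservation uses unaligned cohorts with a positional
homology heuristic: a species "has" the reference site when a site of any
class starts within ±10 nt of the reference position. This is adequate
for the substitution-only simulator (coordinates stay colinear) and for
closely related cohorts; for deeply diverged UTRs a projected alignment
position would be needed. Species lacking the reference site are
re-searched within a compensatory window (default 0–160 nt 3′ of the
reference position).

## Insertion forensics

Candidate insertions are gap blocks in the reference row of a global
affine-gap alignment (defaults +1/−1/−5/−0.5, a gap of length L scoring
open + (L−1)·extend). Two robustness steps reflect how aligners actually
behave around long insertions: gap blocks separated by ≤ 20 aligned
carrier bases are merged (aligners occasionally stitch a few spurious
matches into the middle of a long insertion), and each interval is
canonicalised by sliding 3′-ward through the flanking repeat so that the
TSD's second copy sits at the insertion's 3′ terminus (the inside-edge
convention).

Alignment is delegated to Biopython's pairwise aligner (global and local
modes); its first traceback is deterministic, and the test suite checks
score equality against an independently written three-matrix DP on 500
random pairs. TSD detection compares the k-mer ending immediately 5′ of
the insertion with the k-mer at the insertion's 3′ terminus, longest k
(8–30) winning; a `boundary_slack` parameter (pipeline default 25) lets
the comparison end near rather than exactly at the nominal boundary,
because alignment-inferred breakpoints are imprecise within flanking
repeats. Poly-A/T detection reports the longest terminal homopolymer
(≥ 8): a 3′ A-run for sense integration, a 5′ T-run as the antisense
signature; the pipeline strips the detected TSD copy before measuring,
since the tail sits 5′ of it. Element classification takes the best
local-alignment score against each library consensus in both
orientations (antisense when the reverse complement wins; unclassified
below `min_score`, default 50 — far above the background distribution of
random ~300-mers, which peaks near 20).

Gain placement is Dollo parsimony with the single gain asserted, not
inferred: retroelement insertions are effectively homoplasy-free
characters, so the gain edge is the stem of the MRCA of carrier species
and the losses are the deepest edges within that clade whose entire
subtree lacks the insertion.

## The simulator and what it does (not) emulate

The generator exists so every stage is testable with known truth. Its
substitution model is deliberately minimal: per site, per edge of length
b, substitution probability min(1, p·b), multiplied by a protection
factor f ∈ [0, 1] inside protected intervals, replacement uniform over
the other three bases. There are no background indels (truth coordinates
stay stable), no rate heterogeneity, no CpG effects, no GTR matrix. A
replacement event overwrites one lineage's motif with tandem copies of
another word after evolution; insertion implants duplicate the
`tsd_len`-mer 5′ of the integration site and place the (optionally
reverse-complemented) element plus poly-A tail between the copies.

Two determinism guarantees matter for exact-recovery testing. First, the
implanted duplication is made maximal and frame-unambiguous: if the base
5′ of the left copy equals the insert body's last base (which would
extend the repeat), or the host base 3′ of the integration site equals
the body's first base (which would shift the duplication frame), that
base is nudged to the next base in A<C<G<T order. Real TSDs are by
construction flanked by non-duplicated sequence; without the nudge,
longest-wins detection correctly reports the extended repeat and no
simulator can promise exact length recovery. Second, all randomness flows
from explicit integer seeds; identical spec + seed gives byte-identical
FASTA and truth output.

Because the generator has no indels and no alignment noise beyond what
the aligner itself introduces, a passing test shows the algorithms are
correct under colinear orthologs with point substitutions — it does not
show robustness to assembly gaps, segmental duplications, or
alignment-quality pathologies in real draft genomes.

## Preset study conditions

`phylofoot.presets` pins the cohorts used by the fixtures command, the
test suite and the acceptance script:

* 20-species eutherian promoter cohort, 600 nt, GC 0.6, per-edge
  substitution probability 0.03, fully protected SOX11 word flanked by a
  perfect and a single-mismatch NRF1 site, with the elephant lineage's
  SOX11 motif replaced by two tandem copies of the perfect NRF1 site plus
  a 3-nt spacer (the spacer prevents the two copies fusing into a
  spurious junction site). Motif counts are reported within the
  footprinted region (positions 250–420), as a footprinting study counts
  sites in its aligned promoter window.
* 38-species mammalian UTR cohort, 800 nt, GC 0.45, rate 0.04, with a
  protected miR-96 8mer site and an upstream 7mer-A1 site; a variant
  ablates the 8mer in 10 species and leaves a compensatory 7mer-A1
  ~120 nt downstream intact in 5 of them.
* 10-primate UTR cohort with a ~280-nt synthetic SINE-like element
  (random, GC 0.55 — labelled synthetic; no real repeat consensus ships
  with the package) inserted antisense with an 18-nt TSD and 12-nt tail
  in the 6 catarrhine species. Rate 0.005 per edge, giving ~6–8% maximum
  pairwise divergence, typical of primate 3′-UTRs.

Site ablation in UTR presets reverse-complements the implanted word in
place — deterministic, and guaranteed not to leave the original word —
rather than resampling bases.

## Numerical and degenerate-input choices

Empty FASTA, duplicate ids, ragged alignments, unbalanced Newick, zero
TSS coordinates, overlapping implants and a presence matrix that does not
cover the tree all raise `ValueError` with the offending item named. A
sequence shorter than a motif yields an empty hit list, not an error. A
reference species without any seed-match site produces a report with a
warning field rather than an exception. TSD detection on an interval
touching the sequence start returns None (no 5′ flank to compare).
Scores are floats; score comparisons in tests use exact equality only
where both routes compute sums of the same terms, otherwise
`math.isclose`.

## Problem sizes

Default verification sizes: 500 random pairs (length ≤ 8) for the
alignment-score oracle, 500 miRNA/UTR pairs for the seed classifier
oracle, 200 implanted insertions (TSD uniform 8–25) for exact TSD
recovery, 100 random clade-consistent trees for gain placement, 1000
sites for the single-edge identity check (within 3 standard errors of
1 − min(1, p·b)), and 40 replicate 12-leaf cohorts at p = 0.3, f = 0.05
for protected-motif recovery. These sizes give the property suites
sub-second to few-second runtimes while keeping binomial noise well below
the effect sizes under test.

## Known limitations

* Conservation is identity-based; no branch-length weighting.
* Site homology across species is positional, not alignment-projected.
* Element classification needs a user-supplied consensus library; no
  repeat database ships with the package, so the synthetic element is a
  stand-in, not a real SINE consensus.
* The aligner's co-optimal tie-breaking is the library's canonical first
  traceback; gap placement within repeats is therefore a convention, and
  downstream code (interval canonicalisation, TSD slack) is written to be
  insensitive to it.
* Dollo placement assumes the presence calls are correct; a false
  negative in one carrier species shows up as a spurious loss, not as a
  revised gain.
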