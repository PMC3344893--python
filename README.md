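# phylofoot

Phylogenetic footprinting of regulatory elements in ortholog cohorts:
transcription-factor motif scanning over promoter orthologs, miRNA
seed-match analysis in 3′-UTRs, retroelement-insertion forensics, and a
deterministic synthetic-cohort generator with ground truth.

## Who this is for

Comparative genomicists asking the classic footprinting questions about a
single locus: which short promoter motifs stand out as conserved patches
against a diverged background, which miRNA seed-match sites in the 3′-UTR
are maintained across species, and when a lineage-restricted retroelement
insertion created a new regulatory site, on which branch of the species
tree did it arise?

## What it computes

**Motif scanning** (`phylofoot.motifscan`). Degenerate IUPAC consensus
matching on both strands (e.g. SOX11 `CAACAAAGA`, Sp1 GC-box `GGGCGG`),
plus the NRF1 half-site rule: the near-palindromic consensus
`yGCGCAnGCGCr` binds as a dimer on two GCGC tetramers, and a single
mismatch is tolerated only within one tetramer — hits are classed
`perfect` or `tolerated`. Local exact duplications (the signature of a
motif cluster derived by tandem duplication) are reported as maximal
repeat pairs.

**Conservation** (`phylofoot.conserve`). Plain identity counting over an
ortholog alignment: a column is starred (`*`) when every row carries the
same base, marked `^` when the majority base reaches the high-tier
threshold (default 0.89, which admits both a 17/19 and a 35/38 column as
"~90% conserved"), and per-species motif presence is classed
exact / degenerate / absent.

**miRNA targeting** (`phylofoot.mirtarget`). Canonical seed-match classes
for a mature miRNA (seed = positions 2–7): 8mer (reverse complement of
positions 2–8 followed by an adenine opposite position 1), 7mer-m8
(positions 2–8), 7mer-A1 (positions 2–7 plus the adenine). The
position-1 adenine is required as a literal A. Classification is strict
Watson–Crick; G:U wobbles appear only in duplex diagrams. Cross-species
site conservation reports, per species, the best class anywhere in the
UTR, whether the reference site is present, and whether a species lacking
it carries a compensatory site within a configurable window downstream.
miRNAs sharing positions 2–7 are grouped into seed families.

**Insertions** (`phylofoot.insertion`). Pairwise global alignment
(affine gaps: +1 match, −1 mismatch, −5 open, −0.5 extend) of a carrier
UTR against an insertion-free reference yields candidate insertions; each
is then characterised by its L1-pathway hallmarks: target-site duplication
(longest exact direct repeat flanking the insertion, searched between 8
and 30 nt), terminal homopolymer (3′ poly-A in sense orientation, 5′
poly-T when the element integrated antisense), and element identity and
orientation by local alignment against a consensus library. Presence /
absence across species is placed on a rooted tree by single-gain Dollo
parsimony: one gain on the stem of the carriers' MRCA, losses free inside.

**Simulation** (`phylofoot.simulate`). An ancestral sequence evolves along
a Newick tree; each site substitutes with probability min(1, p·b) per
edge of length b, scaled by a protection factor f inside protected
intervals. Implants: protected motif words, seed-match target words,
lineage-specific motif replacement by tandem duplications, and
clade-restricted element insertions with an exact TSD and homopolymer
tail. Output is byte-deterministic for a fixed spec and seed and carries
a full ground-truth table.

## Worked example

Generate the canned 20-species promoter cohort (a protected SOX11 word
flanked by two NRF1 sites, with one lineage whose SOX11 motif has been
replaced by tandem NRF1 duplications) and scan it:

```
$ phylofoot fixtures --seed 1 -o demo
$ phylofoot promoter-scan demo/promoter_cohort.fa -o demo_out
INFO SOX11: {'exact': 19, 'degenerate': 0, 'absent': 1}
INFO NRF1: {'exact': 20, 'degenerate': 0, 'absent': 0}
INFO SP1: {'exact': 13, 'degenerate': 0, 'absent': 7}
```

The SOX11 word is exactly present in 19 of the 20 species and absent in
the replaced lineage (elephant); every species retains at least one
perfect NRF1 site. `demo_out/hits.tsv` lists each located site:

```
record_id  motif  start  end  strand  class      mismatches
cat        NRF1   270    281  +       tolerated  5
cat        SOX11  300    308  +       perfect
cat        NRF1   320    331  +       perfect
```

The tolerated NRF1 hit carries its single mismatch at consensus position
5, inside the first GCGC half-site. The other commands follow the same
pattern: `utr-scan` (seed-match sites, conservation, duplex diagrams,
seed families), `insertion-scan` (insertion events with TSD/tail/element
calls, presence matrix, gain placement as annotated Newick),
`conservation` (column tiers for an alignment) and `simulate` (cohort
from a YAML spec).

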