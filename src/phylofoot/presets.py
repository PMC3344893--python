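"""Canned cohort specifications for the demo pipeline and the test fixtures.

Each preset encodes one study condition the package is built around:

* ``promoter_spec`` — 20 eutherian promoter orthologs with a protected
  SOX11 word flanked by one perfect and one single-mismatch NRF1 site, and a
  single lineage (elephant) whose SOX11 motif is overwritten by tandem
  duplications of the perfect NRF1 site.  The expected readout is the SOX11
  word exactly present in 19 of 20 species, and four NRF1 sites (three
  perfect) in the replaced lineage.
* ``utr_conservation_spec`` — 38 mammalian 3'-UTR orthologs carrying a
  protected miR-96 8mer site in every species plus an upstream 7mer-A1 site.
* ``utr_compensatory_spec`` — the same cohort with the 8mer site ablated in
  10 species, 5 of which carry a 7mer-A1 site ~120 nt downstream of the
  reference position (a compensatory site).
* ``primate_insertion_spec`` — 10 primates, with a ~280-nt synthetic
  element inserted antisense (poly-T head) with an 18-nt target-site
  duplication in the 6 catarrhine species only.

All presets are parameterised by a single integer seed and are fully
deterministic.
"""

from __future__ import annotations

from .mirtarget import Mirna
from .seqio import SeqRecord
from .simulate import (
    CohortSpec,
    InsertionImplant,
    MotifImplant,
    SeedImplant,
    make_ancestor,
)

__all__ = [
    "MIR96",
    "NRF1_PERFECT_SITE",
    "NRF1_TOLERATED_SITE",
    "EUTHERIANS_20",
    "MAMMALS_38",
    "PRIMATES_10",
    "CATARRHINES",
    "balanced_newick",
    "promoter_spec",
    "utr_conservation_spec",
    "utr_compensatory_spec",
    "primate_insertion_spec",
    "synthetic_element",
]

#: Mature hsa-miR-96 (miRBase), whose seed targets the canonical 8mer GTGCCAAA.
MIR96 = Mirna("miR-96", "UUUGGCACUAGCACAUUUUUGCU")

#: A perfect-match realisation of the NRF1 consensus yGCGCAnGCGCr.
NRF1_PERFECT_SITE = "TGCGCATGCGCG"
#: One mismatch inside the first GCGC half-site (position 5 C->T).
NRF1_TOLERATED_SITE = "TGCGTATGCGCG"
#: Duplication unit for the replaced lineage: the perfect site plus a short
#: spacer, so tandem copies do not fuse into a spurious junction site.
NRF1_DUPLICATION_UNIT = NRF1_PERFECT_SITE + "ACT"

#: The footprinted motif-cluster region of the promoter preset (1-based,
#: ancestor coordinates, wide enough to cover the replaced lineage's shifted
#: sites).  Motif counts are reported within this region, as a footprinting
#: study counts sites in its aligned promoter window, not genome-wide.
PROMOTER_FOOTPRINT = (250, 420)

EUTHERIANS_20 = (
    "human", "chimpanzee", "gorilla", "orangutan", "macaque", "marmoset",
    "mouse", "rat", "guinea_pig", "rabbit", "dog", "cat", "horse", "cow",
    "pig", "sheep", "microbat", "megabat", "tenrec", "elephant",
)

MAMMALS_38 = tuple(f"mammal_{i:02d}" for i in range(1, 39))

PRIMATES_10 = (
    "human", "chimpanzee", "orangutan", "gibbon", "macaque", "baboon",
    "marmoset", "squirrel_monkey", "tarsier", "mouse_lemur",
)

#: Old World monkeys + apes: the clade carrying the insertion.
CATARRHINES = ("human", "chimpanzee", "orangutan", "gibbon", "macaque", "baboon")

PRIMATE_NEWICK = (
    "((((((human:1,chimpanzee:1):1,orangutan:1):1,gibbon:1):1,"
    "(macaque:1,baboon:1):2):2,(marmoset:1,squirrel_monkey:1):4):2,"
    "(tarsier:6,mouse_lemur:6):1);"
)


def balanced_newick(names: tuple[str, ...]) -> str:
    """Balanced rooted topology over the given leaves, unit branch lengths."""
    nodes = [f"{n}:1" for n in names]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(f"({nodes[i]},{nodes[i + 1]}):1")
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0] + ";"


def promoter_spec(seed: int) -> CohortSpec:
    """Promoter cohort: protected SOX11 + two NRF1 sites, elephant replacement."""
    return CohortSpec(
        newick=balanced_newick(EUTHERIANS_20),
        length=600,
        gc=0.6,
        rate=0.03,
        seed=seed,
        motif_implants=(
            MotifImplant(
                name="NRF1_5prime",
                word=NRF1_TOLERATED_SITE,
                position=270,
                protection=0.0,
            ),
            MotifImplant(
                name="SOX11",
                word="CAACAAAGA",
                position=300,
                protection=0.0,
                replacement_on="elephant",
                replacement_word=NRF1_DUPLICATION_UNIT,
                replacement_copies=2,
            ),
            MotifImplant(
                name="NRF1_3prime",
                word=NRF1_PERFECT_SITE,
                position=320,
                protection=0.0,
            ),
        ),
    )


def utr_conservation_spec(seed: int) -> CohortSpec:
    """38-species UTR cohort: miR-96 8mer in all, 7mer-A1 site 50 nt upstream."""
    return CohortSpec(
        newick=balanced_newick(MAMMALS_38),
        length=800,
        gc=0.45,
        rate=0.04,
        seed=seed,
        seed_implants=(
            SeedImplant(mirna=MIR96, site_class="7mer-A1", position=450),
            SeedImplant(mirna=MIR96, site_class="8mer", position=500),
        ),
    )


def utr_compensatory_spec(seed: int) -> CohortSpec:
    """As the conservation cohort, but the 8mer is ablated in 10 species and a
    compensatory 7mer-A1 placed ~120 nt 3' of it survives in 5 of those 10."""
    lacking = MAMMALS_38[:10]
    keep_compensatory = lacking[:5]
    ablate_comp = tuple(sp for sp in MAMMALS_38 if sp not in keep_compensatory)
    return CohortSpec(
        newick=balanced_newick(MAMMALS_38),
        length=800,
        gc=0.45,
        rate=0.04,
        seed=seed,
        seed_implants=(
            SeedImplant(
                mirna=MIR96, site_class="8mer", position=500, ablate_on=lacking
            ),
            SeedImplant(
                mirna=MIR96, site_class="7mer-A1", position=620, ablate_on=ablate_comp
            ),
        ),
    )


def synthetic_element(seed: int, length: int = 280) -> SeqRecord:
    """A synthetic ~300-nt SINE-like element consensus (random, GC-rich)."""
    return SeqRecord(
        id="SINE_synthetic",
        residues=make_ancestor(length, gc=0.55, seed=seed + 17),
        description="synthetic element consensus for classification tests",
    )


def primate_insertion_spec(seed: int) -> CohortSpec:
    """10-primate UTR cohort with a catarrhine-restricted antisense insertion."""
    element = synthetic_element(seed)
    # per-edge substitution probability chosen so the most distant pair
    # diverges ~6-8%, matching typical primate 3'-UTR identity
    return CohortSpec(
        newick=PRIMATE_NEWICK,
        length=800,
        gc=0.45,
        rate=0.005,
        seed=seed,
        insertion_implants=(
            InsertionImplant(
                name="SINE_insertion",
                clade=CATARRHINES,
                element=element.residues,
                position=400,
                orientation="antisense",
                tsd_len=18,
                tail_len=12,
            ),
        ),
    )
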