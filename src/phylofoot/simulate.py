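"""Synthetic ortholog-cohort generator with ground truth.

The generator emulates the data a phylogenetic-footprinting study works
from: an ancestral promoter or 3'-UTR evolved along a species tree under a
simple substitution-only model, with implanted functional elements
(transcription-factor motif words, miRNA seed-match words) held under
selective protection, optional motif-replacement events on named branches
(e.g. a lineage whose motif is overwritten by tandem duplications of a
different site), and clade-restricted element insertions carrying the L1
hallmarks (exact target-site duplication, homopolymer tail, antisense
orientation).

The substitution model is deliberately minimal: along an edge of length b
each site substitutes independently with probability min(1, p*b), multiplied
by a protection factor f inside protected intervals, and is replaced
uniformly by one of the other three bases.  There are no background indels,
so ancestor coordinates remain valid in every leaf except where an explicit
insertion or replacement event applies; the ground-truth table records the
adjusted per-species coordinates.

All randomness flows from explicit seeds; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .mirtarget import Mirna, seed_targets
from .seqio import SeqRecord, read_newick, revcomp

__all__ = [
    "EvolveParams",
    "MotifImplant",
    "SeedImplant",
    "InsertionImplant",
    "CohortSpec",
    "Cohort",
    "make_ancestor",
    "evolve",
    "implant_insertion",
    "make_promoter_cohort",
    "make_utr_cohort",
]

BASES = "ACGT"
_OTHER = {b: [o for o in BASES if o != b] for b in BASES}


@dataclass(frozen=True)
class EvolveParams:
    """Per-site substitution probability per unit branch length, protection factor."""

    rate: float = 0.1
    protection: float = 0.0  # multiplier applied inside protected intervals
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must lie in [0, 1]")
        if not 0 <= self.protection <= 1:
            raise ValueError("protection factor must lie in [0, 1]")


@dataclass(frozen=True)
class MotifImplant:
    """A motif word written into the ancestor and protected during evolution.

    ``replacement_on`` names a leaf (or internal clade via its member leaves
    elsewhere) whose copy of the motif is overwritten after evolution by
    ``replacement_copies`` tandem copies of ``replacement_word`` — emulating
    a lineage-specific loss-and-duplication event.
    """

    name: str
    word: str
    position: int  # 1-based in the ancestor
    protection: float = 0.0
    replacement_on: Optional[str] = None
    replacement_word: Optional[str] = None
    replacement_copies: int = 2

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("implant position must be >= 1")
        if self.replacement_on and not self.replacement_word:
            raise ValueError("replacement event requires a replacement word")

    @property
    def interval(self) -> tuple[int, int]:
        return self.position, self.position + len(self.word) - 1


@dataclass(frozen=True)
class SeedImplant:
    """A miRNA seed-match target word implant for UTR cohorts."""

    mirna: Mirna
    site_class: str
    position: int
    protection: float = 0.0
    ablate_on: tuple[str, ...] = ()  # species whose site is scrambled post-evolution

    def to_motif(self) -> MotifImplant:
        word = seed_targets(self.mirna, "dna")[self.site_class]
        return MotifImplant(
            name=f"{self.mirna.name}:{self.site_class}",
            word=word,
            position=self.position,
            protection=self.protection,
        )


@dataclass(frozen=True)
class InsertionImplant:
    """A clade-restricted element insertion with TSD and homopolymer tail."""

    name: str
    clade: tuple[str, ...]
    element: str
    position: int  # 1-based: first base of the inserted segment in carriers
    orientation: str = "antisense"
    tsd_len: int = 18
    tail_len: int = 12

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be 'sense' or 'antisense'")
        if self.tsd_len < 1 or self.tail_len < 0:
            raise ValueError("tsd_len must be >= 1 and tail_len >= 0")


@dataclass
class CohortSpec:
    """Everything needed to generate one ortholog cohort deterministically."""

    newick: str
    length: int = 600
    gc: float = 0.6
    rate: float = 0.1
    seed: int = 0
    motif_implants: tuple[MotifImplant, ...] = ()
    seed_implants: tuple[SeedImplant, ...] = ()
    insertion_implants: tuple[InsertionImplant, ...] = ()

    def __post_init__(self) -> None:
        self.motif_implants = tuple(self.motif_implants)
        self.seed_implants = tuple(self.seed_implants)
        self.insertion_implants = tuple(self.insertion_implants)
        ivs = [m.interval for m in self.motif_implants] + [
            s.to_motif().interval for s in self.seed_implants
        ]
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("implants overlap in the ancestor")
        for s, e in ivs:
            if e > self.length:
                raise ValueError("implant extends beyond the ancestor")


@dataclass
class Cohort:
    """Generated leaf records plus the ground-truth table."""

    records: list[SeqRecord]
    truth: dict  # per species: sequence, per-feature coordinates and status

    def record(self, species: str) -> SeqRecord:
        for rec in self.records:
            if rec.id == species:
                return rec
        raise KeyError(species)

    def truth_json(self) -> str:
        return json.dumps(self.truth, indent=2, sort_keys=True)


def make_ancestor(length: int, gc: float, seed: int) -> str:
    """Random ancestral sequence with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _site_factors(length: int, protected: Sequence[tuple[int, int, float]]) -> np.ndarray:
    factors = np.ones(length)
    for start, end, f in protected:
        factors[start - 1 : end] = f
    return factors


def _mutate(seq: str, prob: np.ndarray, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < prob)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER[chars[i]][rng.integers(3)]
    return "".join(chars)


def evolve(
    tree: dendropy.Tree | str,
    ancestor: str,
    params: EvolveParams,
    protected: Sequence[tuple[int, int, float] | tuple[int, int]] = (),
) -> dict[str, str]:
    """Evolve an ancestor along a tree; returns leaf label -> sequence.

    Each edge of length b (1 when branch lengths are absent) substitutes each
    site with probability min(1, rate*b), scaled by the protection factor
    inside ``protected`` intervals (1-based closed).  An interval given as
    ``(start, end)`` uses ``params.protection``; ``(start, end, factor)``
    overrides it per interval.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    rng = np.random.default_rng(params.seed)
    intervals = [
        iv if len(iv) == 3 else (iv[0], iv[1], params.protection)
        for iv in protected
    ]
    base_prob = _site_factors(len(ancestor), intervals)
    leaves: dict[str, str] = {}

    def descend(node: dendropy.Node, seq: str) -> None:
        for child in node.child_nodes():
            b = child.edge.length if child.edge.length is not None else 1.0
            p_edge = min(1.0, params.rate * b)
            child_seq = _mutate(seq, p_edge * base_prob, rng)
            if child.is_leaf():
                leaves[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    root_seq = ancestor.upper()
    root = tree.seed_node
    if root.is_leaf():
        leaves[root.taxon.label] = root_seq
    descend(root, root_seq)
    return leaves


def _build_insert(imp: InsertionImplant) -> str:
    """Inserted residues ahead of the TSD copy (element + tail, orientation applied)."""
    if imp.orientation == "sense":
        return imp.element.upper() + "A" * imp.tail_len
    return revcomp(imp.element.upper() + "A" * imp.tail_len)


def implant_insertion(
    sequences: dict[str, str],
    imp: InsertionImplant,
) -> tuple[dict[str, str], dict[str, dict]]:
    """Insert an element with TSD into each clade member's sequence.

    At ``position`` the ``tsd_len``-mer immediately 5' is duplicated and the
    (optionally reverse-complemented) element plus tail placed between the
    two copies, so the inserted segment reads element+tail+TSD-copy and its
    3' terminus repeats the 5' flank — the geometry ``detect_tsd`` expects.
    A real TSD is maximal (flanked by non-duplicated sequence), so the
    implanted duplication is made unambiguous: when the base immediately 5'
    of the left copy equals the body's last base (which would extend the
    repeat leftward), the body's last base is nudged to the next base in
    A<C<G<T order; when the host base immediately 3' of the integration site
    equals the body's first base (which would make the duplication frame
    ambiguous), that host base is nudged likewise.
    Returns updated sequences and per-species truth entries.
    """
    missing = [sp for sp in imp.clade if sp not in sequences]
    if missing:
        raise ValueError(f"clade members not in cohort: {missing}")
    out = dict(sequences)
    truth: dict[str, dict] = {}
    body = _build_insert(imp)
    for sp in sequences:
        if sp not in imp.clade:
            truth[sp] = {"status": "absent"}
            continue
        seq = sequences[sp]
        pos0 = imp.position - 1
        if pos0 < imp.tsd_len:
            raise ValueError(
                f"tsd_len {imp.tsd_len} exceeds 5' flank at position {imp.position}"
            )
        if pos0 > len(seq):
            raise ValueError(f"insertion position {imp.position} beyond sequence of {sp}")
        tsd = seq[pos0 - imp.tsd_len : pos0]
        sp_body = body
        if pos0 - imp.tsd_len - 1 >= 0 and seq[pos0 - imp.tsd_len - 1] == sp_body[-1]:
            nudge = BASES[(BASES.index(sp_body[-1]) + 1) % 4]
            sp_body = sp_body[:-1] + nudge
        if pos0 < len(seq) and seq[pos0] == sp_body[0]:
            nudge = BASES[(BASES.index(seq[pos0]) + 1) % 4]
            seq = seq[:pos0] + nudge + seq[pos0 + 1 :]
        inserted = sp_body + tsd
        out[sp] = seq[:pos0] + inserted + seq[pos0:]
        truth[sp] = {
            "status": "present",
            "start": imp.position,
            "length": len(inserted),
            "tsd_len": imp.tsd_len,
            "tail_len": imp.tail_len,
            "orientation": imp.orientation,
        }
    return out, truth


def _clade_members(tree: dendropy.Tree, names: Sequence[str]) -> set[str]:
    return set(names)


def _apply_replacement(seq: str, imp: MotifImplant) -> tuple[str, int, int]:
    """Overwrite the motif interval with tandem replacement copies; return new coords."""
    start, end = imp.interval
    replacement = imp.replacement_word * imp.replacement_copies
    new_seq = seq[: start - 1] + replacement + seq[end:]
    return new_seq, start, start + len(replacement) - 1


def _generate(spec: CohortSpec, implants: Sequence[MotifImplant]) -> Cohort:
    tree = read_newick(spec.newick)
    ancestor = make_ancestor(spec.length, spec.gc, spec.seed)
    chars = list(ancestor)
    for imp in implants:
        s, e = imp.interval
        chars[s - 1 : e] = imp.word.upper().replace("U", "T")
    ancestor = "".join(chars)
    protected = [(*imp.interval, imp.protection) for imp in implants]
    leaves = evolve(
        tree, ancestor, EvolveParams(rate=spec.rate, seed=spec.seed + 1), protected
    )

    truth: dict[str, dict] = {
        sp: {"features": {}} for sp in leaves
    }
    # lineage-specific replacement events (after evolution, before insertions)
    replaced: dict[str, list[tuple[int, int, str]]] = {sp: [] for sp in leaves}
    for imp in implants:
        if not imp.replacement_on:
            continue
        sp = imp.replacement_on
        if sp not in leaves:
            raise ValueError(f"replacement lineage {sp!r} not a leaf of the tree")
        new_seq, s, e = _apply_replacement(leaves[sp], imp)
        delta = (e - s + 1) - len(imp.word)
        leaves[sp] = new_seq
        replaced[sp].append((imp.position, delta, imp.name))
        truth[sp]["features"][imp.name] = {
            "status": "replaced",
            "start": s,
            "end": e,
        }
    # per-species realized status at (shift-adjusted) implant coordinates
    for sp, seq in leaves.items():
        for imp in implants:
            if imp.name in truth[sp]["features"]:
                continue  # replaced on this lineage
            shift = sum(d for pos, d, _ in replaced[sp] if pos < imp.position)
            s, e = imp.position + shift, imp.position + shift + len(imp.word) - 1
            realized = seq[s - 1 : e]
            status = "intact" if realized == imp.word else "degraded"
            truth[sp]["features"][imp.name] = {"status": status, "start": s, "end": e}

    # clade-restricted insertions
    seqs = dict(leaves)
    for ins in spec.insertion_implants:
        members = _clade_members(tree, ins.clade)
        adjusted = InsertionImplant(
            name=ins.name,
            clade=tuple(sorted(members)),
            element=ins.element,
            position=ins.position,
            orientation=ins.orientation,
            tsd_len=ins.tsd_len,
            tail_len=ins.tail_len,
        )
        seqs, ins_truth = implant_insertion(seqs, adjusted)
        for sp, entry in ins_truth.items():
            truth[sp]["features"][ins.name] = entry
            if entry["status"] == "present":
                delta = entry["length"]
                for fname, f in truth[sp]["features"].items():
                    if fname != ins.name and "start" in f and f["start"] >= ins.position:
                        f["start"] += delta
                        f["end"] += delta

    records = [
        SeqRecord(id=sp, residues=seqs[sp]) for sp in sorted(seqs)
    ]
    for sp in seqs:
        truth[sp]["sequence"] = seqs[sp]
    return Cohort(records=records, truth=truth)


def make_promoter_cohort(spec: CohortSpec) -> Cohort:
    """Promoter ortholog cohort: TF motif implants under protection."""
    return _generate(spec, spec.motif_implants)


def make_utr_cohort(spec: CohortSpec) -> Cohort:
    """3'-UTR ortholog cohort: seed-match word implants (plus any raw motifs).

    ``SeedImplant.ablate_on`` species have the implanted target word scrambled
    (reverse-complemented in place) after evolution, giving cohorts with
    known absent-site species for conservation tests.
    """
    implants = list(spec.motif_implants) + [s.to_motif() for s in spec.seed_implants]
    cohort = _generate(spec, implants)
    for simp in spec.seed_implants:
        motif = simp.to_motif()
        s, e = motif.interval
        for sp in simp.ablate_on:
            rec = cohort.record(sp)
            seq = rec.residues
            feature = cohort.truth[sp]["features"][motif.name]
            fs, fe = feature["start"], feature["end"]
            ablated = seq[: fs - 1] + revcomp(seq[fs - 1 : fe]) + seq[fe:]
            idx = cohort.records.index(rec)
            cohort.records[idx] = SeqRecord(id=sp, residues=ablated)
            feature["status"] = "ablated"
            cohort.truth[sp]["sequence"] = ablated
    return cohort
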