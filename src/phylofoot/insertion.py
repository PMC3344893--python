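"""Retroelement insertion detection and phylogenetic gain placement.

A clade-specific insertion is found by global pairwise alignment of a
carrier UTR against an insertion-free reference; the L1-pathway hallmarks
are then read directly off the carrier: a target-site duplication (TSD, a
short exact direct repeat created at integration), a terminal homopolymer
(poly-A tail in sense orientation, poly-T head when the element integrated
antisense), and identity/orientation by local alignment against an element
consensus library.  The gain is placed on a species tree by single-gain
Dollo parsimony: retroelement insertions are effectively homoplasy-free, so
one gain on the stem of the MRCA of carriers plus a minimal set of losses
explains any presence/absence pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
from Bio import Align

from .seqio import SeqRecord, revcomp

__all__ = [
    "AlignParams",
    "PairwiseAlignment",
    "Tsd",
    "PolyTail",
    "ElementCall",
    "InsertionEvent",
    "GainPlacement",
    "align_pair",
    "find_insertions",
    "detect_tsd",
    "detect_polya",
    "classify_element",
    "place_gain",
    "render_gain_newick",
]


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring; a gap of length L scores open + (L-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class GapBlock:
    row: int  # 0 = first sequence, 1 = second
    start: int  # 1-based alignment column of the first gap position
    length: int


@dataclass(frozen=True)
class PairwiseAlignment:
    a_aligned: str
    b_aligned: str
    score: float

    @property
    def gap_blocks(self) -> tuple[GapBlock, ...]:
        blocks = []
        for row, seq in ((0, self.a_aligned), (1, self.b_aligned)):
            j = 0
            while j < len(seq):
                if seq[j] == "-":
                    k = j
                    while k < len(seq) and seq[k] == "-":
                        k += 1
                    blocks.append(GapBlock(row, j + 1, k - j))
                    j = k
                else:
                    j += 1
        return tuple(blocks)


def _aligner(params: AlignParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_pair(
    a: SeqRecord | str, b: SeqRecord | str, params: AlignParams = DEFAULT_PARAMS
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps; deterministic for fixed input.

    Among co-optimal alignments the aligner's canonical first traceback is
    returned, so repeated runs give byte-identical output.
    """
    sa = a.residues if isinstance(a, SeqRecord) else a.upper().replace("U", "T")
    sb = b.residues if isinstance(b, SeqRecord) else b.upper().replace("U", "T")
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(params, "global").align(sa, sb)
    best = aln[0]
    return PairwiseAlignment(a_aligned=best[0], b_aligned=best[1], score=aln.score)


@dataclass(frozen=True)
class InsertionInterval:
    """Carrier-coordinate insertion: 1-based position of the first inserted base."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def find_insertions(
    carrier: SeqRecord | str,
    reference: SeqRecord | str,
    min_len: int = 50,
    params: AlignParams = DEFAULT_PARAMS,
    merge_distance: int = 20,
) -> list[InsertionInterval]:
    """Carrier segments absent from the reference (gap blocks in the reference row).

    Gap blocks separated by at most ``merge_distance`` aligned carrier bases
    are merged into one interval first — an aligner will occasionally stitch
    a few spurious matches into the middle of a long insertion.  Intervals
    are then canonicalised by sliding each insertion as far 3' as the
    flanking repeat allows, so an insertion flanked by a TSD is reported with
    the duplication's second copy at its 3' terminus (the inside-edge
    convention used by ``detect_tsd``).
    """
    sc = carrier.residues if isinstance(carrier, SeqRecord) else carrier.upper()
    sr = reference.residues if isinstance(reference, SeqRecord) else reference.upper()
    aln = align_pair(sc, sr, params)
    blocks: list[tuple[int, int]] = []  # (start, end) in carrier coords, any length
    carrier_pos = 0  # 1-based position of last consumed carrier base
    j = 0
    ca, ra = aln.a_aligned, aln.b_aligned
    while j < len(ca):
        if ra[j] == "-" and ca[j] != "-":
            k = j
            while k < len(ca) and ra[k] == "-":
                k += 1
            length = k - j
            blocks.append((carrier_pos + 1, carrier_pos + length))
            carrier_pos += length
            j = k
        else:
            if ca[j] != "-":
                carrier_pos += 1
            j += 1
    merged: list[list[int]] = []
    for s, e in blocks:
        if merged and s - merged[-1][1] - 1 <= merge_distance:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    intervals = [
        InsertionInterval(s, e - s + 1) for s, e in merged if e - s + 1 >= min_len
    ]
    # canonicalise: slide right while the base before the insert equals its last base
    out = []
    n = len(sc)
    for iv in intervals:
        s, L = iv.start, iv.length
        while s + L - 1 < n and sc[s - 1] == sc[s + L - 1]:
            s += 1
        out.append(InsertionInterval(s, L))
    return out


@dataclass(frozen=True)
class Tsd:
    length: int
    left: str
    right: str
    mismatches: int


def detect_tsd(
    carrier: SeqRecord | str,
    interval: InsertionInterval,
    min_len: int = 8,
    max_len: int = 30,
    max_mismatch: int = 0,
    boundary_slack: int = 0,
) -> Optional[Tsd]:
    """Longest direct repeat flanking an insertion (inside-edge convention).

    Compares the k-mer ending immediately 5' of the insertion with the k-mer
    forming the 3' terminus of the inserted segment, for k from ``max_len``
    down to ``min_len``; the longest k within ``max_mismatch`` differences
    wins.  ``boundary_slack`` lets each comparison end up to that many bases
    away from the nominal boundary, for intervals inferred by alignment whose
    breakpoints are imprecise (flanking-repeat ambiguity); offsets closest to
    the nominal boundary are preferred.  Returns None when no k qualifies or
    the interval touches the sequence start (no 5' flank to compare).
    """
    seq = carrier.residues if isinstance(carrier, SeqRecord) else carrier.upper()
    s0 = interval.start - 1  # 0-based index of first inserted base
    if s0 <= 0 or interval.end > len(seq) + boundary_slack:
        return None
    offsets = sorted(range(-boundary_slack, boundary_slack + 1), key=lambda d: (abs(d), d))
    for k in range(min(max_len, s0 + boundary_slack, interval.length + boundary_slack), min_len - 1, -1):
        for dl in offsets:
            le = s0 + dl  # exclusive end of the left copy (0-based slice bound)
            if le - k < 0 or le > len(seq):
                continue
            left = seq[le - k : le]
            for dr in offsets:
                re = s0 + interval.length + dr
                if re > len(seq) or re - k < le:
                    continue
                right = seq[re - k : re]
                mm = sum(1 for x, y in zip(left, right) if x != y)
                if mm <= max_mismatch:
                    return Tsd(length=k, left=left, right=right, mismatches=mm)
    return None


@dataclass(frozen=True)
class PolyTail:
    side: str  # 'A-tail' (3' poly-A, sense) or 'T-head' (5' poly-T, antisense)
    length: int


def detect_polya(insert: str, min_run: int = 8) -> Optional[PolyTail]:
    """Terminal homopolymer: 3' A-run (sense) or 5' T-run (antisense signature).

    If both termini qualify the longer run wins (A-tail on a tie).
    """
    seq = insert.upper().replace("U", "T")
    if not seq:
        raise ValueError("insert must be non-empty")
    a_run = len(seq) - len(seq.rstrip("A"))
    t_run = len(seq) - len(seq.lstrip("T"))
    best: Optional[PolyTail] = None
    if a_run >= min_run:
        best = PolyTail("A-tail", a_run)
    if t_run >= min_run and (best is None or t_run > best.length):
        best = PolyTail("T-head", t_run)
    return best


@dataclass(frozen=True)
class ElementCall:
    name: str
    orientation: str  # 'sense' | 'antisense'
    score: float


def classify_element(
    insert: str,
    consensus_records: Sequence[SeqRecord],
    min_score: float = 50.0,
    params: AlignParams = DEFAULT_PARAMS,
) -> Optional[ElementCall]:
    """Best local-alignment match of an insert against an element library.

    Each consensus is scored in both orientations; antisense is called when
    the reverse complement wins (sense on ties).  Returns None (unclassified)
    when the best score is below ``min_score``.
    """
    if not consensus_records:
        raise ValueError("element consensus library is empty")
    seq = insert.upper().replace("U", "T")
    aligner = _aligner(params, "local")
    best: Optional[ElementCall] = None
    for rec in consensus_records:
        for orientation, cons in (
            ("sense", rec.residues),
            ("antisense", revcomp(rec.residues)),
        ):
            score = aligner.score(seq, cons)
            if best is None or score > best.score:
                best = ElementCall(rec.id, orientation, score)
    assert best is not None
    return best if best.score >= min_score else None


@dataclass
class InsertionEvent:
    """One characterised insertion in one carrier species."""

    species: str
    interval: InsertionInterval
    residues: str
    tsd: Optional[Tsd] = None
    polya: Optional[PolyTail] = None
    element: Optional[ElementCall] = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "position": self.interval.start,
            "length": self.interval.length,
            "residues": self.residues,
            "tsd": None
            if self.tsd is None
            else {
                "length": self.tsd.length,
                "left": self.tsd.left,
                "right": self.tsd.right,
                "mismatches": self.tsd.mismatches,
            },
            "polya": None
            if self.polya is None
            else {"side": self.polya.side, "length": self.polya.length},
            "element": None
            if self.element is None
            else {
                "name": self.element.name,
                "orientation": self.element.orientation,
                "score": self.element.score,
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class GainPlacement:
    """Single-gain Dollo placement: gain on the MRCA stem, losses inside."""

    gain_clade: frozenset[str]
    loss_clades: tuple[frozenset[str], ...]


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def place_gain(tree: dendropy.Tree, presence: dict[str, bool]) -> GainPlacement:
    """Dollo placement of a presence/absence character on a rooted tree.

    The gain edge is the stem of the MRCA of all present species; losses are
    the deepest edges within that clade whose entire subtree is absent.
    Raises ``ValueError`` when no species is present or the presence matrix
    does not cover the tree's leaves exactly.
    """
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if set(presence) != labels:
        missing = sorted(labels - set(presence))
        extra = sorted(set(presence) - labels)
        raise ValueError(
            f"presence matrix mismatch: missing {missing}, unknown {extra}"
        )
    present = {sp for sp, p in presence.items() if p}
    if not present:
        raise ValueError("at least one species must carry the feature")
    if len(present) == 1:
        (sp,) = present
        mrca = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == sp
        )
    else:
        mrca = tree.mrca(taxa=[l.taxon for l in tree.leaf_node_iter() if l.taxon.label in present])
    losses: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            below = _leaf_labels(child)
            if below.isdisjoint(present):
                losses.append(below)
            elif not below <= present:
                walk(child)

    walk(mrca)
    return GainPlacement(
        gain_clade=_leaf_labels(mrca),
        loss_clades=tuple(sorted(losses, key=lambda s: sorted(s))),
    )


def render_gain_newick(tree: dendropy.Tree, placement: GainPlacement) -> str:
    """Newick with the gain and loss edges labelled on their subtending nodes."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        below = _leaf_labels(node) if not node.is_leaf() else frozenset(
            [node.taxon.label]
        )
        tag = ""
        if below == placement.gain_clade:
            tag = "GAIN"
        elif below in placement.loss_clades:
            tag = "LOSS"
        if tag:
            if node.is_leaf():
                node.taxon.label = f"{node.taxon.label}[{tag}]"
            else:
                node.label = tag
    return clone.as_string(schema="newick").strip()
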