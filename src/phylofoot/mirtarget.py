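"""miRNA seed-match analysis in 3'-UTR ortholog cohorts.

Seed-match classes follow the canonical hierarchy used in target prediction:

* 8mer     — target matches the reverse complement of miRNA positions 2-8,
             followed by an adenine opposite miRNA position 1;
* 7mer-m8  — match to positions 2-8 only;
* 7mer-A1  — match to positions 2-7 plus the adenine.

The position-1 adenine is required as a literal A in the target regardless
of the identity of miRNA position 1.  Classification is strict Watson-Crick:
G:U wobbles never rescue a seed match (they are only rendered in duplex
diagrams).  UTR coordinates are 1-based with position 1 the first nucleotide
after the stop codon; a site's position is the 5'-most nucleotide of the
target word.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .seqio import SeqRecord, revcomp

__all__ = [
    "SITE_CLASSES",
    "Mirna",
    "UtrSite",
    "DuplexPairing",
    "SeedFamily",
    "SiteConservation",
    "seed_targets",
    "classify_site",
    "scan_utr",
    "duplex",
    "site_conservation",
    "seed_family",
]

#: Site classes in priority order (strongest first).
SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1")

_RNA = set("ACGU")


@dataclass(frozen=True)
class Mirna:
    """A mature miRNA, 5'->3', RNA alphabet, length >= 8."""

    name: str
    mature: str

    def __post_init__(self) -> None:
        seq = self.mature.upper().replace("T", "U")
        object.__setattr__(self, "mature", seq)
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.name!r}: mature length must be >= 8")
        bad = set(seq) - _RNA
        if bad:
            raise ValueError(f"miRNA {self.name!r}: invalid residues {sorted(bad)}")

    @property
    def seed(self) -> str:
        """Positions 2-7, the seed proper."""
        return self.mature[1:7]

    @classmethod
    def from_record(cls, rec: SeqRecord) -> "Mirna":
        return cls(name=rec.id, mature=rec.display_residues.replace("T", "U"))


@dataclass(frozen=True)
class UtrSite:
    """A classified seed-match site in a UTR (position of the 5'-most base)."""

    mirna: str
    position: int
    site_class: str
    target_word: str

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")
        want = 8 if self.site_class == "8mer" else 7
        if len(self.target_word) != want:
            raise ValueError(
                f"{self.site_class} target word must be {want} nt, got {self.target_word!r}"
            )


@dataclass(frozen=True)
class DuplexPairing:
    """Antiparallel miRNA:target pairing with per-position pair types."""

    mirna: str
    mirna_seq: str  # 5'->3' RNA
    target_seq: str  # 5'->3' as given (DNA or RNA), window only
    pairs: tuple[str, ...]  # per miRNA position: 'WC' | 'GU' | 'mismatch'
    seed_paired: int  # paired count over miRNA positions 2-8
    aux_paired: int  # paired count over positions 9..end

    def render(self) -> str:
        """Fixed-width duplex diagram, target on top (3'->5' under the miRNA)."""
        tgt = self.target_seq[::-1]  # 3'->5' left to right under miRNA 5'->3'
        bonds = "".join(
            "|" if p == "WC" else (":" if p == "GU" else " ") for p in self.pairs
        )
        return (
            f"target 3' {tgt} 5'\n"
            f"          {bonds}\n"
            f"{self.mirna:>6} 5' {self.mirna_seq} 3'"
        )


@dataclass(frozen=True)
class SeedFamily:
    """miRNAs sharing positions 2-7 exactly (hence the same 7mer-A1 target)."""

    seed: str
    members: tuple[str, ...]


def seed_targets(mirna: Mirna, alphabet: str = "dna") -> dict[str, str]:
    """Target words for each site class, 5'->3' in the requested alphabet."""
    if alphabet not in ("dna", "rna"):
        raise ValueError("alphabet must be 'dna' or 'rna'")
    m = mirna.mature.replace("U", "T")  # work in DNA space
    rc28 = revcomp(m[1:8])  # reverse complement of positions 2-8
    rc27 = revcomp(m[1:7])
    words = {"8mer": rc28 + "A", "7mer-m8": rc28, "7mer-A1": rc27 + "A"}
    if alphabet == "rna":
        words = {k: v.replace("T", "U") for k, v in words.items()}
    return words


def classify_site(mirna: Mirna, utr: SeqRecord | str, pos: int) -> Optional[str]:
    """Highest-priority site class whose target word starts at ``pos``, or None."""
    seq = utr.residues if isinstance(utr, SeqRecord) else utr.upper().replace("U", "T")
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} out of range 1..{len(seq)}")
    words = seed_targets(mirna, "dna")
    for cls in SITE_CLASSES:
        w = words[cls]
        if seq[pos - 1 : pos - 1 + len(w)] == w:
            return cls
    return None


def scan_utr(utr: SeqRecord | str, mirna: Mirna) -> list[UtrSite]:
    """All seed-match sites of any class, sorted by position.

    At each start position only the highest class is reported, and a site
    whose target word lies entirely inside a higher-class site's word (the
    7mer-A1 that is every 8mer's suffix) is the same physical site and is
    suppressed.
    """
    seq = utr.residues if isinstance(utr, SeqRecord) else utr.upper().replace("U", "T")
    if not seq:
        raise ValueError("UTR sequence is empty")
    words = seed_targets(mirna, "dna")
    rank = {c: i for i, c in enumerate(SITE_CLASSES)}
    sites: list[UtrSite] = []
    for pos in range(1, len(seq) + 1):
        cls = classify_site(mirna, seq, pos)
        if cls is not None:
            sites.append(UtrSite(mirna.name, pos, cls, words[cls]))
    return [
        s
        for s in sites
        if not any(
            rank[o.site_class] < rank[s.site_class]
            and o.position <= s.position
            and s.position + len(s.target_word) <= o.position + len(o.target_word)
            for o in sites
        )
    ]


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}  # target in DNA space: U rendered as T


def duplex(mirna: Mirna, utr_window: str, allow_gu: bool = True) -> DuplexPairing:
    """Pair a miRNA against a target window of equal length, antiparallel.

    miRNA position i (5'->3') pairs with window position L+1-i.  G:U wobbles
    are typed 'GU' and count as paired only when ``allow_gu``; classification
    elsewhere in this module never uses them.
    """
    win_dna = utr_window.upper().replace("U", "T")
    m = mirna.mature.replace("U", "T")
    if len(win_dna) != len(m):
        raise ValueError(
            f"window length {len(win_dna)} != mature length {len(m)}"
        )
    pairs: list[str] = []
    for i, mi in enumerate(m):
        tj = win_dna[len(m) - 1 - i]
        if (mi, tj) in _WC:
            pairs.append("WC")
        elif (mi, tj) in _GU:
            pairs.append("GU" if allow_gu else "mismatch")
        else:
            pairs.append("mismatch")
    paired = [p != "mismatch" for p in pairs]
    seed_paired = sum(paired[1:8])
    aux_paired = sum(paired[8:])
    return DuplexPairing(
        mirna=mirna.name,
        mirna_seq=mirna.mature,
        target_seq=utr_window.upper(),
        pairs=tuple(pairs),
        seed_paired=seed_paired,
        aux_paired=aux_paired,
    )


@dataclass
class SiteConservation:
    """Cross-species summary for one miRNA's reference site."""

    mirna: str
    reference_id: str
    reference_site: Optional[UtrSite]
    best_class: dict[str, Optional[str]]  # per species, anywhere in the UTR
    has_ref_site: dict[str, bool]
    compensatory: dict[str, bool]
    warning: str = ""

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in SITE_CLASSES}
        out["none"] = 0
        for cls in self.best_class.values():
            out[cls if cls else "none"] += 1
        out["with_ref_site"] = sum(self.has_ref_site.values())
        out["compensatory"] = sum(self.compensatory.values())
        return out

    def to_json(self) -> str:
        ref = None
        if self.reference_site is not None:
            ref = {
                "position": self.reference_site.position,
                "class": self.reference_site.site_class,
                "word": self.reference_site.target_word,
            }
        return json.dumps(
            {
                "mirna": self.mirna,
                "reference": self.reference_id,
                "reference_site": ref,
                "best_class": self.best_class,
                "has_ref_site": self.has_ref_site,
                "compensatory": self.compensatory,
                "counts": self.counts,
                "warning": self.warning,
            },
            indent=2,
        )


def site_conservation(
    cohort: Sequence[SeqRecord],
    mirna: Mirna,
    reference_id: str = "",
    compensatory_window: tuple[int, int] = (0, 160),
    position_tolerance: int = 10,
) -> SiteConservation:
    """Best site class per species plus compensatory-site calls.

    The reference species' strongest (then 5'-most) site anchors homology: a
    species "has" the reference site when a site of any class starts within
    ``position_tolerance`` of the reference position (cohorts are unaligned;
    the simulator keeps coordinates colinear).  Species lacking it are
    re-searched within ``compensatory_window`` nt 3' of the reference
    position and flagged compensatory when any class of site is found there.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    ref_id = reference_id or cohort[0].id
    by_id = {rec.id: rec for rec in cohort}
    if ref_id not in by_id:
        raise ValueError(f"reference species {ref_id!r} not in cohort")

    sites_by_species = {rec.id: scan_utr(rec, mirna) for rec in cohort}
    rank = {c: i for i, c in enumerate(SITE_CLASSES)}

    ref_sites = sites_by_species[ref_id]
    warning = ""
    ref_site: Optional[UtrSite] = None
    if ref_sites:
        ref_site = min(ref_sites, key=lambda s: (rank[s.site_class], s.position))
    else:
        warning = f"reference species {ref_id!r} has no seed-match site"

    best_class: dict[str, Optional[str]] = {}
    has_ref: dict[str, bool] = {}
    compensatory: dict[str, bool] = {}
    lo, hi = compensatory_window
    for rec in cohort:
        sites = sites_by_species[rec.id]
        best_class[rec.id] = (
            min((s.site_class for s in sites), key=lambda c: rank[c]) if sites else None
        )
        if ref_site is None:
            has_ref[rec.id] = False
            compensatory[rec.id] = False
            continue
        has_ref[rec.id] = any(
            abs(s.position - ref_site.position) <= position_tolerance for s in sites
        )
        if has_ref[rec.id]:
            compensatory[rec.id] = False
        else:
            start = ref_site.position + lo
            stop = ref_site.position + hi
            compensatory[rec.id] = any(start <= s.position <= stop for s in sites)
    return SiteConservation(
        mirna=mirna.name,
        reference_id=ref_id,
        reference_site=ref_site,
        best_class=best_class,
        has_ref_site=has_ref,
        compensatory=compensatory,
        warning=warning,
    )


def seed_family(mirnas: Sequence[Mirna]) -> list[SeedFamily]:
    """Group miRNAs by their exact positions 2-7 word; singletons allowed."""
    if not mirnas:
        raise ValueError("at least one miRNA required")
    groups: dict[str, list[str]] = {}
    for m in mirnas:
        groups.setdefault(m.seed, []).append(m.name)
    return [
        SeedFamily(seed=s, members=tuple(names)) for s, names in sorted(groups.items())
    ]
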