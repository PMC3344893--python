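"""Degenerate-consensus motif scanning and local duplication detection.

Scanning is plain IUPAC set matching — no position weight matrices, no
background model.  The one tolerance rule implemented is the NRF1 half-site
rule: the near-palindromic consensus yGCGCAnGCGCr binds as a homodimer on
two GCGC half-sites, and a single mismatch is tolerated provided it falls
inside one (and only one) GCGC tetramer; the degenerate flanking positions
must always match their base sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seqio import IUPAC_SETS, SeqRecord, revcomp, to_bed_interval

__all__ = [
    "MotifPattern",
    "Nrf1Rule",
    "MotifHit",
    "DuplicationBlock",
    "DEFAULT_REGISTRY",
    "NRF1_RULE",
    "iupac_match",
    "scan",
    "scan_nrf1",
    "nonoverlapping_hits",
    "find_duplications",
    "hits_to_tsv",
    "hits_to_bed",
]


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate consensus, e.g. SOX11 CAACAAAGA."""

    name: str
    consensus: str
    source: str = ""

    def __post_init__(self) -> None:
        cons = self.consensus.upper().replace("U", "T")
        object.__setattr__(self, "consensus", cons)
        if not cons:
            raise ValueError("motif consensus must be non-empty")
        bad = set(cons) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class Nrf1Rule:
    """NRF1 consensus with its half-site mismatch budget.

    ``half_sites`` are 1-based closed spans of the two GCGC tetramers within
    the consensus; at most ``mismatch_budget`` mismatches are tolerated, all
    within a single half-site.
    """

    consensus: str = "YGCGCANGCGCR"
    half_sites: tuple[tuple[int, int], tuple[int, int]] = ((2, 5), (8, 11))
    mismatch_budget: int = 1

    def __post_init__(self) -> None:
        (a1, a2), (b1, b2) = self.half_sites
        if a2 >= b1:
            raise ValueError("half-sites must be disjoint and ordered")
        for s, e in self.half_sites:
            if self.consensus[s - 1 : e] != "GCGC":
                raise ValueError("each half-site span must read GCGC")

    @property
    def half_site_positions(self) -> frozenset[int]:
        out = set()
        for s, e in self.half_sites:
            out.update(range(s, e + 1))
        return frozenset(out)


#: Motif registry used by the promoter pipeline.  The Sp1 entry is the
#: canonical GC-box core (Sp1 consensus definitions vary; override in config
#: for a different one).
DEFAULT_REGISTRY: dict[str, MotifPattern] = {
    "SOX11": MotifPattern("SOX11", "CAACAAAGA", source="SOX-C family consensus"),
    "NRF1": MotifPattern("NRF1", "YGCGCANGCGCR", source="NRF1 palindromic consensus"),
    "SP1": MotifPattern("SP1", "GGGCGG", source="GC-box core"),
}

NRF1_RULE = Nrf1Rule()


@dataclass(frozen=True)
class MotifHit:
    """A located motif match, 1-based closed coordinates on the + strand."""

    motif_name: str
    start: int
    end: int
    strand: str
    matched: str
    mismatches: tuple[int, ...] = ()
    hit_class: str = "perfect"
    both_strands: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.hit_class not in ("perfect", "tolerated"):
            raise ValueError("hit_class must be 'perfect' or 'tolerated'")


@dataclass(frozen=True)
class DuplicationBlock:
    """A maximal pair of exact repeated substrings within one sequence."""

    pos_a: int
    pos_b: int
    length: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not self.pos_a < self.pos_b:
            raise ValueError("pos_a must precede pos_b")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must lie in (0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return self.pos_a, self.pos_b + self.length - 1

    @property
    def offset(self) -> int:
        return self.pos_b - self.pos_a


def iupac_match(pattern: MotifPattern | str, window: str) -> tuple[bool, tuple[int, ...]]:
    """Match a window against an IUPAC consensus position by position.

    Returns ``(is_match, mismatch_positions)`` with 1-based positions.  An N
    (or other degeneracy code) in the *window* only matches a pattern
    position whose base set contains the window code's full set — so N in a
    scanned sequence never satisfies a non-N pattern position.
    """
    cons = pattern.consensus if isinstance(pattern, MotifPattern) else pattern.upper().replace("U", "T")
    win = window.upper().replace("U", "T")
    if len(win) != len(cons):
        raise ValueError(
            f"window length {len(win)} != consensus length {len(cons)}"
        )
    mismatches = []
    for i, (p, w) in enumerate(zip(cons, win), start=1):
        try:
            wset = IUPAC_SETS[w]
        except KeyError:
            raise ValueError(f"non-IUPAC character in window: {w!r}") from None
        if not wset <= IUPAC_SETS[p]:
            mismatches.append(i)
    return (not mismatches), tuple(mismatches)


def _dedupe_palindromic(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse +/− hits occupying the same span to a single + hit."""
    by_span: dict[tuple[int, int], list[MotifHit]] = {}
    for h in hits:
        by_span.setdefault((h.start, h.end), []).append(h)
    out = []
    for span in sorted(by_span):
        group = by_span[span]
        if len(group) == 1:
            out.append(group[0])
        else:
            plus = next(h for h in group if h.strand == "+")
            out.append(
                MotifHit(
                    motif_name=plus.motif_name,
                    start=plus.start,
                    end=plus.end,
                    strand="+",
                    matched=plus.matched,
                    mismatches=plus.mismatches,
                    hit_class=plus.hit_class,
                    both_strands=True,
                )
            )
    return out


def _residues(record: SeqRecord | str) -> str:
    if isinstance(record, SeqRecord):
        return record.residues
    return record.upper().replace("U", "T")


def scan(
    record: SeqRecord | str,
    pattern: MotifPattern,
    strands: str = "both",
) -> list[MotifHit]:
    """Exact IUPAC scan of one sequence; hits sorted by start position.

    Minus-strand hits carry plus-strand coordinates with strand '-'.
    Palindromic sites matched on both strands at the same span are collapsed
    to one + hit flagged ``both_strands``.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    seq = _residues(record)
    m = len(pattern)
    hits: list[MotifHit] = []
    rc_cons = revcomp(pattern.consensus)
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if strands in ("+", "both"):
            ok, _ = iupac_match(pattern.consensus, window)
            if ok:
                hits.append(
                    MotifHit(pattern.name, i + 1, i + m, "+", window)
                )
        if strands in ("-", "both"):
            ok, _ = iupac_match(rc_cons, window)
            if ok:
                hits.append(
                    MotifHit(pattern.name, i + 1, i + m, "-", window)
                )
    if strands == "both":
        hits = _dedupe_palindromic(hits)
    return sorted(hits, key=lambda h: (h.start, h.strand))


def _nrf1_window(rule: Nrf1Rule, window: str) -> Optional[tuple[tuple[int, ...], str]]:
    """Evaluate one window under the half-site rule.

    Returns (mismatch_positions, hit_class) or None when the window fails.
    """
    half = rule.half_site_positions
    _, mism = iupac_match(rule.consensus, window)
    # degenerate flanking positions (outside the GCGC tetramers) are strict
    if any(pos not in half for pos in mism):
        return None
    if len(mism) > rule.mismatch_budget:
        return None
    if mism:
        sites_touched = {
            idx
            for idx, (s, e) in enumerate(rule.half_sites)
            for pos in mism
            if s <= pos <= e
        }
        if len(sites_touched) > 1:
            return None
    return mism, ("perfect" if not mism else "tolerated")


def scan_nrf1(
    record: SeqRecord | str,
    rule: Nrf1Rule = NRF1_RULE,
    strands: str = "both",
    name: str = "NRF1",
) -> list[MotifHit]:
    """Scan for NRF1 sites allowing one mismatch inside a single GCGC half-site."""
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    seq = _residues(record)
    m = len(rule.consensus)
    hits: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        if strands in ("+", "both"):
            res = _nrf1_window(rule, window)
            if res is not None:
                mism, cls = res
                hits.append(MotifHit(name, i + 1, i + m, "+", window, mism, cls))
        if strands in ("-", "both"):
            res = _nrf1_window(rule, revcomp(window))
            if res is not None:
                mism, cls = res
                hits.append(MotifHit(name, i + 1, i + m, "-", window, mism, cls))
    if strands == "both":
        hits = _dedupe_palindromic(hits)
    return sorted(hits, key=lambda h: (h.start, h.strand))


def nonoverlapping_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Reduce overlapping hits to distinct sites.

    A motif footprint can bind only one factor, so overlapping calls are the
    same site seen more than once (e.g. a perfect match shadowed by a
    tolerated call one step away).  Greedy selection: perfect class first,
    then leftmost; every survivor excludes later overlapping hits.
    """
    order = sorted(hits, key=lambda h: (h.hit_class != "perfect", h.start, h.strand))
    chosen: list[MotifHit] = []
    for h in order:
        if all(h.end < c.start or h.start > c.end for c in chosen):
            chosen.append(h)
    return sorted(chosen, key=lambda h: h.start)


def find_duplications(
    record: SeqRecord | str,
    min_len: int = 8,
    region: Optional[tuple[int, int]] = None,
) -> list[DuplicationBlock]:
    """All maximal pairs of exact repeated substrings of length >= min_len.

    For each offset d the matched run s[i..] == s[i+d..] is extended maximally
    left and right.  Periodic regions (tandem arrays, homopolymers) generate
    derivative pairs at multiples of the fundamental period; a block whose
    combined span is contained in the span of a smaller-offset block is
    suppressed, so e.g. a homopolymer run yields the single offset-1 block.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    seq = _residues(record)
    lo = 1
    if region is not None:
        lo, hi = region
        seq = seq[lo - 1 : hi]
    n = len(seq)
    raw: list[DuplicationBlock] = []
    for d in range(1, n):
        i = 0
        limit = n - d
        while i < limit:
            if seq[i] != seq[i + d]:
                i += 1
                continue
            j = i
            while j < limit and seq[j] == seq[j + d]:
                j += 1
            run = j - i
            if run >= min_len:
                raw.append(
                    DuplicationBlock(pos_a=i + lo, pos_b=i + d + lo, length=run)
                )
            i = j + 1
    raw.sort(key=lambda b: (b.offset, b.pos_a))
    kept: list[DuplicationBlock] = []
    for b in raw:
        s, e = b.span
        if any(k.span[0] <= s and e <= k.span[1] for k in kept):
            continue
        kept.append(b)
    return sorted(kept, key=lambda b: (b.pos_a, b.pos_b))


def hits_to_tsv(hits_by_record: dict[str, Sequence[MotifHit]]) -> str:
    """Render hits as TSV: record_id, motif, start, end, strand, class, mismatches."""
    lines = ["record_id\tmotif\tstart\tend\tstrand\tclass\tmismatches"]
    for rid in hits_by_record:
        for h in hits_by_record[rid]:
            mm = ",".join(map(str, h.mismatches))
            lines.append(
                f"{rid}\t{h.motif_name}\t{h.start}\t{h.end}\t{h.strand}\t{h.hit_class}\t{mm}"
            )
    return "\n".join(lines) + "\n"


def hits_to_bed(hits_by_record: dict[str, Sequence[MotifHit]]) -> str:
    """Render hits as BED6 (0-based half-open, score column = mismatch count)."""
    lines = []
    for rid in hits_by_record:
        for h in hits_by_record[rid]:
            b0, b1 = to_bed_interval(h.start, h.end)
            lines.append(
                f"{rid}\t{b0}\t{b1}\t{h.motif_name}\t{len(h.mismatches)}\t{h.strand}"
            )
    return "\n".join(lines) + ("\n" if lines else "")
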