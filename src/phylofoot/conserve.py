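"""Column- and motif-level conservation over ortholog alignments.

Conservation here is plain identity counting — no phylogeny weighting.  The
tier symbols mirror the usual footprinting annotation: '*' marks a column
where every row carries the same base (no gaps), '^' marks a column whose
majority base reaches ``high_threshold`` (default 0.89, which admits both a
17/19 and a 35/38 column as "~90% conserved") without being invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .motifscan import MotifPattern, Nrf1Rule, scan, scan_nrf1
from .seqio import GAP, Alignment, SeqRecord

__all__ = [
    "ColumnTier",
    "ConservationProfile",
    "MotifConservationReport",
    "column_tiers",
    "motif_presence",
    "project_coords",
    "column_to_ref",
    "render_annotated_alignment",
]

HIGH_THRESHOLD_DEFAULT = 0.89


@dataclass(frozen=True)
class ColumnTier:
    column: int  # 1-based
    majority: str
    fraction: float
    symbol: str  # '*', '^' or ' '


@dataclass
class ConservationProfile:
    n_rows: int
    columns: list[ColumnTier]

    @property
    def symbol_line(self) -> str:
        return "".join(c.symbol for c in self.columns)

    def to_tsv(self) -> str:
        lines = ["column\tmajority\tfraction\tsymbol"]
        for c in self.columns:
            lines.append(f"{c.column}\t{c.majority}\t{c.fraction:.4f}\t{c.symbol}")
        return "\n".join(lines) + "\n"


@dataclass
class MotifConservationReport:
    motif_name: str
    status_by_species: dict[str, str]  # exact | degenerate | absent
    reference_id: str = ""
    reference_hits: tuple[tuple[int, int], ...] = ()

    @property
    def counts(self) -> dict[str, int]:
        out = {"exact": 0, "degenerate": 0, "absent": 0}
        for status in self.status_by_species.values():
            out[status] += 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "motif": self.motif_name,
                "reference": self.reference_id,
                "reference_hits": [list(h) for h in self.reference_hits],
                "species": self.status_by_species,
                "counts": self.counts,
            },
            indent=2,
        )


def column_tiers(
    alignment: Alignment, high_threshold: float = HIGH_THRESHOLD_DEFAULT
) -> ConservationProfile:
    """Per-column majority residue, identity fraction and tier symbol.

    Gaps count in the denominator and block '*'.  Majority ties break
    alphabetically so output is deterministic.
    """
    n = len(alignment.rows)
    cols: list[ColumnTier] = []
    seqs = [seq for _, seq in alignment.rows]
    for j in range(alignment.length):
        column = [s[j] for s in seqs]
        counts: dict[str, int] = {}
        for ch in column:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            best = max(counts.values())
            majority = min(ch for ch, c in counts.items() if c == best)
            fraction = counts[majority] / n
        else:
            majority, fraction = GAP, 0.0
        has_gap = GAP in column
        if fraction == 1.0 and not has_gap:
            symbol = "*"
        elif fraction >= high_threshold:
            symbol = "^"
        else:
            symbol = " "
        cols.append(ColumnTier(j + 1, majority, fraction, symbol))
    return ConservationProfile(n_rows=n, columns=cols)


def motif_presence(
    records: Sequence[SeqRecord],
    pattern: MotifPattern,
    mode: str = "iupac",
    strands: str = "both",
    nrf1_rule: Optional[Nrf1Rule] = None,
) -> MotifConservationReport:
    """Classify each species as exact / degenerate / absent for one motif.

    ``exact`` means a perfect consensus match somewhere in the sequence.  In
    ``iupac`` mode with an ``nrf1_rule`` supplied, a species whose only hits
    are mismatch-tolerated is classed ``degenerate``; otherwise degenerate
    never applies.  ``exact`` mode requires a literal (non-degenerate) word
    match of the consensus string itself.
    """
    if not records:
        raise ValueError("cohort must be non-empty")
    if mode not in ("exact", "iupac"):
        raise ValueError("mode must be 'exact' or 'iupac'")
    status: dict[str, str] = {}
    for rec in records:
        if mode == "exact":
            word = pattern.consensus
            found = word in rec.residues or _revcomp_in(word, rec.residues, strands)
            status[rec.id] = "exact" if found else "absent"
            continue
        if nrf1_rule is not None:
            hits = scan_nrf1(rec, nrf1_rule, strands=strands, name=pattern.name)
            if any(h.hit_class == "perfect" for h in hits):
                status[rec.id] = "exact"
            elif hits:
                status[rec.id] = "degenerate"
            else:
                status[rec.id] = "absent"
        else:
            hits = scan(rec, pattern, strands=strands)
            status[rec.id] = "exact" if hits else "absent"
    return MotifConservationReport(motif_name=pattern.name, status_by_species=status)


def _revcomp_in(word: str, seq: str, strands: str) -> bool:
    from .seqio import revcomp

    if strands == "+":
        return False
    return revcomp(word) in seq


def project_coords(alignment: Alignment, ref_id: str, ref_pos: int) -> int:
    """Column (1-based) of the ref_pos-th non-gap character of the reference row."""
    row = alignment.row(ref_id)
    if ref_pos < 1:
        raise ValueError("reference position must be >= 1")
    seen = 0
    for j, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == ref_pos:
                return j
    raise ValueError(
        f"reference position {ref_pos} exceeds ungapped length {seen} of {ref_id!r}"
    )


def column_to_ref(alignment: Alignment, ref_id: str, column: int) -> int | str:
    """Reference position at an alignment column, or the string 'gap'."""
    row = alignment.row(ref_id)
    if not 1 <= column <= len(row):
        raise ValueError(f"column {column} out of range 1..{len(row)}")
    if row[column - 1] == GAP:
        return "gap"
    return len(row[:column].replace(GAP, ""))


def render_annotated_alignment(
    alignment: Alignment,
    profile: Optional[ConservationProfile] = None,
    high_threshold: float = HIGH_THRESHOLD_DEFAULT,
    block_width: int = 60,
) -> str:
    """Fixed-width alignment text with a conservation symbol line per block."""
    if profile is None:
        profile = column_tiers(alignment, high_threshold)
    name_w = max(len(rid) for rid, _ in alignment.rows) + 2
    out = []
    for start in range(0, alignment.length, block_width):
        stop = min(start + block_width, alignment.length)
        for rid, seq in alignment.rows:
            out.append(f"{rid:<{name_w}}{seq[start:stop]}")
        out.append(f"{'':<{name_w}}{profile.symbol_line[start:stop]}")
        out.append("")
    return "\n".join(out)
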