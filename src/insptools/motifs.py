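"""HAD-superfamily signature motif scanning and domain interval arithmetic.

HAD (haloacid dehalogenase-like) superfamily hydrolases carry four
signature motifs arranged around one catalytic cleft:

* Motif I   - DxD at the end of strand S1; the first aspartate is the
  catalytic nucleophile.  The canonical pattern is D-x-D; a degenerate
  D-x-x variant (second aspartate absent, as in the DES sequence of some
  ITPK4 N-terminal domains) is reported as a non-canonical hit.
* Motif II  - a conserved Ser/Thr at the end of S2 (single-residue anchor).
* Motif III - a conserved Lys on the loop or helix after S3 (anchor).
* Motif IV  - (G/S)(D/S)x{3,4}(D/E) on the loop after S4.

Motifs II and III are located structurally in real proteins; as pure
sequence anchors they are scanned with optional user context windows.

Cap classification: HAD domains are grouped by the insertions that shield
the catalytic cleft.  No beta-hairpin flap or cap insert at all puts a
domain in the capless C0 class; an insert between the two flap strands is
a C1 cap; an insert immediately after strand S3 is a C2 cap.

Residue coordinates are 1-based and inclusive throughout (crystallographic
convention), so a domain spanning residues 12-25 has 14 residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "MotifPattern",
    "MotifHit",
    "DomainAnnotation",
    "FlapAnnotation",
    "HAD_MOTIFS",
    "scan_motifs",
    "match_motif_at",
    "domain_length",
    "classify_cap",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """An ordered set of residue-class constraints with bounded gaps.

    ``elements`` is a tuple of entries ``(residue_classes, min_gap, max_gap)``
    where ``residue_classes`` is a string of allowed residues ("*" = any)
    and the gap bounds count wildcard residues *before* the element.
    """

    motif_id: str
    elements: tuple
    canonical: bool = True
    name: str = ""

    def __post_init__(self):
        if len(self.elements) < 2:
            raise ValueError("pattern must have at least 2 elements")
        for classes, lo, hi in self.elements:
            if lo < 0 or hi < lo:
                raise ValueError("gap bounds must be non-negative and ordered")
            if classes != "*" and not set(classes) <= AA_ALPHABET:
                raise ValueError(f"bad residue class {classes!r}")

    def to_regexes(self):
        """All fixed-gap regex realizations of the pattern."""
        def expand(parts, elements):
            if not elements:
                yield "".join(parts)
                return
            (classes, lo, hi), rest = elements[0], elements[1:]
            cls = "." if classes == "*" else f"[{classes}]"
            for gap in range(lo, hi + 1):
                yield from expand(parts + ["." * gap, cls], rest)

        return [re.compile(r) for r in expand([], list(self.elements))]


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is 1-based, match re-extractable."""

    motif_id: str
    start: int
    match: str
    canonical: bool


#: Canonical HAD signature motifs plus the degenerate Motif I variant.
HAD_MOTIFS = (
    MotifPattern("I", (("D", 0, 0), ("*", 0, 0), ("D", 0, 0)), True, "DxD"),
    MotifPattern("I", (("D", 0, 0), ("*", 0, 0), ("*", 0, 0)), False, "DxX"),
    MotifPattern("II", (("ST", 0, 0), ("*", 0, 0)), True, "S/T anchor"),
    MotifPattern("III", (("K", 0, 0), ("*", 0, 0)), True, "K anchor"),
    MotifPattern(
        "IV", (("GS", 0, 0), ("DS", 0, 0), ("DE", 3, 4)), True, "(G/S)(D/S)x3-4(D/E)"
    ),
)


def _validate_sequence(sequence: str) -> str:
    seq = str(sequence).strip().upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue letters: {sorted(bad)}")
    return seq


def scan_motifs(sequence, patterns=HAD_MOTIFS) -> list:
    """All motif matches in a protein sequence.

    ``sequence`` may be a plain string or a Biopython ``SeqRecord``.  For
    each pattern every distinct match start is reported once (lookahead
    scanning, so overlapping occurrences of the same pattern are all
    found); where a canonical pattern of a motif matches at a start, the
    degenerate variant of the same motif is suppressed at that start.
    Hits are sorted by start position, then motif id.
    """
    if hasattr(sequence, "seq"):
        sequence = str(sequence.seq)
    seq = _validate_sequence(sequence)
    hits = {}
    for pat in patterns:
        for rx in pat.to_regexes():
            for m in re.finditer(f"(?=({rx.pattern}))", seq):
                start = m.start() + 1
                key = (pat.motif_id, start)
                matched = m.group(1)
                prev = hits.get(key)
                if prev is None or (pat.canonical and not prev.canonical):
                    hits[key] = MotifHit(pat.motif_id, start, matched, pat.canonical)
    return sorted(hits.values(), key=lambda h: (h.start, h.motif_id))


def match_motif_at(sequence, pattern: MotifPattern, start: int) -> Optional[MotifHit]:
    """Anchored evaluation: does ``pattern`` match at 1-based ``start``?

    Used when a motif's location is fixed by structural alignment and the
    question is whether the sequence at that position fits the signature
    (e.g. ASSRKEE aligned to Motif IV fails the canonical pattern because
    its first residue is not G/S).
    """
    if hasattr(sequence, "seq"):
        sequence = str(sequence.seq)
    seq = _validate_sequence(sequence)
    if not 1 <= start <= len(seq):
        raise ValueError(f"start {start} outside sequence of length {len(seq)}")
    for rx in pattern.to_regexes():
        m = rx.match(seq, start - 1)
        if m:
            return MotifHit(pattern.motif_id, start, m.group(0), pattern.canonical)
    return None


@dataclass(frozen=True)
class DomainAnnotation:
    """A named residue interval, 1-based and inclusive at both ends."""

    name: str
    start: int
    end: int
    fold: str = ""

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError("interval must satisfy 1 <= start <= end")


def domain_length(d: DomainAnnotation) -> int:
    """Residue count of an inclusive interval: end - start + 1."""
    return d.end - d.start + 1


@dataclass(frozen=True)
class FlapAnnotation:
    """Secondary-structure annotation of the flap region after strand S1.

    ``structure`` is "beta-hairpin" or "loop"; ``insert_location`` is
    None, "between-flap-strands" or "after-S3".
    """

    interval: DomainAnnotation
    structure: str
    insert_location: Optional[str] = None

    def __post_init__(self):
        if self.structure not in ("beta-hairpin", "loop"):
            raise ValueError(f"unknown flap structure {self.structure!r}")
        if self.insert_location not in (None, "between-flap-strands", "after-S3"):
            raise ValueError(f"unknown insert location {self.insert_location!r}")
        if self.insert_location == "between-flap-strands" and (
            self.structure != "beta-hairpin"
        ):
            raise ValueError("an insert between flap strands requires a beta-hairpin")


def classify_cap(flap: FlapAnnotation) -> str:
    """HAD cap class from the flap annotation: C0 (capless), C1 or C2."""
    if flap is None:
        raise ValueError("missing flap annotation")
    if flap.insert_location == "between-flap-strands":
        return "C1"
    if flap.insert_location == "after-S3":
        return "C2"
    return "C0"
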