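"""Grammar for segmented poly(A) tail designs.

A segmented tail interleaves adenine tracts with short heteronucleotide
spacers, e.g. a 30-nt tract followed by eleven repeats of a single cytosine
plus a 15-nt tract.  Designs are written in one of three notations:

* compact   -- ``A30(CA15)11``: an ``A<n>`` head followed by repeated groups
  ``(<spacer>A<n>)<k>`` whose spacer is a literal base string;
* explicit  -- ``A30-GCATATGACT-A70``: dash-delimited alternation of ``A<n>``
  tracts and literal spacer sequences;
* raw       -- a plain nucleotide string, segmented into maximal adenine runs
  and maximal non-adenine runs.

Parsing is case-insensitive and treats U and T as interchangeable; segments
are stored in the DNA alphabet and converted on rendering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "ADENINE",
    "SPACER",
    "PatternError",
    "Segment",
    "TailDesign",
    "parse_pattern",
    "design_from_sequence",
    "total_length",
    "longest_adenine_run",
    "render_sequence",
    "design_report",
    "is_novel_design_compliant",
    "BUILTIN_PATTERNS",
    "get_builtin",
]

ADENINE = "adenine"
SPACER = "spacer"

_BASES = set("ACGT")

#: Tract/spacer length ranges of the novel segmented designs. Reference tails
#: (90-nt homopolymer, the 10-nt-spacer vaccine tail) intentionally violate
#: them, so violating designs parse fine and are merely flagged.
NOVEL_TRACT_RANGE = (10, 45)
NOVEL_SPACER_RANGE = (1, 6)


class PatternError(ValueError):
    """Raised when a tail pattern cannot be parsed."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Segment:
    """One tail segment: an adenine tract or a heteronucleotide spacer."""

    kind: str
    sequence: str  # stored in the DNA alphabet, uppercase

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        if self.kind not in (ADENINE, SPACER):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.sequence:
            raise ValueError("segment sequence must be non-empty")
        if set(self.sequence) - _BASES:
            bad = sorted(set(self.sequence) - _BASES)
            raise ValueError(f"invalid bases in segment: {bad}")
        if self.kind == ADENINE and set(self.sequence) != {"A"}:
            raise ValueError("adenine segment must contain only A")
        if self.kind == SPACER and set(self.sequence) == {"A"}:
            raise ValueError("spacer segment must contain at least one non-A base")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def adenine(cls, length: int) -> "Segment":
        if length < 1:
            raise ValueError("adenine tract length must be positive")
        return cls(ADENINE, "A" * length)

    @classmethod
    def spacer(cls, sequence: str) -> "Segment":
        return cls(SPACER, sequence)


@dataclass(frozen=True)
class TailDesign:
    """An ordered list of segments defining one poly(A) tail variant.

    Canonical form: adjacent segments of the same kind are merged, so a
    design never stores two spacers (or two adenine tracts) back to back.
    """

    name: str
    segments: tuple[Segment, ...]
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        if self.alphabet.upper() not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        object.__setattr__(self, "alphabet", self.alphabet.upper())
        segs = tuple(self.segments)
        if not any(s.kind == ADENINE for s in segs):
            raise ValueError("design must contain at least one adenine tract")
        for left, right in zip(segs, segs[1:]):
            if left.kind == right.kind:
                raise ValueError(
                    "adjacent segments of the same kind must be merged "
                    "(use parse_pattern / _merge_segments)"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def pattern(self) -> str:
        """Explicit dash-delimited notation for this design."""
        parts = []
        for s in self.segments:
            parts.append(f"A{s.length}" if s.kind == ADENINE else s.sequence)
        return "-".join(parts)

    def rename(self, name: str) -> "TailDesign":
        return TailDesign(name, self.segments, self.alphabet)


def _merge_segments(raw: Iterable[tuple[str, str]]) -> tuple[Segment, ...]:
    """Build canonical segments from (kind, sequence) pairs, merging runs."""
    merged: list[tuple[str, str]] = []
    for kind, seq in raw:
        if not seq:
            continue
        if merged and merged[-1][0] == kind:
            merged[-1] = (kind, merged[-1][1] + seq)
        else:
            merged.append((kind, seq))
    return tuple(Segment(kind, seq) for kind, seq in merged)


_COMPACT_HEAD = re.compile(r"A(\d+)")
_COMPACT_GROUP = re.compile(r"\(([ACGT]+?)A(\d+)\)(\d+)")


def _parse_compact(text: str) -> tuple[Segment, ...]:
    head = _COMPACT_HEAD.match(text)
    if head is None:
        raise PatternError(
            f"compact pattern must start with 'A<length>', got {text!r}"
        )
    raw: list[tuple[str, str]] = [(ADENINE, "A" * int(head.group(1)))]
    pos = head.end()
    while pos < len(text):
        group = _COMPACT_GROUP.match(text, pos)
        if group is None:
            raise PatternError(f"malformed group at {text[pos:]!r}")
        spacer, tract_len, repeats = group.group(1), int(group.group(2)), int(group.group(3))
        if repeats == 0:
            raise PatternError(f"zero repeat count in group {group.group(0)!r}")
        if set(spacer) == {"A"}:
            raise PatternError(
                f"group spacer {spacer!r} contains only adenines; "
                "extend the adjacent tract instead"
            )
        for _ in range(repeats):
            raw.append((SPACER, spacer))
            raw.append((ADENINE, "A" * tract_len))
        pos = group.end()
    return _merge_segments(raw)


_EXPLICIT_TRACT = re.compile(r"A(\d+)$")


def _parse_explicit(text: str) -> tuple[Segment, ...]:
    raw: list[tuple[str, str]] = []
    for token in text.split("-"):
        if not token:
            raise PatternError("empty token between dashes")
        tract = _EXPLICIT_TRACT.match(token)
        if tract is not None:
            raw.append((ADENINE, "A" * int(tract.group(1))))
        elif set(token) <= _BASES:
            if set(token) == {"A"}:  # literal all-A token is just a tract
                raw.append((ADENINE, token))
            else:
                raw.append((SPACER, token))
        else:
            raise PatternError(f"unrecognized token {token!r}")
    return _merge_segments(raw)


def design_from_sequence(sequence: str, name: str | None = None) -> TailDesign:
    """Segment a raw tail sequence into adenine runs and non-A spacer runs.

    Note: adenines *inside* a multi-base spacer (e.g. GCATATGACT) cannot be
    told apart from tract adenines in a raw sequence, so the recovered
    segmentation splits such spacers at their A's.  Sequence content is always
    preserved exactly.
    """
    seq = _normalize(sequence.strip())
    if not seq:
        raise PatternError("empty sequence")
    if set(seq) - _BASES:
        raise PatternError(f"invalid bases: {sorted(set(seq) - _BASES)}")
    raw = [
        (ADENINE if run.group(0)[0] == "A" else SPACER, run.group(0))
        for run in re.finditer(r"A+|[^A]+", seq)
    ]
    segments = _merge_segments(raw)
    return TailDesign(name or seq, segments)


def parse_pattern(pattern: str, name: str | None = None) -> TailDesign:
    """Parse a tail design from compact, explicit, or raw-sequence notation."""
    if pattern is None:
        raise PatternError("empty pattern")
    text = _normalize(re.sub(r"\s+", "", pattern))
    if not text:
        raise PatternError("empty pattern")
    if "-" in text:
        segments = _parse_explicit(text)
    elif any(ch.isdigit() for ch in text):
        segments = _parse_compact(text)
    else:
        return design_from_sequence(text, name=name or pattern.strip())
    return TailDesign(name or pattern.strip(), segments)


def total_length(design: TailDesign) -> int:
    """Total tail length in nucleotides (sum of segment lengths)."""
    return design.total_length


def render_sequence(
    design: TailDesign, alphabet: str = "DNA", strand: str = "sense"
) -> str:
    """Render the design's nucleotide sequence.

    Sense RNA substitutes U for T in spacers; antisense returns the reverse
    complement of the sense DNA strand (cloning inserts are DNA, so antisense
    RNA is rejected).
    """
    alphabet = alphabet.upper()
    strand = strand.lower()
    if alphabet not in ("DNA", "RNA"):
        raise ValueError(f"alphabet must be DNA or RNA, got {alphabet!r}")
    if strand not in ("sense", "antisense"):
        raise ValueError(f"strand must be sense or antisense, got {strand!r}")
    if strand == "antisense" and alphabet == "RNA":
        raise ValueError("antisense strand is only defined for the DNA alphabet")
    sense = "".join(s.sequence for s in design.segments)
    if strand == "antisense":
        return str(Seq(sense).reverse_complement())
    if alphabet == "RNA":
        return sense.replace("T", "U")
    return sense


def longest_adenine_run(design: TailDesign) -> int:
    """Length of the longest uninterrupted adenine run in the rendered tail.

    Computed on the rendered sequence, so adenines at spacer edges join
    adjacent tracts.  Motivated by the ~27-nt poly(A)-binding-protein
    footprint that sets the minimum useful tract length.
    """
    seq = render_sequence(design, "DNA", "sense")
    runs = re.findall(r"A+", seq)
    return max((len(r) for r in runs), default=0)


def is_novel_design_compliant(design: TailDesign) -> bool:
    """True iff all tracts are 10-45 nt and all spacers 1-6 nt."""
    t_lo, t_hi = NOVEL_TRACT_RANGE
    s_lo, s_hi = NOVEL_SPACER_RANGE
    for seg in design.segments:
        lo, hi = (t_lo, t_hi) if seg.kind == ADENINE else (s_lo, s_hi)
        if not lo <= seg.length <= hi:
            return False
    return True


def segment_table(design: TailDesign) -> pd.DataFrame:
    """Per-segment table with 0-based half-open coordinates on the sense strand."""
    rows = []
    pos = 0
    for i, seg in enumerate(design.segments):
        rows.append(
            {
                "index": i,
                "kind": seg.kind,
                "start": pos,
                "end": pos + seg.length,
                "length": seg.length,
                "sequence": seg.sequence,
            }
        )
        pos += seg.length
    return pd.DataFrame(rows)


def design_report(design: TailDesign) -> dict:
    """Summary counts characterizing one design (lengths, spacers, A-runs)."""
    adenine_segments = [s for s in design.segments if s.kind == ADENINE]
    spacers = [s for s in design.segments if s.kind == SPACER]
    first = design.segments[0]
    return {
        "name": design.name,
        "pattern": design.pattern,
        "total_length": design.total_length,
        "adenine_count": sum(s.length for s in adenine_segments),
        "n_adenine_segments": len(adenine_segments),
        "n_spacers": len(spacers),
        "spacer_nt_total": sum(s.length for s in spacers),
        "longest_adenine_run": longest_adenine_run(design),
        "has_5prime_A30": first.kind == ADENINE and first.length >= 30,
        "novel_design_compliant": is_novel_design_compliant(design),
        "segments": segment_table(design),
    }


#: Text-attested built-in designs.  R1: 90-nt homopolymer; R2: the
#: 30-A + 10-nt spacer (GCATATGACT) + 70-A vaccine-style tail; R3: 90-A with a
#: TCTAG terminal pentamer; R4/R5: 60-A + single G/C + 60-A; S8/S9/S13/S14:
#: segmented variants named in the text.  Other variants are figure-only and
#: can be supplied as arbitrary patterns.
BUILTIN_PATTERNS: Mapping[str, str] = {
    "R1": "A90",
    "R2": "A30-GCATATGACT-A70",
    "R3": "A90-TCTAG",
    "R4": "A60-G-A60",
    "R5": "A60-C-A60",
    "S8": "A30(CA15)6",
    "S9": "A10(CA10)11",
    "S13": "A20(CA20)5",
    "S14": "A30(CA15)11",
}


def get_builtin(name: str) -> TailDesign:
    key = name.upper()
    if key not in BUILTIN_PATTERNS:
        raise KeyError(
            f"unknown built-in design {name!r}; choose from {sorted(BUILTIN_PATTERNS)}"
        )
    return parse_pattern(BUILTIN_PATTERNS[key], name=key)
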