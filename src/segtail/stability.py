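"""Plasmid-instability QC for segmented poly(A) tails.

During plasmid amplification in E. coli, long adenine tracts recombine and
shorten.  Given the tail sequences observed in individual bacterial clones
(pre-excised from Sanger reads) and the reference design, each clone is
classified as

* ``intact``    -- identical to the rendered reference;
* ``shortened`` -- obtainable from the reference by deleting adenines only
  (every spacer present, in order; tracts may contract, possibly to zero);
* ``altered``   -- anything else: substitutions, spacer loss, insertions, or
  elongation.

The aggregate instability rate is the percentage of non-intact clones with a
95% Wilson score interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .grammar import ADENINE, TailDesign, render_sequence

__all__ = [
    "INTACT",
    "SHORTENED",
    "ALTERED",
    "CLASSES",
    "CloneRecord",
    "InstabilityResult",
    "classify_clone",
    "classify_clones",
    "instability_rate",
]

INTACT = "intact"
SHORTENED = "shortened"
ALTERED = "altered"
CLASSES = (INTACT, SHORTENED, ALTERED)

_DNA = set("ACGT")


@lru_cache(maxsize=256)
def _contraction_regex(design: TailDesign) -> re.Pattern[str]:
    """Regex matching every adenine-only contraction of the reference.

    Spacers appear as fixed literals (so spacers containing adenines, e.g.
    GCATATGACT, are anchored correctly via backtracking); each tract of
    length n becomes ``A{0,n}``.
    """
    parts = []
    for seg in design.segments:
        if seg.kind == ADENINE:
            parts.append(f"A{{0,{seg.length}}}")
        else:
            parts.append(re.escape(seg.sequence))
    return re.compile("".join(parts))


def classify_clone(observed_tail: str, reference: TailDesign) -> str:
    """Classify one observed clone tail against its reference design."""
    if observed_tail is None or not observed_tail.strip():
        raise ValueError("empty observed sequence")
    obs = observed_tail.strip().upper().replace("U", "T")
    bad = set(obs) - _DNA
    if bad:
        raise ValueError(f"observed tail contains invalid characters: {sorted(bad)}")
    ref = render_sequence(reference, "DNA", "sense")
    if obs == ref:
        return INTACT
    if len(obs) < len(ref) and _contraction_regex(reference).fullmatch(obs):
        return SHORTENED
    return ALTERED


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone: observed tail plus its reference design."""

    clone_id: str
    observed_tail: str
    reference: TailDesign

    def classify(self) -> str:
        return classify_clone(self.observed_tail, self.reference)


def classify_clones(
    clones: Iterable[tuple[str, str]], reference: TailDesign
) -> list[dict]:
    """Classify (clone_id, sequence) pairs; returns per-clone report rows."""
    ref_len = reference.total_length
    rows = []
    for clone_id, seq in clones:
        rows.append(
            {
                "clone_id": clone_id,
                "class": classify_clone(seq, reference),
                "observed_length": len(seq.strip()),
                "reference_length": ref_len,
            }
        )
    return rows


@dataclass(frozen=True)
class InstabilityResult:
    """Altered-clone percentage with a 95% Wilson confidence interval."""

    n_total: int
    n_altered: int
    rate: float  # percent, 0-100
    ci_low: float
    ci_high: float


def instability_rate(classifications: Sequence[str]) -> InstabilityResult:
    """Aggregate clone classes into the instability percentage.

    Both ``shortened`` and ``altered`` clones count as deviating from the
    original construct ("altered poly(A) tail length or sequence").
    """
    classes = list(classifications)
    if not classes:
        raise ValueError("empty classification list")
    unknown = set(classes) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    n_total = len(classes)
    n_altered = sum(1 for c in classes if c != INTACT)
    rate = 100.0 * n_altered / n_total
    lo, hi = proportion_confint(n_altered, n_total, alpha=0.05, method="wilson")
    return InstabilityResult(n_total, n_altered, rate, 100.0 * lo, 100.0 * hi)
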