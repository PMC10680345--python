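"""Base composition, A+T content, and strand-asymmetry skew statistics.

Skews follow the usual strand-asymmetry definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed over unambiguous bases only. For gene-class regions both the
coding-sense and the deposited plus-strand variants are kept, because the
two differ in sign for N-strand genes; the reported convention is
plus-strand for the whole genome and the control region and coding-sense
for PCG/rRNA/tRNA classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .mito_io import (
    CR_NAME,
    MitoGenome,
    extract_feature_sequence,
)

_CANONICAL_BASES = frozenset("ACGT")
_AMBIGUITY = frozenset("NRYSWKMBDHV")

REGIONS = ("whole", "PCGs", "rrnL", "rrnS", "tRNA", "CR")


@dataclass(frozen=True)
class BaseCounts:
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    ambiguous: int = 0

    @property
    def total_unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def total(self) -> int:
        return self.total_unambiguous + self.ambiguous

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a + other.a, self.c + other.c, self.g + other.g,
            self.t + other.t, self.ambiguous + other.ambiguous,
        )


def count_bases(sequence: str) -> BaseCounts:
    """Exact base tally; IUPAC ambiguity letters are counted separately,
    anything else raises with the offending position."""
    seq = sequence.upper()
    counts = {b: 0 for b in "ACGT"}
    ambiguous = 0
    for i, ch in enumerate(seq):
        if ch in _CANONICAL_BASES:
            counts[ch] += 1
        elif ch in _AMBIGUITY or ch == "U":
            if ch == "U":
                counts["T"] += 1
            else:
                ambiguous += 1
        else:
            raise ValueError(f"illegal character {ch!r} at position {i + 1}")
    return BaseCounts(counts["A"], counts["C"], counts["G"], counts["T"],
                      ambiguous)


def at_content(counts: BaseCounts) -> Optional[float]:
    """A+T percentage over unambiguous bases; None when undefined."""
    n = counts.total_unambiguous
    if n == 0:
        return None
    return 100.0 * (counts.a + counts.t) / n


def gc_content(counts: BaseCounts) -> Optional[float]:
    n = counts.total_unambiguous
    if n == 0:
        return None
    return 100.0 * (counts.g + counts.c) / n


def at_skew(counts: BaseCounts) -> Optional[float]:
    denom = counts.a + counts.t
    if denom == 0:
        return None
    return (counts.a - counts.t) / denom


def gc_skew(counts: BaseCounts) -> Optional[float]:
    denom = counts.g + counts.c
    if denom == 0:
        return None
    return (counts.g - counts.c) / denom


def codon_position_composition(
    pcg_sequences: Sequence[str],
) -> tuple:
    """A+T% at codon positions 1-3, pooling complete codons across PCGs.

    Each sequence is read in frame from its first base; trailing incomplete
    codons are excluded. Returns ``(None, None, None)`` for empty input.
    """
    pos_counts = [BaseCounts(), BaseCounts(), BaseCounts()]
    for seq in pcg_sequences:
        n_codons = len(seq) // 3
        for p in range(3):
            sub = seq[p:3 * n_codons:3]
            pos_counts[p] = pos_counts[p] + count_bases(sub)
    return tuple(at_content(c) for c in pos_counts)


@dataclass
class RegionSummary:
    """One Table-2-style row: length, AT%, AT-skew, GC-skew for a region.

    ``at_skew``/``gc_skew`` hold the reported convention (plus strand for
    whole/CR, coding sense for gene classes); both underlying variants are
    kept in ``at_skew_plus``/``at_skew_coding`` and the GC analogues.
    """

    region: str
    length: int
    counts: BaseCounts = field(repr=False, default_factory=BaseCounts)
    at_percent: Optional[float] = None
    at_skew: Optional[float] = None
    gc_skew: Optional[float] = None
    at_skew_plus: Optional[float] = None
    gc_skew_plus: Optional[float] = None
    at_skew_coding: Optional[float] = None
    gc_skew_coding: Optional[float] = None


def _complement_counts(counts: BaseCounts) -> BaseCounts:
    return BaseCounts(counts.t, counts.g, counts.c, counts.a,
                      counts.ambiguous)


def region_summary(genome: MitoGenome) -> List[RegionSummary]:
    """Per-region composition rows: whole genome, PCGs (concatenated in
    genome order, coding sense), rrnL, rrnS, tRNAs (concatenated), CR.

    Concatenated gene regions count each gene's full span, so overlapping
    nucleotides contribute once per gene, matching how published per-region
    lengths sum individual gene lengths. Absent regions are omitted.
    """
    rows: List[RegionSummary] = []
    whole = count_bases(genome.sequence)
    rows.append(_summary_row("whole", whole, whole, plus_convention=True))

    def class_counts(feats) -> tuple:
        coding = BaseCounts()
        plus = BaseCounts()
        for f in feats:
            c = count_bases(extract_feature_sequence(genome, f))
            coding = coding + c
            plus = plus + (_complement_counts(c) if f.strand == "N" else c)
        return coding, plus

    pcgs = genome.features_of_class("PCG")
    if pcgs:
        coding, plus = class_counts(pcgs)
        rows.append(_summary_row("PCGs", coding, plus, plus_convention=False))
    for rname in ("rrnL", "rrnS"):
        feat = genome.feature_by_name(rname)
        if feat is not None:
            coding, plus = class_counts([feat])
            rows.append(_summary_row(rname, coding, plus,
                                     plus_convention=False))
    trnas = genome.features_of_class("tRNA")
    if trnas:
        coding, plus = class_counts(trnas)
        rows.append(_summary_row("tRNA", coding, plus, plus_convention=False))
    cr = genome.feature_by_name(CR_NAME)
    if cr is None:
        crs = genome.features_of_class("CR")
        cr = crs[0] if crs else None
    if cr is not None:
        coding, plus = class_counts([cr])
        rows.append(_summary_row("CR", coding, plus, plus_convention=True))
    return rows


def _summary_row(region: str, coding: BaseCounts, plus: BaseCounts,
                 plus_convention: bool) -> RegionSummary:
    chosen = plus if plus_convention else coding
    return RegionSummary(
        region=region,
        length=coding.total,
        counts=chosen,
        at_percent=at_content(coding),
        at_skew=at_skew(chosen),
        gc_skew=gc_skew(chosen),
        at_skew_plus=at_skew(plus),
        gc_skew_plus=gc_skew(plus),
        at_skew_coding=at_skew(coding),
        gc_skew_coding=gc_skew(coding),
    )


def summaries_to_table(rows: List[RegionSummary]) -> "object":
    """Region summaries as a pandas DataFrame in Table-2 column layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "length": [r.length for r in rows],
            "at_percent": [r.at_percent for r in rows],
            "at_skew": [r.at_skew for r in rows],
            "gc_skew": [r.gc_skew for r in rows],
        }
    )


__all__ = [
    "BaseCounts", "RegionSummary", "count_bases", "at_content", "gc_content",
    "at_skew", "gc_skew", "codon_position_composition", "region_summary",
    "summaries_to_table", "REGIONS",
]
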