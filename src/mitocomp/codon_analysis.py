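"""Codon extraction, start/stop classification, codon usage and RSCU.

All translation uses the invertebrate mitochondrial code (NCBI table 5),
under which TAA/TAG are the only stops; TGA reads Trp, ATA reads Met and
AGA/AGG read Ser. Mitochondrial genes frequently end on a truncated stop
("T" or "TA") completed to TAA by polyadenylation of the transcript; such
tails are classified as incomplete stop markers "T-" / "TA-".

RSCU (relative synonymous codon usage) for codon ``c`` in synonymous family
``F`` is ``count(c) * |F| / sum_{c' in F} count(c')`` — 1 for a uniformly
used family, >1 for preferred codons.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .genetic_code import (
    AMINO_ACID_NAMES,
    ALL_CODONS,
    STOP,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    TABLE5,
)
from .mito_io import MitoGenome, extract_feature_sequence

INCOMPLETE_MARKERS = {"T": "T-", "TA": "TA-"}


def extract_codons(coding_sequence: str, codon_start: int = 1
                   ) -> Tuple[List[str], str]:
    """Split a coding-sense sequence into consecutive triplets.

    ``codon_start`` is the GenBank 1-3 frame offset. Returns the codon list
    and the trailing incomplete tail of length 0-2.
    """
    if codon_start not in (1, 2, 3):
        raise ValueError(f"codon_start must be 1-3, got {codon_start}")
    seq = coding_sequence.upper()[codon_start - 1:]
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon after offset")
    n = len(seq) // 3
    codons = [seq[3 * i:3 * i + 3] for i in range(n)]
    return codons, seq[3 * n:]


@dataclass
class GeneCodonReport:
    """Start/stop classification of one protein-coding gene."""

    gene: str
    length: int
    start_codon: str
    stop_codon: str              # full stop, "T-"/"TA-", or "" if none found
    n_complete_codons: int
    n_internal_stops: int
    start_canonical: bool        # start matches AT[ACGT]
    stop_found: bool

    @property
    def incomplete_stop(self) -> bool:
        return self.stop_codon in ("T-", "TA-")


def classify_start_stop(gene: str, coding_sequence: str,
                        codon_start: int = 1) -> GeneCodonReport:
    """Classify a gene's start and stop architecture.

    The stop is the last complete codon when it is TAA/TAG; otherwise a
    trailing "T"/"TA" tail is read as an incomplete, polyadenylation-
    completed stop. A gene ending on neither is flagged (``stop_found``
    False), never coerced.
    """
    codons, tail = extract_codons(coding_sequence, codon_start)
    start = codons[0]
    stop: str = ""
    stop_found = False
    terminal_is_stop = codons[-1] in STOP_CODONS and not tail
    if terminal_is_stop:
        stop, stop_found = codons[-1], True
    elif tail in INCOMPLETE_MARKERS:
        stop, stop_found = INCOMPLETE_MARKERS[tail], True
    internal = codons[1:-1] if terminal_is_stop else codons[1:]
    n_internal_stops = sum(1 for c in internal if c in STOP_CODONS)
    return GeneCodonReport(
        gene=gene,
        length=len(coding_sequence) - (codon_start - 1),
        start_codon=start,
        stop_codon=stop,
        n_complete_codons=len(codons),
        n_internal_stops=n_internal_stops,
        start_canonical=(len(start) == 3 and start[:2] == "AT"),
        stop_found=stop_found,
    )


def translate(coding_sequence: str) -> str:
    """Translate complete codons under table 5; ``*`` marks stops and
    ambiguity-containing codons give ``X``."""
    codons, tail = extract_codons(coding_sequence)
    if tail:
        raise ValueError("translate expects complete codons only")
    out = []
    for c in codons:
        out.append(TABLE5.get(c, "X"))
    return "".join(out)


@dataclass
class CodonProfile:
    """Pooled codon counts with RSCU and per-codon amino-acid mapping."""

    counts: Dict[str, int] = field(default_factory=lambda: dict.fromkeys(ALL_CODONS, 0))
    rscu: Dict[str, float] = field(default_factory=dict)
    family: Dict[str, str] = field(default_factory=lambda: dict(TABLE5))
    total_nonstop_codons: int = 0
    unused_families: List[str] = field(default_factory=list)

    def gene_reports(self) -> List[GeneCodonReport]:
        return list(getattr(self, "_gene_reports", []))


def codon_usage(genome: MitoGenome) -> CodonProfile:
    """Pool complete codons of all annotated PCGs (coding sense).

    Terminal complete stop codons and trailing incomplete tails are
    excluded, so the total matches the published "non-stop codon" counting
    convention. A genome missing PCGs proceeds with a warning.
    """
    counts: Counter = Counter()
    reports: List[GeneCodonReport] = []
    pcgs = genome.features_of_class("PCG")
    if len(pcgs) < 13:
        warnings.warn(
            f"{genome.record_id}: only {len(pcgs)} PCGs annotated",
            UserWarning, stacklevel=2,
        )
    for feat in pcgs:
        seq = extract_feature_sequence(genome, feat)
        report = classify_start_stop(feat.name, seq, feat.codon_start)
        reports.append(report)
        codons, tail = extract_codons(seq, feat.codon_start)
        if codons[-1] in STOP_CODONS and not tail:
            codons = codons[:-1]
        counts.update(codons)
    profile = CodonProfile()
    for codon, n in counts.items():
        profile.counts[codon] = n
    profile.total_nonstop_codons = sum(
        n for c, n in profile.counts.items() if c not in STOP_CODONS
    )
    profile._gene_reports = reports  # type: ignore[attr-defined]
    return profile


def rscu(profile: CodonProfile) -> CodonProfile:
    """Fill in RSCU values; unused synonymous families get 0 and are
    flagged in ``unused_families``."""
    profile.rscu = {}
    profile.unused_families = []
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        total = sum(profile.counts.get(c, 0) for c in fam)
        if total == 0:
            profile.unused_families.append(aa)
            for c in fam:
                profile.rscu[c] = 0.0
        else:
            size = len(fam)
            for c in fam:
                profile.rscu[c] = profile.counts.get(c, 0) * size / total
    return profile


def amino_acid_frequency(profile: CodonProfile
                         ) -> List[Tuple[str, int]]:
    """Per-amino-acid usage over non-stop codons, sorted by descending
    count with alphabetical (three-letter name) tie-break."""
    agg: Counter = Counter()
    for codon, n in profile.counts.items():
        aa = TABLE5[codon]
        if aa != STOP and n:
            agg[AMINO_ACID_NAMES[aa]] += n
    return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))


def profile_to_table(profile: CodonProfile) -> "object":
    """64-row codon table (codon, amino acid, count, RSCU) as a DataFrame."""
    import pandas as pd

    if not profile.rscu:
        rscu(profile)
    return pd.DataFrame(
        {
            "codon": ALL_CODONS,
            "amino_acid": [TABLE5[c] for c in ALL_CODONS],
            "count": [profile.counts.get(c, 0) for c in ALL_CODONS],
            "rscu": [profile.rscu.get(c, 0.0) if TABLE5[c] != STOP else float("nan")
                     for c in ALL_CODONS],
        }
    )


def gene_reports_table(reports: Sequence[GeneCodonReport]) -> "object":
    """Table-3-style per-gene summary (gene, start, stop, length)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [r.gene for r in reports],
            "start_codon": [r.start_codon for r in reports],
            "stop_codon": [r.stop_codon or "none" for r in reports],
            "length_bp": [r.length for r in reports],
        }
    )


__all__ = [
    "GeneCodonReport", "CodonProfile", "extract_codons",
    "classify_start_stop", "translate", "codon_usage", "rscu",
    "amino_acid_frequency", "profile_to_table", "gene_reports_table",
]
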