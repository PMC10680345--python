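"""Reading, writing and normalizing annotated circular mitogenomes.

GenBank flat files and FASTA are handled through Biopython; this module adds
the circle-aware coordinate conventions used throughout the package:

* coordinates are 1-based inclusive on the deposited plus strand, matching
  GenBank feature tables;
* the plus strand is called **J** (majority) and its complement **N**
  (minority), the standard naming for leafhopper/insect mitogenomes;
* a feature that spans the origin of the circle has ``wraps_origin=True`` and
  ``end < start``; its length is ``end - start + 1 + genome_length``.

Gene names are normalized to the canonical 37-gene vocabulary
(nad1-6, nad4l, cox1-3, cob, atp6, atp8, rrnL, rrnS, trnX with the
serine/leucine isoacceptors disambiguated by anticodon, plus CR for the
A+T-rich control region).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord


class GenBankParseError(ValueError):
    """Raised for structurally invalid GenBank input (e.g. no ORIGIN)."""


class CoordinateError(ValueError):
    """Raised when feature coordinates are inconsistent with the sequence."""


class AnnotationWarning(UserWarning):
    """Non-fatal annotation problems (unrecognized names, duplicate ids)."""


# ---------------------------------------------------------------------------
# canonical vocabulary

PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)
RRNA_NAMES = ("rrnL", "rrnS")
TRNA_NAMES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)
CR_NAME = "CR"

GENE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# common dialects for non-tRNA genes, all keys lower-case with separators
# stripped; extensible at run time via register_gene_alias()
_DIALECT = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytochromecoxidasesubunit1": "cox1",
    "cytochromecoxidasesubuniti": "cox1",
    "cytochromecoxidasesubunit2": "cox2",
    "cytochromecoxidasesubunitii": "cox2",
    "cytochromecoxidasesubunit3": "cox3",
    "cytochromecoxidasesubunitiii": "cox3",
    "cob": "cob", "cytb": "cob", "cytochromeb": "cob", "cb": "cob",
    "atp6": "atp6", "atpase6": "atp6", "atpsynthasef0subunit6": "atp6",
    "atp8": "atp8", "atpase8": "atp8", "atpsynthasef0subunit8": "atp8",
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "16sribosomalrna": "rrnL", "largesubunitribosomalrna": "rrnL", "lsu": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    "12sribosomalrna": "rrnS", "smallsubunitribosomalrna": "rrnS", "ssu": "rrnS",
    "controlregion": CR_NAME, "dloop": CR_NAME, "atrichregion": CR_NAME,
    "a+trichregion": CR_NAME, "atregion": CR_NAME, "cr": CR_NAME,
    "putativecontrolregion": CR_NAME,
}
for _i in range(1, 7):
    _DIALECT[f"nad{_i}"] = f"nad{_i}"
    _DIALECT[f"nd{_i}"] = f"nad{_i}"
    _DIALECT[f"nadh{_i}"] = f"nad{_i}"
    _DIALECT[f"nadhdehydrogenasesubunit{_i}"] = f"nad{_i}"
_DIALECT.update({"nad4l": "nad4l", "nd4l": "nad4l", "nadh4l": "nad4l",
                 "nadhdehydrogenasesubunit4l": "nad4l"})

# codon family -> disambiguated label for the two-isoacceptor amino acids
_SER_LEU_BY_FIRST2 = {
    ("S", "AG"): "trnS1",   # AGN family
    ("S", "TC"): "trnS2",   # UCN family
    ("L", "CT"): "trnL1",   # CUN family
    ("L", "TT"): "trnL2",   # UUR family
}
_FAMILY_TAGS = {
    "agn": "trnS1", "ucn": "trnS2", "tcn": "trnS2",
    "cun": "trnL1", "ctn": "trnL1", "uur": "trnL2", "ttr": "trnL2",
}


def register_gene_alias(alias: str, canonical: str) -> None:
    """Extend the dialect table with a project-specific alias."""
    _DIALECT[_squash(alias)] = canonical


def _squash(name: str) -> str:
    return re.sub(r"[\s_\-\.]+", "", name.strip().lower())


def gene_class_for_name(name: str) -> Optional[str]:
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name in TRNA_NAMES:
        return "tRNA"
    if name == CR_NAME:
        return "CR"
    return None


def _anticodon_to_codon(anticodon: str) -> str:
    ac = anticodon.upper().replace("U", "T")
    return reverse_complement(ac)


def canonicalize_gene_name(
    raw_name: str, anticodon: Optional[str] = None
) -> Tuple[str, bool]:
    """Map a gene-name dialect to the canonical label.

    Returns ``(label, is_canonical)``. Serine/leucine tRNAs are
    disambiguated by anticodon (trnS1 = AGN family, trnS2 = UCN; trnL1 = CUN,
    trnL2 = UUR) or by an explicit 1/2 suffix or family tag in the name.
    Unmappable names come back unchanged with ``is_canonical=False``.
    """
    if not raw_name:
        raise ValueError("empty gene name")
    squashed = _squash(raw_name)
    if squashed in _DIALECT:
        return _DIALECT[squashed], True

    # tRNA dialects: trnA / trn-A / tRNA-Ala / tRNA-Ser1 / trnS(gct) / trnL(uur)
    m = re.match(
        r"^trna?-?([a-z]{3}|[a-z])(\d?)(?:\(([a-z]{3})\))?$", squashed
    )
    if m:
        aa_part, suffix, tag = m.groups()
        aa = _AA3_TO_1.get(aa_part, aa_part.upper() if len(aa_part) == 1 else None)
        if aa:
            if aa not in {"S", "L"}:
                label = f"trn{aa}"
                return (label, True) if label in TRNA_NAMES else (raw_name, False)
            if suffix in ("1", "2"):
                return f"trn{aa}{suffix}", True
            if tag:
                if tag in _FAMILY_TAGS and _FAMILY_TAGS[tag][3] == aa:
                    return _FAMILY_TAGS[tag], True
                # tag is an anticodon triplet
                codon = _anticodon_to_codon(tag)
                key = (aa, codon[:2])
                if key in _SER_LEU_BY_FIRST2:
                    return _SER_LEU_BY_FIRST2[key], True
            if anticodon:
                codon = _anticodon_to_codon(anticodon)
                key = (aa, codon[:2])
                if key in _SER_LEU_BY_FIRST2:
                    return _SER_LEU_BY_FIRST2[key], True
            return raw_name, False
    if squashed in ("trns1", "trns2", "trnl1", "trnl2"):
        return "trn" + squashed[3].upper() + squashed[4], True
    return raw_name, False


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneFeature:
    """One annotated gene/region on the circle.

    ``start``/``end`` are 1-based inclusive plus-strand positions; a feature
    with ``wraps_origin=True`` has ``end < start`` and runs through the
    origin. ``strand`` is ``"J"`` (plus) or ``"N"`` (complement).
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: str = "J"
    wraps_origin: bool = False
    codon_start: int = 1
    anticodon: Optional[str] = None
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be J or N, got {self.strand!r}")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if not self.wraps_origin and self.end < self.start:
            raise CoordinateError(
                f"{self.name}: end < start without wraps_origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return self.end - self.start + 1 + genome_length
        return self.end - self.start + 1


@dataclass
class MitoGenome:
    """A circular annotated mitochondrial genome."""

    record_id: str
    organism: str
    sequence: str
    circular: bool = True
    features: List[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen = set()
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise CoordinateError(
                    f"{f.name}: coordinates {f.start}..{f.end} outside "
                    f"1..{self.length}"
                )
            if f.wraps_origin and not self.circular:
                raise CoordinateError(
                    f"{f.name}: wrapping feature on a non-circular genome"
                )
            key = (f.name, f.start)
            if key in seen:
                raise ValueError(f"duplicate feature (name, start) = {key}")
            seen.add(key)

    def features_of_class(self, gene_class: str) -> List[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]

    def feature_by_name(self, name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.name == name:
                return f
        return None


# ---------------------------------------------------------------------------
# sequence extraction


def extract_feature_sequence(genome: MitoGenome, feat: GeneFeature) -> str:
    """Coding-sense sequence of a feature (plus-strand slice for J,
    reverse complement for N, wrap-around concatenation across the origin)."""
    seq = genome.sequence
    if feat.wraps_origin:
        if not genome.circular:
            raise CoordinateError(
                f"{feat.name}: wrapping feature on a non-circular genome"
            )
        plus = seq[feat.start - 1:] + seq[:feat.end]
    else:
        plus = seq[feat.start - 1:feat.end]
    return reverse_complement(plus) if feat.strand == "N" else plus


# ---------------------------------------------------------------------------
# GenBank

_FEATURE_TYPE_FOR_CLASS = {
    "PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature",
}
_CR_HINTS = re.compile(r"control region|a\s*\+?\s*t[- ]rich|d-?loop", re.I)


def _feature_name(sf: SeqFeature) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return None


def _feature_anticodon(sf: SeqFeature) -> Optional[str]:
    if "anticodon" in sf.qualifiers:
        raw = str(sf.qualifiers["anticodon"][0])
        m = re.search(r"seq:([acgtuACGTU]{3})", raw)
        if m:
            return m.group(1).upper().replace("U", "T")
        if re.fullmatch(r"[acgtuACGTU]{3}", raw.strip()):
            return raw.strip().upper().replace("U", "T")
    return None


def _location_to_coords(
    sf: SeqFeature, genome_length: int
) -> Tuple[int, int, bool]:
    """(start, end, wraps_origin) in 1-based inclusive plus-strand coords."""
    loc = sf.location
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    if len(parts) == 1:
        return int(parts[0].start) + 1, int(parts[0].end), False
    ends_at_origin = [p for p in parts if int(p.end) == genome_length]
    starts_at_origin = [p for p in parts if int(p.start) == 0]
    if len(parts) == 2 and ends_at_origin and starts_at_origin:
        return (
            int(ends_at_origin[0].start) + 1,
            int(starts_at_origin[0].end),
            True,
        )
    # non-wrapping join (e.g. annotated with a zero-length intron): span it
    start = min(int(p.start) for p in parts) + 1
    end = max(int(p.end) for p in parts)
    return start, end, False


def read_genbank(path) -> MitoGenome:
    """Parse a GenBank flat file into a :class:`MitoGenome`.

    Gene/CDS/tRNA/rRNA/misc_feature annotations are collected with names
    canonicalized; unrecognizable names are kept raw and reported through an
    :class:`AnnotationWarning`. Origin-spanning join locations become
    wrapping features.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - normalize Biopython errors
        raise GenBankParseError(f"{path}: {exc}") from exc
    try:
        sequence = str(record.seq).upper()
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise GenBankParseError(f"{path}: record has no sequence") from exc
    if not sequence:
        raise GenBankParseError(f"{path}: record has no sequence")
    length = len(sequence)
    circular = record.annotations.get("topology", "circular") == "circular"
    organism = record.annotations.get("organism", "")

    features: List[GeneFeature] = []
    seen_keys = set()
    seen_names = set()
    # typed features first; bare `gene` markers only backfill genes that have
    # no CDS/tRNA/rRNA entry of their own
    typed = [sf for sf in record.features
             if sf.type in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop")]
    bare = [sf for sf in record.features if sf.type == "gene"]
    for sf in typed + bare:
        raw = _feature_name(sf)
        if raw is None:
            if sf.type == "D-loop":
                raw = "control region"
            else:
                continue
        anticodon = _feature_anticodon(sf)
        name, canonical = canonicalize_gene_name(raw, anticodon)
        if sf.type in ("misc_feature", "D-loop") and not canonical:
            if _CR_HINTS.search(raw):
                name, canonical = CR_NAME, True
        if sf.type == "gene" and name in seen_names:
            continue
        if not canonical:
            if sf.type == "gene":
                continue
            warnings.warn(
                f"unrecognized gene name {raw!r} kept as-is",
                AnnotationWarning, stacklevel=2,
            )
        start, end, wraps = _location_to_coords(sf, length)
        if not (1 <= start <= length and 1 <= end <= length):
            raise CoordinateError(
                f"{path}: {raw}: location {start}..{end} outside 1..{length}"
            )
        gene_class = gene_class_for_name(name)
        if gene_class is None:
            gene_class = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}.get(
                sf.type, "CR"
            )
        key = (name, start)
        if key in seen_keys:
            continue
        codon_start = int(sf.qualifiers.get("codon_start", [1])[0])
        strand = "N" if sf.location.strand == -1 else "J"
        features.append(GeneFeature(
            name=name, gene_class=gene_class, start=start, end=end,
            strand=strand, wraps_origin=wraps, codon_start=codon_start,
            anticodon=anticodon, canonical=canonical,
        ))
        seen_keys.add(key)
        seen_names.add(name)
    features.sort(key=lambda f: f.start)
    return MitoGenome(
        record_id=record.id or record.name,
        organism=organism,
        sequence=sequence,
        circular=circular,
        features=features,
        source=str(path),
    )


def write_genbank(genome: MitoGenome, path) -> None:
    """Emit a GenBank flat file that re-reads to an equivalent genome."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.record_id,
        name=re.sub(r"\W", "", genome.record_id)[:16] or "SYNTH",
        description=genome.organism or "synthetic mitogenome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["organism"] = genome.organism
    L = genome.length
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps_origin:
            p1 = SimpleLocation(f.start - 1, L, strand)
            p2 = SimpleLocation(0, f.end, strand)
            loc = CompoundLocation([p2, p1] if strand == -1 else [p1, p2])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers = {"gene": [f.name]}
        if f.gene_class == "PCG" and f.codon_start != 1:
            qualifiers["codon_start"] = [str(f.codon_start)]
        if f.anticodon:
            qualifiers["anticodon"] = [f.anticodon]
        if f.gene_class == "CR":
            qualifiers["note"] = ["putative control region; A+T-rich region"]
        record.features.append(
            SeqFeature(loc, type=_FEATURE_TYPE_FOR_CLASS[f.gene_class],
                       qualifiers=qualifiers)
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA entries as ``(id, SEQUENCE)`` pairs, case-folded to upper."""
    entries: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            warnings.warn(
                f"duplicated FASTA id {rec.id!r}", AnnotationWarning,
                stacklevel=2,
            )
        seen.add(rec.id)
        entries.append((rec.id, str(rec.seq).upper()))
    return entries


def write_fasta(entries: Iterable[Tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


__all__ = [
    "MitoGenome", "GeneFeature", "GenBankParseError", "CoordinateError",
    "AnnotationWarning", "read_genbank", "write_genbank", "read_fasta",
    "write_fasta", "canonicalize_gene_name", "extract_feature_sequence",
    "gene_class_for_name", "register_gene_alias",
    "PCG_NAMES", "RRNA_NAMES", "TRNA_NAMES", "CR_NAME",
]
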