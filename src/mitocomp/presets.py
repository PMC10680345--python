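"""Published-table parameterizations of the synthetic generator.

Each preset captures one of the three *Abrus* leafhopper mitogenomes as its
printed summary tables describe it: per-gene lengths, start/stop codons,
junction overlaps and composition targets. Per-tRNA lengths are a synthetic
assignment (only the class total and the 61-76 bp range are published);
spacer placements other than the Cys-Tyr spacer are likewise synthetic,
chosen so the regions tile the published genome length where the printed
numbers permit it (they do for the daozhenensis- and expansivus-like
presets; the yunshanensis-like printed region lengths are mutually
inconsistent with the printed total, so that preset's total differs).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Tuple

from .synthetic import (
    DEFAULT_JUNCTION_GAPS,
    DEFAULT_PCG_LENGTHS,
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    DEFAULT_TRNA_LENGTHS,
    SyntheticSpec,
)
from .mito_io import CR_NAME


def _spec(seed: int, **kw) -> SyntheticSpec:
    return replace(SyntheticSpec(seed=seed), **kw)


def daozhenensis_like(seed: int = 0) -> SyntheticSpec:
    """MZ274046-like genome; this is the generator default: 16,391 bp,
    A+T 76.2%, CR 2,035 bp, 11 overlap junctions totalling 36 bp, longest
    spacer trnC-trnY 38 bp."""
    return _spec(
        seed,
        record_id="SYN_MZ274046",
        organism="Abrus daozhenensis-like (synthetic)",
    )


def yunshanensis_like(seed: int = 0) -> SyntheticSpec:
    """MZ274047-like genome: A+T 76.3%, AT-skew 0.097, GC-skew -0.161,
    CR 1,947 bp, longest spacer trnC-trnY 39 bp."""
    trna = dict(DEFAULT_TRNA_LENGTHS)
    trna.update({"trnV": 75, "trnK": 69, "trnQ": 67, "trnM": 67})  # sum 1437
    gaps: Dict[Tuple[str, str], int] = dict(DEFAULT_JUNCTION_GAPS)
    gaps[("trnC", "trnY")] = 39
    return _spec(
        seed,
        record_id="SYN_MZ274047",
        organism="Abrus yunshanensis-like (synthetic)",
        gene_lengths={**DEFAULT_PCG_LENGTHS, **trna,
                      "rrnL": 1203, "rrnS": 743, CR_NAME: 1947},
        junction_gaps=gaps,
        stop_codons={**DEFAULT_STOP_CODONS, "cox3": "TAG"},
        at_fraction=0.763,
        at_skew_target=0.097,
        gc_skew_target=-0.161,
        cr_at_fraction=0.824,
        cr_at_skew=0.015,
        cr_gc_skew=-0.119,
    )


def expansivus_like(seed: int = 0) -> SyntheticSpec:
    """NC_045238/MK033020-like genome: 15,904 bp, A+T 74.7%, CR 1,545 bp,
    12 overlap junctions, longest spacer trnC-trnY 18 bp."""
    pcg = dict(DEFAULT_PCG_LENGTHS)
    pcg.update({"nad4": 1305, "nad6": 477})  # sum 10,936
    trna = dict(DEFAULT_TRNA_LENGTHS)
    trna.update({"trnV": 75, "trnK": 68, "trnQ": 67, "trnM": 67})  # sum 1436
    gaps: Dict[Tuple[str, str], int] = {
        ("trnI", "trnQ"): -1, ("nad2", "trnW"): -8, ("trnD", "atp8"): -7,
        ("atp8", "atp6"): -1, ("trnG", "nad3"): -1, ("trnA", "trnR"): -1,
        ("trnR", "trnN"): -1, ("trnN", "trnS1"): -3, ("trnS1", "trnE"): -1,
        ("trnH", "nad4"): -4, ("trnP", "nad6"): -1, ("cob", "trnS2"): -1,
        ("trnC", "trnY"): 18, ("trnS2", "nad1"): 10, ("trnQ", "trnM"): 8,
        ("trnY", "cox1"): 6, ("cox2", "trnK"): 5, ("trnK", "trnD"): 4,
        ("trnE", "trnF"): 3, ("trnT", "trnP"): 3,
    }
    return _spec(
        seed,
        record_id="SYN_NC045238",
        organism="Abrus expansivus-like (synthetic)",
        gene_lengths={**pcg, **trna, "rrnL": 1204, "rrnS": 756,
                      CR_NAME: 1545},
        junction_gaps=gaps,
        start_codons={**DEFAULT_START_CODONS, "cox1": "ATA", "nad6": "ATA"},
        stop_codons={**DEFAULT_STOP_CODONS, "nad3": "TAA", "nad4l": "TAG"},
        at_fraction=0.747,
        at_skew_target=0.095,
        gc_skew_target=-0.138,
        cr_at_fraction=0.822,
        cr_at_skew=0.041,
        cr_gc_skew=-0.107,
    )


PRESETS = {
    "daozhenensis-like": daozhenensis_like,
    "yunshanensis-like": yunshanensis_like,
    "expansivus-like": expansivus_like,
}

#: published per-species summary values usable as cross-checks; None where
#: the printed numbers are internally inconsistent
PUBLISHED = {
    "daozhenensis-like": {
        "genome_length": 16391, "at_percent": 76.2, "at_skew": 0.091,
        "gc_skew": -0.144, "pcg_length": 10945, "cr_length": 2035,
        "rrnL_length": 1204, "nonstop_codons": 3636,
        "n_overlap_junctions": 11, "overlap_bp": 36,
        "longest_spacer": ("trnC", "trnY", 38),
    },
    "yunshanensis-like": {
        "genome_length": None, "at_percent": 76.3, "at_skew": 0.097,
        "gc_skew": -0.161, "pcg_length": 10945, "cr_length": 1947,
        "rrnL_length": 1203, "nonstop_codons": 3636,
        "n_overlap_junctions": 11, "overlap_bp": 36,
        "longest_spacer": ("trnC", "trnY", 39),
    },
    "expansivus-like": {
        "genome_length": 15904, "at_percent": 74.7, "at_skew": 0.095,
        "gc_skew": -0.138, "pcg_length": 10936, "cr_length": 1545,
        "rrnL_length": 1204, "nonstop_codons": None,
        "n_overlap_junctions": 12, "overlap_bp": 30,
        "longest_spacer": ("trnC", "trnY", 18),
    },
}

__all__ = ["PRESETS", "PUBLISHED", "daozhenensis_like", "yunshanensis_like",
           "expansivus_like"]
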