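"""Invertebrate mitochondrial genetic code (NCBI translation table 5).

The table is embedded as data: codon -> one-letter amino acid, with ``*``
for stop. Relative to the standard code, table 5 reads AGA/AGG as Ser,
ATA as Met and TGA as Trp, so the only stop codons are TAA and TAG.
"""

from __future__ import annotations

from typing import Dict, List

STOP = "*"

#: NCBI translation table 5, DNA alphabet, codon -> amino acid.
TABLE5: Dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "S", "AGG": "S",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in TABLE5.items() if aa == STOP)

#: Synonymous families under table 5 (stop codons excluded), amino acid ->
#: sorted codon list. Ser is a single 6-member family (TCN + AGN).
SYNONYMOUS_FAMILIES: Dict[str, List[str]] = {}
for _codon, _aa in TABLE5.items():
    if _aa != STOP:
        SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)
for _fam in SYNONYMOUS_FAMILIES.values():
    _fam.sort()

AMINO_ACID_NAMES: Dict[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}

ALL_CODONS: List[str] = sorted(TABLE5)
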