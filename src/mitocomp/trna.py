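"""Parsing and segmenting tRNA cloverleaf secondary structures.

Structures are consumed as sequence + dot-bracket text (the format
secondary-structure annotators emit); folding is never predicted here. A
canonical cloverleaf has four helices: the acceptor stem enclosing three
inner stem-loops which, read 5'->3', are the DHU arm, the anticodon arm and
the TψC arm. Mitochondrial tRNAs often lose the DHU arm (trnS1 in nearly
all animals) or, more rarely, the TψC arm; the lost arm is replaced by an
unpaired loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

ARM_NAMES = ("acceptor", "DHU", "anticodon", "TpsiC")

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}


class StructureParseError(ValueError):
    """Unbalanced or malformed dot-bracket input."""


@dataclass
class Arm:
    present: bool
    stem_pairs: int = 0
    loop_length: int = 0
    pair_indices: Tuple[Tuple[int, int], ...] = ()


@dataclass
class CloverleafStructure:
    """A parsed tRNA secondary structure.

    ``sequence`` is stored RNA-style (T normalized to U); ``pairs`` are
    1-based (i, j) with i < j, nested (non-crossing) by construction.
    """

    trna_name: str
    sequence: str
    pairs: List[Tuple[int, int]] = field(default_factory=list)
    arms: Dict[str, Arm] = field(default_factory=dict)
    anticodon_triplet: Optional[str] = None
    cloverleaf: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1], chars[j - 1] = "(", ")"
        return "".join(chars)


def parse_dot_bracket(sequence: str, structure: str,
                      name: str = "") -> CloverleafStructure:
    """Pair list from a dot-bracket string (``(``, ``)``, ``.``).

    Sequence and structure must have equal length and brackets must
    balance; errors report the offending position.
    """
    if len(sequence) != len(structure):
        raise StructureParseError(
            f"{name or 'structure'}: sequence length {len(sequence)} != "
            f"structure length {len(structure)}"
        )
    seq = sequence.upper().replace("T", "U")
    stack: List[int] = []
    pairs: List[Tuple[int, int]] = []
    for pos, ch in enumerate(structure, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureParseError(
                    f"{name or 'structure'}: unmatched ')' at position {pos}"
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureParseError(
                f"{name or 'structure'}: illegal character {ch!r} at "
                f"position {pos}"
            )
    if stack:
        raise StructureParseError(
            f"{name or 'structure'}: unmatched '(' at position {stack[-1]}"
        )
    pairs.sort()
    return CloverleafStructure(trna_name=name, sequence=seq, pairs=pairs)


def _helices(pairs: Sequence[Tuple[int, int]]) -> List[List[Tuple[int, int]]]:
    """Group pairs into stacked helices ((i,j),(i+1,j-1),...)."""
    helices: List[List[Tuple[int, int]]] = []
    for p in sorted(pairs):
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def _encloses(outer: List[Tuple[int, int]],
              inner: List[Tuple[int, int]]) -> bool:
    (i, j) = outer[0]
    (a, b) = inner[0]
    return i < a and b < j


def classify_arms(structure: CloverleafStructure) -> CloverleafStructure:
    """Assign helices to cloverleaf arms.

    The outermost helix (one enclosing all others) is the acceptor stem;
    helices directly inside it are the inner arms, assigned DHU, anticodon
    and TψC in 5'->3' order. With only two inner stem-loops the missing arm
    is identified positionally: the longer unpaired run on the 5' side of
    the first inner helix (vs the 3' side of the last) marks a lost DHU arm,
    otherwise the TψC arm is the one lost. Zero inner stem-loops flag the
    structure as non-cloverleaf.
    """
    helices = _helices(structure.pairs)
    arms: Dict[str, Arm] = {a: Arm(present=False) for a in ARM_NAMES}
    structure.arms = arms
    if not helices:
        structure.cloverleaf = False
        return structure

    # top-level helices (not enclosed by any other)
    top = [h for h in helices
           if not any(_encloses(o, h) for o in helices if o is not h)]
    acceptor: Optional[List[Tuple[int, int]]] = None
    if len(top) == 1 and len(helices) > 1:
        acceptor = top[0]
        inner_region = [h for h in helices if h is not acceptor]
        # group nested helices (bulged stems) into one arm per top child
        children = [h for h in inner_region
                    if not any(_encloses(o, h) for o in inner_region
                               if o is not h)]
    else:
        # no enclosing acceptor pairing in the input
        children = top

    def _subtree_pairs(root: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
        out = list(root)
        for h in helices:
            if h is not root and _encloses(root, h):
                out.extend(h)
        return sorted(out)

    if acceptor is not None:
        acc_pairs = tuple(acceptor)
        arms["acceptor"] = Arm(
            present=True, stem_pairs=len(acceptor),
            loop_length=0, pair_indices=acc_pairs,
        )

    children = sorted(children, key=lambda h: h[0][0])
    if not children:
        structure.cloverleaf = False
        return structure

    def _arm_from(h: List[Tuple[int, int]]) -> Arm:
        pairs = _subtree_pairs(h)
        innermost = max(pairs, key=lambda p: p[0])
        loop_len = innermost[1] - innermost[0] - 1
        return Arm(present=True, stem_pairs=len(pairs),
                   loop_length=loop_len, pair_indices=tuple(pairs))

    n = len(children)
    if n >= 3:
        order = ["DHU", "anticodon", "TpsiC"]
        for armname, h in zip(order, children[:3]):
            arms[armname] = _arm_from(h)
        anticodon_arm = arms["anticodon"]
    elif n == 2:
        # decide which arm is missing from the unpaired runs flanking the
        # two inner helices
        if acceptor is not None:
            left_bound = acceptor[-1][0]  # innermost acceptor pair, 5' side
            right_bound = acceptor[-1][1]
        else:
            left_bound, right_bound = 0, structure.length + 1
        run_5p = children[0][0][0] - left_bound - 1
        run_3p = right_bound - max(p[1] for p in _subtree_pairs(children[1])) - 1
        if run_5p >= run_3p:
            arms["anticodon"] = _arm_from(children[0])
            arms["TpsiC"] = _arm_from(children[1])
        else:
            arms["DHU"] = _arm_from(children[0])
            arms["anticodon"] = _arm_from(children[1])
        anticodon_arm = arms["anticodon"]
    else:  # single inner stem-loop: read it as the anticodon arm
        arms["anticodon"] = _arm_from(children[0])
        anticodon_arm = arms["anticodon"]

    if anticodon_arm.present and anticodon_arm.loop_length >= 7:
        innermost = max(anticodon_arm.pair_indices, key=lambda p: p[0])
        loop_start, loop_end = innermost[0] + 1, innermost[1] - 1
        mid = (loop_start + loop_end) // 2
        structure.anticodon_triplet = structure.sequence[mid - 2:mid + 1]
    return structure


def pair_type_tally(structure: CloverleafStructure) -> Dict[str, int]:
    """Tally Watson-Crick, G-U wobble and mismatched base pairs."""
    tally = {"watson_crick": 0, "gu_wobble": 0, "mismatch": 0}
    for i, j in structure.pairs:
        duo = (structure.sequence[i - 1], structure.sequence[j - 1])
        if duo in _WC_PAIRS:
            tally["watson_crick"] += 1
        elif duo in _GU_PAIRS:
            tally["gu_wobble"] += 1
        else:
            tally["mismatch"] += 1
    return tally


def read_structures(path) -> List[CloverleafStructure]:
    """Read plain-text structures: repeated blocks of
    name / sequence / dot-bracket lines (blank lines ignored)."""
    structures = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) % 3:
        raise StructureParseError(
            f"{path}: expected name/sequence/structure triples"
        )
    for k in range(0, len(lines), 3):
        name = lines[k].lstrip(">")
        structures.append(parse_dot_bracket(lines[k + 1], lines[k + 2], name))
    return structures


def write_structures(structures: Sequence[CloverleafStructure], path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f">{s.trna_name}\n{s.sequence}\n{s.dot_bracket()}\n")


def summarize_trnas(genome, structures: Sequence[CloverleafStructure]
                    ) -> "object":
    """Per-tRNA table joining genome annotation with parsed structures:
    name, length, strand, arm presence, pair-type counts."""
    import pandas as pd
    import warnings as _warnings

    annotated = {f.name: f for f in genome.features_of_class("tRNA")}
    rows = []
    by_name = {}
    for s in structures:
        by_name[s.trna_name] = s
        if s.trna_name not in annotated:
            _warnings.warn(
                f"structure {s.trna_name!r} has no matching annotation",
                UserWarning, stacklevel=2,
            )
    L = genome.length
    for name, feat in annotated.items():
        s = by_name.get(name)
        row = {
            "trna": name,
            "length": feat.length(L),
            "strand": feat.strand,
        }
        if s is not None:
            if not s.arms:
                classify_arms(s)
            tally = pair_type_tally(s)
            row.update({
                "acceptor": s.arms["acceptor"].present,
                "DHU": s.arms["DHU"].present,
                "anticodon_arm": s.arms["anticodon"].present,
                "TpsiC": s.arms["TpsiC"].present,
                "n_pairs": len(s.pairs),
                **tally,
            })
        rows.append(row)
    for name, s in by_name.items():
        if name not in annotated:
            if not s.arms:
                classify_arms(s)
            tally = pair_type_tally(s)
            rows.append({
                "trna": name + " (unannotated)", "length": s.length,
                "strand": "?",
                "acceptor": s.arms["acceptor"].present,
                "DHU": s.arms["DHU"].present,
                "anticodon_arm": s.arms["anticodon"].present,
                "TpsiC": s.arms["TpsiC"].present,
                "n_pairs": len(s.pairs), **tally,
            })
    return pd.DataFrame(rows)


__all__ = [
    "CloverleafStructure", "Arm", "StructureParseError", "ARM_NAMES",
    "parse_dot_bracket", "classify_arms", "pair_type_tally",
    "read_structures", "write_structures", "summarize_trnas",
]
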