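"""Gene architecture of the circular mitogenome.

Junction analysis (overlaps and intergenic spacers between consecutive
genes on the circle), control-region location, per-class strand tallies,
circular gene-order encoding and breakpoint-distance comparison against the
ancestral insect arrangement (the *Drosophila yakuba* order, which nearly
all leafhopper mitogenomes retain).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .mito_io import CR_NAME, GeneFeature, MitoGenome

#: The 37-gene ancestral insect mitochondrial gene order (as in
#: *D. yakuba*), starting from trnI, with strands. The control region sits
#: between rrnS and trnI and is excluded from the order.
ANCESTRAL_ORDER: Tuple[Tuple[str, str], ...] = (
    ("trnI", "J"), ("trnQ", "N"), ("trnM", "J"), ("nad2", "J"),
    ("trnW", "J"), ("trnC", "N"), ("trnY", "N"), ("cox1", "J"),
    ("trnL2", "J"), ("cox2", "J"), ("trnK", "J"), ("trnD", "J"),
    ("atp8", "J"), ("atp6", "J"), ("cox3", "J"), ("trnG", "J"),
    ("nad3", "J"), ("trnA", "J"), ("trnR", "J"), ("trnN", "J"),
    ("trnS1", "J"), ("trnE", "J"), ("trnF", "N"), ("nad5", "N"),
    ("trnH", "N"), ("nad4", "N"), ("nad4l", "N"), ("trnT", "J"),
    ("trnP", "N"), ("nad6", "J"), ("cob", "J"), ("trnS2", "J"),
    ("nad1", "N"), ("trnL1", "N"), ("rrnL", "N"), ("trnV", "N"),
    ("rrnS", "N"),
)


@dataclass(frozen=True)
class JunctionRecord:
    """Gap/overlap between two genes consecutive on the circle.

    ``gap_bp`` < 0 is an overlap of ``|gap_bp|`` bp, 0 abutting, > 0 an
    intergenic spacer. Junctions flanking the control region are flagged
    ``cr_adjacent`` and excluded from overlap/spacer summaries; a feature
    fully contained in another is flagged ``containment`` and excluded from
    gap arithmetic.
    """

    upstream: str
    downstream: str
    gap_bp: int
    cr_adjacent: bool = False
    containment: bool = False


@dataclass(frozen=True)
class GeneOrder:
    """Circular ordered list of (gene, strand); comparisons are
    rotation-invariant."""

    genes: Tuple[Tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> Tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def rotated_to(self, name: str) -> "GeneOrder":
        names = self.names()
        if name not in names:
            return self
        i = names.index(name)
        return GeneOrder(self.genes[i:] + self.genes[:i])


ANCESTRAL_GENE_ORDER = GeneOrder(ANCESTRAL_ORDER)


def _sorted_features(genome: MitoGenome) -> List[GeneFeature]:
    return sorted(genome.features, key=lambda f: (f.start, f.end))


def _linear_span(f: GeneFeature, L: int) -> Tuple[int, int]:
    """(start, end) with end possibly > L for wrapping features."""
    end = f.end + L if f.wraps_origin else f.end
    return f.start, end


def junctions(genome: MitoGenome) -> List[JunctionRecord]:
    """Junction records for every consecutive feature pair on the circle,
    including the wrap-around pair."""
    feats = _sorted_features(genome)
    if len(feats) < 2:
        raise ValueError("junction analysis needs at least two features")
    L = genome.length
    spans = [_linear_span(f, L) for f in feats]
    records: List[JunctionRecord] = []
    n = len(feats)
    # detect containment: feature j fully inside feature i
    contained = set()
    for i in range(n):
        si, ei = spans[i]
        for j in range(n):
            if i == j:
                continue
            sj, ej = spans[j]
            if si <= sj and ej <= ei and (si, ei) != (sj, ej):
                contained.add(j)
    kept = [k for k in range(n) if k not in contained]
    for idx, k in enumerate(kept):
        nxt = kept[(idx + 1) % len(kept)]
        s_k, e_k = spans[k]
        s_n, _ = spans[nxt]
        if nxt > k:
            gap = s_n - e_k - 1
        else:  # wrap-around junction back to the first feature
            gap = s_n + L - e_k - 1
        cr_adj = feats[k].gene_class == "CR" or feats[nxt].gene_class == "CR"
        records.append(JunctionRecord(
            upstream=feats[k].name, downstream=feats[nxt].name,
            gap_bp=gap, cr_adjacent=cr_adj,
        ))
    for j in sorted(contained):
        records.append(JunctionRecord(
            upstream=feats[j].name, downstream=feats[j].name,
            gap_bp=0, containment=True,
        ))
    return records


def overlap_summary(junction_list: Sequence[JunctionRecord]
                    ) -> Tuple[int, int, int]:
    """(n_overlap_junctions, total_overlap_bp, max_overlap_bp) over
    gene-gene junctions (CR-adjacent and containment excluded)."""
    overlaps = [-j.gap_bp for j in junction_list
                if j.gap_bp < 0 and not j.cr_adjacent and not j.containment]
    if not overlaps:
        return 0, 0, 0
    return len(overlaps), sum(overlaps), max(overlaps)


def spacer_summary(junction_list: Sequence[JunctionRecord]
                   ) -> Tuple[int, int, Optional[Tuple[str, str, int]]]:
    """(n_spacers, total_spacer_bp, longest (upstream, downstream, bp));
    ties go to the first occurrence in the given junction order."""
    spacers = [j for j in junction_list
               if j.gap_bp > 0 and not j.cr_adjacent and not j.containment]
    if not spacers:
        return 0, 0, None
    longest = max(spacers, key=lambda j: j.gap_bp)  # max keeps first on ties
    return (len(spacers), sum(j.gap_bp for j in spacers),
            (longest.upstream, longest.downstream, longest.gap_bp))


def locate_control_region(genome: MitoGenome) -> GeneFeature:
    """The control region feature; if not annotated, synthesized as the
    span between the end of rrnS and the start of trnI on the circle."""
    annotated = genome.features_of_class("CR")
    if annotated:
        return annotated[0]
    rrns = genome.feature_by_name("rrnS")
    trni = genome.feature_by_name("trnI")
    if rrns is None or trni is None:
        raise ValueError("cannot locate control region: rrnS or trnI missing")
    L = genome.length
    start = (rrns.end % L) + 1
    end = trni.start - 1 if trni.start > 1 else L
    if start == trni.start:  # abutting: no room for a CR
        raise ValueError("rrnS and trnI are adjacent; control region absent")
    wraps = end < start
    return GeneFeature(name=CR_NAME, gene_class="CR", start=start, end=end,
                       strand="J", wraps_origin=wraps)


def strand_tally(genome: MitoGenome) -> Dict[str, Tuple[int, int]]:
    """Per-gene-class (n_J, n_N) counts."""
    tally: Dict[str, List[int]] = {}
    for f in genome.features:
        t = tally.setdefault(f.gene_class, [0, 0])
        t[0 if f.strand == "J" else 1] += 1
    return {k: (v[0], v[1]) for k, v in tally.items()}


def gene_order(genome: MitoGenome) -> GeneOrder:
    """Circular gene order by start coordinate, CR excluded, rotated to
    begin at trnI when present."""
    feats = [f for f in _sorted_features(genome) if f.gene_class != "CR"]
    names = [f.name for f in feats]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names in order: {dupes}")
    order = GeneOrder(tuple((f.name, f.strand) for f in feats))
    return order.rotated_to("trnI")


def _adjacency_set(order: GeneOrder) -> set:
    """Unordered circular adjacencies (strand-blind)."""
    names = order.names()
    n = len(names)
    if n == 1:
        return set()
    return {frozenset((names[i], names[(i + 1) % n])) for i in range(n)}


def _signed_adjacency_set(order: GeneOrder) -> set:
    """Signed circular adjacencies; each adjacency is stored in a
    reading-direction-invariant canonical form."""
    genes = order.genes
    n = len(genes)
    out = set()
    for i in range(n):
        (a, sa), (b, sb) = genes[i], genes[(i + 1) % n]
        fwd = (a, sa, b, sb)
        flip = {"J": "N", "N": "J"}
        rev = (b, flip[sb], a, flip[sa])
        out.add(min(fwd, rev))
    return out


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder,
                        signed: bool = False) -> int:
    """Number of circular adjacencies of ``order_a`` absent from
    ``order_b``; 0 iff the circular orders are rotations of each other
    (strand-blind default; ``signed=True`` also requires matching strands
    up to reading direction)."""
    set_a, set_b = set(order_a.names()), set(order_b.names())
    if set_a != set_b:
        diff = sorted(set_a ^ set_b)
        raise ValueError(f"gene sets differ: {diff}")
    if signed:
        adj_a, adj_b = _signed_adjacency_set(order_a), _signed_adjacency_set(order_b)
    else:
        adj_a, adj_b = _adjacency_set(order_a), _adjacency_set(order_b)
    return len(adj_a - adj_b)


@dataclass
class RearrangementReport:
    """Broken adjacencies of a genome's order relative to a reference."""

    distance: int
    broken_adjacencies: List[Tuple[str, str]]
    displaced_genes: List[str]

    @property
    def rearranged(self) -> bool:
        return self.distance > 0


def detect_rearrangement(genome_or_order, reference_order: GeneOrder
                         ) -> RearrangementReport:
    """Compare a genome's (or order's) circular gene order against a
    reference; empty report iff breakpoint distance is zero."""
    if isinstance(genome_or_order, GeneOrder):
        order = genome_or_order
    else:
        order = gene_order(genome_or_order)
    dist = breakpoint_distance(order, reference_order)
    names = order.names()
    n = len(names)
    ref_adj = _adjacency_set(reference_order)
    broken = []
    displaced = set()
    for i in range(n):
        a, b = names[i], names[(i + 1) % n]
        if frozenset((a, b)) not in ref_adj:
            broken.append((a, b))
            displaced.update((a, b))
    return RearrangementReport(
        distance=dist,
        broken_adjacencies=broken,
        displaced_genes=sorted(displaced),
    )


def rotate_origin(genome: MitoGenome, shift: int) -> MitoGenome:
    """A new genome with the origin moved forward by ``shift`` bases on the
    circle; features crossing the new origin become wrapping features.
    Junction gaps and all per-gene statistics are invariant under this."""
    if not genome.circular:
        raise ValueError("origin rotation requires a circular genome")
    L = genome.length
    shift %= L
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    feats = []
    for f in genome.features:
        ns = (f.start - shift - 1) % L + 1
        ne = (f.end - shift - 1) % L + 1
        feats.append(replace(f, start=ns, end=ne, wraps_origin=ne < ns))
    return MitoGenome(
        record_id=genome.record_id, organism=genome.organism, sequence=seq,
        circular=True, features=feats, source=genome.source,
    )


def junction_table(genome: MitoGenome) -> "object":
    """Supplementary-table-style organization table: gene, strand, start,
    end, length, anticodon, gap to next gene."""
    import pandas as pd

    feats = _sorted_features(genome)
    recs = {(j.upstream): j for j in junctions(genome) if not j.containment}
    L = genome.length
    return pd.DataFrame(
        {
            "gene": [f.name for f in feats],
            "class": [f.gene_class for f in feats],
            "strand": [f.strand for f in feats],
            "start": [f.start for f in feats],
            "end": [f.end for f in feats],
            "length": [f.length(L) for f in feats],
            "anticodon": [f.anticodon or "" for f in feats],
            "gap_to_next": [
                recs[f.name].gap_bp if f.name in recs else None for f in feats
            ],
        }
    )


__all__ = [
    "JunctionRecord", "GeneOrder", "RearrangementReport",
    "ANCESTRAL_ORDER", "ANCESTRAL_GENE_ORDER",
    "junctions", "overlap_summary", "spacer_summary",
    "locate_control_region", "strand_tally", "gene_order",
    "breakpoint_distance", "detect_rearrangement", "junction_table",
    "rotate_origin",
]
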