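"""Junctions, control region, strand tallies, gene order, breakpoints."""

import random

import pytest

from mitocomp.architecture import (
    ANCESTRAL_GENE_ORDER,
    ANCESTRAL_ORDER,
    GeneOrder,
    breakpoint_distance,
    detect_rearrangement,
    gene_order,
    junctions,
    locate_control_region,
    overlap_summary,
    rotate_origin,
    spacer_summary,
    strand_tally,
)
from mitocomp.mito_io import GeneFeature, MitoGenome


def _genome(features, length=60):
    seq = ("ACGT" * (length // 4 + 1))[:length]
    return MitoGenome(record_id="A1", organism="t", sequence=seq,
                      features=features)


def test_abutting_genes_gap_zero():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 10, "J"),
                 GeneFeature("trnR", "tRNA", 11, 20, "J")])
    recs = {(j.upstream, j.downstream): j.gap_bp for j in junctions(g)}
    assert recs[("trnA", "trnR")] == 0
    assert recs[("trnR", "trnA")] == 60 - 20 + 1 - 1  # wrap-around spacer


def test_overlapping_genes_negative_gap():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 10, "J"),
                 GeneFeature("trnR", "tRNA", 8, 20, "J")])
    recs = {(j.upstream, j.downstream): j.gap_bp for j in junctions(g)}
    assert recs[("trnA", "trnR")] == -3


def test_containment_excluded_from_gap_arithmetic():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 30, "J"),
                 GeneFeature("trnR", "tRNA", 5, 10, "J"),
                 GeneFeature("trnN", "tRNA", 31, 40, "J")])
    recs = junctions(g)
    contained = [j for j in recs if j.containment]
    assert len(contained) == 1 and contained[0].upstream == "trnR"
    gaps = {(j.upstream, j.downstream): j.gap_bp for j in recs
            if not j.containment}
    assert gaps[("trnA", "trnN")] == 0


def test_summaries_on_synthetic_genome(dao_genome):
    genome, truth = dao_genome
    j = junctions(genome)
    n, total, biggest = overlap_summary(j)
    expected = [-g for g in truth.junction_gaps.values() if g < 0]
    assert (n, total, biggest) == (len(expected), sum(expected), max(expected))
    n_sp, total_sp, longest = spacer_summary(j)
    pos = {k: v for k, v in truth.junction_gaps.items() if v > 0}
    assert n_sp == len(pos) and total_sp == sum(pos.values())
    up, down, bp = longest
    assert pos[(up, down)] == bp == max(pos.values())


def test_all_abutting_gives_zero_summaries():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 30, "J"),
                 GeneFeature("trnR", "tRNA", 31, 60, "J")])
    j = junctions(g)
    assert overlap_summary(j) == (0, 0, 0)
    assert spacer_summary(j) == (0, 0, None)


def test_junction_gaps_invariant_under_origin_rotation(dao_genome):
    genome, _ = dao_genome
    base = {(j.upstream, j.downstream): j.gap_bp for j in junctions(genome)}
    for shift in (1, 4321, genome.length - 7):
        rotated = rotate_origin(genome, shift)
        moved = {(j.upstream, j.downstream): j.gap_bp
                 for j in junctions(rotated)}
        assert moved == base


def test_length_conservation_on_circle(dao_genome):
    genome, truth = dao_genome
    total_genes = sum(truth.gene_lengths.values())
    total_gaps = sum(j.gap_bp for j in junctions(genome) if not j.containment)
    assert total_genes + total_gaps == genome.length


def test_locate_annotated_and_synthesized_cr(dao_genome):
    genome, truth = dao_genome
    cr = locate_control_region(genome)
    assert cr.length(genome.length) == truth.gene_lengths["CR"]
    # remove the annotation: located span must be identical
    stripped = MitoGenome(
        record_id=genome.record_id, organism=genome.organism,
        sequence=genome.sequence,
        features=[f for f in genome.features if f.gene_class != "CR"],
    )
    synth = locate_control_region(stripped)
    assert synth.length(genome.length) == truth.gene_lengths["CR"]


def test_locate_cr_requires_flanking_genes():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 10, "J"),
                 GeneFeature("trnR", "tRNA", 11, 20, "J")])
    with pytest.raises(ValueError):
        locate_control_region(g)


def test_strand_tally_matches_published_architecture(dao_genome):
    genome, _ = dao_genome
    tally = strand_tally(genome)
    assert tally["tRNA"] == (14, 8)
    assert tally["PCG"] == (9, 4)
    assert tally["rRNA"] == (0, 2)


def test_gene_order_rotates_to_trni(dao_genome):
    genome, _ = dao_genome
    order = gene_order(genome)
    assert order.genes == ANCESTRAL_ORDER
    # rotating the genome origin does not change the circular order
    rotated = rotate_origin(genome, 5000)
    assert gene_order(rotated).genes == ANCESTRAL_ORDER


def test_gene_order_rejects_duplicates():
    g = _genome([GeneFeature("trnA", "tRNA", 1, 10, "J"),
                 GeneFeature("trnA", "tRNA", 21, 30, "J")])
    with pytest.raises(ValueError, match="duplicate"):
        gene_order(g)


def _brute_force_breakpoints(a, b):
    """Independent oracle: for every neighbour pair on circle a, scan the
    neighbourhood lists of circle b."""
    names_b = list(b)
    n = len(names_b)
    neighbours = {}
    for i, x in enumerate(names_b):
        neighbours.setdefault(x, set()).update(
            {names_b[(i - 1) % n], names_b[(i + 1) % n]})
    missing = 0
    for i, x in enumerate(a):
        y = a[(i + 1) % len(a)]
        if y not in neighbours.get(x, set()):
            missing += 1
    return missing


def test_breakpoint_identity_and_swap():
    order = ANCESTRAL_GENE_ORDER
    assert breakpoint_distance(order, order) == 0
    genes = list(order.genes)
    i, j = [k for k, (n, _) in enumerate(genes) if n in ("trnW", "trnC")]
    genes[i], genes[j] = genes[j], genes[i]
    swapped = GeneOrder(tuple(genes))
    assert breakpoint_distance(order, swapped) == 2
    assert breakpoint_distance(swapped, order) == 2


def test_breakpoint_matches_brute_force_oracle():
    rng = random.Random(20240901)
    names = [n for n, _ in ANCESTRAL_ORDER]
    for _ in range(100):
        a, b = names[:], names[:]
        rng.shuffle(a)
        rng.shuffle(b)
        oa = GeneOrder(tuple((n, "J") for n in a))
        ob = GeneOrder(tuple((n, "J") for n in b))
        expected = _brute_force_breakpoints(a, b)
        assert breakpoint_distance(oa, ob) == expected
        assert breakpoint_distance(ob, oa) == expected  # symmetry


def test_breakpoint_rotation_invariance():
    order = ANCESTRAL_GENE_ORDER
    rotated = GeneOrder(order.genes[5:] + order.genes[:5])
    assert breakpoint_distance(order, rotated) == 0
    assert breakpoint_distance(rotated.rotated_to("trnI"), order) == 0


def test_breakpoint_rejects_different_gene_sets():
    a = GeneOrder((("trnA", "J"), ("trnR", "J")))
    b = GeneOrder((("trnA", "J"), ("trnN", "J")))
    with pytest.raises(ValueError, match="trnN"):
        breakpoint_distance(a, b)


def test_detect_rearrangement_reports_swapped_cluster(dao_genome):
    genome, _ = dao_genome
    clean = detect_rearrangement(genome, ANCESTRAL_GENE_ORDER)
    assert not clean.rearranged and clean.broken_adjacencies == []

    genes = list(ANCESTRAL_ORDER)
    i, j = [k for k, (n, _) in enumerate(genes) if n in ("trnW", "trnC")]
    genes[i], genes[j] = genes[j], genes[i]
    rep = detect_rearrangement(GeneOrder(tuple(genes)), ANCESTRAL_GENE_ORDER)
    assert rep.rearranged and {"trnW", "trnC"} <= set(rep.displaced_genes)


def test_single_gene_order_vs_itself():
    solo = GeneOrder((("trnA", "J"),))
    assert breakpoint_distance(solo, solo) == 0
    assert not detect_rearrangement(solo, solo).rearranged
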