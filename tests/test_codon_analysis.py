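"""Codon extraction, start/stop classification, table-5 translation, RSCU."""

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.codon_analysis import (
    CodonProfile,
    amino_acid_frequency,
    classify_start_stop,
    codon_usage,
    extract_codons,
    rscu,
    translate,
)
from mitocomp.genetic_code import ALL_CODONS, STOP, SYNONYMOUS_FAMILIES, TABLE5
from mitocomp.mito_io import GeneFeature, MitoGenome


def test_extract_codons_examples():
    assert extract_codons("ATGAAAT") == (["ATG", "AAA"], "T")
    assert extract_codons("ATGTAA") == (["ATG", "TAA"], "")
    codons, tail = extract_codons("A" * 679)
    assert len(codons) == 226 and tail == "A"


def test_extract_codons_respects_offset():
    assert extract_codons("GATGAAA", codon_start=2) == (["ATG", "AAA"], "")
    with pytest.raises(ValueError):
        extract_codons("AT")


def test_classify_start_stop_complete_stop():
    r = classify_start_stop("nad2", "ATT" + "AAA" * 3 + "TAG")
    assert r.start_codon == "ATT" and r.stop_codon == "TAG"
    assert r.start_canonical and r.stop_found and r.n_internal_stops == 0


def test_classify_start_stop_incomplete_tail():
    r = classify_start_stop("cox2", "ATAAAAT")
    assert r.start_codon == "ATA" and r.stop_codon == "T-"
    assert r.incomplete_stop and r.stop_found


def test_classify_start_stop_simple():
    r = classify_start_stop("x", "ATGAAATAA")
    assert (r.start_codon, r.stop_codon) == ("ATG", "TAA")
    assert r.n_complete_codons == 3 and r.n_internal_stops == 0


def test_classify_no_stop_is_flagged_not_raised():
    r = classify_start_stop("x", "ATGAAAGGG")
    assert not r.stop_found and r.stop_codon == ""


def test_classify_counts_internal_stops():
    r = classify_start_stop("x", "ATGTAAAAATAA")
    assert r.n_internal_stops == 1


def test_translate_against_biopython_table5():
    """Embedded invertebrate-mitochondrial code agrees with Biopython's
    CodonTable 5 for all 64 codons (independent oracle)."""
    from Bio.Data import CodonTable

    bio = CodonTable.unambiguous_dna_by_id[5]
    for codon in ALL_CODONS:
        expected = STOP if codon in bio.stop_codons else bio.forward_table[codon]
        assert TABLE5[codon] == expected, codon


def test_translate_examples():
    assert translate("ATA") == "M"
    assert translate("AGA") == "S"
    assert translate("TGA") == "W"
    assert translate("TAA") == STOP
    assert translate("ATGNNN") == "MX"


def test_rscu_hand_computed_family():
    profile = CodonProfile()
    profile.counts["AAA"], profile.counts["AAG"] = 3, 1
    rscu(profile)
    assert profile.rscu["AAA"] == pytest.approx(1.5)
    assert profile.rscu["AAG"] == pytest.approx(0.5)


def test_rscu_uniform_family_is_one_and_unused_flagged():
    profile = CodonProfile()
    for c in SYNONYMOUS_FAMILIES["V"]:
        profile.counts[c] = 7
    rscu(profile)
    assert all(profile.rscu[c] == pytest.approx(1.0)
               for c in SYNONYMOUS_FAMILIES["V"])
    assert "K" in profile.unused_families
    assert all(profile.rscu[c] == 0.0 for c in SYNONYMOUS_FAMILIES["K"])


@given(st.lists(st.integers(0, 50), min_size=64, max_size=64))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_rscu_family_sums_equal_family_size(counts):
    profile = CodonProfile()
    for codon, n in zip(ALL_CODONS, counts):
        profile.counts[codon] = n
    rscu(profile)
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if sum(profile.counts[c] for c in fam) > 0:
            assert sum(profile.rscu[c] for c in fam) == pytest.approx(len(fam))


def test_amino_acid_frequency_ranking():
    profile = CodonProfile()
    profile.counts.update({"ATT": 5, "ATC": 2, "ATG": 4, "AAA": 7, "TAA": 9})
    ranked = amino_acid_frequency(profile)
    assert ranked == [("Ile", 7), ("Lys", 7), ("Met", 4)]  # stop excluded


def test_codon_usage_single_gene():
    g = MitoGenome(
        record_id="U1", organism="t", sequence="ATGTAA",
        features=[GeneFeature("cox1", "PCG", 1, 6, "J")],
    )
    with pytest.warns(UserWarning):  # fewer than 13 PCGs
        profile = codon_usage(g)
    assert profile.counts["ATG"] == 1
    assert profile.total_nonstop_codons == 1  # terminal TAA excluded


def test_codon_usage_matches_generator_ground_truth(dao_genome):
    genome, truth = dao_genome
    profile = codon_usage(genome)
    assert profile.total_nonstop_codons == truth.total_nonstop_codons
    for codon, n in truth.codon_counts.items():
        assert profile.counts[codon] == n, codon


def test_codon_length_identity_per_gene(dao_genome):
    genome, _ = dao_genome
    from mitocomp.mito_io import extract_feature_sequence

    for feat in genome.features_of_class("PCG"):
        seq = extract_feature_sequence(genome, feat)
        codons, tail = extract_codons(seq, feat.codon_start)
        assert 3 * len(codons) + len(tail) == len(seq) - (feat.codon_start - 1)


def test_synthetic_pcgs_have_no_internal_stops(dao_genome):
    genome, _ = dao_genome
    from mitocomp.mito_io import extract_feature_sequence

    for feat in genome.features_of_class("PCG"):
        seq = extract_feature_sequence(genome, feat)
        codons, tail = extract_codons(seq)
        body = codons[:-1] if not tail else codons
        assert STOP not in translate("".join(body))
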