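"""GenBank/FASTA round trips, name canonicalization, feature extraction."""

import textwrap
from dataclasses import replace

import pytest

from mitocomp.mito_io import (
    AnnotationWarning,
    CoordinateError,
    GenBankParseError,
    GeneFeature,
    MitoGenome,
    canonicalize_gene_name,
    extract_feature_sequence,
    read_fasta,
    read_genbank,
    write_fasta,
    write_genbank,
)


@pytest.mark.parametrize(
    "raw,anticodon,expected",
    [
        ("tRNA-Ser", "GCT", "trnS1"),     # AGN-family serine
        ("tRNA-Ser", "TGA", "trnS2"),     # UCN-family serine
        ("tRNA-Leu", "TAG", "trnL1"),     # CUN-family leucine
        ("tRNA-Leu", "TAA", "trnL2"),     # UUR-family leucine
        ("nad2", None, "nad2"),
        ("ND4L", None, "nad4l"),
        ("COIII", None, "cox3"),
        ("COI", None, "cox1"),
        ("CYTB", None, "cob"),
        ("16S ribosomal RNA", None, "rrnL"),
        ("12S rRNA", None, "rrnS"),
        ("tRNA-Ala", None, "trnA"),
        ("trnM", None, "trnM"),
        ("trnL(uur)", None, "trnL2"),
        ("tRNA-Ser1", None, "trnS1"),
        ("D-loop", None, "CR"),
        ("A+T-rich region", None, "CR"),
    ],
)
def test_canonicalize_dialects(raw, anticodon, expected):
    name, ok = canonicalize_gene_name(raw, anticodon)
    assert ok and name == expected


def test_canonicalize_unmappable_flagged():
    name, ok = canonicalize_gene_name("mystery-orf")
    assert name == "mystery-orf" and not ok
    # serine tRNA without anticodon cannot be disambiguated
    name, ok = canonicalize_gene_name("tRNA-Ser")
    assert not ok


def _tiny_genome():
    return MitoGenome(
        record_id="T1", organism="test", sequence="ATGCGG", circular=True,
        features=[], source="synthetic",
    )


def test_extract_plus_strand():
    g = _tiny_genome()
    f = GeneFeature("trnA", "tRNA", 1, 4, "J")
    assert extract_feature_sequence(g, f) == "ATGC"


def test_extract_reverse_complement():
    g = _tiny_genome()
    f = GeneFeature("trnA", "tRNA", 1, 4, "N")
    assert extract_feature_sequence(g, f) == "GCAT"


def test_extract_wrapping_feature():
    g = _tiny_genome()
    f = GeneFeature("trnA", "tRNA", 5, 2, "J", wraps_origin=True)
    assert extract_feature_sequence(g, f) == "GGAT"
    assert f.length(g.length) == 4


def test_wrapping_on_linear_genome_rejected():
    g = replace(_tiny_genome(), circular=False)
    f = GeneFeature("trnA", "tRNA", 5, 2, "J", wraps_origin=True)
    with pytest.raises(CoordinateError):
        extract_feature_sequence(g, f)


def test_genbank_round_trip_synthetic(dao_genome, tmp_path):
    genome, _ = dao_genome
    path = tmp_path / "g.gb"
    write_genbank(genome, path)
    back = read_genbank(path)
    assert back.sequence == genome.sequence
    key = lambda f: (f.name, f.start, f.end, f.strand, f.wraps_origin)
    assert sorted(map(key, back.features)) == sorted(map(key, genome.features))


def test_genbank_round_trip_wrapping_feature(tmp_path):
    g = MitoGenome(
        record_id="W1", organism="t", sequence="ATGCGGATGCGG", circular=True,
        features=[
            GeneFeature("trnA", "tRNA", 11, 3, "J", wraps_origin=True),
            GeneFeature("trnR", "tRNA", 4, 9, "N"),
        ],
    )
    path = tmp_path / "w.gb"
    write_genbank(g, path)
    back = read_genbank(path)
    f = back.feature_by_name("trnA")
    assert f.wraps_origin and (f.start, f.end) == (11, 3)
    assert extract_feature_sequence(back, f) == extract_feature_sequence(g, g.features[0])


def test_genbank_empty_feature_list_round_trips(tmp_path):
    g = _tiny_genome()
    path = tmp_path / "e.gb"
    write_genbank(g, path)
    back = read_genbank(path)
    assert back.sequence == g.sequence and back.features == []


def test_read_handcrafted_record_with_join(tmp_path):
    text = textwrap.dedent("""\
        LOCUS       TESTREC                   30 bp    DNA     circular INV 01-JAN-2024
        DEFINITION  handcrafted test record.
        ACCESSION   TESTREC
        SOURCE      test organism
        FEATURES             Location/Qualifiers
             CDS             1..9
                             /gene="nad2"
             tRNA            join(28..30,1..4)
                             /product="tRNA-Met"
        ORIGIN
                1 atgaaatagc ccggggtttt aaaaccccgg
        //
        """)
    path = tmp_path / "h.gb"
    path.write_text(text)
    g = read_genbank(path)
    assert g.length == 30
    nad2 = g.feature_by_name("nad2")
    assert (nad2.start, nad2.end, nad2.gene_class) == (1, 9, "PCG")
    met = g.feature_by_name("trnM")
    assert met.wraps_origin and met.length(30) == 7


def test_read_record_without_sequence_raises(tmp_path):
    text = textwrap.dedent("""\
        LOCUS       EMPTYREC                  30 bp    DNA     circular INV 01-JAN-2024
        DEFINITION  no origin block.
        FEATURES             Location/Qualifiers
             CDS             1..9
                             /gene="nad2"
        //
        """)
    path = tmp_path / "no_origin.gb"
    path.write_text(text)
    with pytest.raises(GenBankParseError):
        read_genbank(path)


def test_unrecognized_name_warns_and_is_kept(tmp_path):
    text = textwrap.dedent("""\
        LOCUS       ODDREC                    12 bp    DNA     circular INV 01-JAN-2024
        FEATURES             Location/Qualifiers
             tRNA            1..6
                             /product="tRNA-Xyz"
        ORIGIN
                1 atgcatgcat gc
        //
        """)
    path = tmp_path / "odd.gb"
    path.write_text(text)
    with pytest.warns(AnnotationWarning):
        g = read_genbank(path)
    assert g.features[0].name == "tRNA-Xyz" and not g.features[0].canonical


def test_fasta_round_trip_and_case_fold(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">x\nacgt\n>y desc\nTTAA\nGGCC\n")
    entries = read_fasta(path)
    assert entries == [("x", "ACGT"), ("y", "TTAAGGCC")]
    out = tmp_path / "y.fasta"
    write_fasta(entries, out)
    assert read_fasta(out) == entries


def test_fasta_duplicate_ids_warn(tmp_path):
    path = tmp_path / "d.fasta"
    path.write_text(">x\nACGT\n>x\nTTTT\n")
    with pytest.warns(AnnotationWarning):
        read_fasta(path)


def test_empty_fasta(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    assert read_fasta(path) == []
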