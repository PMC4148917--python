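"""Read classification: precedence rules, strand inference, tallies."""

import numpy as np
import pytest

import exintron as ex
from exintron.classify import blocks_from_cigar
from exintron.naive import NaiveClassifier
from helpers import classify_library, random_fragments


def frag(blocks, strand="+", rank="first", chrom="chr1", qname="q"):
    return ex.AlignedFragment(chrom, tuple(blocks), 60, strand, rank, qname)


# -- CIGAR block extraction --------------------------------------------------


@pytest.mark.parametrize(
    "pos, cigar, expected",
    [
        (100, [(0, 50)], ((100, 150),)),  # 50M
        (0, [(0, 20), (3, 1000), (0, 30)], ((0, 20), (1020, 1050))),  # 20M1000N30M
        (10, [(4, 5), (0, 20), (2, 5), (0, 10)], ((10, 45),)),  # soft clip + deletion extends
        (0, [(0, 10), (1, 5), (0, 10)], ((0, 20),)),  # insertion consumes no reference
    ],
)
def test_blocks_from_cigar(pos, cigar, expected):
    assert blocks_from_cigar(pos, cigar) == expected


def test_sam_loading_applies_mapq_and_flag_filters(tmp_path, small_ref):
    sam = tmp_path / "t.sam"
    lines = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:10000"]
    lines.append("keep\t0\tchr1\t101\t30\t50M\t*\t0\t0\t*\t*")
    lines.append("lowq\t0\tchr1\t101\t0\t50M\t*\t0\t0\t*\t*")  # MAPQ 0 skipped
    lines.append("unmapped\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
    lines.append("secondary\t256\tchr1\t201\t30\t50M\t*\t0\t0\t*\t*")
    sam.write_text("\n".join(lines) + "\n")
    got = list(ex.load_alignments(sam, mapq_min=1))
    assert [f.qname for f in got] == ["keep"]
    assert got[0].blocks == ((100, 150),)
    # mapq_min=0 keeps the MAPQ-0 record
    assert [f.qname for f in ex.load_alignments(sam, mapq_min=0)] == ["keep", "lowq"]


# -- strand inference --------------------------------------------------------


@pytest.mark.parametrize(
    "read_strand, rank, protocol, expected",
    [
        ("+", "first", "fr_firststrand", "-"),
        ("-", "first", "fr_firststrand", "+"),
        ("+", "second", "fr_firststrand", "+"),
        ("-", "second", "fr_firststrand", "-"),
        ("+", "first", "fr_secondstrand", "+"),
        ("-", "second", "fr_secondstrand", "+"),
        ("+", "first", "unstranded", "unknown"),
    ],
)
def test_infer_transcription_strand(read_strand, rank, protocol, expected):
    assert ex.infer_transcription_strand(read_strand, rank, protocol) == expected


# -- classification precedence ----------------------------------------------


@pytest.fixture()
def simple_index(two_gene_annotation):
    ann, sizes = two_gene_annotation
    return ex.AnnotationIndex(ann, sizes)


def test_exon_containment_sense(simple_index):
    # gene A(+) exon (1000,1200); fr_firststrand second mate on + => tx +
    label = simple_index.classify(frag([(1020, 1070)], "+", "second"), "+")
    assert label == ex.ClassLabel("exon", "sense", "A")


def test_partial_exon_overlap_beats_intron(simple_index):
    # straddles A's exon start at 1000: NOT completely inside any intron
    label = simple_index.classify(frag([(995, 1005)]), "+")
    assert label.category == "exon" and label.gene_id == "A"


def test_intron_requires_full_containment_and_orientation(simple_index):
    # inside A's intron piece (1200,1500); tx '-' vs A '+': antisense
    label = simple_index.classify(frag([(1250, 1300)]), "-")
    assert label == ex.ClassLabel("intron", "antisense", "A")
    label = simple_index.classify(frag([(1250, 1300)]), "+")
    assert label.orientation == "sense"


def test_read_straddling_gene_boundary_is_unclassified(simple_index):
    # spans intergenic space into A's first exon? overlap => exon; take one
    # crossing from intergenic into A's span start without touching exons:
    # A span starts at 1000 with an exon, so use B's trailing exon edge at 4200
    label = simple_index.classify(frag([(4150, 4250)]), "+")
    assert label.category == "exon"  # overlaps B's exon
    # a spliced read with one block intronic and one intergenic is unclassified
    label = simple_index.classify(frag([(1250, 1290), (5000, 5040)]), "+")
    assert label.category == "unclassified"


def test_intergenic_full_containment(simple_index):
    assert simple_index.classify(frag([(6000, 6050)]), "+").category == "intergenic"


def test_mito_precedence(small_index):
    label = small_index.classify(frag([(500, 550)], chrom="chrM"), "+")
    assert label == ex.ClassLabel("mito", "not_applicable")


def test_rrna_precedence_over_exon(small_ref, small_index):
    rr = small_ref.annotation.merged_exons(small_ref.rrna_gene_id).intervals[0]
    label = small_index.classify(frag([(rr[0] + 5, rr[0] + 55)]), "+")
    assert label.category == "rRNA" and label.gene_id == small_ref.rrna_gene_id


def test_junction_spanning_read_is_exonic(simple_index):
    label = simple_index.classify(frag([(1150, 1200), (2000, 2050)]), "+")
    assert label.category == "exon" and label.gene_id == "A"


def test_largest_overlap_wins_between_genes():
    g1 = ex.GeneModel("A1", "protein_coding", "chr1", "+", [(100, 200)])
    g2 = ex.GeneModel("A2", "protein_coding", "chr1", "+", [(180, 300)])
    idx = ex.AnnotationIndex(ex.GenomeAnnotation([g1, g2]), {"chr1": 1000})
    assert idx.classify(frag([(150, 260)]), "+").gene_id == "A2"  # 50 vs 80 bases
    assert idx.classify(frag([(160, 220)]), "+").gene_id == "A1"  # tie 20/20 -> lexicographic
    assert idx.tie_break_count == 1


def test_classifier_agrees_with_perbase_bruteforce():
    """Interval-index classification must equal the per-base oracle on random
    fragments over random toy annotations."""
    for seed in range(3):
        cfg = ex.SimulationConfig(seed=seed, n_genes=6, n_lncrna=2,
                                  intron_len_range=(200, 800), gap_range=(300, 900))
        ref = ex.build_toy_reference(cfg)
        idx = ex.AnnotationIndex(ref.annotation, ref.sizes)
        naive = NaiveClassifier(ref.annotation, ref.sizes)
        rng = np.random.default_rng(seed + 1000)
        for f in random_fragments(ref, 400, rng):
            tx = ex.infer_transcription_strand(f.read_strand, f.mate_rank, "fr_firststrand")
            assert idx.classify(f, tx) == naive.classify(f, tx)


# -- tallies -----------------------------------------------------------------


def test_tally_unique_starts_and_percentages(simple_index):
    frags = [
        frag([(1020, 1070)], "+", "second", qname="a"),
        frag([(1020, 1070)], "+", "second", qname="b"),  # duplicate start
        frag([(1250, 1300)], "+", "second", qname="c"),  # intron sense (A+)
        frag([(6000, 6050)], "+", "first", qname="d"),  # intergenic
    ]
    counts = ex.tally(frags, simple_index, "fr_firststrand")
    assert counts.n_total_mapq_pass == 4
    assert counts.unique_start_positions == 3
    pct = counts.percentages()
    assert pct["exon_sense"] == 50.0 and pct["intron_sense"] == 25.0 and pct["intergenic"] == 25.0
    counts.check_conservation()


def test_tally_empty_stream(simple_index):
    counts = ex.tally([], simple_index)
    assert counts.n_total_mapq_pass == 0
    assert all(v == 0 for v in counts.category_totals().values())


def test_counts_partition_total_on_simulated_library(small_cfg, small_ref):
    counts, _, _, _, _ = classify_library(small_cfg, small_ref)
    counts.check_conservation()
    assert counts.n_total_mapq_pass == small_cfg.n_reads


def test_protocol_swap_swaps_sense_antisense(small_cfg, small_ref):
    c1, _, _, _, _ = classify_library(small_cfg, small_ref, protocol="fr_firststrand")
    c2, _, _, _, _ = classify_library(small_cfg, small_ref, protocol="fr_secondstrand")
    t1, t2 = c1.category_totals(), c2.category_totals()
    for cat in ("exon", "intron"):
        assert t1[f"{cat}_sense"] == t2[f"{cat}_antisense"]
        assert t1[f"{cat}_antisense"] == t2[f"{cat}_sense"]


def test_sense_fraction_arithmetic_and_undefined():
    counts = ex.CountsTable(per_gene={"G": [0, 0, 82, 18]})
    counts.n_total_mapq_pass = 100
    assert ex.sense_fraction(counts, "intron") == pytest.approx(0.82)
    assert ex.sense_fraction(counts, "exon") is None
    counts_all_anti = ex.CountsTable(per_gene={"G": [0, 5, 0, 0]})
    assert ex.sense_fraction(counts_all_anti, "exon") == 0.0


def test_fragment_pairing_merges_mates(simple_index):
    mates = [
        frag([(1020, 1070)], "-", "first", qname="p1"),
        frag([(1150, 1200)], "+", "second", qname="p1"),
        frag([(6000, 6050)], "+", "first", qname="solo"),
    ]
    merged = sorted(ex.pair_fragments(mates), key=lambda f: f.qname)
    assert [f.qname for f in merged] == ["p1", "solo"]
    assert merged[0].blocks == ((1020, 1070), (1150, 1200))
    assert merged[0].read_strand == "-"  # taken from first mate
    counts = ex.tally(merged, simple_index, "fr_firststrand")
    assert counts.n_total_mapq_pass == 2
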