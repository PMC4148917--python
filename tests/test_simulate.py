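"""Simulator: determinism, ground-truth consistency, analytic expectations."""

import numpy as np
import pytest

import exintron as ex
from helpers import classify_library


def test_reference_is_deterministic(tmp_path):
    cfg = ex.SimulationConfig(seed=1, n_genes=5, n_reads=1000)
    r1, r2 = ex.build_toy_reference(cfg), ex.build_toy_reference(cfg)
    for name, ref in (("a", r1), ("b", r2)):
        ref.write_fasta(tmp_path / f"{name}.fa")
        ref.write_gtf(tmp_path / f"{name}.gtf")
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()
    s1 = list(ex.simulate_library(cfg, r1))
    s2 = list(ex.simulate_library(cfg, r2))
    assert s1 == s2


def test_gtf_contains_requested_genes():
    cfg = ex.SimulationConfig(seed=2, n_genes=3, n_lncrna=0)
    ref = ex.build_toy_reference(cfg)
    biotypes = [g.biotype for g in ref.annotation]
    assert biotypes.count("protein_coding") == 3
    assert biotypes.count("rRNA") == 1
    assert biotypes.count("Mt") == 1  # mitochondrial chromosome gene


def test_exon_sequences_extractable_from_fasta(tmp_path):
    """Annotated exon coordinates round-trip through the written FASTA."""
    import pyfaidx

    cfg = ex.SimulationConfig(seed=3, n_genes=4)
    ref = ex.build_toy_reference(cfg)
    fa_path = tmp_path / "g.fa"
    ref.write_fasta(fa_path)
    fa = pyfaidx.Fasta(str(fa_path))
    for g in ref.annotation:
        for s, e in g.exons:
            assert str(fa[g.chrom][s:e]) == ref.genome[g.chrom][s:e]
            assert len(str(fa[g.chrom][s:e])) == e - s


def test_chrom_len_too_small_raises():
    with pytest.raises(ValueError, match="need >="):
        ex.build_toy_reference(ex.SimulationConfig(seed=1, n_genes=10, chrom_len=5000))


def test_config_validation():
    with pytest.raises(ValueError):
        ex.SimulationConfig(seed=1, premrna_fraction=1.5)
    with pytest.raises(ValueError):
        ex.SimulationConfig(seed=1, rrna_fraction=0.6, mito_fraction=0.6)
    with pytest.raises(ValueError):
        ex.SimulationConfig(seed=1, read_len=100, fragment_len=50)


def test_no_premrna_means_no_intronic_reads(small_ref):
    cfg = ex.SimulationConfig(seed=4, n_genes=8, n_lncrna=3, n_reads=6000,
                              premrna_fraction=0.0)
    ref = ex.build_toy_reference(cfg)
    counts, truths, labels, _, _ = classify_library(cfg, ref)
    assert all(t.source_class != "premrna" for t in truths)
    totals = counts.category_totals()
    assert totals["intron_sense"] + totals["intron_antisense"] == 0


def test_polyA_mode_hard_exclusion():
    cfg0 = ex.SimulationConfig(seed=5, n_genes=10, n_reads=4000)
    ref = ex.build_toy_reference(cfg0)
    excluded = ref.coding_gene_ids[:3]
    cfg = ex.SimulationConfig(seed=5, n_genes=10, n_reads=4000,
                              polyA_mode=True, leakage_rate=0.0,
                              nonpolyA_gene_ids=excluded)
    truths = [t for _, t in ex.simulate_library(cfg, ref)]
    assert all(t.gene_id not in excluded for t in truths if t.source_class in ("mature", "premrna"))


def test_polyA_leakage_downweights():
    cfg0 = ex.SimulationConfig(seed=6, n_genes=10, n_reads=40_000)
    ref = ex.build_toy_reference(cfg0)
    target = ref.coding_gene_ids[0]
    cfg = ex.SimulationConfig(seed=6, n_genes=10, n_reads=40_000,
                              polyA_mode=True, leakage_rate=0.05,
                              nonpolyA_gene_ids=(target,))
    n_full = sum(t.gene_id == target for _, t in ex.simulate_library(cfg0, ref))
    n_leak = sum(t.gene_id == target for _, t in ex.simulate_library(cfg, ref))
    assert 0 < n_leak < 0.2 * n_full


def test_truth_labels_consistent_with_classification(small_cfg, small_ref):
    """Classified exon reads genuinely overlap exons; pre-mRNA reads fully
    inside introns are labelled intron."""
    idx = ex.AnnotationIndex(small_ref.annotation, small_ref.sizes)
    ann = small_ref.annotation
    n_pre_in_intron = n_pre_intron_labelled = 0
    for frag, truth in ex.simulate_library(small_cfg, small_ref):
        tx = ex.infer_transcription_strand(frag.read_strand, frag.mate_rank, "fr_firststrand")
        label = idx.classify(frag, tx)
        if label.category == "exon":
            merged = ann.merged_exons(label.gene_id)
            assert any(merged.overlaps_interval(s, e) for s, e in frag.blocks)
        if truth.source_class == "premrna":
            introns = ann.introns(truth.gene_id)
            if all(introns.contains_interval(s, e) for s, e in frag.blocks):
                n_pre_in_intron += 1
                if label.category == "intron":
                    n_pre_intron_labelled += 1
    assert n_pre_in_intron > 100
    assert n_pre_intron_labelled / n_pre_in_intron >= 0.99


def test_expected_class_fractions_degenerate_cases():
    cfg = ex.SimulationConfig(seed=8, n_genes=6, premrna_fraction=0.0,
                              rrna_fraction=0.0, mito_fraction=0.0, intergenic_fraction=0.0)
    ref = ex.build_toy_reference(cfg)
    exp = ex.expected_class_fractions(cfg, ref)
    assert exp["intron"] == 0.0 and exp["exon"] == pytest.approx(1.0)
    assert exp["rrna"] == 0.0 and exp["mito"] == 0.0


def test_symmetric_two_gene_reference_equal_shares():
    cfg = ex.SimulationConfig(seed=9, n_genes=2, n_lncrna=0, n_reads=40_000,
                              premrna_fraction=0.0,
                              expression_profile={"G0000": 1.0, "G0001": 1.0})
    ref = ex.build_toy_reference(cfg)
    counts = {g: 0 for g in ref.coding_gene_ids}
    n_gene = 0
    for _, t in ex.simulate_library(cfg, ref):
        if t.source_class == "mature":
            counts[t.gene_id] += 1
            n_gene += 1
    share = counts["G0000"] / n_gene
    # per-fragment draw: binomial 3 sigma on n_gene/2 fragments
    sd = np.sqrt(0.25 / (n_gene / 2))
    assert abs(share - 0.5) < 3 * sd


def test_monte_carlo_matches_analytic_fractions():
    """Measured class fractions agree with the closed-form expectation."""
    cfg = ex.SimulationConfig(seed=10, n_reads=60_000, premrna_fraction=0.35)
    ref = ex.build_toy_reference(cfg)
    counts, _, _, _, _ = classify_library(cfg, ref)
    exp, sd = ex.expected_class_fractions(cfg, ref, with_variance=True)
    n = counts.n_total_mapq_pass
    totals = counts.category_totals()
    meas_intron = (totals["intron_sense"] + totals["intron_antisense"]) / n
    assert abs(meas_intron - exp["intron"]) < 3 * sd
    n_frags = n / 2
    for key, meas in (
        ("rrna", counts.n_rRNA / n),
        ("mito", counts.n_mito / n),
        ("intergenic", counts.n_intergenic / n),
    ):
        p = exp[key]
        assert abs(meas - p) < 3 * np.sqrt(p * (1 - p) / n_frags) + 1e-12


def test_intronic_fraction_monotone_in_premrna_weight():
    fracs = []
    for pm in (0.0, 0.4, 0.8):
        cfg = ex.SimulationConfig(seed=12, n_reads=20_000, premrna_fraction=pm)
        ref = ex.build_toy_reference(cfg)
        counts, _, _, _, _ = classify_library(cfg, ref)
        t = counts.category_totals()
        fracs.append((t["intron_sense"] + t["intron_antisense"]) / counts.n_total_mapq_pass)
    assert fracs[0] < fracs[1] < fracs[2]


def test_unpaired_mode():
    cfg = ex.SimulationConfig(seed=14, n_reads=5000, paired=False)
    ref = ex.build_toy_reference(cfg)
    pairs = list(ex.simulate_library(cfg, ref))
    assert len(pairs) == 5000
    assert all(r.mate_rank == "first" for r, _ in pairs)
    counts, _, _, _, _ = classify_library(cfg, ref)
    counts.check_conservation()


def test_sam_and_truth_files_written(tmp_path):
    cfg = ex.SimulationConfig(seed=15, n_reads=2000)
    ref = ex.build_toy_reference(cfg)
    paths = ex.write_library(cfg, ref, tmp_path, "lib")
    reloaded = list(ex.load_alignments(paths["sam"], 1))
    assert len(reloaded) == 2000
    truth_lines = (tmp_path / "lib.truth.tsv").read_text().splitlines()
    assert len(truth_lines) == 2001  # header + one row per read
    assert truth_lines[0].startswith("qname\t")


def test_fastq_export_reverse_complements(tmp_path):
    cfg = ex.SimulationConfig(seed=16, n_reads=200)
    ref = ex.build_toy_reference(cfg)
    reads = [r for r, _ in ex.simulate_library(cfg, ref)]
    fq = tmp_path / "r.fq"
    ex.simulate.reads_to_fastq(reads, ref, fq)
    lines = fq.read_text().splitlines()
    assert len(lines) == 4 * len(reads)
    rec = {lines[i][1:]: lines[i + 1] for i in range(0, len(lines), 4)}
    r0 = reads[0]
    fwd = "".join(ref.genome[r0.chrom][s:e] for s, e in r0.blocks)
    seq = rec[f"{r0.qname}/{1 if r0.mate_rank == 'first' else 2}"]
    if r0.read_strand == "+":
        assert seq == fwd
    else:
        comp = str.maketrans("ACGT", "TGCA")
        assert seq == fwd.translate(comp)[::-1]
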