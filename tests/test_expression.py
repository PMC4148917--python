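"""RPKM, expressed calls, coverage statistics, body profiles, GLog."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import exintron as ex
from exintron.expression import coverage_stats, mean_profile
from helpers import expression_for


# -- RPKM --------------------------------------------------------------------


@pytest.mark.parametrize(
    "count, length, lib, expected",
    [
        (10, 1000, 1_000_000, 10.0),
        (0, 1000, 1_000_000, 0.0),
        (123, 2500, 5_000_000, 9.84),
    ],
)
def test_rpkm_closed_form(count, length, lib, expected):
    assert ex.compute_rpkm(count, length, lib) == pytest.approx(expected)


def test_rpkm_rejects_degenerate_denominators():
    with pytest.raises(ValueError):
        ex.compute_rpkm(1, 0, 1_000_000)
    with pytest.raises(ValueError):
        ex.compute_rpkm(1, 1000, 0)


@settings(max_examples=100, derandomize=True)
@given(
    st.integers(0, 10**6),
    st.integers(1, 10**5),
    st.integers(1, 10**8),
)
def test_rpkm_scale_invariance(count, length, lib):
    """Doubling every count and the library size leaves RPKM unchanged."""
    a = ex.compute_rpkm(count, length, lib)
    b = ex.compute_rpkm(2 * count, length, 2 * lib)
    assert b == pytest.approx(a, rel=1e-12)


# -- GLog --------------------------------------------------------------------


def test_glog_fixed_point_monotone_asymptotic():
    assert ex.glog(0) == 0.0
    grid = np.linspace(0, 1e4, 2001)
    vals = ex.glog(grid)
    assert np.all(np.diff(vals) > 0)
    assert abs(ex.glog(1000) - np.log2(2000)) < 1e-4
    with pytest.raises(ValueError):
        ex.glog(-0.1)


# -- expressed calls ---------------------------------------------------------


def _table(rpkms: dict[str, float], biotype="protein_coding") -> ex.ExpressionTable:
    df = pd.DataFrame(
        {
            "biotype": biotype,
            "exon_count": 0,
            "intron_count": 0,
            "exon_len_bp": 1000,
            "intron_len_bp": 1000,
            "exon_rpkm": pd.Series(rpkms),
            "intron_rpkm": 0.0,
            "covered_fraction": 0.0,
        }
    )
    df.index.name = "gene_id"
    return ex.ExpressionTable("t", 1_000_000, df)


def test_call_expressed_inclusive_bound_and_monotone():
    t = _table({"A": 0.5, "B": 0.49, "C": 3.0, "D": 0.0})
    assert ex.call_expressed(t, 0.5) == {"A", "C"}  # 0.5 is included
    assert ex.call_expressed(t, 0.0) == {"A", "B", "C", "D"}
    for lo, hi in [(0.0, 0.5), (0.5, 1.0), (1.0, 5.0)]:
        assert ex.call_expressed(t, hi) <= ex.call_expressed(t, lo)


def test_call_expressed_empty_on_all_zero():
    t = _table({"A": 0.0, "B": 0.0})
    assert ex.call_expressed(t, 0.5) == set()


# -- coverage profiles -------------------------------------------------------


def test_profile_uniform_depth():
    prof = ex.coverage_profile(np.full(1000, 7.0), 10)
    assert np.allclose(prof, 7.0)


def test_profile_first_decile_plus_strand():
    depth = np.zeros(1000)
    depth[:100] = 4
    prof = ex.coverage_profile(depth, 10, minus_strand=False)
    assert prof[0] == 4 and np.all(prof[1:] == 0)


def test_profile_minus_strand_reverses_orientation():
    depth = np.zeros(1000)
    depth[:100] = 4  # genomic 5' end carries signal
    plus = ex.coverage_profile(depth, 10, minus_strand=False)
    minus = ex.coverage_profile(depth, 10, minus_strand=True)
    assert plus[0] == 4 and minus[-1] == 4 and minus[0] == 0
    assert np.allclose(minus, plus[::-1])


@settings(max_examples=60, derandomize=True)
@given(st.integers(10, 137), st.integers(0, 2**31 - 1))
def test_profile_conserves_total_depth(length, seed):
    """Sum of (bin mean x bin width) equals the total depth in the vector."""
    depth = np.random.default_rng(seed).integers(0, 50, length)
    prof = ex.coverage_profile(depth, 10)
    q, r = divmod(length, 10)
    widths = np.array([q + 1] * r + [q] * (10 - r))
    assert np.isclose((prof * widths).sum(), depth.sum())


def test_profile_rejects_short_features():
    with pytest.raises(ValueError):
        ex.coverage_profile(np.ones(5), 10)


# -- coverage stats ----------------------------------------------------------


def test_coverage_stats_hand_built(two_gene_annotation):
    ann, sizes = two_gene_annotation
    idx = ex.AnnotationIndex(ann, sizes)
    depth = ex.DepthStore(idx)

    def add(blocks, gene):
        f = ex.AlignedFragment("chr1", tuple(blocks), 60, "+", "first", "q")
        depth.add(f, ex.ClassLabel("exon", "sense", gene))

    # A merged exons: (1000,1200)+(2000,2300) = 500 bp; tile fully
    for s in range(1000, 1200, 50):
        add([(s, s + 50)], "A")
    for s in range(2000, 2300, 50):
        add([(s, s + 50)], "A")
    # B merged exons: (1500,1600)+(4000,4200) = 300 bp; one 50 bp read
    add([(1500, 1550)], "B")

    counts = ex.CountsTable(per_gene={"A": [10, 0, 0, 0], "B": [1, 0, 0, 0]})
    counts.n_total_mapq_pass = 1_000_000
    table = ex.build_expression_table("s", counts, ann, depth)
    assert table.df.loc["A", "covered_fraction"] == 1.0
    assert table.df.loc["B", "covered_fraction"] == pytest.approx(50 / 300)

    stats = coverage_stats(table, expressed_threshold=0.5)
    assert stats["n_genes"] == 2
    assert stats["n_100pct_covered"] == 1
    assert stats["n_ge50pct_covered"] == 1  # 100% nests inside >=50%
    assert stats["n_only1read"] == 1
    assert stats["n_ge5_reads"] == 1
    assert stats["n_zero_covered"] == 0


def test_fully_tiled_gene_counts_in_both_nesting_rows():
    # one gene fully tiled, one untouched
    g1 = ex.GeneModel("G1", "protein_coding", "chr1", "+", [(100, 200)])
    g2 = ex.GeneModel("G2", "protein_coding", "chr1", "+", [(500, 600)])
    ann = ex.GenomeAnnotation([g1, g2])
    idx = ex.AnnotationIndex(ann, {"chr1": 1000})
    depth = ex.DepthStore(idx)
    depth.add(ex.AlignedFragment("chr1", ((100, 200),), 60, "+", "first", "q"),
              ex.ClassLabel("exon", "sense", "G1"))
    counts = ex.CountsTable(per_gene={"G1": [1, 0, 0, 0]})
    counts.n_total_mapq_pass = 100
    table = ex.build_expression_table("s", counts, ann, depth)
    stats = coverage_stats(table)
    assert stats["n_100pct_covered"] == 1 and stats["n_ge50pct_covered"] == 1
    assert stats["n_zero_covered"] == 1


# -- exon/intron correlation -------------------------------------------------


def test_correlation_identity_is_one():
    df = pd.DataFrame(
        {
            "biotype": "protein_coding",
            "exon_count": 1,
            "intron_count": 1,
            "exon_len_bp": 1000,
            "intron_len_bp": 1000,
            "exon_rpkm": [1.0, 5.0, 20.0, 80.0],
            "intron_rpkm": [1.0, 5.0, 20.0, 80.0],
            "covered_fraction": 0.0,
        },
        index=["A", "B", "C", "D"],
    )
    t = ex.ExpressionTable("s", 1_000_000, df)
    assert ex.exon_intron_correlation(t) == pytest.approx(1.0)


def test_correlation_undefined_for_degenerate_variance():
    df = pd.DataFrame(
        {
            "biotype": "protein_coding",
            "exon_count": 1,
            "intron_count": 1,
            "exon_len_bp": 1000,
            "intron_len_bp": 1000,
            "exon_rpkm": [2.0, 2.0, 2.0],
            "intron_rpkm": [1.0, 2.0, 3.0],
            "covered_fraction": 0.0,
        },
        index=["A", "B", "C"],
    )
    assert ex.exon_intron_correlation(ex.ExpressionTable("s", 10, df)) is None


def test_independent_values_give_small_r():
    rng = np.random.default_rng(42)
    n = 400
    df = pd.DataFrame(
        {
            "biotype": "protein_coding",
            "exon_count": 1,
            "intron_count": 1,
            "exon_len_bp": 1000,
            "intron_len_bp": 1000,
            "exon_rpkm": 2.0 ** rng.normal(2, 1.5, n),
            "intron_rpkm": 2.0 ** rng.normal(0, 1.5, n),
            "covered_fraction": 0.0,
        },
        index=[f"G{i}" for i in range(n)],
    )
    r = ex.exon_intron_correlation(ex.ExpressionTable("s", 10, df))
    # null band ~ 3/sqrt(n)
    assert abs(r) < 3 / np.sqrt(n)


def test_premrna_coupled_library_correlates():
    """With substantial nuclear carry-over, intronic RPKM tracks exonic RPKM
    gene by gene (pre-mRNA abundance is proportional to transcription)."""
    cfg = ex.SimulationConfig(seed=5, n_genes=30, n_lncrna=0, n_reads=120_000,
                              premrna_fraction=0.4)
    ref = ex.build_toy_reference(cfg)
    table = expression_for(cfg, ref)
    coding = [g for g in ref.coding_gene_ids
              if table.df.loc[g, "intron_len_bp"] > 0]
    r = ex.exon_intron_correlation(table, coding)
    assert r is not None and r > 0.7


def test_expression_table_from_simulation_and_profiles(small_cfg, small_ref):
    table = expression_for(small_cfg, small_ref)
    df = table.df
    assert table.library_size == small_cfg.n_reads
    assert (df["exon_rpkm"] >= 0).all() and df["covered_fraction"].between(0, 1).all()
    # RPKM recomputes from its own columns
    recomputed = df["exon_count"] / (df["exon_len_bp"] / 1000) / (table.library_size / 1e6)
    assert np.allclose(df["exon_rpkm"], recomputed)
    assert all(len(p) == 10 for p in table.profiles.values())
    avg = mean_profile(table.profiles)
    assert len(avg) == 10 and np.all(avg >= 0)
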