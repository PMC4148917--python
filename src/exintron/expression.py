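"""Expression measures: RPKM on merged feature lengths, expressed-gene calls,
coverage statistics, 10-bin gene-body profiles, and the generalized log.

RPKM is computed per gene twice — once against the merged exonic length from
sense exonic hits, once against the non-overlapping intronic length from sense
intronic hits — and normalised by the same library size (all MAPQ-passing
reads), so exonic and intronic signal are directly comparable within a sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .classify import CountsTable, DepthStore


def compute_rpkm(count: int, feature_len_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped (MAPQ-passing) reads."""
    if feature_len_bp <= 0:
        raise ValueError(f"feature length must be > 0, got {feature_len_bp}")
    if library_size <= 0:
        raise ValueError(f"library size must be > 0, got {library_size}")
    return count / (feature_len_bp / 1000.0) / (library_size / 1e6)


def glog(x):
    """Generalized logarithm: log2(x + sqrt(x^2 + 1)).

    A variance-stabilising transform with glog(0) = 0 and
    glog(x) ~ log2(2x) for large x; accepts scalars or arrays, x >= 0.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("glog is defined for non-negative expression values only")
    out = np.log2(arr + np.sqrt(arr * arr + 1.0))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass
class ExpressionTable:
    """Per-gene exon/intron RPKM for one sample.

    ``df`` is indexed by gene_id with columns: biotype, exon_count,
    intron_count, exon_len_bp, intron_len_bp, exon_rpkm, intron_rpkm,
    covered_fraction.  ``profiles`` holds 10-bin gene-body coverage
    profiles (5'→3') for genes long enough to bin.
    """

    sample_id: str
    library_size: int
    df: pd.DataFrame
    profiles: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate gene_ids in expression table")

    def rpkm(self, feature: str = "exon") -> pd.Series:
        return self.df[f"{feature}_rpkm"]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, sample_id: str, library_size: int) -> "ExpressionTable":
        return cls(sample_id, library_size, pd.read_csv(path, sep="\t", index_col="gene_id"))


def build_expression_table(
    sample_id: str,
    counts: CountsTable,
    annotation: GenomeAnnotation,
    depth: DepthStore | None = None,
    n_bins: int = 10,
) -> ExpressionTable:
    """Assemble the per-gene expression table from classified counts.

    Counts used are sense-orientation hits only, consistent with the
    strand-specific protocols; library size is every MAPQ-passing read.
    """
    lib = counts.n_total_mapq_pass
    rows = []
    profiles: dict[str, np.ndarray] = {}
    for g in sorted(annotation, key=lambda g: g.gene_id):
        es, _ea, is_, _ia = counts.gene_counts(g.gene_id)
        exon_len = annotation.merged_exons(g.gene_id).total_length
        intron_len = annotation.introns(g.gene_id).total_length
        covered = 0.0
        if depth is not None:
            d = depth.gene_exon_depth(g.gene_id)
            covered = float(np.count_nonzero(d)) / exon_len
            if exon_len >= n_bins:
                profiles[g.gene_id] = coverage_profile(d, n_bins=n_bins, minus_strand=g.strand == "-")
        rows.append(
            {
                "gene_id": g.gene_id,
                "biotype": g.biotype,
                "exon_count": es,
                "intron_count": is_,
                "exon_len_bp": exon_len,
                "intron_len_bp": intron_len,
                "exon_rpkm": compute_rpkm(es, exon_len, lib) if lib else 0.0,
                "intron_rpkm": compute_rpkm(is_, intron_len, lib) if intron_len and lib else 0.0,
                "covered_fraction": covered,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return ExpressionTable(sample_id, max(lib, 1), df, profiles)


def call_expressed(table: ExpressionTable, threshold: float = 0.5, feature: str = "exon") -> set[str]:
    """Genes with RPKM >= threshold (inclusive bound) on the chosen feature."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    r = table.rpkm(feature)
    return set(r.index[r >= threshold])


def coverage_stats(
    table: ExpressionTable,
    gene_ids=None,
    expressed_threshold: float = 0.5,
) -> dict[str, float]:
    """Transcript-coverage summary over a gene set (Table-2 style rows).

    covered_fraction per gene = exonic bases with depth >= 1 / merged exon
    length; read-count rows use sense exonic hits.
    """
    if gene_ids is None:
        gene_ids = list(table.df.index)
    sub = table.df.loc[list(gene_ids)]
    expressed = sub["exon_rpkm"] >= expressed_threshold
    frac = sub["covered_fraction"]
    reads = sub["exon_count"]
    return {
        "n_genes": len(sub),
        "n_expressed": int(expressed.sum()),
        "mean_covered_fraction": float(frac[expressed].mean()) if expressed.any() else 0.0,
        "n_zero_covered": int((frac == 0).sum()),
        "n_ge50pct_covered": int((frac >= 0.5).sum()),
        "n_100pct_covered": int((frac == 1.0).sum()),
        "n_only1read": int((reads == 1).sum()),
        "n_ge5_reads": int((reads >= 5).sum()),
        "n_ge50_reads": int((reads >= 50).sum()),
        "n_ge100_reads": int((reads >= 100).sum()),
    }


def coverage_profile(depth: np.ndarray, n_bins: int = 10, minus_strand: bool = False) -> np.ndarray:
    """Mean depth in ``n_bins`` bins along the feature body, 5'→3'.

    Bin widths partition the length as evenly as possible (remainder spread
    over the leading bins).  Minus-strand features are reversed first so bin 1
    is the biological 5' end.
    """
    depth = np.asarray(depth)
    if depth.size < n_bins:
        raise ValueError(f"feature length {depth.size} shorter than {n_bins} bins")
    if minus_strand:
        depth = depth[::-1]
    q, r = divmod(depth.size, n_bins)
    widths = np.full(n_bins, q, dtype=int)
    widths[:r] += 1
    edges = np.concatenate([[0], np.cumsum(widths)])
    return np.array([depth[edges[i] : edges[i + 1]].mean() for i in range(n_bins)])


def mean_profile(profiles: dict[str, np.ndarray], gene_ids=None, normalize: bool = True) -> np.ndarray:
    """Across-gene average profile, each gene weighted equally.

    With ``normalize`` each gene's profile is scaled to unit mean first so
    highly expressed genes do not dominate the gene-body shape.
    """
    ids = list(profiles if gene_ids is None else (g for g in gene_ids if g in profiles))
    if not ids:
        raise ValueError("no genes with profiles")
    mat = np.stack([profiles[g] for g in ids]).astype(float)
    if normalize:
        means = mat.mean(axis=1, keepdims=True)
        keep = means[:, 0] > 0
        mat = mat[keep] / means[keep]
    return mat.mean(axis=0)


def exon_intron_correlation(table: ExpressionTable, gene_ids=None) -> float | None:
    """Pearson r of glog(exon RPKM) vs glog(intron RPKM) over a gene filter.

    Default filter: genes with both exonic and intronic length > 0.  Returns
    None (flagged undefined) for degenerate variance or < 3 genes.
    """
    from scipy import stats

    df = table.df
    if gene_ids is None:
        mask = (df["exon_len_bp"] > 0) & (df["intron_len_bp"] > 0)
        sub = df[mask]
    else:
        sub = df.loc[list(gene_ids)]
    if len(sub) < 3:
        return None
    x = glog(sub["exon_rpkm"].to_numpy())
    y = glog(sub["intron_rpkm"].to_numpy())
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
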