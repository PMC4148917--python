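"""Cross-sample analysis: correlations, PCA, and the rule-based filters that
flag non-polyadenylated genes by contrasting rRNA-depleted with poly(A)+
libraries.

The filters are deliberately simple threshold rules (no statistical model):
a protein-coding gene is called non-poly(A) when its mean RPKM in the
rRNA-depleted condition exceeds the poly(A)+ mean by more than ``min_delta``
AND by more than ``min_fc``-fold; an lncRNA is called poly(A)- when it is
essentially absent from poly(A)+ data (RPKM < 0.5) yet detected (>= 1) after
rRNA depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import LNCRNA_BIOTYPES
from .expression import ExpressionTable, call_expressed, glog


@dataclass
class SampleInfo:
    sample_id: str
    extraction: str = ""  # trizol | qiagen | cytoplasmic | nuclear
    selection: str = ""  # polyA | ribozero


def build_sample_matrix(
    tables: Sequence[ExpressionTable],
    feature: str = "exon",
    transform: bool = True,
) -> pd.DataFrame:
    """Genes x samples matrix of (glog-transformed) RPKM.

    All tables must share the gene universe; absent expression is 0 RPKM
    before the transform, so there are no missing cells.
    """
    if len(tables) < 1:
        raise ValueError("need at least one expression table")
    universe = set(tables[0].df.index)
    for t in tables[1:]:
        if set(t.df.index) != universe:
            raise ValueError(f"sample {t.sample_id}: gene universe differs")
    genes = sorted(universe)
    data = {t.sample_id: t.rpkm(feature).reindex(genes).to_numpy() for t in tables}
    mat = pd.DataFrame(data, index=genes)
    return mat.apply(glog) if transform else mat


def pairwise_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation between samples (columns).

    Zero-variance samples yield NaN entries (flagged undefined); the diagonal
    is 1 by definition.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 genes")
    corr = matrix.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Centered SVD of the samples x genes matrix.

    Sign convention: in each component the largest-magnitude gene loading is
    made positive, so coordinates are reproducible across runs.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    X = matrix.to_numpy().T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    n = X.shape[0]
    coords = U * S
    comp_names = [f"PC{i+1}" for i in range(len(S))]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.columns, columns=comp_names),
        explained_variance=S**2 / max(n - 1, 1),
        explained_variance_ratio=(S**2 / S.dot(S)) if S.dot(S) > 0 else np.zeros_like(S),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comp_names),
    )


@dataclass
class FilterResult:
    """Gene set passing a rule-based filter plus per-gene evidence."""

    genes: set[str]
    evidence: pd.DataFrame


def _condition_means(tables: Sequence[ExpressionTable], feature: str = "exon") -> pd.Series:
    if not tables:
        raise ValueError("need at least one table per condition")
    universe = set(tables[0].df.index)
    for t in tables[1:]:
        if set(t.df.index) != universe:
            raise ValueError("gene universes differ between replicates")
    stacked = pd.concat([t.rpkm(feature) for t in tables], axis=1)
    return stacked.mean(axis=1)


def filter_nonpolyA_coding(
    ribo: Sequence[ExpressionTable] | ExpressionTable,
    polyA: Sequence[ExpressionTable] | ExpressionTable,
    min_delta: float = 5.0,
    min_fc: float = 2.0,
) -> FilterResult:
    """Protein-coding genes enriched after rRNA depletion versus poly(A)+.

    Both arms are strict: mean(ribo) - mean(polyA) > min_delta AND
    mean(ribo)/mean(polyA) > min_fc; a poly(A)+ mean of exactly 0 passes the
    fold-change arm outright (no pseudocount).
    """
    ribo_t = [ribo] if isinstance(ribo, ExpressionTable) else list(ribo)
    polyA_t = [polyA] if isinstance(polyA, ExpressionTable) else list(polyA)
    if set(ribo_t[0].df.index) != set(polyA_t[0].df.index):
        raise ValueError("ribo and polyA tables have mismatched gene universes")
    biotype = ribo_t[0].df["biotype"]
    coding = biotype.index[biotype == "protein_coding"]
    rm = _condition_means(ribo_t).loc[coding]
    pm = _condition_means(polyA_t).loc[coding]
    delta = rm - pm
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = rm / pm
    fc_pass = (pm == 0) | (fc > min_fc)
    selected = (delta > min_delta) & fc_pass
    evidence = pd.DataFrame(
        {"ribo_mean_rpkm": rm, "polyA_mean_rpkm": pm, "delta_rpkm": delta, "fold_change": fc, "selected": selected}
    )
    return FilterResult(set(coding[selected]), evidence)


def filter_nonpolyA_lncRNA(
    ribo: Sequence[ExpressionTable] | ExpressionTable,
    polyA: Sequence[ExpressionTable] | ExpressionTable,
    polyA_max: float = 0.5,
    ribo_min: float = 1.0,
) -> FilterResult:
    """lncRNAs absent from poly(A)+ (RPKM < polyA_max, strict) but detected
    after rRNA depletion (RPKM >= ribo_min, inclusive)."""
    ribo_t = [ribo] if isinstance(ribo, ExpressionTable) else list(ribo)
    polyA_t = [polyA] if isinstance(polyA, ExpressionTable) else list(polyA)
    if set(ribo_t[0].df.index) != set(polyA_t[0].df.index):
        raise ValueError("ribo and polyA tables have mismatched gene universes")
    biotype = ribo_t[0].df["biotype"]
    lnc = biotype.index[biotype.isin(LNCRNA_BIOTYPES)]
    rm = _condition_means(ribo_t).loc[lnc]
    pm = _condition_means(polyA_t).loc[lnc]
    selected = (pm < polyA_max) & (rm >= ribo_min)
    evidence = pd.DataFrame(
        {"ribo_mean_rpkm": rm, "polyA_mean_rpkm": pm, "selected": selected}
    )
    return FilterResult(set(lnc[selected]), evidence)


def lncRNA_subtype_tally(table: ExpressionTable, threshold: float = 0.5) -> dict[str, int]:
    """Detected genes (RPKM >= threshold) per lncRNA subtype biotype."""
    expressed = call_expressed(table, threshold)
    out = {bt: 0 for bt in sorted(LNCRNA_BIOTYPES)}
    bt = table.df["biotype"]
    for gid in expressed:
        b = bt.loc[gid]
        if b in out:
            out[b] += 1
    return out


def detection_overlap(tables: Sequence[ExpressionTable], threshold: float = 0.5) -> dict:
    """Set algebra over per-sample expressed-gene calls.

    Returns the genes detected by every sample, those unique to each sample,
    the union, and the per-sample detected sets.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 tables")
    universe = set(tables[0].df.index)
    for t in tables[1:]:
        if set(t.df.index) != universe:
            raise ValueError("gene universes differ between tables")
    detected = {t.sample_id: call_expressed(t, threshold) for t in tables}
    sets = list(detected.values())
    union = set().union(*sets)
    in_all = set.intersection(*sets)
    unique = {
        sid: s - set().union(*(o for other, o in detected.items() if other != sid))
        for sid, s in detected.items()
    }
    return {"detected": detected, "detected_in_all": in_all, "union": union, "unique": unique}


def load_external_de_list(path, probability_min: float = 0.8) -> set[str]:
    """Plug-point for an external differential-expression call list.

    TSV with columns gene_id and probability; genes at or above
    ``probability_min`` are returned.  The differential-expression model
    itself is out of scope here.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "probability"} <= set(df.columns):
        raise ValueError("external DE list needs columns: gene_id, probability")
    return set(df.loc[df["probability"] >= probability_min, "gene_id"])
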