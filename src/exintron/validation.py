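"""End-to-end validation scenarios on synthetic libraries with known truth.

Each function builds its own study conditions (reference, mixture weights,
depth), runs the production pipeline, and returns measured quantities next to
the independent expectation (per-base brute force, closed-form mixture
algebra, binomial error bands).  The scenarios mirror the experimental axes
the pipeline is meant to quantify: nuclear pre-mRNA carry-over drives the
intronic read fraction up and the junction-read fraction down
(cytoplasmic < silica-column rRNA-depleted < TRIzol rRNA-depleted < nuclear),
poly(A)+ selection suppresses non-polyadenylated (histone-like) genes, and
replicate libraries reproduce each other's expression estimates.
"""

from __future__ import annotations

import numpy as np

from . import classify as cls_mod
from . import compare as cmp_mod
from . import expression as expr_mod
from . import junctions as junc_mod
from .classify import AnnotationIndex, CountsTable, DepthStore
from .naive import NaiveClassifier, naive_junction_support
from .simulate import SimulationConfig, build_toy_reference, expected_class_fractions, simulate_library

#: z-quantile of the two-sided 99% binomial confidence interval
Z99 = 2.5758293035489004


def _run_library(cfg, ref, protocol="fr_firststrand", junction_seed=5, with_depth=False):
    """Stream one simulated library through classify + junction counting."""
    idx = AnnotationIndex(ref.annotation, ref.sizes)
    jindex = junc_mod.index_junctions(junc_mod.known_junctions(ref.annotation))
    depth = DepthStore(idx) if with_depth else None
    counts = CountsTable()
    starts = set()
    n_junc = 0
    intron_frag_total: dict[str, int] = {}
    intron_frag_sense: dict[str, int] = {}
    for frag, truth in simulate_library(cfg, ref):
        tx = cls_mod.infer_transcription_strand(frag.read_strand, frag.mate_rank, protocol)
        label = idx.classify(frag, tx)
        counts.n_total_mapq_pass += 1
        starts.add((frag.chrom, frag.start_pos, frag.read_strand))
        cat = label.category
        if cat in ("exon", "intron"):
            g = counts.per_gene.setdefault(label.gene_id, [0, 0, 0, 0])
            g[(0 if cat == "exon" else 2) + (0 if label.orientation == "sense" else 1)] += 1
            if depth is not None:
                depth.add(frag, label)
            if cat == "intron":
                intron_frag_total[frag.qname] = intron_frag_total.get(frag.qname, 0) + 1
                if label.orientation == "sense":
                    intron_frag_sense[frag.qname] = intron_frag_sense.get(frag.qname, 0) + 1
        elif cat == "intergenic":
            counts.n_intergenic += 1
        elif cat == "rRNA":
            counts.n_rRNA += 1
        elif cat == "mito":
            counts.n_mito += 1
        else:
            counts.n_unclassified += 1
        if junc_mod.read_junction_support(frag, jindex, junction_seed):
            n_junc += 1
    counts.unique_start_positions = len(starts)
    counts.check_conservation()
    return counts, n_junc, len(intron_frag_total), depth


# ---------------------------------------------------------------------------


def classifier_oracle_agreement(seed: int, n_instances: int = 20, n_fragments: int = 1000) -> dict:
    """Interval-index classifier vs per-base brute force on random toy
    instances (small dense genes, random single and spliced fragments)."""
    n_total = n_agree = 0
    for i in range(n_instances):
        cfg = SimulationConfig(
            seed=seed + i, n_genes=4, n_lncrna=1, read_len=20, fragment_len=60,
            exons_per_gene=(3, 5), exon_len_range=(30, 80),
            intron_len_range=(50, 200), gap_range=(80, 200),
        )
        ref = build_toy_reference(cfg)
        idx = AnnotationIndex(ref.annotation, ref.sizes)
        naive = NaiveClassifier(ref.annotation, ref.sizes)
        rng = np.random.default_rng([seed + i, 77])
        clen = ref.sizes[ref.main_chrom]
        for k in range(n_fragments):
            s = int(rng.integers(0, clen - 600))
            if rng.random() < 0.35:
                l1 = int(rng.integers(4, 25))
                gap = int(rng.integers(20, 400))
                l2 = int(rng.integers(4, 25))
                blocks = ((s, s + l1), (s + l1 + gap, s + l1 + gap + l2))
            else:
                blocks = ((s, s + int(rng.integers(15, 30))),)
            frag = cls_mod.AlignedFragment(
                ref.main_chrom, blocks, 60,
                "+" if rng.random() < 0.5 else "-",
                "first" if rng.random() < 0.5 else "second", f"r{k}",
            )
            tx = cls_mod.infer_transcription_strand(frag.read_strand, frag.mate_rank, "fr_firststrand")
            n_total += 1
            if idx.classify(frag, tx) == naive.classify(frag, tx):
                n_agree += 1
    return {"n_total": n_total, "n_agree": n_agree, "agreement_pct": 100.0 * n_agree / n_total}


def partition_conservation(seed: int, n_libraries: int = 4, n_reads: int = 30_000) -> dict:
    """Category counts must sum exactly to the MAPQ-passing total in every
    simulated library across the mixture grid."""
    n_checked = 0
    for i, pm in enumerate(np.linspace(0, 1, n_libraries)):
        cfg = SimulationConfig(seed=seed + i, n_reads=n_reads, premrna_fraction=float(pm))
        ref = build_toy_reference(cfg)
        counts, _, _, _ = _run_library(cfg, ref)  # check_conservation raises on violation
        assert counts.n_total_mapq_pass == n_reads
        n_checked += 1
    return {"n_libraries": n_checked, "all_conserved": True}


def mixture_recovery(seed: int, n_reads: int = 200_000,
                     grid=(0.0, 0.2, 0.4, 0.7, 1.0)) -> dict:
    """Measured intronic fraction vs the closed-form expectation over the
    pre-mRNA weight grid; junction fraction must fall as the weight rises."""
    rows = []
    for pm in grid:
        cfg = SimulationConfig(seed=seed, n_reads=n_reads, premrna_fraction=pm)
        ref = build_toy_reference(cfg)
        counts, n_junc, _, _ = _run_library(cfg, ref)
        exp, sd = expected_class_fractions(cfg, ref, with_variance=True)
        t = counts.category_totals()
        meas = (t["intron_sense"] + t["intron_antisense"]) / counts.n_total_mapq_pass
        z = (meas - exp["intron"]) / sd if sd > 0 else 0.0
        rows.append({
            "premrna_fraction": pm,
            "intron_fraction_measured": meas,
            "intron_fraction_expected": exp["intron"],
            "sd": sd,
            "z": z,
            "junction_read_fraction": n_junc / counts.n_total_mapq_pass,
        })
    meas = [r["intron_fraction_measured"] for r in rows]
    junc = [r["junction_read_fraction"] for r in rows]
    return {
        "rows": rows,
        "n_reads": n_reads,
        "max_abs_z": max(abs(r["z"]) for r in rows),
        "intron_strictly_increasing": all(a < b for a, b in zip(meas, meas[1:])),
        "junction_strictly_decreasing": all(a > b for a, b in zip(junc, junc[1:])),
    }


def sense_fraction_recovery(seed: int, sense_fraction: float = 0.82,
                            n_reads: int = 160_000) -> dict:
    """Recover the orientation-fidelity parameter from classified intronic
    reads.  Orientation flips are per fragment, so the binomial CI uses the
    number of intronic fragments, not reads (a conservative lower bound)."""
    cfg = SimulationConfig(seed=seed, n_reads=n_reads, premrna_fraction=0.7,
                           sense_fraction=sense_fraction)
    ref = build_toy_reference(cfg)
    counts, _, n_intron_frags, _ = _run_library(cfg, ref)
    recovered = cls_mod.sense_fraction(counts, "intron")
    t = counts.category_totals()
    n_intron_reads = t["intron_sense"] + t["intron_antisense"]
    half_width = Z99 * np.sqrt(sense_fraction * (1 - sense_fraction) / n_intron_frags)
    return {
        "target": sense_fraction,
        "recovered": recovered,
        "n_intron_reads": n_intron_reads,
        "n_intron_fragments": n_intron_frags,
        "ci99_half_width": half_width,
        "within_ci": abs(recovered - sense_fraction) <= half_width,
    }


def planted_nonpolyA_detection(seed: int, n_ordinary: int = 500, n_planted: int = 40,
                               n_reads: int = 1_000_000, n_replicates: int = 2) -> dict:
    """Plant non-polyadenylated coding genes, sequence paired poly(A)+ and
    rRNA-depleted libraries, and ask the delta/fold-change filter to find
    exactly the planted set."""
    n_genes = n_ordinary + n_planted
    base = dict(n_genes=n_genes, n_lncrna=10, n_reads=n_reads)
    ref = build_toy_reference(SimulationConfig(seed=seed, **base))
    planted = tuple(ref.coding_gene_ids[:n_planted])

    def tables_for(selection: str):
        out = []
        for rep in range(n_replicates):
            if selection == "polyA":
                cfg = SimulationConfig(seed=seed + 100 + rep, **base,
                                       premrna_fraction=0.05, rrna_fraction=0.003,
                                       mito_fraction=0.045, intergenic_fraction=0.022,
                                       polyA_mode=True, leakage_rate=0.05,
                                       nonpolyA_gene_ids=planted)
            else:
                cfg = SimulationConfig(seed=seed + 200 + rep, **base,
                                       premrna_fraction=0.25, rrna_fraction=0.0002,
                                       mito_fraction=0.004, intergenic_fraction=0.028)
            counts, _, _, _ = _run_library(cfg, ref)
            out.append(expr_mod.build_expression_table(f"{selection}{rep}", counts, ref.annotation))
        return out

    polyA_tables = tables_for("polyA")
    ribo_tables = tables_for("ribozero")
    res = cmp_mod.filter_nonpolyA_coding(ribo_tables, polyA_tables, min_delta=5.0, min_fc=2.0)
    planted_set = set(planted)
    found = res.genes
    ribo_means = res.evidence.loc[list(planted), "ribo_mean_rpkm"]
    return {
        "n_planted": n_planted,
        "n_ordinary": n_ordinary,
        "n_reads_per_library": n_reads,
        "min_planted_ribo_rpkm": float(ribo_means.min()),
        "sensitivity": len(found & planted_set) / n_planted,
        "false_positives": len(found - planted_set),
    }


def junction_seed_rule(seed: int, n_reads: int = 1000) -> dict:
    """Seed-rule boundary behaviour plus brute-force recount agreement on
    simulated spliced reads."""
    jset = {junc_mod.Junction("chr1", 99, 200, "+")}
    jidx = junc_mod.index_junctions(jset)

    def support(blocks):
        frag = cls_mod.AlignedFragment("chr1", blocks, 60, "+", "first", "q")
        return bool(junc_mod.read_junction_support(frag, jidx, 5))

    boundary_ok = (
        support(((95, 100), (200, 210)))  # exactly 5 donor bases
        and not support(((96, 100), (200, 210)))  # 4 donor bases
        and not support(((90, 100), (200, 204)))  # 4 acceptor bases
    )

    cfg = SimulationConfig(seed=seed, n_reads=n_reads, premrna_fraction=0.3)
    ref = build_toy_reference(cfg)
    juncs = junc_mod.known_junctions(ref.annotation)
    reads = [r for r, _ in simulate_library(cfg, ref)]
    jc = junc_mod.count_junction_reads(reads, juncs, 5)
    brute = {j: sum(naive_junction_support(r, j, 5) for r in reads) for j in juncs}
    agree = sum(jc.counts[j] == brute[j] for j in juncs)
    return {
        "boundary_cases_ok": boundary_ok,
        "n_junctions": len(juncs),
        "n_junctions_agreeing": agree,
        "agreement_pct": 100.0 * agree / len(juncs),
        "n_reads": len(reads),
    }


def replicate_correlation(seed: int, n_reads: int = 500_000) -> dict:
    """Two replicates of the same truth with independent sampling noise must
    reproduce each other's glog(RPKM) almost perfectly at deep coverage."""
    base = dict(n_genes=20, n_lncrna=6, n_reads=n_reads, premrna_fraction=0.15)
    ref = build_toy_reference(SimulationConfig(seed=seed, **base))
    tables = []
    for rep in range(2):
        cfg = SimulationConfig(seed=seed + 300 + rep, **base)
        counts, _, _, _ = _run_library(cfg, ref)
        tables.append(expr_mod.build_expression_table(f"rep{rep + 1}", counts, ref.annotation))
    corr = cmp_mod.pairwise_correlation(cmp_mod.build_sample_matrix(tables))
    return {"pearson_r": float(corr.loc["rep1", "rep2"]), "n_reads_per_replicate": n_reads}


def rpkm_closed_form() -> dict:
    """Unit definition and scale invariance of the RPKM formula."""
    value = expr_mod.compute_rpkm(10, 1000, 1_000_000)
    doubled = expr_mod.compute_rpkm(20, 1000, 2_000_000)
    return {
        "rpkm_10_1000_1e6": value,
        "scale_invariant": abs(value - doubled) < 1e-15,
    }
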