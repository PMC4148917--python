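"""Shared test utilities: small simulation drivers and per-base oracles."""

from __future__ import annotations

import numpy as np

import exintron as ex
from exintron import junctions as junc_mod


def classify_library(cfg, ref, protocol="fr_firststrand", with_depth=False, junction_seed=5):
    """Simulate a library in memory and run the full classify/junction pass.

    Returns (counts, truths, labels, junction_counts, depth).
    """
    idx = ex.AnnotationIndex(ref.annotation, ref.sizes)
    juncs = ex.known_junctions(ref.annotation)
    jindex = junc_mod.index_junctions(juncs)
    depth = ex.DepthStore(idx) if with_depth else None

    counts = ex.CountsTable()
    truths, labels = [], []
    starts = set()
    n_junc = 0
    for frag, truth in ex.simulate_library(cfg, ref):
        tx = ex.infer_transcription_strand(frag.read_strand, frag.mate_rank, protocol)
        label = idx.classify(frag, tx)
        truths.append(truth)
        labels.append(label)
        counts.n_total_mapq_pass += 1
        starts.add((frag.chrom, frag.start_pos, frag.read_strand))
        if label.category in ("exon", "intron"):
            g = counts.per_gene.setdefault(label.gene_id, [0, 0, 0, 0])
            col = (0 if label.category == "exon" else 2) + (0 if label.orientation == "sense" else 1)
            g[col] += 1
            if depth is not None:
                depth.add(frag, label)
        elif label.category == "intergenic":
            counts.n_intergenic += 1
        elif label.category == "rRNA":
            counts.n_rRNA += 1
        elif label.category == "mito":
            counts.n_mito += 1
        else:
            counts.n_unclassified += 1
        if junc_mod.read_junction_support(frag, jindex, junction_seed):
            n_junc += 1
    counts.unique_start_positions = len(starts)
    return counts, truths, labels, n_junc, depth


def expression_for(cfg, ref, sample_id="s"):
    counts, _, _, _, depth = classify_library(cfg, ref, with_depth=True)
    return ex.build_expression_table(sample_id, counts, ref.annotation, depth)


def random_fragments(ref, n, rng, spliced_fraction=0.3, read_len=51):
    """Uniform random single/spliced fragments over the main chromosome."""
    clen = ref.sizes[ref.main_chrom]
    out = []
    for i in range(n):
        s = int(rng.integers(0, clen - 5000))
        if rng.random() < spliced_fraction:
            l1 = int(rng.integers(5, read_len))
            gap = int(rng.integers(50, 3000))
            l2 = int(rng.integers(5, read_len))
            blocks = ((s, s + l1), (s + l1 + gap, s + l1 + gap + l2))
        else:
            blocks = ((s, s + read_len),)
        out.append(
            ex.AlignedFragment(
                ref.main_chrom,
                blocks,
                60,
                "+" if rng.random() < 0.5 else "-",
                "first" if rng.random() < 0.5 else "second",
                f"r{i}",
            )
        )
    return out


def interval_bases(intervals):
    bases = set()
    for s, e in intervals:
        bases.update(range(s, e))
    return bases
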