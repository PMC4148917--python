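"""Stream MAPQ-filtered alignments and partition them into read classes.

Each read (or pair, in fragment mode) gets exactly one label out of
{mito, rRNA, exon, intron, intergenic, unclassified}, applied in that
precedence order:

1. mitochondrial chromosome wins outright;
2. any aligned block overlapping an rRNA-biotype gene's merged exons → rRNA;
3. any block overlapping any merged exon → exon (gene with the largest
   overlap; junction-spanning reads are exonic by construction);
4. ALL blocks completely inside one gene's non-overlapping introns → intron;
5. ALL blocks completely inside intergenic space → intergenic;
6. otherwise unclassified (e.g. straddling a gene boundary).

Intron/intergenic labels require full containment; exon labels require only
a single base of overlap.  Orientation (sense/antisense) is the transcription
strand inferred from the strand-specific protocol versus the host gene strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import numpy as np
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation
from .intervals import IntervalSet

log = logging.getLogger(__name__)

Strand = Literal["+", "-"]
Protocol = Literal["fr_firststrand", "fr_secondstrand", "unstranded"]

DEFAULT_MITO_CHROMS = frozenset({"chrM", "MT", "M"})

CATEGORIES = ("exon", "intron", "intergenic", "rRNA", "mito", "unclassified")


@dataclass(frozen=True)
class AlignedFragment:
    """One mapped read (or pair-collapsed fragment) as aligned genomic blocks."""

    chrom: str
    blocks: tuple[tuple[int, int], ...]
    mapq: int
    read_strand: Strand
    mate_rank: Literal["first", "second"] = "first"
    qname: str = ""

    @property
    def start_pos(self) -> int:
        return self.blocks[0][0]

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass(frozen=True)
class ClassLabel:
    category: str
    orientation: Literal["sense", "antisense", "not_applicable"]
    gene_id: str | None = None


def blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Aligned reference blocks; N splits blocks, D extends, I/S/H/P are skipped."""
    blocks: list[tuple[int, int]] = []
    cur_start, cur = pos, pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            cur += length
        elif op == 3:  # N: splice gap
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        elif op in (1, 4, 5, 6):  # I, S, H, P
            continue
        else:
            raise ValueError(f"unsupported CIGAR operation code {op}")
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return tuple(blocks)


def load_alignments(path: str | Path, mapq_min: int = 1) -> Iterator[AlignedFragment]:
    """Stream primary, mapped, MAPQ-filtered records from SAM/BAM via pysam."""
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"record {rec.query_name}: missing CIGAR")
            blocks = blocks_from_cigar(rec.reference_start, rec.cigartuples)
            if not blocks:
                raise ValueError(f"record {rec.query_name}: CIGAR consumes no reference")
            yield AlignedFragment(
                chrom=rec.reference_name,
                blocks=blocks,
                mapq=rec.mapping_quality,
                read_strand="-" if rec.is_reverse else "+",
                mate_rank="second" if rec.is_read2 else "first",
                qname=rec.query_name,
            )


def pair_fragments(frags: Iterable[AlignedFragment]) -> Iterator[AlignedFragment]:
    """Collapse mates sharing a query name into one fragment (union of blocks).

    Fragment-level counting mode; the transcription strand is inferred from the
    first mate.  Mates on different chromosomes are passed through unpaired.
    """
    from .intervals import merge_intervals

    pending: dict[str, AlignedFragment] = {}
    for f in frags:
        other = pending.pop(f.qname, None)
        if other is None:
            pending[f.qname] = f
            continue
        if other.chrom != f.chrom:
            yield other
            yield f
            continue
        first = f if f.mate_rank == "first" else other
        merged = tuple(merge_intervals(list(f.blocks) + list(other.blocks)))
        yield AlignedFragment(
            chrom=f.chrom,
            blocks=merged,
            mapq=min(f.mapq, other.mapq),
            read_strand=first.read_strand,
            mate_rank="first",
            qname=f.qname,
        )
    yield from pending.values()


def infer_transcription_strand(
    read_strand: Strand, mate_rank: str, protocol: Protocol
) -> str:
    """Map alignment orientation to the transcribed strand for the protocol.

    Under the dUTP-style ``fr_firststrand`` chemistry the first mate aligns
    antisense to the transcript; ``fr_secondstrand`` is the mirror image.
    """
    if protocol == "unstranded":
        return "unknown"
    flip = (protocol == "fr_firststrand") == (mate_rank == "first")
    if flip:
        return "-" if read_strand == "+" else "+"
    return read_strand


class AnnotationIndex:
    """Per-chromosome overlap/containment indexes over the derived partitions."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        sizes: Mapping[str, int],
        mito_chroms: Iterable[str] = DEFAULT_MITO_CHROMS,
    ):
        self.annotation = annotation
        self.sizes = dict(sizes)
        self.mito_chroms = frozenset(mito_chroms)
        self.gene_strand = {g.gene_id: g.strand for g in annotation}
        self.tie_break_count = 0

        self._exon_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._rrna_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intron_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._gene_introns: dict[str, IntervalSet] = {}
        self._gene_merged: dict[str, IntervalSet] = {}

        for g in annotation:
            merged = annotation.merged_exons(g.gene_id)
            self._gene_merged[g.gene_id] = merged
            for s, e in merged:
                self._exon_tree[g.chrom].addi(s, e, g.gene_id)
                if g.biotype == "rRNA":
                    self._rrna_tree[g.chrom].addi(s, e, g.gene_id)
            introns = annotation.introns(g.gene_id)
            self._gene_introns[g.gene_id] = introns
            for s, e in introns:
                self._intron_tree[g.chrom].addi(s, e, g.gene_id)

        self._intergenic: dict[str, IntervalSet] = annotation.intergenic(self.sizes)

    # -- queries ------------------------------------------------------------

    def classify(self, frag: AlignedFragment, tx_strand: str) -> ClassLabel:
        chrom = frag.chrom
        if chrom in self.mito_chroms:
            return ClassLabel("mito", "not_applicable")

        exon_tree = self._exon_tree.get(chrom)
        if exon_tree is not None:
            rrna_tree = self._rrna_tree.get(chrom)
            if rrna_tree:
                for s, e in frag.blocks:
                    if rrna_tree.overlap(s, e):
                        hit = min(iv.data for iv in rrna_tree.overlap(s, e))
                        return ClassLabel("rRNA", self._orient(tx_strand, hit), hit)
            overlap_bp: dict[str, int] = {}
            for s, e in frag.blocks:
                for iv in exon_tree.overlap(s, e):
                    overlap_bp[iv.data] = overlap_bp.get(iv.data, 0) + min(e, iv.end) - max(s, iv.begin)
            if overlap_bp:
                best = max(overlap_bp.values())
                winners = sorted(gid for gid, bp in overlap_bp.items() if bp == best)
                if len(winners) > 1:
                    self.tie_break_count += 1
                    log.debug("exon overlap tie between %s; keeping %s", winners, winners[0])
                gid = winners[0]
                return ClassLabel("exon", self._orient(tx_strand, gid), gid)

        intron_tree = self._intron_tree.get(chrom)
        if intron_tree is not None:
            s0, e0 = frag.blocks[0]
            candidates = sorted({iv.data for iv in intron_tree.overlap(s0, e0)})
            for gid in candidates:
                iset = self._gene_introns[gid]
                if all(iset.contains_interval(s, e) for s, e in frag.blocks):
                    return ClassLabel("intron", self._orient(tx_strand, gid), gid)

        inter = self._intergenic.get(chrom)
        if inter is not None and all(inter.contains_interval(s, e) for s, e in frag.blocks):
            return ClassLabel("intergenic", "not_applicable")

        return ClassLabel("unclassified", "not_applicable")

    def _orient(self, tx_strand: str, gene_id: str) -> str:
        # unknown transcription strand (unstranded protocol) counts as sense
        if tx_strand == "unknown":
            return "sense"
        return "sense" if tx_strand == self.gene_strand[gene_id] else "antisense"


@dataclass
class CountsTable:
    """Per-gene stranded hit counts plus per-sample tallies (Table-1 style)."""

    per_gene: dict[str, list[int]] = field(default_factory=dict)  # [es, ea, is, ia]
    n_total_mapq_pass: int = 0
    n_intergenic: int = 0
    n_rRNA: int = 0
    n_mito: int = 0
    n_unclassified: int = 0
    unique_start_positions: int = 0

    GENE_COLS = ("exon_sense", "exon_antisense", "intron_sense", "intron_antisense")

    def gene_counts(self, gene_id: str) -> list[int]:
        return self.per_gene.get(gene_id, [0, 0, 0, 0])

    def category_totals(self) -> dict[str, int]:
        es = ea = is_ = ia = 0
        for c in self.per_gene.values():
            es += c[0]
            ea += c[1]
            is_ += c[2]
            ia += c[3]
        return {
            "exon_sense": es,
            "exon_antisense": ea,
            "intron_sense": is_,
            "intron_antisense": ia,
            "intergenic": self.n_intergenic,
            "rRNA": self.n_rRNA,
            "mito": self.n_mito,
            "unclassified": self.n_unclassified,
        }

    def check_conservation(self) -> None:
        if sum(self.category_totals().values()) != self.n_total_mapq_pass:
            raise AssertionError("category counts do not partition n_total_mapq_pass")

    def percentages(self) -> dict[str, float]:
        """Category percentages of all MAPQ-passing reads."""
        n = self.n_total_mapq_pass
        if n == 0:
            return {k: 0.0 for k in self.category_totals()}
        return {k: 100.0 * v / n for k, v in self.category_totals().items()}

    def to_frame(self):
        import pandas as pd

        rows = {gid: dict(zip(self.GENE_COLS, c)) for gid, c in self.per_gene.items()}
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
        if df.empty:
            df = pd.DataFrame(columns=list(self.GENE_COLS), dtype=int)
        df.index.name = "gene_id"
        return df.sort_index()

    def summary(self) -> dict:
        out = {
            "n_total_mapq_pass": self.n_total_mapq_pass,
            "unique_start_positions": self.unique_start_positions,
            **{f"n_{k}": v for k, v in self.category_totals().items()},
        }
        out.update({f"pct_{k}": v for k, v in self.percentages().items()})
        return out


class DepthStore:
    """Per-gene base depth over merged exons and introns (sense reads only).

    Depth arrays are concatenations of the gene's feature intervals in genomic
    order; offsets map genomic coordinates into the arrays.
    """

    def __init__(self, index: AnnotationIndex):
        self._index = index
        self.exon_depth: dict[str, np.ndarray] = {}
        self.intron_depth: dict[str, np.ndarray] = {}

    def _ensure(self, store, gid, iset):
        if gid not in store:
            store[gid] = np.zeros(iset.total_length, dtype=np.int32)
        return store[gid]

    def add(self, frag: AlignedFragment, label: ClassLabel) -> None:
        if label.orientation != "sense" or label.gene_id is None:
            return
        if label.category == "exon":
            iset = self._index._gene_merged[label.gene_id]
            depth = self._ensure(self.exon_depth, label.gene_id, iset)
        elif label.category == "intron":
            iset = self._index._gene_introns[label.gene_id]
            depth = self._ensure(self.intron_depth, label.gene_id, iset)
        else:
            return
        off = 0
        for fs, fe in iset:
            for bs, be in frag.blocks:
                s, e = max(bs, fs), min(be, fe)
                if s < e:
                    depth[off + s - fs : off + e - fs] += 1
            off += fe - fs

    def gene_exon_depth(self, gene_id: str) -> np.ndarray:
        iset = self._index._gene_merged[gene_id]
        return self.exon_depth.get(gene_id, np.zeros(iset.total_length, dtype=np.int32))

    def gene_intron_depth(self, gene_id: str) -> np.ndarray:
        iset = self._index._gene_introns[gene_id]
        return self.intron_depth.get(gene_id, np.zeros(iset.total_length, dtype=np.int32))


def tally(
    frags: Iterable[AlignedFragment],
    index: AnnotationIndex,
    protocol: Protocol = "fr_firststrand",
    depth: DepthStore | None = None,
) -> CountsTable:
    """Classify a stream of fragments and accumulate the counts table."""
    counts = CountsTable()
    starts: set[tuple[str, int, str]] = set()
    per_gene = counts.per_gene
    for frag in frags:
        tx = infer_transcription_strand(frag.read_strand, frag.mate_rank, protocol)
        label = index.classify(frag, tx)
        counts.n_total_mapq_pass += 1
        starts.add((frag.chrom, frag.start_pos, frag.read_strand))
        cat = label.category
        if cat == "exon" or cat == "intron":
            g = per_gene.get(label.gene_id)
            if g is None:
                g = per_gene[label.gene_id] = [0, 0, 0, 0]
            col = (0 if cat == "exon" else 2) + (0 if label.orientation == "sense" else 1)
            g[col] += 1
            if depth is not None:
                depth.add(frag, label)
        elif cat == "intergenic":
            counts.n_intergenic += 1
        elif cat == "rRNA":
            counts.n_rRNA += 1
        elif cat == "mito":
            counts.n_mito += 1
        else:
            counts.n_unclassified += 1
    counts.unique_start_positions = len(starts)
    counts.check_conservation()
    return counts


def sense_fraction(counts: CountsTable, category: Literal["exon", "intron"]) -> float | None:
    """Fraction of reads in `category` oriented with their host gene.

    Returns None (flagged undefined) when no reads fall in the category.
    """
    t = counts.category_totals()
    sense = t[f"{category}_sense"]
    anti = t[f"{category}_antisense"]
    if sense + anti == 0:
        return None
    return sense / (sense + anti)
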