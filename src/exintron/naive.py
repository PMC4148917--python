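"""Slow per-base reference implementations used for validation.

These deliberately avoid the interval algebra and index structures of the
production code path: classification is decided by explicit membership of
every covered base in per-base sets, so agreement between the two routes is a
meaningful check.  Only usable on toy chromosomes (memory is O(genome)).
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .annotation import GenomeAnnotation
from .classify import AlignedFragment, ClassLabel, DEFAULT_MITO_CHROMS


def interval_bases(intervals: Iterable[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in intervals:
        out.update(range(s, e))
    return out


class NaiveClassifier:
    """Per-base brute-force classifier applying the same precedence rules."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        sizes: Mapping[str, int],
        mito_chroms=DEFAULT_MITO_CHROMS,
    ):
        self.mito_chroms = frozenset(mito_chroms)
        self.gene_strand = {g.gene_id: g.strand for g in annotation}
        self.exon_bases: dict[str, dict[str, set[int]]] = {}  # chrom -> gene -> bases
        self.rrna_bases: dict[str, set[int]] = {}
        self.intron_bases: dict[str, dict[str, set[int]]] = {}
        self.intergenic_bases: dict[str, set[int]] = {}
        for g in annotation:
            bases = interval_bases(annotation.merged_exons(g.gene_id))
            self.exon_bases.setdefault(g.chrom, {})[g.gene_id] = bases
            if g.biotype == "rRNA":
                self.rrna_bases.setdefault(g.chrom, set()).update(bases)
            self.intron_bases.setdefault(g.chrom, {})[g.gene_id] = interval_bases(
                annotation.introns(g.gene_id)
            )
        for chrom, iset in annotation.intergenic(sizes).items():
            self.intergenic_bases[chrom] = interval_bases(iset)

    def classify(self, frag: AlignedFragment, tx_strand: str) -> ClassLabel:
        if frag.chrom in self.mito_chroms:
            return ClassLabel("mito", "not_applicable")
        covered = interval_bases(frag.blocks)

        rrna = self.rrna_bases.get(frag.chrom, set())
        if covered & rrna:
            gid = min(
                g for g, b in self.exon_bases[frag.chrom].items()
                if (covered & rrna) & b
            )
            return ClassLabel("rRNA", self._orient(tx_strand, gid), gid)

        overlaps = {
            gid: len(covered & bases)
            for gid, bases in self.exon_bases.get(frag.chrom, {}).items()
            if covered & bases
        }
        if overlaps:
            best = max(overlaps.values())
            gid = min(g for g, n in overlaps.items() if n == best)
            return ClassLabel("exon", self._orient(tx_strand, gid), gid)

        for gid in sorted(self.intron_bases.get(frag.chrom, {})):
            if covered <= self.intron_bases[frag.chrom][gid]:
                return ClassLabel("intron", self._orient(tx_strand, gid), gid)

        if covered <= self.intergenic_bases.get(frag.chrom, set()):
            return ClassLabel("intergenic", "not_applicable")
        return ClassLabel("unclassified", "not_applicable")

    def _orient(self, tx_strand: str, gene_id: str) -> str:
        if tx_strand == "unknown":
            return "sense"
        return "sense" if tx_strand == self.gene_strand[gene_id] else "antisense"


def naive_junction_support(frag: AlignedFragment, junction, seed: int = 5) -> bool:
    """Per-base reading of the seed rule: the read covers the last ``seed``
    donor-side exonic bases and the first ``seed`` acceptor-side bases, and no
    base of the bridged intron."""
    if junction.chrom != frag.chrom:
        return False
    covered = interval_bases(frag.blocks)
    donor = set(range(junction.donor_end - seed + 1, junction.donor_end + 1))
    acceptor = set(range(junction.acceptor_start, junction.acceptor_start + seed))
    intron = set(range(junction.donor_end + 1, junction.acceptor_start))
    return donor <= covered and acceptor <= covered and not (intron & covered)
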