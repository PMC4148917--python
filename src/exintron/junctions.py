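"""Splice-junction read counting against annotated junctions.

A junction is a unique genomic (chrom, donor_end, acceptor_start) triple taken
from consecutive exons of annotated transcripts.  A spliced read supports a
junction when two consecutive aligned blocks bridge exactly that intron and
the read anchors at least ``seed`` bases on each side (default 5).  The
per-sample junction-read fraction — supporting reads over all MAPQ-passing
reads — tracks how much mature, spliced RNA a library contains.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from .annotation import GenomeAnnotation
from .classify import AlignedFragment


class Junction(NamedTuple):
    chrom: str
    donor_end: int  # last exonic base before the intron, 0-based
    acceptor_start: int  # first exonic base after the intron
    strand: str


@dataclass
class JunctionCounts:
    counts: dict[Junction, int]
    n_junction_reads: int  # reads supporting >= 1 known junction
    n_total_reads: int

    @property
    def junction_read_fraction(self) -> float:
        return self.n_junction_reads / self.n_total_reads if self.n_total_reads else 0.0

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tdonor_end\tacceptor_start\tname\tcount\tstrand\n")
            for j in sorted(self.counts):
                fh.write(
                    f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\t"
                    f"{j.chrom}:{j.donor_end}-{j.acceptor_start}\t{self.counts[j]}\t{j.strand}\n"
                )


def known_junctions(annotation: GenomeAnnotation) -> set[Junction]:
    """Distinct consecutive-exon boundaries across all transcripts.

    Junctions shared between transcripts collapse to one (unique genome
    position); single-exon transcripts contribute none.
    """
    by_pos: dict[tuple[str, int, int], Junction] = {}
    for g in annotation:
        for exons in g.transcripts.values():
            ordered = sorted(exons)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 > e1:  # overlapping/adjacent exons give no junction
                    key = (g.chrom, e1 - 1, s2)
                    if key not in by_pos:
                        by_pos[key] = Junction(g.chrom, e1 - 1, s2, g.strand)
    return set(by_pos.values())


def index_junctions(junctions: Iterable[Junction]) -> dict[tuple[str, int, int], Junction]:
    """Lookup table keyed by genome position (strand is annotation only)."""
    return {(j.chrom, j.donor_end, j.acceptor_start): j for j in junctions}


def read_junction_support(
    frag: AlignedFragment,
    junction_index: dict[tuple[str, int, int], Junction],
    seed: int = 5,
) -> list[Junction]:
    """Known junctions this read supports under the seed rule."""
    hits = []
    for (s1, e1), (s2, e2) in zip(frag.blocks, frag.blocks[1:]):
        j = junction_index.get((frag.chrom, e1 - 1, s2))
        if j is not None and e1 - s1 >= seed and e2 - s2 >= seed:
            hits.append(j)
    return hits


def count_junction_reads(
    frags: Iterable[AlignedFragment],
    junctions: set[Junction],
    seed: int = 5,
    n_total_reads: int | None = None,
) -> JunctionCounts:
    """Tally per-junction supporting reads and the sample junction fraction.

    A read spanning two junctions counts once toward the sample total but
    increments both junctions' individual counts.
    """
    if seed < 1:
        raise ValueError("seed must be >= 1")
    jindex = index_junctions(junctions)
    counts: Counter = Counter({j: 0 for j in junctions})
    n_support = 0
    n_seen = 0
    for frag in frags:
        n_seen += 1
        hits = read_junction_support(frag, jindex, seed)
        if hits:
            n_support += 1
            for j in hits:
                counts[j] += 1
    return JunctionCounts(dict(counts), n_support, n_total_reads if n_total_reads is not None else n_seen)


def load_junctions_tsv(path: str | Path) -> set[Junction]:
    out = set()
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "chrom")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path} line {i}: expected 6 columns")
        out.add(Junction(f[0], int(f[1]), int(f[2]), f[5]))
    return out
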