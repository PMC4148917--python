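"""Gene annotation parsing and derivation of the genomic counting partition.

The pipeline counts reads against three disjoint feature spaces per chromosome:

* **merged exons** — per gene, the union of all its transcripts' exons;
* **non-overlapping introns** — per gene, the gaps between its merged exons
  minus *every* gene's merged exons on that chromosome (BEDTools-subtract
  semantics), so an exon of gene B inside an intron of gene A never counts as
  intronic space;
* **intergenic** — per chromosome, the complement of all gene spans
  (min exon start .. max exon end).

Input is GTF (1-based closed, converted on read) or BED12 (already 0-based
half-open).  Internally everything is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .intervals import IntervalSet, merge_intervals, subtract_intervals

log = logging.getLogger(__name__)

#: Canonical biotype labels; GTF values are normalised onto these.
BIOTYPES = (
    "protein_coding",
    "processed_transcript",
    "lincRNA",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "three_prime_overlapping_ncrna",
    "non_coding",
    "rRNA",
    "Mt",
    "other",
)

LNCRNA_BIOTYPES = frozenset(
    {
        "processed_transcript",
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "three_prime_overlapping_ncrna",
        "non_coding",
    }
)

_BIOTYPE_ALIASES = {
    "3prime_overlapping_ncrna": "three_prime_overlapping_ncrna",
    "3prime_overlapping_ncRNA": "three_prime_overlapping_ncrna",
    "Mt_rRNA": "Mt",
    "Mt_tRNA": "Mt",
    "rRNA_pseudogene": "rRNA",
}


def normalize_biotype(raw: str) -> str:
    raw = _BIOTYPE_ALIASES.get(raw, raw)
    return raw if raw in BIOTYPES else "other"


@dataclass
class GeneModel:
    """One gene: strand, biotype, and exon intervals pooled over transcripts."""

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    #: per-transcript exon lists (needed for splice-junction derivation)
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: bad exon ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length)."""
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path} line {i}: expected 'chrom\\tlength'")
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: length not an integer: {parts[1]!r}") from exc
        if length <= 0:
            raise ValueError(f"{path} line {i}: length must be > 0")
        sizes[parts[0]] = length
    return sizes


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


class GenomeAnnotation:
    """Gene models plus cached derived partitions."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._merged: dict[str, IntervalSet] = {}
        self._exon_union: dict[str, list[tuple[int, int]]] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def chroms(self) -> list[str]:
        return sorted({g.chrom for g in self})

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self if g.chrom == chrom]

    # -- derived partitions -------------------------------------------------

    def merged_exons(self, gene_id: str) -> IntervalSet:
        if gene_id not in self._merged:
            g = self.genes[gene_id]
            self._merged[gene_id] = IntervalSet.from_raw(g.chrom, g.exons)
        return self._merged[gene_id]

    def exon_union_by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        """Merged union of ALL genes' exons, per chromosome."""
        if self._exon_union is None:
            pooled: dict[str, list[tuple[int, int]]] = {}
            for g in self:
                pooled.setdefault(g.chrom, []).extend(g.exons)
            self._exon_union = {c: merge_intervals(ivs) for c, ivs in pooled.items()}
        return self._exon_union

    def introns(self, gene_id: str) -> IntervalSet:
        """Non-overlapping introns: inter-exon gaps minus all exonic space."""
        g = self.genes[gene_id]
        merged = self.merged_exons(gene_id).intervals
        gaps = [
            (merged[i][1], merged[i + 1][0]) for i in range(len(merged) - 1)
        ]
        if not gaps:
            return IntervalSet(g.chrom, ())
        all_exons = self.exon_union_by_chrom()[g.chrom]
        return IntervalSet(g.chrom, tuple(subtract_intervals(gaps, all_exons)))

    def intergenic(self, sizes: Mapping[str, int]) -> dict[str, IntervalSet]:
        """Per-chromosome complement of all gene spans (covers every chrom in sizes)."""
        spans: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
        for g in self:
            if g.chrom not in sizes:
                raise ValueError(f"chromosome {g.chrom} present in annotation but missing from sizes")
            spans[g.chrom].append(g.span)
        out = {}
        for chrom, ivs in spans.items():
            comp = subtract_intervals([(0, sizes[chrom])], ivs)
            out[chrom] = IntervalSet(chrom, tuple(comp))
        return out

    # -- export -------------------------------------------------------------

    def write_partition_bed6(self, path: str | Path, sizes: Mapping[str, int]) -> None:
        """Export merged exons, introns and intergenic space as BED6."""
        lines = []
        for g in sorted(self, key=lambda g: (g.chrom, g.span)):
            for s, e in self.merged_exons(g.gene_id):
                lines.append((g.chrom, s, e, f"{g.gene_id}|exon", g.strand))
            for s, e in self.introns(g.gene_id):
                lines.append((g.chrom, s, e, f"{g.gene_id}|intron", g.strand))
        for chrom, iset in self.intergenic(sizes).items():
            for s, e in iset:
                lines.append((chrom, s, e, "intergenic", "."))
        with open(path, "w") as fh:
            for chrom, s, e, name, strand in sorted(lines):
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}\n")


def parse_annotation(
    path: str | Path,
    chrom_whitelist: set[str] | None = None,
) -> GenomeAnnotation:
    """Read a GTF or BED12 annotation into a :class:`GenomeAnnotation`.

    Records on chromosomes outside ``chrom_whitelist`` are silently dropped
    (the reference analysis restricts itself to the primary assembly);
    genes left with zero exons are excluded with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _parse_bed12(path, chrom_whitelist)
    return _parse_gtf(path, chrom_whitelist)


def _parse_gtf(path: Path, whitelist: set[str] | None) -> GenomeAnnotation:
    exons: dict[str, GeneModel] = {}
    seen_gene_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path} line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_field = fields
            if whitelist is not None and chrom not in whitelist:
                continue
            attrs = _parse_gtf_attributes(attr_field)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path} line {lineno}: record lacks gene_id attribute")
            if feature == "gene":
                seen_gene_ids.add(gene_id)
            if feature != "exon":
                continue
            try:
                s, e = int(start) - 1, int(end)  # GTF is 1-based closed
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates") from exc
            if s < 0 or s >= e:
                raise ValueError(f"{path} line {lineno}: bad exon coordinates {start}-{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path} line {lineno}: bad strand {strand!r}")
            biotype = normalize_biotype(attrs.get("gene_biotype", attrs.get("gene_type", "other")))
            tx_id = attrs.get("transcript_id", f"{gene_id}.t")
            g = exons.get(gene_id)
            if g is None:
                g = GeneModel(gene_id, biotype, chrom, strand, [(s, e)], {tx_id: [(s, e)]})
                exons[gene_id] = g
            else:
                if g.chrom != chrom or g.strand != strand:
                    raise ValueError(
                        f"{path} line {lineno}: gene {gene_id} spans multiple chroms/strands"
                    )
                g.exons.append((s, e))
                g.transcripts.setdefault(tx_id, []).append((s, e))
    for gid in seen_gene_ids - set(exons):
        log.warning("gene %s has no exons after filtering; excluded", gid)
    return GenomeAnnotation(exons.values())


def _parse_bed12(path: Path, whitelist: set[str] | None) -> GenomeAnnotation:
    """BED12, one transcript per line; name is 'gene_id' or 'gene_id|biotype'."""
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path} line {lineno}: BED12 needs 12 fields, got {len(f)}")
            chrom = f[0]
            if whitelist is not None and chrom not in whitelist:
                continue
            try:
                tx_start = int(f[1])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: malformed BED12 numeric field") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path} line {lineno}: blockCount disagrees with block lists")
            name, _, biotype = f[3].partition("|")
            strand = f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path} line {lineno}: bad strand {strand!r}")
            ex = [(tx_start + o, tx_start + o + sz) for o, sz in zip(starts, sizes)]
            tx_id = f"{name}.L{lineno}"
            g = genes.get(name)
            if g is None:
                genes[name] = GeneModel(
                    name, normalize_biotype(biotype or "other"), chrom, strand, list(ex), {tx_id: ex}
                )
            else:
                if g.chrom != chrom or g.strand != strand:
                    raise ValueError(f"{path} line {lineno}: gene {name} spans multiple chroms/strands")
                g.exons.extend(ex)
                g.transcripts[tx_id] = ex
    return GenomeAnnotation(genes.values())
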