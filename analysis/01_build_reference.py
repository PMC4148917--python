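#!/usr/bin/env python
"""Build the synthetic study reference and export its counting partition.

Writes the toy genome annotation (GTF), chromosome sizes, and the derived
merged-exon / non-overlapping-intron / intergenic partition (BED6), and
prints the per-class base totals the later read-partitioning rests on.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, build_reference


def main() -> None:
    ref = build_reference()
    outdir = RESULTS / "reference"
    outdir.mkdir(parents=True, exist_ok=True)
    ref.write_gtf(outdir / "annotation.gtf")
    ref.write_sizes(outdir / "chrom.sizes.tsv")
    ref.annotation.write_partition_bed6(outdir / "partition.bed", ref.sizes)

    ann = ref.annotation
    exon_bp = sum(ann.merged_exons(g.gene_id).total_length for g in ann)
    intron_bp = sum(ann.introns(g.gene_id).total_length for g in ann)
    inter_bp = sum(s.total_length for s in ann.intergenic(ref.sizes).values())
    n_junc = len(__import__("exintron").known_junctions(ann))

    print(f"reference: {len(ann)} genes on {ref.sizes['chr1']:,} bp chr1 + chrM")
    print(f"  merged exons: {exon_bp:,} bp; non-overlapping introns: {intron_bp:,} bp; "
          f"intergenic: {inter_bp:,} bp")
    print(f"  known splice junctions: {n_junc}")
    print(f"wrote {outdir}/annotation.gtf, chrom.sizes.tsv, partition.bed")


if __name__ == "__main__":
    main()
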