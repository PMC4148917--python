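"""End-to-end orchestration: annotation -> classify -> expression ->
junctions -> cross-sample comparison, driven by a single YAML/JSON config.

Every run writes the exact parameter set next to its outputs so Table-1-style
comparisons are reproducible from the frozen config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann_mod
from . import classify as cls_mod
from . import compare as cmp_mod
from . import expression as expr_mod
from . import junctions as junc_mod

log = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    id: str
    path: str
    extraction: str = ""  # trizol | qiagen | cytoplasmic | nuclear
    selection: str = ""  # polyA | ribozero


@dataclass
class RunConfig:
    samples: list[SampleSpec]
    annotation: str
    chrom_sizes: str
    outdir: str
    seed: int = 0
    mapq_min: int = 1
    strand_protocol: str = "fr_firststrand"
    count_unit: str = "read"  # read | fragment
    mito_chroms: tuple[str, ...] = tuple(sorted(cls_mod.DEFAULT_MITO_CHROMS))
    chrom_whitelist: tuple[str, ...] | None = None
    expressed_rpkm: float = 0.5
    min_delta: float = 5.0
    min_fc: float = 2.0
    lnc_polyA_max: float = 0.5
    lnc_ribo_min: float = 1.0
    junction_seed: int = 5

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        raw.pop("comment", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mito_chroms", "chrom_whitelist"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(samples=samples, **raw)


def validate(config: RunConfig) -> list[str]:
    """Return a list of violations (empty = ok); unusual values only warn."""
    violations: list[str] = []
    ids = [s.id for s in config.samples]
    if len(ids) != len(set(ids)):
        violations.append("samples: duplicate sample id")
    if not config.samples:
        violations.append("samples: at least one sample required")
    for s in config.samples:
        if not s.path:
            violations.append(f"samples[{s.id}]: missing alignment path")
        elif not Path(s.path).exists():
            violations.append(f"samples[{s.id}]: alignment file not found: {s.path}")
    for key in ("annotation", "chrom_sizes"):
        p = getattr(config, key)
        if not p:
            violations.append(f"{key}: missing path")
        elif not Path(p).exists():
            violations.append(f"{key}: file not found: {p}")
    if config.strand_protocol not in ("fr_firststrand", "fr_secondstrand", "unstranded"):
        violations.append(f"strand_protocol: unknown protocol {config.strand_protocol!r}")
    if config.count_unit not in ("read", "fragment"):
        violations.append(f"count_unit: must be 'read' or 'fragment'")
    if config.mapq_min < 0:
        violations.append("mapq_min: must be >= 0")
    elif config.mapq_min == 0:
        log.warning("mapq_min=0 keeps multi-mapping reads; proceeding")
    if config.junction_seed < 1:
        violations.append("junction_seed: must be >= 1")
    return violations


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns a manifest of written artifacts."""
    problems = validate(config)
    if problems:
        raise ValueError("invalid run config:\n  " + "\n  ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, object] = {}

    def _stage(name: str, sample: str | None = None):
        label = f"{name}" + (f"[{sample}]" if sample else "")
        log.info("stage %s", label)
        return label

    whitelist = set(config.chrom_whitelist) if config.chrom_whitelist else None
    try:
        t0 = time.time()
        annotation = ann_mod.parse_annotation(config.annotation, whitelist)
        sizes = ann_mod.read_chrom_sizes(config.chrom_sizes)
        index = cls_mod.AnnotationIndex(annotation, sizes, config.mito_chroms)
        junctions = junc_mod.known_junctions(annotation)
        log.info("annotation: %d genes, %d junctions (%.1fs)", len(annotation), len(junctions), time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage annotate failed: {exc}") from exc

    tables: list[expr_mod.ExpressionTable] = []
    infos: list[cmp_mod.SampleInfo] = []
    metrics_rows = []
    for spec in config.samples:
        label = _stage("classify", spec.id)
        try:
            t0 = time.time()
            frags = cls_mod.load_alignments(spec.path, config.mapq_min)
            if config.count_unit == "fragment":
                frags = cls_mod.pair_fragments(frags)
            frags = list(frags)
            depth = cls_mod.DepthStore(index)
            counts = cls_mod.tally(frags, index, config.strand_protocol, depth)
            counts.to_frame().to_csv(outdir / f"{spec.id}.counts.tsv", sep="\t")
            summary = counts.summary()
            summary["sample_id"] = spec.id
            summary["sense_fraction_intron"] = cls_mod.sense_fraction(counts, "intron")
            summary["sense_fraction_exon"] = cls_mod.sense_fraction(counts, "exon")
            metrics_rows.append(summary)

            table = expr_mod.build_expression_table(spec.id, counts, annotation, depth)
            table.to_tsv(outdir / f"{spec.id}.expression.tsv")
            cov = expr_mod.coverage_stats(table, expressed_threshold=config.expressed_rpkm)
            pd.Series(cov).to_csv(outdir / f"{spec.id}.coverage.tsv", sep="\t", header=False)
            if table.profiles:
                prof = pd.DataFrame(table.profiles).T
                prof.columns = [f"bin{i+1}" for i in range(prof.shape[1])]
                prof.to_csv(outdir / f"{spec.id}.profiles.tsv", sep="\t", index_label="gene_id")

            jc = junc_mod.count_junction_reads(
                frags, junctions, config.junction_seed, counts.n_total_mapq_pass
            )
            jc.write_tsv(outdir / f"{spec.id}.junctions.tsv")
            summary["n_junction_reads"] = jc.n_junction_reads
            summary["junction_read_fraction"] = jc.junction_read_fraction
            tables.append(table)
            infos.append(cmp_mod.SampleInfo(spec.id, spec.extraction, spec.selection))
            log.info("%s: %d reads (%.1fs)", label, counts.n_total_mapq_pass, time.time() - t0)
        except Exception as exc:
            raise RuntimeError(f"stage {label} failed: {exc}") from exc

    metrics = pd.DataFrame(metrics_rows).set_index("sample_id")
    metrics.to_csv(outdir / "sample_metrics.tsv", sep="\t")
    metrics.to_json(outdir / "sample_metrics.json", orient="index", indent=2)
    manifest["sample_metrics"] = str(outdir / "sample_metrics.tsv")

    if len(tables) >= 2:
        label = _stage("compare")
        try:
            matrix = cmp_mod.build_sample_matrix(tables)
            cmp_mod.pairwise_correlation(matrix).to_csv(outdir / "correlation.tsv", sep="\t")
            if len(tables) >= 3:
                res = cmp_mod.pca(matrix)
                coords = res.coordinates.copy()
                coords["explained_variance_ratio"] = res.explained_variance_ratio
                coords.to_csv(outdir / "pca.tsv", sep="\t")
            overlap = cmp_mod.detection_overlap(tables, config.expressed_rpkm)
            with open(outdir / "detection_overlap.tsv", "w") as fh:
                fh.write(f"detected_in_all\t{len(overlap['detected_in_all'])}\t"
                         + ",".join(sorted(overlap["detected_in_all"])) + "\n")
                for sid, s in overlap["unique"].items():
                    fh.write(f"unique_to_{sid}\t{len(s)}\t" + ",".join(sorted(s)) + "\n")

            ribo = [t for t, i in zip(tables, infos) if i.selection == "ribozero"]
            polyA = [t for t, i in zip(tables, infos) if i.selection == "polyA"]
            if ribo and polyA:
                fr = cmp_mod.filter_nonpolyA_coding(ribo, polyA, config.min_delta, config.min_fc)
                fr.evidence.to_csv(outdir / "nonpolyA_coding.tsv", sep="\t", index_label="gene_id")
                fl = cmp_mod.filter_nonpolyA_lncRNA(ribo, polyA, config.lnc_polyA_max, config.lnc_ribo_min)
                fl.evidence.to_csv(outdir / "nonpolyA_lncRNA.tsv", sep="\t", index_label="gene_id")
        except Exception as exc:
            raise RuntimeError(f"stage compare failed: {exc}") from exc

    params = asdict(config)
    (outdir / "run_params.json").write_text(json.dumps(params, indent=2, default=list) + "\n")
    manifest["run_params"] = str(outdir / "run_params.json")
    manifest["outdir"] = str(outdir)
    manifest["n_samples"] = len(tables)
    return manifest
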