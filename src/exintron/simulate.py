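"""Synthetic stranded paired-end RNA-seq libraries with per-read ground truth.

The generator emulates the experimental axes of an extraction/selection
comparison: a library is a mixture of

* **mature** fragments sampled from spliced transcripts (mapped back to the
  genome with N-split CIGARs),
* **pre-mRNA** fragments sampled uniformly from unspliced gene spans — the
  nuclear-RNA knob (``premrna_fraction``), the source of intronic reads,
* **rRNA** fragments from an rRNA-biotype gene (poly(A)+ libraries retain a
  trace, rRNA-depleted libraries almost none),
* **mitochondrial** fragments (chrM), and
* **intergenic** fragments.

Poly(A)+ selection is modelled by ``polyA_mode``: designated non-poly(A)
genes (histone-like) are down-weighted to ``leakage_rate`` of their abundance,
mimicking the residual polyadenylated histone transcripts that escape 3'-end
processing.  ``sense_fraction`` sets the orientation fidelity of pre-mRNA
fragments; flips are per fragment (both mates carry the same cDNA strand).

Reads are emitted as already-aligned SAM records (alignment itself is outside
the pipeline's scope); every read carries a ground-truth row.  Everything is
deterministic under ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .annotation import GeneModel, GenomeAnnotation
from .classify import AlignedFragment

_CLASS_NAMES = ("mature", "premrna", "rrna", "mito", "intergenic")


@dataclass
class SimulationConfig:
    """Generative parameters for one library.

    Fractions are of fragments; ``n_reads`` counts reads (two per fragment in
    paired mode).  Defaults mirror a poly(A)+-like total-RNA library: 51-base
    reads, a log-normal expression profile spanning several orders of
    magnitude, ~0.3% rRNA carry-over, a few percent mitochondrial and
    intergenic signal, and 82% sense fidelity of intronic fragments.
    """

    seed: int = 0
    n_genes: int = 20
    n_lncrna: int = 6
    chrom_len: int | None = None  # None: fit to the generated layout
    mito_len: int = 16000
    read_len: int = 51
    fragment_len: int = 180
    n_reads: int = 100_000
    paired: bool = True
    premrna_fraction: float = 0.2
    sense_fraction: float = 0.82
    rrna_fraction: float = 0.003
    mito_fraction: float = 0.03
    intergenic_fraction: float = 0.025
    polyA_mode: bool = False
    leakage_rate: float = 0.05
    nonpolyA_gene_ids: tuple[str, ...] = ()
    expression_profile: dict[str, float] | None = None  # per-gene weight override
    log2_mean: float = 1.0  # log-normal expression profile, log2 scale
    log2_sd: float = 1.5
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len_range: tuple[int, int] = (120, 300)
    intron_len_range: tuple[int, int] = (500, 3000)
    gap_range: tuple[int, int] = (800, 2000)

    def __post_init__(self):
        for name in ("premrna_fraction", "sense_fraction", "rrna_fraction",
                     "mito_fraction", "intergenic_fraction", "leakage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rrna_fraction + self.mito_fraction + self.intergenic_fraction > 1.0:
            raise ValueError("rrna + mito + intergenic fractions exceed 1")
        if self.read_len < 1 or self.fragment_len < self.read_len:
            raise ValueError("need fragment_len >= read_len >= 1")

    def class_probs(self) -> dict[str, float]:
        gene_mass = 1.0 - self.rrna_fraction - self.mito_fraction - self.intergenic_fraction
        return {
            "mature": gene_mass * (1.0 - self.premrna_fraction),
            "premrna": gene_mass * self.premrna_fraction,
            "rrna": self.rrna_fraction,
            "mito": self.mito_fraction,
            "intergenic": self.intergenic_fraction,
        }

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)


class SimTruth(NamedTuple):
    """Ground-truth provenance of one simulated read."""

    qname: str
    mate_rank: str
    source_class: str  # mature | premrna | rrna | mito | intergenic
    gene_id: str  # "" for mito/intergenic
    true_strand: str
    junctions: tuple[tuple[int, int], ...]  # (donor_end, acceptor_start) spanned


@dataclass
class ToyReference:
    """In-memory toy genome + annotation, writable as FASTA/GTF/TSV."""

    annotation: GenomeAnnotation
    sizes: dict[str, int]
    genome: dict[str, str]
    gene_weights: dict[str, float]  # relative abundances, coding + lncRNA genes
    main_chrom: str
    mito_chrom: str
    rrna_gene_id: str
    coding_gene_ids: tuple[str, ...]
    lnc_gene_ids: tuple[str, ...]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sizes):
                fh.write(f"{chrom}\t{self.sizes[chrom]}\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.annotation, key=lambda g: (g.chrom, g.span)):
                gs, ge = g.span
                attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
                fh.write(f"{g.chrom}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n")
                for tx_id, exons in g.transcripts.items():
                    ts = min(s for s, _ in exons) + 1
                    te = max(e for _, e in exons)
                    txa = f'{attrs} transcript_id "{tx_id}";'
                    fh.write(f"{g.chrom}\tsim\ttranscript\t{ts}\t{te}\t.\t{g.strand}\t.\t{txa}\n")
                    for s, e in sorted(exons):
                        fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{txa}\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def build_toy_reference(cfg: SimulationConfig) -> ToyReference:
    """Lay out multi-exon genes on both strands with intergenic gaps, one
    rRNA gene, and a mitochondrial chromosome; deterministic under seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    if cfg.n_genes < 1:
        raise ValueError("need n_genes >= 1")

    specs: list[tuple[str, str]] = [(f"G{i:04d}", "protein_coding") for i in range(cfg.n_genes)]
    lnc_subtypes = ("lincRNA", "antisense", "processed_transcript",
                    "sense_intronic", "sense_overlapping", "non_coding")
    specs += [(f"L{i:03d}", lnc_subtypes[i % len(lnc_subtypes)]) for i in range(cfg.n_lncrna)]
    rrna_id = "RRNA1"
    specs.append((rrna_id, "rRNA"))
    order = rng.permutation(len(specs))

    genes: list[GeneModel] = []
    pos = int(rng.integers(*cfg.gap_range))
    for idx in order:
        gid, biotype = specs[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "rRNA":
            exlens = [max(1500, cfg.fragment_len)]
        else:
            lo, hi = cfg.exons_per_gene
            n_ex = int(rng.integers(max(2, lo), hi + 1))
            exlens = list(rng.integers(*cfg.exon_len_range, size=n_ex))
            while sum(exlens) < cfg.fragment_len:  # transcript must hold a fragment
                exlens.append(int(rng.integers(*cfg.exon_len_range)))
        inlens = list(rng.integers(*cfg.intron_len_range, size=len(exlens) - 1))
        exons = []
        p = pos
        for i, el in enumerate(exlens):
            exons.append((p, p + int(el)))
            p += int(el)
            if i < len(inlens):
                p += int(inlens[i])
        tx_id = f"{gid}.t1"
        genes.append(GeneModel(gid, biotype, "chr1", strand, list(exons), {tx_id: list(exons)}))
        pos = p + int(rng.integers(*cfg.gap_range))

    required = pos + 200
    if cfg.chrom_len is None:
        chrom_len = required
    elif cfg.chrom_len < required:
        raise ValueError(f"chrom_len={cfg.chrom_len} too small for layout; need >= {required}")
    else:
        chrom_len = cfg.chrom_len

    mito_gene = GeneModel("MTG1", "Mt", "chrM", "+",
                          [(100, cfg.mito_len - 100)], {"MTG1.t1": [(100, cfg.mito_len - 100)]})
    genes.append(mito_gene)

    ann = GenomeAnnotation(genes)
    sizes = {"chr1": chrom_len, "chrM": cfg.mito_len}
    genome = {"chr1": _random_seq(rng, chrom_len), "chrM": _random_seq(rng, cfg.mito_len)}

    coding = tuple(g for g, b in specs if b == "protein_coding")
    lnc = tuple(g for g, b in specs if b not in ("protein_coding", "rRNA"))
    weighted = coding + lnc
    weights = dict(zip(weighted, 2.0 ** rng.normal(cfg.log2_mean, cfg.log2_sd, len(weighted))))
    return ToyReference(ann, sizes, genome, weights, "chr1", "chrM", rrna_id, coding, lnc)


# ---------------------------------------------------------------------------
# sampling machinery


class _GeneSampler:
    """Precomputed per-gene layout arrays shared by the simulator and the
    closed-form class-fraction oracle."""

    def __init__(self, cfg: SimulationConfig, ref: ToyReference):
        self.cfg = cfg
        self.ref = ref
        ann = ref.annotation
        self.gene_ids = list(ref.coding_gene_ids + ref.lnc_gene_ids)
        self.exons = []
        self.cumlen = []
        self.txlen = np.zeros(len(self.gene_ids), dtype=np.int64)
        self.span_start = np.zeros(len(self.gene_ids), dtype=np.int64)
        self.span_len = np.zeros(len(self.gene_ids), dtype=np.int64)
        self.strand = []
        for i, gid in enumerate(self.gene_ids):
            merged = ann.merged_exons(gid).intervals
            self.exons.append(merged)
            cl = np.cumsum([e - s for s, e in merged])
            self.cumlen.append(cl)
            self.txlen[i] = cl[-1]
            g = ann.genes[gid]
            self.span_start[i], end = g.span
            self.span_len[i] = end - self.span_start[i]
            self.strand.append(g.strand)
        if np.any(self.txlen < cfg.fragment_len):
            raise ValueError("a gene's transcript is shorter than fragment_len")

        w = np.array([ref.gene_weights[g] for g in self.gene_ids], dtype=float)
        if cfg.expression_profile:
            for gid, wt in cfg.expression_profile.items():
                w[self.gene_ids.index(gid)] = wt
        if cfg.polyA_mode:
            non = set(cfg.nonpolyA_gene_ids)
            for i, gid in enumerate(self.gene_ids):
                if gid in non:
                    w[i] *= cfg.leakage_rate
        if w.sum() <= 0:
            raise ValueError("all gene weights are zero")
        self.weights = w / w.sum()

        rr = ann.genes[ref.rrna_gene_id]
        self.rrna_exon = ann.merged_exons(ref.rrna_gene_id).intervals[0]
        self.rrna_strand = rr.strand

        inter = ann.intergenic(ref.sizes)[ref.main_chrom].intervals
        F = cfg.fragment_len
        usable = [(s, e) for s, e in inter if e - s >= F]
        if not usable and cfg.intergenic_fraction > 0:
            raise ValueError("no intergenic interval can hold a fragment")
        self.inter_ivs = usable
        self.inter_w = np.array([e - s - F + 1 for s, e in usable], dtype=float)
        if self.inter_w.size:
            self.inter_w /= self.inter_w.sum()

    def tx_to_blocks(self, gi: int, a: int, b: int) -> tuple[tuple[int, int], ...]:
        """Map transcript-coordinate interval [a, b) to genomic blocks."""
        exons, cum = self.exons[gi], self.cumlen[gi]
        blocks = []
        i = int(np.searchsorted(cum, a, side="right"))
        off = a - (cum[i - 1] if i else 0)
        pos = exons[i][0] + off
        remaining = b - a
        while remaining > 0:
            avail = exons[i][1] - pos
            take = min(avail, remaining)
            blocks.append((int(pos), int(pos + take)))
            remaining -= take
            i += 1
            if remaining > 0:
                pos = exons[i][0]
        return tuple(blocks)


def _opp(strand: str) -> str:
    return "-" if strand == "+" else "+"


def simulate_library(
    cfg: SimulationConfig, ref: ToyReference, chunk: int = 65536
) -> Iterator[tuple[AlignedFragment, SimTruth]]:
    """Yield (read, truth) pairs; reads come mate1-then-mate2 per fragment.

    Strand flags follow the dUTP-style fr_firststrand convention: the first
    mate aligns antisense to the (possibly flipped) transcription strand.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    sampler = _GeneSampler(cfg, ref)
    L, F = cfg.read_len, cfg.fragment_len
    reads_per_frag = 2 if cfg.paired else 1
    n_frags = cfg.n_reads // reads_per_frag

    probs = cfg.class_probs()
    pvec = np.array([probs[c] for c in _CLASS_NAMES])
    mito_len = ref.sizes[ref.mito_chrom]
    rrs, rre = sampler.rrna_exon

    emitted = 0
    frag_i = 0
    while emitted < n_frags:
        m = min(chunk, n_frags - emitted)
        cls = rng.choice(len(_CLASS_NAMES), size=m, p=pvec)
        gidx = rng.choice(len(sampler.gene_ids), size=m, p=sampler.weights)
        u = rng.random(m)
        flip = rng.random(m) >= cfg.sense_fraction
        rand_strand = rng.random(m) < 0.5
        inter_pick = (
            rng.choice(len(sampler.inter_ivs), size=m, p=sampler.inter_w)
            if sampler.inter_w.size
            else np.zeros(m, dtype=int)
        )
        for k in range(m):
            c = _CLASS_NAMES[cls[k]]
            gi = int(gidx[k])
            junction_sides: list[tuple[tuple[int, int], ...]] = []
            if c == "mature":
                gid = sampler.gene_ids[gi]
                true_strand = sampler.strand[gi]
                s = int(u[k] * (sampler.txlen[gi] - F + 1))
                mate_tx = [(s, s + L), (s + F - L, s + F)][:reads_per_frag]
                mate_blocks = [sampler.tx_to_blocks(gi, a, b) for a, b in mate_tx]
                obs = true_strand
            elif c == "premrna":
                gid = sampler.gene_ids[gi]
                true_strand = sampler.strand[gi]
                s = int(sampler.span_start[gi] + u[k] * (sampler.span_len[gi] - F + 1))
                mate_blocks = [((s, s + L),), ((s + F - L, s + F),)][:reads_per_frag]
                obs = _opp(true_strand) if flip[k] else true_strand
            elif c == "rrna":
                gid = ref.rrna_gene_id
                true_strand = sampler.rrna_strand
                s = int(rrs + u[k] * (rre - rrs - F + 1))
                mate_blocks = [((s, s + L),), ((s + F - L, s + F),)][:reads_per_frag]
                obs = true_strand
            elif c == "mito":
                gid = ""
                true_strand = "+" if rand_strand[k] else "-"
                s = int(u[k] * (mito_len - F + 1))
                mate_blocks = [((s, s + L),), ((s + F - L, s + F),)][:reads_per_frag]
                obs = true_strand
            else:  # intergenic
                gid = ""
                true_strand = "+" if rand_strand[k] else "-"
                ivs, ive = sampler.inter_ivs[inter_pick[k]]
                s = int(ivs + u[k] * (ive - ivs - F + 1))
                mate_blocks = [((s, s + L),), ((s + F - L, s + F),)][:reads_per_frag]
                obs = true_strand

            chrom = ref.mito_chrom if c == "mito" else ref.main_chrom
            qname = f"sim{frag_i}"
            for mi, blocks in enumerate(mate_blocks):
                rank = "first" if mi == 0 else "second"
                read_strand = _opp(obs) if rank == "first" else obs
                juncs = tuple(
                    (b1[1] - 1, b2[0]) for b1, b2 in zip(blocks, blocks[1:])
                )
                yield (
                    AlignedFragment(chrom, blocks, 60, read_strand, rank, qname),
                    SimTruth(qname, rank, c, gid, true_strand, juncs),
                )
            frag_i += 1
        emitted += m


# ---------------------------------------------------------------------------
# closed-form oracle


def expected_class_fractions(
    cfg: SimulationConfig, ref: ToyReference, with_variance: bool = False
):
    """Exact expected classifier fractions under the generative model.

    Pre-mRNA fragments are uniform over the unspliced gene span, so the chance
    a mate lies completely inside an intron is a ratio of integer interval
    counts; everything else lands in its class deterministically.  With
    ``with_variance`` also returns the exact SD of the measured intronic read
    fraction at ``cfg.n_reads`` (mates of one fragment are correlated, so the
    variance is computed per fragment, not per read).
    """
    sampler = _GeneSampler(cfg, ref)
    ann = ref.annotation
    L, F = cfg.read_len, cfg.fragment_len
    paired = cfg.paired
    rpf = 2 if paired else 1

    mean_mates = 0.0  # E[# intronic mates per pre-mRNA fragment]
    second_moment = 0.0
    for i, gid in enumerate(sampler.gene_ids):
        introns = ann.introns(gid).intervals
        s0 = int(sampler.span_start[i])
        S = int(sampler.span_len[i])
        ok = np.zeros(S - L + 1, dtype=bool)
        for a, b in introns:
            a, b = a - s0, b - s0
            if b - a >= L:
                ok[a : b - L + 1] = True
        if paired:
            M = S - F + 1
            p1 = ok[:M]
            p2 = ok[F - L : F - L + M]
            x = p1.astype(np.int8) + p2.astype(np.int8)
            m_g = float(x.mean())
            q_g = float((x.astype(np.int16) ** 2).mean())
        else:
            m_g = float(ok.mean())
            q_g = m_g
        mean_mates += sampler.weights[i] * m_g
        second_moment += sampler.weights[i] * q_g

    probs = cfg.class_probs()
    p_pre = probs["premrna"]
    intron = p_pre * mean_mates / rpf
    fractions = {
        "exon": probs["mature"] + p_pre - intron,
        "intron": intron,
        "intergenic": probs["intergenic"],
        "rrna": probs["rrna"],
        "mito": probs["mito"],
    }
    if not with_variance:
        return fractions
    n_frags = cfg.n_reads // rpf
    ex = p_pre * mean_mates
    ex2 = p_pre * second_moment
    sd = float(np.sqrt(max(ex2 - ex**2, 0.0) / n_frags) / rpf)
    return fractions, sd


# ---------------------------------------------------------------------------
# output writers


def write_sam(
    reads: Sequence[AlignedFragment] | Iterator[AlignedFragment],
    sizes: dict[str, int],
    path: str | Path,
    paired: bool = True,
) -> int:
    """Write aligned reads as SAM; consecutive reads sharing a qname become a
    proper pair.  Returns the number of records written."""

    def cigar(blocks) -> str:
        parts = []
        for i, (s, e) in enumerate(blocks):
            if i:
                parts.append(f"{s - blocks[i - 1][1]}N")
            parts.append(f"{e - s}M")
        return "".join(parts)

    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom in sorted(sizes):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{sizes[chrom]}\n")
        pending: AlignedFragment | None = None
        for r in reads:
            if not paired:
                flag = 16 if r.read_strand == "-" else 0
                fh.write(
                    f"{r.qname}\t{flag}\t{r.chrom}\t{r.start_pos + 1}\t{r.mapq}\t"
                    f"{cigar(r.blocks)}\t*\t0\t0\t*\t*\n"
                )
                n += 1
                continue
            if pending is None:
                pending = r
                continue
            if pending.qname != r.qname:
                raise ValueError(f"unpaired read {pending.qname} in paired stream")
            for mate, other in ((pending, r), (r, pending)):
                flag = 0x1 | 0x2
                flag |= 0x40 if mate.mate_rank == "first" else 0x80
                if mate.read_strand == "-":
                    flag |= 0x10
                if other.read_strand == "-":
                    flag |= 0x20
                left = min(mate.span[0], other.span[0])
                right = max(mate.span[1], other.span[1])
                tlen = right - left if mate.span[0] <= other.span[0] else left - right
                fh.write(
                    f"{mate.qname}\t{flag}\t{mate.chrom}\t{mate.start_pos + 1}\t{mate.mapq}\t"
                    f"{cigar(mate.blocks)}\t=\t{other.start_pos + 1}\t{tlen}\t*\t*\n"
                )
                n += 1
            pending = None
        if pending is not None:
            raise ValueError(f"dangling unpaired read {pending.qname}")
    return n


def write_truth_tsv(truths: Sequence[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("qname\tmate_rank\tsource_class\tgene_id\ttrue_strand\tjunctions\n")
        for t in truths:
            j = ",".join(f"{d}:{a}" for d, a in t.junctions)
            fh.write(f"{t.qname}\t{t.mate_rank}\t{t.source_class}\t{t.gene_id}\t{t.true_strand}\t{j}\n")


def write_library(cfg: SimulationConfig, ref: ToyReference, outdir: str | Path, prefix: str = "sim") -> dict:
    """Materialise a library: SAM + truth TSV (+ reference files + config echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads, truths = [], []
    for r, t in simulate_library(cfg, ref):
        reads.append(r)
        truths.append(t)
    paths = {
        "sam": outdir / f"{prefix}.sam",
        "truth": outdir / f"{prefix}.truth.tsv",
        "config": outdir / f"{prefix}.config.json",
    }
    write_sam(reads, ref.sizes, paths["sam"], paired=cfg.paired)
    write_truth_tsv(truths, paths["truth"])
    paths["config"].write_text(cfg.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}


def reads_to_fastq(
    reads: Sequence[AlignedFragment], ref: ToyReference, path: str | Path
) -> None:
    """Sequence-level export: reconstructs read sequences from the reference.

    Untested against external aligners; the pipeline itself consumes SAM.
    """
    comp = str.maketrans("ACGT", "TGCA")
    with open(path, "w") as fh:
        for r in reads:
            seq = "".join(ref.genome[r.chrom][s:e] for s, e in r.blocks)
            if r.read_strand == "-":
                seq = seq.translate(comp)[::-1]
            fh.write(f"@{r.qname}/{1 if r.mate_rank == 'first' else 2}\n{seq}\n+\n{'I' * len(seq)}\n")
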