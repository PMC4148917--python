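"""Shared study design for the analysis scripts.

Six library conditions emulate the crossed extraction x selection design on
one synthetic reference: two poly(A)+ libraries (TRIzol- and silica-column-
like extraction), two rRNA-depleted total-RNA libraries, and rRNA-depleted
cytoplasmic and nuclear fractions.  The pre-mRNA weight is the nuclear-RNA
knob: the nuclear fraction carries the most unspliced RNA, TRIzol extraction
retains more of it than silica columns, and the cytoplasmic fraction the
least.  Each condition is simulated in duplicate; everything is deterministic
under STUDY_SEED so every script can rebuild the same libraries in memory.
"""

from __future__ import annotations

from pathlib import Path

import exintron as ex
from exintron import expression as expr_mod
from exintron import validation as V

STUDY_SEED = 20140811
N_READS = 100_000
RESULTS = Path(__file__).resolve().parent.parent / "results"

REFERENCE_CFG = dict(n_genes=30, n_lncrna=8, n_reads=N_READS)

#: condition -> (selection, extraction, premrna_fraction, sense_fraction,
#:               rrna_fraction, mito_fraction)
CONDITIONS = {
    "polyA_trizol": ("polyA", "trizol", 0.10, 0.82, 0.003, 0.048),
    "polyA_qiagen": ("polyA", "qiagen", 0.07, 0.70, 0.003, 0.046),
    "riboz_trizol": ("ribozero", "trizol", 0.40, 0.82, 0.0004, 0.004),
    "riboz_qiagen": ("ribozero", "qiagen", 0.18, 0.70, 0.0002, 0.003),
    "riboz_cyt": ("ribozero", "cytoplasmic", 0.10, 0.80, 0.0003, 0.006),
    "riboz_nuc": ("ribozero", "nuclear", 0.72, 0.90, 0.0001, 0.0005),
}

N_REPLICATES = 2


def build_reference() -> ex.ToyReference:
    return ex.build_toy_reference(ex.SimulationConfig(seed=STUDY_SEED, **REFERENCE_CFG))


def condition_config(name: str, replicate: int) -> ex.SimulationConfig:
    selection, _extraction, pm, sense, rrna, mito = CONDITIONS[name]
    kwargs = dict(
        REFERENCE_CFG,
        seed=STUDY_SEED + 1000 * (list(CONDITIONS).index(name) + 1) + replicate,
        premrna_fraction=pm,
        sense_fraction=sense,
        rrna_fraction=rrna,
        mito_fraction=mito,
    )
    return ex.SimulationConfig(**kwargs)


def run_condition(name: str, replicate: int, ref: ex.ToyReference):
    """Simulate + classify one replicate; returns (counts, junction reads,
    expression table)."""
    cfg = condition_config(name, replicate)
    counts, n_junc, _, depth = V._run_library(cfg, ref, with_depth=True)
    table = expr_mod.build_expression_table(f"{name}_r{replicate + 1}", counts, ref.annotation, depth)
    return counts, n_junc, table


def all_tables(ref: ex.ToyReference):
    """Expression tables for every condition x replicate (cached per call)."""
    out = {}
    for name in CONDITIONS:
        out[name] = [run_condition(name, rep, ref) for rep in range(N_REPLICATES)]
    return out
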