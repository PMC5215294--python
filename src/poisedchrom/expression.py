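"""FPKM processing: isoform combination, gene classes, induction groups.

Gene classes at a given activation timepoint (default 150 min):

* expressed  — FPKM > 5 in resting cells
* silent     — FPKM < 2 at rest and < 5 after activation
* inducible  — FPKM < 2 at rest and > 5 after activation
* ambiguous  — anything else (boundary values exactly at 2 or 5 included)

Roughly 5-8 FPKM corresponds to one transcript copy per cell, which is the
rationale behind the 2/5 thresholds: "silent" genes are below one copy per
cell, and induction must cross the one-copy level.

The relative-induction ratio between effector-memory (TEM) and naive cells:

    ratio = (|FPKM_TEM,150 - FPKM_TEM,R| + 0.1) / (|FPKM_Naive,150 - FPKM_Naive,R| + 0.1)

computed over the universe of genes that are silent at rest (< 2 FPKM in
both cell types) and induced above 5 FPKM at 150 min in naive or TEM cells.
Genes with ratio >= 3 are "at least 3-fold more inducible in TEM"
(tem_specific), ratio <= 1/3 naive_specific, otherwise shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ExpressionRecord

FPKM_SILENT = 2.0
FPKM_EXPRESSED = 5.0
INDUCTION_OFFSET = 0.1
INDUCTION_FOLD = 3.0
RPKM_FLOOR = 1.0

GENE_CLASSES = ("expressed", "silent", "inducible", "ambiguous")
INDUCTION_GROUPS = ("naive_specific", "tem_specific", "shared")


@dataclass(frozen=True)
class InductionGroup:
    label: str  # naive_specific | tem_specific | shared
    ratio: float


def combine_isoforms(
    isoform_records: Iterable[tuple[str, int, ExpressionRecord]],
) -> dict[tuple[str, int], ExpressionRecord]:
    """Sum FPKM over isoforms that share a TSS.

    Input items are (gene_id, tss, per-isoform record); isoforms of one
    gene with distinct TSSs remain separate entries keyed (gene_id, tss).
    "Combined" is implemented as summation: each isoform contributes its
    own transcript mass, so same-start isoforms add.
    """
    out: dict[tuple[str, int], ExpressionRecord] = {}
    for gene_id, tss, rec in isoform_records:
        key = (gene_id, tss)
        if key not in out:
            out[key] = ExpressionRecord(gene_id=gene_id, fpkm=dict(rec.fpkm))
        else:
            merged = out[key].fpkm
            for cond, val in rec.fpkm.items():
                merged[cond] = merged.get(cond, 0.0) + val
    return out


def classify_gene(
    rec: ExpressionRecord, cell_type: str, activation_time: str = "150min"
) -> str:
    """Classify one gene in one cell type as expressed/silent/inducible.

    Thresholds are strict: a resting FPKM of exactly 2 or 5 falls into
    "ambiguous".  Raises KeyError if a required timepoint is missing.
    """
    rest = rec.get(cell_type, "R")
    act = rec.get(cell_type, activation_time)
    if rest > FPKM_EXPRESSED:
        return "expressed"
    if rest < FPKM_SILENT:
        if act > FPKM_EXPRESSED:
            return "inducible"
        if act < FPKM_EXPRESSED:
            return "silent"
    return "ambiguous"


def in_induction_universe(
    rec: ExpressionRecord,
    naive: str = "Naive",
    tem: str = "TEM",
    activation_time: str = "150min",
) -> bool:
    """Silent at rest in both cell types, induced above 5 in either."""
    try:
        n_r, n_a = rec.get(naive, "R"), rec.get(naive, activation_time)
        t_r, t_a = rec.get(tem, "R"), rec.get(tem, activation_time)
    except KeyError:
        return False
    silent_at_rest = n_r < FPKM_SILENT and t_r < FPKM_SILENT
    induced = n_a > FPKM_EXPRESSED or t_a > FPKM_EXPRESSED
    return silent_at_rest and induced


def induction_ratio(
    rec: ExpressionRecord,
    naive: str = "Naive",
    tem: str = "TEM",
    activation_time: str = "150min",
) -> InductionGroup:
    """Relative induction TEM vs naive, with the 0.1 pseudo-offset.

    Ties at exactly 3-fold go to the cell-type-specific group ("at least
    3 fold more inducible").
    """
    d_tem = abs(rec.get(tem, activation_time) - rec.get(tem, "R"))
    d_naive = abs(rec.get(naive, activation_time) - rec.get(naive, "R"))
    ratio = (d_tem + INDUCTION_OFFSET) / (d_naive + INDUCTION_OFFSET)
    if ratio >= INDUCTION_FOLD:
        label = "tem_specific"
    elif ratio <= 1.0 / INDUCTION_FOLD:
        label = "naive_specific"
    else:
        label = "shared"
    return InductionGroup(label=label, ratio=ratio)


def induction_groups(
    records: Sequence[ExpressionRecord],
    naive: str = "Naive",
    tem: str = "TEM",
    activation_time: str = "150min",
) -> dict[str, InductionGroup]:
    """Induction groups for the genes passing the universe precondition.

    Genes outside the universe are excluded, not an error.
    """
    out: dict[str, InductionGroup] = {}
    for rec in records:
        if in_induction_universe(rec, naive, tem, activation_time):
            out[rec.gene_id] = induction_ratio(rec, naive, tem, activation_time)
    return out


def floor_rpkm(value: float, floor: float = RPKM_FLOOR) -> float:
    """Raise values below the floor (default 1) to the floor, so that fold
    changes among barely-expressed genes do not explode."""
    return max(value, floor)
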