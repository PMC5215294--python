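"""Linking differential islands to genes and summarizing poising.

Genes are associated with differential islands through a window spanning
20 kb upstream to 1 kb downstream of the TSS (in transcription
orientation by default; a genomic-left/right mode is available).  A gene
is "gained" if at least one passing island with direction gained overlaps
its window, "lost" likewise, "both" when both kinds are present.  The
per-induction-group fractions of gained/lost genes are the bar-graph
numbers of the poising analysis: if poising explains differential
inducibility, the TEM-specific induced genes should be enriched for
H3K4me3 gain in the naive-to-memory transition.

The promoter analysis is stricter: a gene gains (loses) the promoter mark
only when a passing island of the same direction overlaps TSS +/- 1 kb in
BOTH replicate comparisons; direction conflicts between replicates
exclude the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import classify_gene, floor_rpkm
from .io_formats import CELL_TYPES, TIMEPOINTS, ExpressionRecord, GeneRecord
from .islands import DifferentialResult

UPSTREAM_DEFAULT = 20_000
DOWNSTREAM_DEFAULT = 1_000
PROMOTER_FLANK = 1_000

CONSEQUENCE_CATEGORIES = (
    "increased_expression",
    "increased_inducibility",
    "no_change",
    "lost_inducibility",
    "lost_expression",
)


@dataclass
class GeneIslandLink:
    gene_id: str
    window: tuple[int, int]
    chrom: str
    linked_islands: list[DifferentialResult] = field(default_factory=list)
    gene_status: str = "none"  # gained | lost | both | none


@dataclass
class PoisingSummary:
    """Per-induction-group gain/loss fractions (the bar-graph numbers)."""

    groups: dict[str, dict[str, float | int | None]] = field(default_factory=dict)


def gene_window(
    gene: GeneRecord,
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    orientation: str = "transcription",
) -> tuple[int, int]:
    """Half-open association window around the TSS.

    orientation='transcription' (default): upstream means 5' of the TSS in
    the direction of transcription, so a minus-strand gene's window extends
    to genomic-right.  orientation='genomic': upstream is genomic-left
    regardless of strand.
    """
    if orientation not in ("transcription", "genomic"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "genomic" or gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    return max(lo, 0), hi


def _status_from_directions(directions: set[str]) -> str:
    has_gain = "gained" in directions
    has_loss = "lost" in directions
    if has_gain and has_loss:
        return "both"
    if has_gain:
        return "gained"
    if has_loss:
        return "lost"
    return "none"


def link_islands_to_genes(
    diff_results: Sequence[DifferentialResult],
    genes: Sequence[GeneRecord],
    upstream: int = UPSTREAM_DEFAULT,
    downstream: int = DOWNSTREAM_DEFAULT,
    orientation: str = "transcription",
) -> list[GeneIslandLink]:
    """Overlap passing differential islands with each gene's window."""
    trees: dict[str, IntervalTree] = {}
    for r in diff_results:
        if not r.passes:
            continue
        trees.setdefault(r.chrom, IntervalTree())[r.start:r.end] = r
    links = []
    for gene in genes:
        lo, hi = gene_window(gene, upstream, downstream, orientation)
        hits = (
            [iv.data for iv in sorted(trees[gene.chrom][lo:hi])]
            if gene.chrom in trees
            else []
        )
        links.append(
            GeneIslandLink(
                gene_id=gene.gene_id,
                window=(lo, hi),
                chrom=gene.chrom,
                linked_islands=hits,
                gene_status=_status_from_directions({h.direction for h in hits}),
            )
        )
    return links


def poising_summary(
    links: Sequence[GeneIslandLink],
    induction_groups: Mapping[str, object],
) -> PoisingSummary:
    """Fraction of genes in each induction group with gained/lost islands.

    ``induction_groups`` maps gene id -> InductionGroup (or bare label).
    Presence/absence counting: a gene counts once no matter how many
    islands its window holds.  Empty groups report fractions as None.
    """
    status = {ln.gene_id: ln.gene_status for ln in links}
    summary = PoisingSummary()
    for group in ("naive_specific", "tem_specific", "shared"):
        members = [
            g
            for g, ig in induction_groups.items()
            if (getattr(ig, "label", ig)) == group
        ]
        n = len(members)
        if n == 0:
            summary.groups[group] = {
                "n_genes": 0,
                "fraction_gained": None,
                "fraction_lost": None,
            }
            continue
        gained = sum(status.get(g) in ("gained", "both") for g in members)
        lost = sum(status.get(g) in ("lost", "both") for g in members)
        summary.groups[group] = {
            "n_genes": n,
            "fraction_gained": gained / n,
            "fraction_lost": lost / n,
        }
    return summary


def promoter_differential(
    results_by_replicate: Sequence[Sequence[DifferentialResult]],
    genes: Sequence[GeneRecord],
    flank: int = PROMOTER_FLANK,
) -> dict[str, list[str]]:
    """Genes gaining/losing the promoter mark consistently in all replicates.

    A gene is gained (lost) iff every replicate comparison has a passing
    island of that direction overlapping TSS +/- ``flank``; replicate
    direction conflicts or a miss in any replicate exclude the gene.
    """
    if not results_by_replicate:
        raise ValueError("need at least one replicate comparison")
    per_rep_links = [
        link_islands_to_genes(
            rep, genes, upstream=flank, downstream=flank, orientation="genomic"
        )
        for rep in results_by_replicate
    ]
    gained, lost = [], []
    for per_gene in zip(*per_rep_links):
        statuses = {ln.gene_status for ln in per_gene}
        if statuses == {"gained"}:
            gained.append(per_gene[0].gene_id)
        elif statuses == {"lost"}:
            lost.append(per_gene[0].gene_id)
    return {"gained": gained, "lost": lost}


# ---------------------------------------------------------------------------
# Expression consequences of promoter gain/loss
# ---------------------------------------------------------------------------

def consequence_category(
    rec: ExpressionRecord,
    naive: str = "Naive",
    memory: str = "TEM",
    activation_time: str = "150min",
) -> str:
    """Categorize the naive -> memory expression change of one gene."""
    before = classify_gene(rec, naive, activation_time)
    after = classify_gene(rec, memory, activation_time)
    if before in ("silent", "inducible") and after == "expressed":
        return "increased_expression"
    if before == "silent" and after == "inducible":
        return "increased_inducibility"
    if before == "inducible" and after == "silent":
        return "lost_inducibility"
    if before == "expressed" and after in ("silent", "inducible"):
        return "lost_expression"
    return "no_change"


def consequence_matrix(
    gene_lists: Mapping[str, Sequence[str]],
    expression: Sequence[ExpressionRecord],
    naive: str = "Naive",
    memory: str = "TEM",
    activation_time: str = "150min",
    cluster: bool = True,
) -> dict:
    """Per-gene consequence categories plus the clustered heatmap input.

    The heatmap matrix is log2 of floored FPKM (values below 1 raised to
    1) over all (cell, time) conditions, rows ordered by average-linkage
    hierarchical clustering on correlation distance within each direction
    list (cosmetic ordering only).
    """
    by_id = {r.gene_id: r for r in expression}
    conditions = [(c, t) for c in CELL_TYPES for t in TIMEPOINTS]
    out: dict = {"categories": {}, "matrix": {}, "conditions": [
        f"{c}:{t}" for c, t in conditions
    ], "row_order": {}}
    for direction, gene_ids in gene_lists.items():
        rows = []
        for gid in gene_ids:
            rec = by_id[gid]
            out["categories"][gid] = consequence_category(
                rec, naive, memory, activation_time
            )
            rows.append(
                [math.log2(floor_rpkm(rec.get(c, t))) for c, t in conditions]
            )
        mat = np.array(rows) if rows else np.empty((0, len(conditions)))
        order = list(range(len(gene_ids)))
        if cluster and len(gene_ids) > 2:
            with np.errstate(invalid="ignore"):
                dist = pdist(mat, metric="correlation")
            dist = np.nan_to_num(dist, nan=1.0)
            order = hierarchy.leaves_list(hierarchy.linkage(dist, "average"))
            order = [int(i) for i in order]
        out["matrix"][direction] = mat
        out["row_order"][direction] = [gene_ids[i] for i in order]
    return out
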