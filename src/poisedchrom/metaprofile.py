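"""Average tag-density profiles around TSSs for a gene set.

Each tag within +/-flank of a TSS contributes at exactly one position: its
5' end shifted by +shift (plus-strand tags) or -shift (minus-strand tags),
where shift is half the average fragment length.  Tags on the X or Y
chromosome contribute with weight 2 (they are present in one copy in the
male-derived libraries this convention originates from).  Raw positional
counts are divided by (total_mapped / 1e6) and by the number of genes, then
smoothed by a centered moving average (window truncated at the array edges).

By default profiles are transcription-oriented: for minus-strand genes the
x axis is flipped so positive positions mean downstream of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneRecord, Tag

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class ProfileSpec:
    flank: int = 2000
    shift: int = 75  # half of the default 150 bp fragment length
    smooth_window: int = 100
    gene_set: list[str] = field(default_factory=list)
    orient_by_strand: bool = True

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass
class Metaprofile:
    positions: np.ndarray  # -flank .. +flank
    density: np.ndarray  # smoothed, normalized
    raw_density: np.ndarray  # pre-smoothing, normalized
    n_genes: int
    n_reads_total: float  # weighted in-window tag count


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window truncated at the edges."""
    if window <= 1:
        return values.astype(float)
    n = len(values)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half_lo, 0)
        hi = min(i + half_hi + 1, n)
        out[i] = values[lo:hi].mean()
    return out


def shifted_position(tag: Tag, shift: int) -> int:
    """Tag 5' end shifted by `shift` in the direction of the read."""
    if tag.strand == "+":
        return tag.five_prime() + shift
    return tag.five_prime() - shift


def tss_profile(
    tags_by_chrom: Mapping[str, Sequence[Tag]],
    genes: Sequence[GeneRecord],
    spec: ProfileSpec,
    total_mapped: int,
) -> Metaprofile:
    """Average tag density around the TSSs of ``spec.gene_set``."""
    if not spec.gene_set:
        raise ValueError("gene_set is empty")
    by_id = {(g.gene_id): g for g in genes}
    unknown = [g for g in spec.gene_set if g not in by_id]
    if unknown:
        raise ValueError(f"unknown gene ids in gene_set: {unknown[:5]}")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")

    flank = spec.flank
    width = 2 * flank + 1
    counts = np.zeros(width)

    # pre-compute shifted positions (and weights) per chromosome once
    shifted: dict[str, tuple[np.ndarray, float]] = {}
    for chrom, tags in tags_by_chrom.items():
        pos = np.fromiter(
            (shifted_position(t, spec.shift) for t in tags),
            dtype=np.int64,
            count=len(tags),
        )
        pos.sort()
        weight = 2.0 if chrom in SEX_CHROMOSOMES else 1.0
        shifted[chrom] = (pos, weight)

    total_weighted = 0.0
    for gid in spec.gene_set:
        gene = by_id[gid]
        if gene.chrom not in shifted:
            continue
        pos, weight = shifted[gene.chrom]
        lo = np.searchsorted(pos, gene.tss - flank, side="left")
        hi = np.searchsorted(pos, gene.tss + flank, side="right")
        rel = pos[lo:hi] - gene.tss
        if spec.orient_by_strand and gene.strand == "-":
            rel = -rel
        np.add.at(counts, rel + flank, weight)
        total_weighted += weight * (hi - lo)

    norm = (total_mapped / 1e6) * len(spec.gene_set)
    raw_density = counts / norm
    density = moving_average(raw_density, spec.smooth_window)
    return Metaprofile(
        positions=np.arange(-flank, flank + 1),
        density=density,
        raw_density=raw_density,
        n_genes=len(spec.gene_set),
        n_reads_total=total_weighted,
    )
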