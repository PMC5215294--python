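"""Synthetic aligned-tag, annotation and FPKM data with planted ground truth.

The generator emulates the data layout of a naive-vs-memory T-cell
poising study: per-cell-type ChIP-Seq tag libraries in which activating-
mark islands are planted at promoters of genes whose inducibility differs
between cell types, plus FPKM tables in which those same genes are silent
at rest and induced on activation preferentially in the cell type carrying
the island.

Gene classes
------------
* constitutive — expressed everywhere; promoter island in every cell type
* poised_TEM   — silent at rest, induced in TEM only; island in TEM only
* poised_naive — symmetric: induced in naive only; island in Naive only
* poised_both  — induced in both naive and TEM; island in both
* silent       — never expressed; no island

Two extra knobs create the partial-coupling scenarios a real comparison
shows: ``poised_island_fraction`` leaves some poised genes without their
island (induction without chromatin gain) and ``decoy_gain_fraction``
gives some silent genes a TEM island (chromatin gain without any
expression consequence).

Tag model
---------
Tags are 36 bp reads drawn from a mixture of uniform genomic background
(``background_rate`` expected tags/bp) and, for each island carried by the
simulated cell type, extra tags at ``island_enrichment`` x background
within the island.  Fragment midpoints are uniform in the source region
and the 5' end is placed so that the midpoint of the fragment_length
extension reproduces the drawn midpoint.  Total tag count is Poisson
around the requested depth.  Replicates differ only by RNG stream and
depth; by default replicate 2 is sequenced at a third of the depth of
replicate 1, so depth normalization has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    CELL_TYPES,
    TIMEPOINTS,
    ExpressionRecord,
    GeneRecord,
    Tag,
    write_expression,
    write_genes,
    write_json,
    write_tags,
    read_json,
)

GENE_CLASS_ORDER = (
    "constitutive",
    "poised_TEM",
    "poised_naive",
    "poised_both",
    "silent",
)

_CELL_INDEX = {c: i for i, c in enumerate(CELL_TYPES)}

# cell types carrying the promoter island, per gene class
_ISLAND_CELLS = {
    "constitutive": ("Naive", "TCM", "TEM"),
    "poised_TEM": ("TEM",),
    "poised_naive": ("Naive",),
    "poised_both": ("Naive", "TEM"),
    "silent": (),
}

# cell types in which the gene is induced post-activation, per class
_INDUCED_CELLS = {
    "poised_TEM": ("TEM",),
    "poised_naive": ("Naive",),
    "poised_both": ("Naive", "TEM"),
}


class SizingError(ValueError):
    """Chromosomes too short to place the requested genes at spacing."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the base conditions used throughout the test-suite:
    200 genes on 2 autosomes + chrX of 4 Mb each, 0.05 background tags/bp
    (50 expected background tags per kb of island), 10x island enrichment,
    1 kb promoter islands, replicate depth ratio 3:1.
    """

    seed: int = 0
    n_chromosomes: int = 2  # autosomes; one X-like chromosome is added
    chrom_length: int = 4_000_000
    n_genes: int = 200
    background_rate: float = 0.05  # expected tags per bp
    island_enrichment: float = 10.0  # fold over background
    fragment_length: int = 150
    read_length: int = 36
    depth_per_sample: int | None = None  # None: expected mixture mass
    replicate_depth_ratio: float = 3.0  # rep1 : rep2 depth
    island_width: int = 1_000
    gene_spacing: int = 50_000  # minimum TSS-to-TSS distance
    gene_length: int = 10_000
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "constitutive": 0.30,
            "poised_TEM": 0.20,
            "poised_naive": 0.10,
            "poised_both": 0.10,
            "silent": 0.30,
        }
    )
    multinomial_classes: bool = False  # proportional allocation by default
    poised_island_fraction: float = 1.0
    decoy_gain_fraction: float = 0.0
    fpkm_high: float = 20.0
    fpkm_low: float = 0.5
    fpkm_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, not 1")
        unknown = set(self.class_fractions) - set(GENE_CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.island_enrichment < 1:
            raise ValueError("island_enrichment must be >= 1")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be > 0")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length < read_length")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)] + ["chrX"]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def genome_size(self) -> int:
        return self.chrom_length * (self.n_chromosomes + 1)


@dataclass
class PlantedIsland:
    chrom: str
    start: int
    end: int
    cell_types: tuple[str, ...]
    gene_id: str


@dataclass
class GroundTruth:
    """The simulator's planted labels, consumed by recovery tests."""

    gene_class: dict[str, str] = field(default_factory=dict)
    planted_islands: list[PlantedIsland] = field(default_factory=list)
    tss_table: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    decoy_gain_genes: list[str] = field(default_factory=list)

    def genes_of_class(self, label: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == label]

    def islands_for(self, cell_type: str) -> list[PlantedIsland]:
        return [i for i in self.planted_islands if cell_type in i.cell_types]

    def to_json(self, path: str | Path) -> None:
        write_json(
            {
                "gene_class": self.gene_class,
                "planted_islands": [asdict(i) for i in self.planted_islands],
                "tss_table": {g: list(v) for g, v in self.tss_table.items()},
                "decoy_gain_genes": self.decoy_gain_genes,
            },
            path,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = read_json(path)
        return cls(
            gene_class=dict(raw["gene_class"]),
            planted_islands=[
                PlantedIsland(
                    chrom=i["chrom"],
                    start=i["start"],
                    end=i["end"],
                    cell_types=tuple(i["cell_types"]),
                    gene_id=i["gene_id"],
                )
                for i in raw["planted_islands"]
            ],
            tss_table={
                g: (v[0], v[1], int(v[2])) for g, v in raw["tss_table"].items()
            },
            decoy_gain_genes=list(raw["decoy_gain_genes"]),
        )


# ---------------------------------------------------------------------------
# Genome / annotation
# ---------------------------------------------------------------------------

def _proportional_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation so expected class counts are exact."""
    raw = {k: fractions.get(k, 0.0) * n for k in GENE_CLASS_ORDER}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def simulate_genome(config: SimConfig) -> tuple[list[GeneRecord], GroundTruth]:
    """Place genes and plant promoter islands according to class labels.

    TSSs are spaced >= ``gene_spacing`` apart (so [TSS-20kb, TSS+1kb]
    association windows never collide) with genes distributed round-robin
    over the autosomes and the X-like chromosome.  Class labels use
    deterministic proportional allocation by default; poised/decoy island
    carriage is likewise allocated deterministically within each class so
    planted rates are exact.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes: list[GeneRecord] = []
    truth = GroundTruth()
    if config.n_genes == 0:
        return genes, truth

    margin = 25_000  # keeps association windows inside the chromosome
    jitter_max = 4_000
    pitch = config.gene_spacing + jitter_max + 1
    chroms = config.chrom_names
    slots_per_chrom = (config.chrom_length - 2 * margin) // pitch + 1
    if slots_per_chrom < 1 or slots_per_chrom * len(chroms) < config.n_genes:
        raise SizingError(
            f"cannot place {config.n_genes} genes at >= {config.gene_spacing} bp "
            f"spacing on {len(chroms)} chromosomes of {config.chrom_length} bp"
        )

    # round-robin chromosome assignment, sequential slots within each
    slot_counter = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        slot = slot_counter[chrom]
        slot_counter[chrom] += 1
        tss = margin + slot * pitch + int(rng.integers(0, jitter_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tes = tss + config.gene_length if strand == "+" else tss - config.gene_length
        gid = f"g{i:04d}"
        genes.append(
            GeneRecord(
                gene_id=gid, chrom=chrom, strand=strand,
                tss=tss, tes=tes, isoform_id=f"{gid}.1",
            )
        )
        truth.tss_table[gid] = (chrom, strand, tss)

    # class labels
    if config.multinomial_classes:
        probs = [config.class_fractions.get(k, 0.0) for k in GENE_CLASS_ORDER]
        draws = rng.multinomial(config.n_genes, probs)
        counts = dict(zip(GENE_CLASS_ORDER, draws))
    else:
        counts = _proportional_counts(config.class_fractions, config.n_genes)
    labels: list[str] = []
    for k in GENE_CLASS_ORDER:
        labels.extend([k] * counts[k])
    order = rng.permutation(config.n_genes)
    for gene, idx in zip(genes, order):
        truth.gene_class[gene.gene_id] = labels[idx]

    # plant promoter islands
    half = config.island_width // 2
    per_class_seen: dict[str, int] = {k: 0 for k in GENE_CLASS_ORDER}
    class_totals = {
        k: sum(1 for v in truth.gene_class.values() if v == k)
        for k in GENE_CLASS_ORDER
    }
    for gene in genes:
        label = truth.gene_class[gene.gene_id]
        rank = per_class_seen[label]
        per_class_seen[label] += 1
        cells = _ISLAND_CELLS[label]
        if label.startswith("poised_"):
            n_with = int(round(config.poised_island_fraction * class_totals[label]))
            if rank >= n_with:
                continue
        if label == "silent":
            n_decoy = int(round(config.decoy_gain_fraction * class_totals[label]))
            if rank < n_decoy:
                cells = ("TEM",)
                truth.decoy_gain_genes.append(gene.gene_id)
            else:
                continue
        if not cells:
            continue
        truth.planted_islands.append(
            PlantedIsland(
                chrom=gene.chrom,
                start=gene.tss - half,
                end=gene.tss - half + config.island_width,
                cell_types=cells,
                gene_id=gene.gene_id,
            )
        )
    return genes, truth


# ---------------------------------------------------------------------------
# ChIP tags
# ---------------------------------------------------------------------------

def expected_depth(truth: GroundTruth, config: SimConfig, cell_type: str) -> float:
    """Expected tag count of the background + islands mixture."""
    w_bg = config.background_rate * config.genome_size
    w_isl = sum(
        (config.island_enrichment - 1.0)
        * config.background_rate
        * (i.end - i.start)
        for i in truth.islands_for(cell_type)
    )
    return w_bg + w_isl


def simulate_chip_tags(
    truth: GroundTruth,
    config: SimConfig,
    cell_type: str,
    replicate_id: int = 1,
    depth: float | None = None,
) -> dict[str, list[Tag]]:
    """Draw one tag library for one cell type / replicate.

    Returns 36 bp BED-style tags grouped by chromosome, sorted by start.
    Tags whose read interval would extend past a chromosome end are
    dropped (a negligible edge effect at genome scale).
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}; expected {CELL_TYPES}")
    if depth is not None and depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(
        [config.seed, 2, _CELL_INDEX[cell_type], replicate_id]
    )
    islands = truth.islands_for(cell_type)
    w_bg = config.background_rate * config.genome_size
    w_isl = np.array(
        [
            (config.island_enrichment - 1.0)
            * config.background_rate
            * (i.end - i.start)
            for i in islands
        ]
    )
    weights = np.concatenate(([w_bg], w_isl))
    if depth is None:
        depth = weights.sum()
    n_total = int(rng.poisson(depth))
    component_n = rng.multinomial(n_total, weights / weights.sum())

    chroms = config.chrom_names
    clen = config.chrom_length
    chrom_idx = np.empty(n_total, dtype=np.int64)
    mids = np.empty(n_total, dtype=np.int64)

    # background: uniform over the concatenated genome
    n_bg = component_n[0]
    flat = rng.integers(0, config.genome_size, n_bg)
    chrom_idx[:n_bg] = flat // clen
    mids[:n_bg] = flat % clen
    # island extras: uniform within each island
    pos = n_bg
    chrom_to_idx = {c: i for i, c in enumerate(chroms)}
    for isl, n_i in zip(islands, component_n[1:]):
        chrom_idx[pos:pos + n_i] = chrom_to_idx[isl.chrom]
        mids[pos:pos + n_i] = rng.integers(isl.start, isl.end, n_i)
        pos += n_i

    plus = rng.random(n_total) < 0.5
    half = config.fragment_length // 2
    rlen = config.read_length
    # 5' end placed so the fragment_length extension has midpoint `mids`
    starts = np.where(plus, mids - half, mids + (config.fragment_length - half) - rlen)
    ends = starts + rlen
    keep = (starts >= 0) & (ends <= clen)

    out: dict[str, list[Tag]] = {c: [] for c in chroms}
    for ci, c in enumerate(chroms):
        mask = keep & (chrom_idx == ci)
        s_arr = starts[mask]
        order = np.argsort(s_arr, kind="stable")
        s_arr = s_arr[order]
        e_arr = ends[mask][order]
        p_arr = plus[mask][order]
        out[c] = [
            Tag(c, int(s), int(e), "+" if p else "-")
            for s, e, p in zip(s_arr, e_arr, p_arr)
        ]
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _fpkm_template(label: str, cell: str, time: str, config: SimConfig) -> float:
    if label == "constitutive":
        return config.fpkm_high
    if label in _INDUCED_CELLS and cell in _INDUCED_CELLS[label]:
        return config.fpkm_high if time in ("150min", "15h") else config.fpkm_low
    return config.fpkm_low


def simulate_expression(
    truth: GroundTruth, config: SimConfig
) -> list[ExpressionRecord]:
    """FPKM table following each gene's class template, with multiplicative
    lognormal noise of sigma ``fpkm_noise_sd`` on every entry."""
    rng = np.random.default_rng([config.seed, 3])
    records = []
    for gid in sorted(truth.gene_class):
        label = truth.gene_class[gid]
        rec = ExpressionRecord(gene_id=gid)
        for cell in CELL_TYPES:
            for time in TIMEPOINTS:
                base = _fpkm_template(label, cell, time, config)
                noise = (
                    float(np.exp(rng.normal(0.0, config.fpkm_noise_sd)))
                    if config.fpkm_noise_sd > 0
                    else 1.0
                )
                rec.fpkm[(cell, time)] = base * noise
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig,
    cell_types: Sequence[str] = ("Naive", "TEM"),
    n_replicates: int = 2,
) -> dict:
    """Simulate annotation, truth, expression and tag libraries in memory.

    Replicate r is sequenced at depth expected/replicate_depth_ratio**(r-1),
    so the default two replicates have a 3:1 depth ratio.
    """
    genes, truth = simulate_genome(config)
    expr = simulate_expression(truth, config)
    tags: dict[tuple[str, int], dict[str, list[Tag]]] = {}
    depths: dict[tuple[str, int], int] = {}
    for cell in cell_types:
        base_depth = (
            config.depth_per_sample
            if config.depth_per_sample is not None
            else expected_depth(truth, config, cell)
        )
        for rep in range(1, n_replicates + 1):
            d = base_depth / (config.replicate_depth_ratio ** (rep - 1))
            t = simulate_chip_tags(truth, config, cell, rep, depth=d)
            tags[(cell, rep)] = t
            depths[(cell, rep)] = sum(len(v) for v in t.values())
    return {
        "genes": genes,
        "truth": truth,
        "expression": expr,
        "tags": tags,
        "depths": depths,
        "chrom_lengths": config.chrom_lengths,
    }


def write_dataset(dataset: dict, outdir: str | Path) -> None:
    """Write a simulated dataset to disk in the package's text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genes(dataset["genes"], outdir / "genes.tsv")
    write_expression(dataset["expression"], outdir / "expression.tsv")
    dataset["truth"].to_json(outdir / "ground_truth.json")
    for (cell, rep), by_chrom in dataset["tags"].items():
        path = outdir / f"tags_{cell}_rep{rep}.bed"
        all_tags = [t for c in sorted(by_chrom) for t in by_chrom[c]]
        write_tags(all_tags, path)
    write_json(
        {f"{cell}_rep{rep}": d for (cell, rep), d in dataset["depths"].items()},
        outdir / "depths.json",
    )
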