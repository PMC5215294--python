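import numpy as np
import pytest
from scipy import stats

from poisedchrom.coverage import midpoints_array
from poisedchrom.expression import classify_gene
from poisedchrom.io_formats import write_genes, write_expression
from poisedchrom.synthetic_data import (
    GroundTruth,
    SimConfig,
    SizingError,
    expected_depth,
    simulate_chip_tags,
    simulate_dataset,
    simulate_expression,
    simulate_genome,
)


class TestSimConfig:
    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(class_fractions={"silent": 0.5, "constitutive": 0.4})

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"background_rate": 0.0},
            {"island_enrichment": 0.5},
            {"fragment_length": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestSimulateGenome:
    def test_zero_genes_gives_empty_outputs(self):
        genes, truth = simulate_genome(SimConfig(n_genes=0))
        assert genes == [] and truth.gene_class == {}
        assert truth.planted_islands == [] and truth.tss_table == {}

    def test_deterministic_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(seed=1, n_genes=100, chrom_length=2_500_000)
        out = []
        for i in (0, 1):
            genes, truth = simulate_genome(cfg)
            gpath = tmp_path / f"g{i}.tsv"
            tpath = tmp_path / f"t{i}.json"
            write_genes(genes, gpath)
            truth.to_json(tpath)
            out.append((gpath.read_bytes(), tpath.read_bytes()))
        assert out[0] == out[1]

    def test_proportional_allocation_is_exact(self):
        cfg = SimConfig(
            seed=7, n_genes=200,
            class_fractions={
                "constitutive": 0.3, "poised_TEM": 0.2, "poised_naive": 0.1,
                "poised_both": 0.1, "silent": 0.3,
            },
        )
        _, truth = simulate_genome(cfg)
        assert len(truth.genes_of_class("poised_TEM")) == 40
        assert len(truth.genes_of_class("constitutive")) == 60

    def test_tss_spacing_at_least_50kb(self):
        genes, _ = simulate_genome(SimConfig(seed=5, n_genes=120,
                                             chrom_length=2_500_000))
        by_chrom: dict = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        for tsses in by_chrom.values():
            tsses.sort()
            assert all(b - a >= 50_000 for a, b in zip(tsses, tsses[1:]))

    def test_fraction_of_genes_on_x_chromosome(self):
        genes, _ = simulate_genome(SimConfig(seed=5, n_genes=120,
                                             chrom_length=2_500_000))
        n_x = sum(g.chrom == "chrX" for g in genes)
        assert n_x == 40  # round-robin over 2 autosomes + chrX

    def test_chromosome_too_short_is_sizing_error(self):
        with pytest.raises(SizingError):
            simulate_genome(SimConfig(n_genes=500, chrom_length=1_000_000))

    def test_planted_islands_respect_gene_class(self):
        cfg = SimConfig(seed=2, n_genes=60, chrom_length=1_500_000)
        _, truth = simulate_genome(cfg)
        islands_by_gene = {i.gene_id: i for i in truth.planted_islands}
        for gid, label in truth.gene_class.items():
            chrom, strand, tss = truth.tss_table[gid]
            if label == "silent":
                assert gid not in islands_by_gene
                continue
            isl = islands_by_gene[gid]
            # inside [TSS-20kb, TSS+1kb] in transcription orientation
            if strand == "+":
                lo, hi = tss - 20_000, tss + 1_000
            else:
                lo, hi = tss - 1_000, tss + 20_000
            assert lo <= isl.start and isl.end <= hi
            expected_cells = {
                "constitutive": ("Naive", "TCM", "TEM"),
                "poised_TEM": ("TEM",),
                "poised_naive": ("Naive",),
                "poised_both": ("Naive", "TEM"),
            }[label]
            assert isl.cell_types == expected_cells

    def test_every_classified_gene_has_a_tss(self):
        _, truth = simulate_genome(SimConfig(seed=3, n_genes=50,
                                             chrom_length=1_500_000))
        assert set(truth.gene_class) == set(truth.tss_table)

    def test_ground_truth_json_roundtrip(self, tmp_path):
        _, truth = simulate_genome(SimConfig(seed=4, n_genes=30,
                                             chrom_length=1_000_000))
        p = tmp_path / "truth.json"
        truth.to_json(p)
        assert GroundTruth.from_json(p) == truth


class TestSimulateChipTags:
    def test_unknown_cell_type_rejected(self):
        _, truth = simulate_genome(SimConfig(n_genes=0))
        with pytest.raises(ValueError, match="cell type"):
            simulate_chip_tags(truth, SimConfig(n_genes=0), "Treg")

    def test_enrichment_one_means_pure_background(self):
        # with fold 1 the island mixture mass vanishes: density inside
        # planted islands is statistically indistinguishable from background
        cfg = SimConfig(seed=9, n_genes=30, chrom_length=1_000_000,
                        island_enrichment=1.0, background_rate=0.05)
        _, truth = simulate_genome(cfg)
        tags = simulate_chip_tags(truth, cfg, "TEM")
        mids = {c: midpoints_array(t, cfg.fragment_length)
                for c, t in tags.items()}
        n_total = sum(m.size for m in mids.values())
        rate = n_total / cfg.genome_size
        isl_counts = []
        isl_len = 0
        for isl in truth.islands_for("TEM")[:10]:
            m = mids[isl.chrom]
            isl_counts.append(
                int(np.searchsorted(m, isl.end) - np.searchsorted(m, isl.start))
            )
            isl_len += isl.end - isl.start
        # two-sample rate test: island counts vs expectation from the rest
        total_isl = sum(isl_counts)
        expected = rate * isl_len
        p = stats.poisson.sf(total_isl - 1, expected) if total_isl > expected \
            else stats.poisson.cdf(total_isl, expected)
        assert p > 0.01

    def test_doubling_depth_doubles_tag_density(self):
        cfg = SimConfig(seed=10, n_genes=20, chrom_length=1_000_000)
        _, truth = simulate_genome(cfg)
        d = expected_depth(truth, cfg, "TEM")
        t1 = simulate_chip_tags(truth, cfg, "TEM", 1, depth=d)
        t2 = simulate_chip_tags(truth, cfg, "TEM", 2, depth=2 * d)
        n1 = sum(len(v) for v in t1.values())
        n2 = sum(len(v) for v in t2.values())
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)

    def test_planted_island_tag_count_matches_poisson_mean(self):
        # 1 kb island at 10x background with lambda = 50 background tags/kb:
        # expected in-island count = 10 * 50 = 500, check within 4 sigma
        cfg = SimConfig(seed=11, n_genes=9, chrom_length=1_000_000,
                        background_rate=0.05, island_enrichment=10.0,
                        class_fractions={"poised_TEM": 1.0})
        _, truth = simulate_genome(cfg)
        tags = simulate_chip_tags(truth, cfg, "TEM")
        mids = {c: midpoints_array(t, cfg.fragment_length)
                for c, t in tags.items()}
        for isl in truth.islands_for("TEM"):
            m = mids[isl.chrom]
            count = int(np.searchsorted(m, isl.end) - np.searchsorted(m, isl.start))
            assert abs(count - 500) <= 4 * np.sqrt(500)

    def test_replicates_differ_but_same_structure(self):
        cfg = SimConfig(seed=12, n_genes=20, chrom_length=1_000_000)
        _, truth = simulate_genome(cfg)
        r1 = simulate_chip_tags(truth, cfg, "TEM", replicate_id=1)
        r2 = simulate_chip_tags(truth, cfg, "TEM", replicate_id=2)
        assert r1 != r2  # independent draws
        again = simulate_chip_tags(truth, cfg, "TEM", replicate_id=1)
        assert r1 == again  # but each replicate is deterministic


class TestSimulateExpression:
    def test_noiseless_template_poised_tem(self):
        cfg = SimConfig(seed=1, n_genes=20, chrom_length=1_000_000,
                        fpkm_noise_sd=0.0, fpkm_high=20.0, fpkm_low=0.5)
        _, truth = simulate_genome(cfg)
        records = {r.gene_id: r for r in simulate_expression(truth, cfg)}
        gid = truth.genes_of_class("poised_TEM")[0]
        rec = records[gid]
        assert [rec.fpkm[("Naive", t)] for t in ("R", "40min", "150min", "15h")] \
            == [0.5, 0.5, 0.5, 0.5]
        assert [rec.fpkm[("TEM", t)] for t in ("R", "40min", "150min", "15h")] \
            == [0.5, 0.5, 20.0, 20.0]

    def test_determinism_of_expression_table(self, tmp_path):
        cfg = SimConfig(seed=6, n_genes=30, chrom_length=1_000_000)
        _, truth = simulate_genome(cfg)
        paths = []
        for i in (0, 1):
            p = tmp_path / f"e{i}.tsv"
            write_expression(simulate_expression(truth, cfg), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_noisy_misclassification_below_5_percent(self):
        # Monte-Carlo over 20 seeds at sigma=0.3: poised_TEM genes nearly
        # always classified inducible-in-TEM / silent-in-Naive
        n_wrong = n_tot = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_genes=40, chrom_length=1_200_000,
                            fpkm_noise_sd=0.3,
                            class_fractions={"poised_TEM": 1.0})
            _, truth = simulate_genome(cfg)
            for rec in simulate_expression(truth, cfg):
                n_tot += 1
                if (classify_gene(rec, "TEM") != "inducible"
                        or classify_gene(rec, "Naive") != "silent"):
                    n_wrong += 1
        assert n_tot == 800
        assert n_wrong / n_tot < 0.05


class TestDataset:
    def test_replicate_depth_ratio_is_3_to_1(self):
        ds = simulate_dataset(SimConfig(seed=13, n_genes=20,
                                        chrom_length=1_000_000))
        for cell in ("Naive", "TEM"):
            ratio = ds["depths"][(cell, 1)] / ds["depths"][(cell, 2)]
            assert ratio == pytest.approx(3.0, rel=0.05)

    def test_poised_island_fraction_thins_planted_islands(self):
        cfg = SimConfig(seed=14, n_genes=40, chrom_length=1_200_000,
                        poised_island_fraction=0.35,
                        class_fractions={"poised_TEM": 0.5, "silent": 0.5})
        _, truth = simulate_genome(cfg)
        n_poised = len(truth.genes_of_class("poised_TEM"))
        with_island = {i.gene_id for i in truth.planted_islands}
        assert n_poised == 20
        assert len(with_island) == round(0.35 * n_poised)

    def test_decoy_gain_fraction_marks_silent_genes(self):
        cfg = SimConfig(seed=15, n_genes=40, chrom_length=1_200_000,
                        decoy_gain_fraction=0.5,
                        class_fractions={"poised_TEM": 0.5, "silent": 0.5})
        _, truth = simulate_genome(cfg)
        assert len(truth.decoy_gain_genes) == 10
        decoy_islands = [i for i in truth.planted_islands
                         if i.gene_id in set(truth.decoy_gain_genes)]
        assert all(i.cell_types == ("TEM",) for i in decoy_islands)
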