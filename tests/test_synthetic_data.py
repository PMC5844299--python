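"""Determinism, calibration and planted structure of the generator."""

import numpy as np
import pandas as pd
import pytest

import methylome_kit as mk
from methylome_kit.synthetic_data import (
    SimulationConfig,
    simulate_amplicon_panel,
    simulate_counts,
    simulate_genome,
    simulate_study,
)

TINY = SimulationConfig(seed=5, n_contigs=2, contig_length=40_000, n_genes=10)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        a = simulate_study(TINY, outdir=tmp_path / "a")
        b = simulate_study(TINY, outdir=tmp_path / "b")
        assert (tmp_path / "a/genome.fa").read_bytes() == (tmp_path / "b/genome.fa").read_bytes()
        assert (
            (tmp_path / "a/cytosine_report.tsv").read_bytes()
            == (tmp_path / "b/cytosine_report.tsv").read_bytes()
        )
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_different_seed_differs(self):
        a = simulate_genome(TINY)
        b = simulate_genome(SimulationConfig(**{**TINY.__dict__, "seed": 6}))
        assert a.sequences != b.sequences


class TestGenomeStructure:
    def test_genes_fit_and_do_not_overlap(self):
        study = simulate_genome(TINY)
        by_chrom = {}
        for g in study.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            assert 1 <= g.start <= g.end <= TINY.contig_length
            assert 2 <= len(g.exons) <= 6
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] < b[0] for a, b in zip(ivs, ivs[1:]))

    def test_overfull_contig_raises_helpful_error(self):
        cfg = SimulationConfig(seed=0, n_contigs=1, contig_length=5_000, n_genes=10)
        with pytest.raises(ValueError, match="contig_length"):
            simulate_genome(cfg)

    def test_deamination_depletes_cpg_oe_in_methylated_genes(self):
        from methylome_kit.cpg_depletion import gene_cpg_oe

        base = dict(TINY.__dict__, n_genes=40, contig_length=120_000,
                    frac_methylated_genes=0.5)
        plain = simulate_genome(SimulationConfig(**{**base, "deamination_strength": 0.0}))
        depleted = simulate_genome(SimulationConfig(**{**base, "deamination_strength": 0.5}))

        def class_gap(study):
            oe = gene_cpg_oe(study.sequences, study.genes)
            m = oe.merge(study.truth.genes, on="gene_id")
            by = m.groupby("true_class")["cpg_oe"].mean()
            return by["nonmethylated"] - by["methylated"]

        assert abs(class_gap(plain)) < 0.1
        assert class_gap(depleted) > 0.2

    def test_site_truth_covers_all_cpgs(self):
        study = simulate_genome(TINY)
        cpgs = mk.enumerate_genome_cpgs(study.sequences)
        assert len(study.truth.sites) == len(cpgs)
        # paired strand cytosines share their true fraction
        s = study.truth.sites
        plus = s[s["strand"] == "+"].set_index(["chrom", "pos"])["true_m"]
        minus = s[s["strand"] == "-"]
        paired = plus.loc[list(zip(minus["chrom"], minus["pos"] - 1))]
        assert np.array_equal(paired.to_numpy(), minus["true_m"].to_numpy())


class TestCountModel:
    def _one_site_study(self, true_m, error_rate, coverage):
        study = simulate_genome(TINY)
        sites = study.truth.sites.copy()
        sites["true_m"] = true_m
        study.truth.sites = sites
        cfg = SimulationConfig(
            **{**TINY.__dict__, "error_rate": error_rate,
               "mean_coverage": coverage, "non_cpg_fraction": 0.0}
        )
        study.config = cfg
        return simulate_counts(study, rng=np.random.default_rng(3))

    def test_unmethylated_without_error_all_zero(self):
        counts = self._one_site_study(0.0, 1e-12, 30)
        assert (counts["n_meth"] == 0).all()

    def test_methylated_without_error_all_meth(self):
        counts = self._one_site_study(1.0, 1e-12, 30)
        assert (counts["n_unmeth"] == 0).all()

    def test_error_rate_recovered_at_depth(self):
        counts = self._one_site_study(0.0, 0.01, 1000)
        total = counts[["n_meth", "n_unmeth"]].sum().sum()
        rate = counts["n_meth"].sum() / total
        assert abs(rate - 0.01) < 3 * np.sqrt(0.01 * 0.99 / total)

    def test_marginal_calibration_mixture(self):
        # pooled level converges to m + (1-m)*error at high coverage
        counts = self._one_site_study(0.4, 0.01, 10_000)
        level = counts["n_meth"].sum() / counts[["n_meth", "n_unmeth"]].sum().sum()
        assert level == pytest.approx(0.4 + 0.6 * 0.01, abs=0.002)


class TestExpressionModel:
    def test_coupling_raises_methylated_expression(self, small_study):
        gt = small_study.truth.genes
        expr = small_study.expression.merge(gt, on="gene_id")
        med = expr.groupby("true_class")["fpkm"].median()
        assert med["methylated"] > med["nonmethylated"]

    def test_zero_coupling_classes_indistinguishable(self):
        from scipy.stats import mannwhitneyu

        cfg = SimulationConfig(
            **{**TINY.__dict__, "n_genes": 60, "contig_length": 200_000,
               "expression_coupling": 0.0, "silent_fraction_nonmethylated": 0.0,
               "silent_fraction_methylated": 0.0, "frac_methylated_genes": 0.5}
        )
        study = simulate_study(cfg)
        m = study.expression.merge(study.truth.genes, on="gene_id")
        a = m.loc[m["true_class"] == "methylated", "fpkm"]
        b = m.loc[m["true_class"] == "nonmethylated", "fpkm"]
        assert mannwhitneyu(a, b).pvalue > 0.01

    def test_silent_fraction_planted(self):
        cfg = SimulationConfig(
            **{**TINY.__dict__, "n_genes": 300, "n_contigs": 4,
               "contig_length": 300_000, "silent_fraction_nonmethylated": 0.3,
               "frac_methylated_genes": 0.0}
        )
        study = simulate_study(cfg)
        frac0 = (study.expression["fpkm"] == 0).mean()
        assert frac0 == pytest.approx(0.3, abs=0.08)


class TestAmpliconPanel:
    SITES = pd.DataFrame(
        {
            "gene_id": ["KDM4", "OXCT"],
            "scaffold": ["s480", "s211"],
            "pos": [8283, 282391],
            "mean_short": [0.325, 0.937],
            "diff": [0.323, -0.035],
        }
    )

    def test_sample_count_and_labels(self):
        samples, labels, truth = simulate_amplicon_panel(self.SITES, seed=0)
        assert len(samples) == 16
        assert (labels.value_counts() == 8).all()
        assert truth["mean_long"].tolist() == pytest.approx([0.648, 0.902])

    def test_invalid_planted_probability_rejected(self):
        bad = self.SITES.assign(diff=[0.9, 0.2])
        with pytest.raises(ValueError, match="outside"):
            simulate_amplicon_panel(bad, seed=0)

    def test_group_means_recover_planted_levels(self):
        samples, labels, _ = simulate_amplicon_panel(
            self.SITES, coverage=2000, seed=4
        )
        fr, _ = mk.site_fractions(samples, min_reads=10)
        long_cols = [c for c in fr.columns if labels[c] == "long"]
        mean_long = fr[long_cols].mean(axis=1)
        expected = 0.648 + (1 - 0.648) * 0.01  # planted + residual error
        assert mean_long.iloc[0] == pytest.approx(expected, abs=0.02)
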