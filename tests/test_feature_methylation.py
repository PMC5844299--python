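"""Site-to-feature assignment, methylation ratios and gene classes."""

import numpy as np
import pandas as pd
import pytest

from methylome_kit.feature_methylation import (
    FEATURE_CLASSES,
    assign_sites,
    classify_genes,
    compute_ratios,
    feature_summary,
)
from methylome_kit.io_formats import GeneModel


def _calls(positions, chrom="c", methylated=None):
    n = len(positions)
    meth = methylated if methylated is not None else [False] * n
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": ["+"] * n,
            "is_methylated": meth,
            "level": [1.0 if m else 0.0 for m in meth],
        }
    )


GENE = GeneModel("g1", "c", "+", 100, 400, ((100, 200), (300, 400)))


class TestAssignSites:
    def test_exonic_site(self):
        out = assign_sites(_calls([150]), [GENE])
        assert out[["gene_id", "feature_class"]].values.tolist() == [["g1", "exon"]]

    def test_intronic_site(self):
        out = assign_sites(_calls([250]), [GENE])
        assert out["feature_class"].tolist() == ["intron"]

    def test_minus_strand_upstream_window(self):
        g = GeneModel("g2", "c", "-", 1000, 1500, ((1000, 1500),))
        out = assign_sites(_calls([2000]), [g], contig_lengths={"c": 5000})
        assert out["feature_class"].tolist() == ["upstream2kb"]
        # 500 bp 5' of a + strand gene start is upstream too
        gp = GeneModel("g3", "c", "+", 1000, 1500, ((1000, 1500),))
        out = assign_sites(_calls([500]), [gp])
        assert out["feature_class"].tolist() == ["upstream2kb"]

    def test_site_in_two_overlapping_genes_counted_in_each(self):
        g2 = GeneModel("g2", "c", "+", 150, 600, ((150, 600),))
        out = assign_sites(_calls([180]), [GENE, g2])
        assert sorted(out["gene_id"]) == ["g1", "g2"]

    def test_matches_bruteforce_interval_scan(self, rng):
        genes = []
        for i in range(25):
            start = int(rng.integers(1, 8000))
            n_ex = int(rng.integers(1, 4))
            exons, p = [], start
            for _ in range(n_ex):
                length = int(rng.integers(20, 200))
                exons.append((p, p + length - 1))
                p += length + int(rng.integers(20, 150))
            genes.append(
                GeneModel(
                    f"g{i}", "c", str(rng.choice(["+", "-"])),
                    start, exons[-1][1], tuple(exons),
                )
            )
        positions = rng.integers(1, 10_000, 300).tolist()
        got = assign_sites(
            _calls(positions), genes, contig_lengths={"c": 10_000}
        )
        got_set = set(zip(got["pos"], got["gene_id"], got["feature_class"]))
        expected = set()
        for pos in positions:
            for g in genes:
                if any(s <= pos <= e for s, e in g.exons):
                    expected.add((pos, g.gene_id, "exon"))
                elif g.start <= pos <= g.end:
                    expected.add((pos, g.gene_id, "intron"))
                up = g.upstream_interval(contig_length=10_000)
                if up and up[0] <= pos <= up[1]:
                    expected.add((pos, g.gene_id, "upstream2kb"))
        assert got_set == expected


class TestComputeRatios:
    def test_hand_counted_ratio(self):
        calls = _calls([110, 120, 310, 320], methylated=[True, True, False, False])
        out = compute_ratios(assign_sites(calls, [GENE]), calls)
        row = out.set_index("gene_id").loc["g1"]
        assert row["exon_n_detected"] == 4
        assert row["exon_ratio"] == 0.5
        assert row["gene_class"] == "methylated"

    def test_no_methylation_anywhere(self):
        calls = _calls([110, 250])
        out = compute_ratios(assign_sites(calls, [GENE]), calls)
        row = out.set_index("gene_id").loc["g1"]
        assert row["exon_ratio"] == 0.0
        assert row["intron_ratio"] == 0.0
        assert not row["has_any_mcpg"]

    def test_undefined_ratio_flagged_not_zero(self):
        calls = _calls([250])  # intron only
        out = compute_ratios(assign_sites(calls, [GENE]), calls)
        row = out.set_index("gene_id").loc["g1"]
        assert np.isnan(row["exon_ratio"])
        assert pd.isna(row["gene_class"])

    def test_genes_without_sites_retained(self):
        calls = _calls([150])
        far = GeneModel("g9", "c2", "+", 1, 100, ((1, 100),))
        out = compute_ratios(assign_sites(calls, [GENE, far]), calls, genes=[GENE, far])
        assert set(out["gene_id"]) == {"g1", "g9"}
        assert np.isnan(out.set_index("gene_id").loc["g9", "exon_ratio"])

    def test_partition_exon_xor_intron(self, small_study, small_calls):
        assign = assign_sites(small_calls, small_study.genes, small_study.contig_lengths)
        genic = assign[assign["feature_class"].isin(["exon", "intron"])]
        dup = genic.duplicated(["chrom", "pos", "strand", "gene_id"])
        assert not dup.any()

    def test_percent_mc_is_weighted_recount(self, small_study, small_calls):
        assign = assign_sites(small_calls, small_study.genes, small_study.contig_lengths)
        gt = compute_ratios(assign, small_calls, genes=small_study.genes)
        summ = feature_summary(gt).set_index("feature_class")
        merged = assign.merge(small_calls, on=["chrom", "pos", "strand"])
        for feat in FEATURE_CLASSES:
            sub = merged[merged["feature_class"] == feat]
            expected = 100.0 * sub["is_methylated"].sum() / len(sub)
            assert summ.loc[feat, "percent_mC"] == pytest.approx(expected)

    def test_exon_exceeds_intron_with_exon_biased_planting(
        self, small_study, small_calls
    ):
        assign = assign_sites(small_calls, small_study.genes, small_study.contig_lengths)
        gt = compute_ratios(assign, small_calls, genes=small_study.genes)
        summ = feature_summary(gt).set_index("feature_class")
        assert summ.loc["exon", "percent_mC"] > summ.loc["intron", "percent_mC"]


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "ratio, expected", [(0.11, "methylated"), (0.10, "nonmethylated"), (0.0, "nonmethylated")]
    )
    def test_strict_threshold_edge(self, ratio, expected):
        gt = pd.DataFrame({"gene_id": ["g"], "exon_ratio": [ratio]})
        assert classify_genes(gt)["gene_class"].iloc[0] == expected

    def test_class_recovery_on_simulation(self, small_study, small_gene_table):
        merged = small_gene_table.merge(small_study.truth.genes, on="gene_id")
        ok = merged.dropna(subset=["gene_class"])
        concordance = (ok["gene_class"] == ok["true_class"]).mean()
        assert concordance >= 0.9
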