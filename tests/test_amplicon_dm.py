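"""Amplicon fraction matrices, coverage filtering and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from methylome_kit.amplicon_dm import compare_groups, concordance_wgbs, site_fractions


def _sample(n_meth, n_total, pos=None):
    n = len(n_meth)
    return pd.DataFrame(
        {
            "gene_id": ["g"] * n,
            "scaffold": ["s"] * n,
            "pos": pos if pos is not None else list(range(1, n + 1)),
            "n_meth": n_meth,
            "n_total": n_total,
        }
    )


def _fractions(matrix, labels=None):
    """Rows = sites, columns = sample names; wraps into the fraction frame."""
    idx = pd.MultiIndex.from_tuples(
        [("g", "s", i + 1) for i in range(matrix.shape[0])],
        names=["gene_id", "scaffold", "pos"],
    )
    cols = [f"long_{i}" for i in range(1, 9)] + [f"short_{i}" for i in range(1, 9)]
    cols = cols[: matrix.shape[1]]
    return pd.DataFrame(matrix, index=idx, columns=cols)


LABELS = pd.Series(
    {f"long_{i}": "long" for i in range(1, 9)} | {f"short_{i}": "short" for i in range(1, 9)}
)


class TestSiteFractions:
    def test_basic_fraction(self):
        fr, dropped = site_fractions({"a": _sample([50], [100])}, min_reads=10)
        assert fr.iloc[0, 0] == 0.5
        assert dropped == 0

    def test_site_below_threshold_everywhere_dropped(self):
        tables = {f"s{i}": _sample([1, 5], [9, 50]) for i in range(16)}
        fr, dropped = site_fractions(tables, min_reads=10)
        assert dropped == 1
        assert fr.index.get_level_values("pos").tolist() == [2]

    def test_thin_sample_becomes_missing_at_retained_site(self):
        tables = {"a": _sample([5], [50]), "b": _sample([1], [5])}
        fr, _ = site_fractions(tables, min_reads=10)
        assert fr.loc[("g", "s", 1), "a"] == 0.1
        assert np.isnan(fr.loc[("g", "s", 1), "b"])

    def test_inconsistent_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            site_fractions(
                {"a": _sample([1], [20], pos=[1]), "b": _sample([1], [20], pos=[2])}
            )

    def test_filter_matches_bruteforce_rule(self, rng):
        for _ in range(10):
            n_sites = 30
            tables = {
                f"s{i}": _sample(
                    [0] * n_sites, rng.integers(0, 25, n_sites).tolist()
                )
                for i in range(6)
            }
            fr, dropped = site_fractions(tables, min_reads=10)
            cov = np.column_stack([t["n_total"] for t in tables.values()])
            expected_keep = (cov >= 10).any(axis=1)
            assert dropped == int((~expected_keep).sum())
            kept_pos = fr.index.get_level_values("pos").to_numpy()
            assert np.array_equal(kept_pos, np.flatnonzero(expected_keep) + 1)

    def test_planted_retained_count_recovered(self, rng):
        # 322 sites pass the rule by construction, mirroring a panel QC
        n_sites = 400
        pass_rule = np.zeros(n_sites, dtype=bool)
        pass_rule[rng.choice(n_sites, 322, replace=False)] = True
        tables = {}
        for i in range(16):
            cov = rng.integers(0, 10, n_sites)  # all below threshold
            tables[f"s{i}"] = _sample([0] * n_sites, cov.tolist())
        # give each passing site one deep sample
        deep_sample = rng.integers(0, 16, n_sites)
        for j in np.flatnonzero(pass_rule):
            tables[f"s{deep_sample[j]}"].loc[j, "n_total"] = 100
        fr, dropped = site_fractions(tables, min_reads=10)
        assert len(fr) == 322
        assert dropped == n_sites - 322


class TestCompareGroups:
    def test_table1_style_mean_difference(self):
        # per-sample fractions equal to the group means recover the
        # printed long-minus-short differences exactly
        m = np.array([[0.648] * 8 + [0.325] * 8])
        st = compare_groups(_fractions(m), LABELS)
        assert st.loc[0, "meth_diff"] == pytest.approx(0.648 - 0.325, abs=1e-12)
        assert st.loc[0, "mean_long"] == pytest.approx(0.648)
        assert st.loc[0, "mean_short"] == pytest.approx(0.325)

    def test_identical_groups_no_difference(self):
        row = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        m = np.array([row + row])
        st = compare_groups(_fractions(m), LABELS)
        assert st.loc[0, "meth_diff"] == 0.0
        assert st.loc[0, "p_value"] == pytest.approx(1.0)

    def test_degenerate_equal_constants_p_one(self):
        m = np.array([[0.5] * 16])
        st = compare_groups(_fractions(m), LABELS)
        assert st.loc[0, "p_value"] == 1.0
        assert st.loc[0, "meth_diff"] == 0.0

    def test_label_swap_negates_difference(self, rng):
        m = rng.random((5, 16))
        a = compare_groups(_fractions(m), LABELS).set_index("pos")
        swapped = LABELS.map({"long": "short", "short": "long"})
        b = compare_groups(_fractions(m), swapped).set_index("pos")
        assert np.allclose(a["meth_diff"], -b["meth_diff"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_too_few_samples_site_skipped(self):
        m = np.full((1, 16), 0.4)
        m[0, :7] = np.nan  # one long sample left
        st = compare_groups(_fractions(m), LABELS)
        assert bool(st.loc[0, "skipped"])
        assert np.isnan(st.loc[0, "p_value"])

    def test_sorted_by_absolute_difference(self, rng):
        m = np.vstack(
            [
                [0.9] * 8 + [0.1] * 8,
                [0.5] * 8 + [0.45] * 8,
                [0.2] * 8 + [0.8] * 8,
            ]
        ) + rng.normal(0, 0.01, (3, 16))
        st = compare_groups(_fractions(m), LABELS)
        diffs = st["meth_diff"].abs().to_numpy()
        assert (np.diff(diffs) <= 0).all()

    def test_planted_difference_power(self, rng):
        # planted 0.2 shift at coverage-500-scale noise: essentially always found
        hits = 0
        for _ in range(50):
            noise = rng.normal(0, 0.02, (1, 16))
            m = np.clip(np.array([[0.5] * 8 + [0.3] * 8]) + noise, 0, 1)
            st = compare_groups(_fractions(m), LABELS)
            hits += st.loc[0, "p_value"] < 0.05
        assert hits >= 45


class TestConcordance:
    def test_identical_vectors_r2_one(self):
        x = np.array([0.1, 0.4, 0.9, 0.3])
        res = concordance_wgbs(x, x)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_anticorrelated_flagged(self):
        res = concordance_wgbs([0.9, 0.5, 0.1], [0.1, 0.5, 0.9])
        assert res["negative_slope"]

    def test_attenuation_from_binomial_noise(self, rng):
        # R^2 between two noisy measurements of shared truth approaches
        # the attenuation prediction var(m)/(var(m)+2*noise-ish)
        n = 300
        cov_a, cov_b = 200, 200
        m = rng.beta(2, 2, n)
        a = rng.binomial(cov_a, m) / cov_a
        b = rng.binomial(cov_b, m) / cov_b
        res = concordance_wgbs(a, b)
        var_m = np.var(m)
        noise = np.mean(m * (1 - m)) / cov_a
        expected = (var_m / (var_m + noise)) ** 2  # corr^2 of two noisy copies
        assert res["r_squared"] == pytest.approx(expected, abs=0.08)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="3"):
            concordance_wgbs([0.1, 0.2], [0.1, 0.2])
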