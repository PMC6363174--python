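"""NB differential expression, BH adjustment, biomarker cascade, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plasmir import diffexpr as de


def nb_counts(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), size=size)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20]}, index=["x", "y"])
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_doubled_column_ratio(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]},
                              index=["x", "y", "z"])
        sf = de.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_per_definition_oracle(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(40, 6)),
                              index=[f"m{i}" for i in range(40)],
                              columns=[f"s{j}" for j in range(6)])
        got = de.size_factors(counts)
        geo = np.exp(np.log(counts.to_numpy()).mean(axis=1))
        expected = np.median(counts.to_numpy() / geo[:, None], axis=0)
        assert np.allclose(got.to_numpy(), expected)


def bh_by_hand(pvals):
    """Textbook step-up computed index by index."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert de.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        # (0.01, 0.02, 0.03) -> all 0.03 after step-up
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        rng = np.random.default_rng(5)
        p = rng.random(50)
        assert np.allclose(de.bh_adjust(p), bh_by_hand(p))

    def test_na_propagated_and_excluded_from_denominator(self):
        out = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # denominator is 2 (tested values only)
        assert np.allclose(out[[0, 2]], bh_by_hand([0.01, 0.04]))
        assert np.isnan(de.bh_adjust([np.nan, np.nan])).all()

    def test_permutation_invariance_and_monotonicity(self):
        rng = np.random.default_rng(6)
        p = rng.random(30)
        perm = rng.permutation(30)
        assert np.allclose(de.bh_adjust(p)[perm], de.bh_adjust(p[perm]))
        adj = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def groups_for(n1, n2):
    cols = [f"s{j}" for j in range(n1 + n2)]
    return cols, {c: ("g1" if j < n1 else "g2") for j, c in enumerate(cols)}


class TestNbTest:
    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(0)
        cols, groups = groups_for(5, 5)
        counts = pd.DataFrame(nb_counts(rng, 100.0, 0.2, (2000, 10)),
                              index=[f"m{i}" for i in range(2000)], columns=cols)
        res = de.nb_test(counts, groups)
        frac = float((res["pvalue"].dropna() < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_fourfold_changes(self):
        rng = np.random.default_rng(1)
        cols, groups = groups_for(10, 10)
        n_genes, n_de = 2000, 100
        mu = np.full(n_genes, 200.0)
        mu2 = mu.copy()
        mu2[:n_de] *= 4.0
        c1 = nb_counts(rng, mu[:, None], 0.1, (n_genes, 10))
        c2 = nb_counts(rng, mu2[:, None], 0.1, (n_genes, 10))
        counts = pd.DataFrame(np.hstack([c1, c2]),
                              index=[f"m{i}" for i in range(n_genes)], columns=cols)
        res = de.nb_test(counts, groups)
        recall = float((res["padj"].iloc[:n_de] < 0.05).mean())
        assert recall >= 0.9

    def test_all_zero_mirna_untested(self):
        rng = np.random.default_rng(2)
        cols, groups = groups_for(3, 3)
        counts = pd.DataFrame(rng.integers(10, 100, (5, 6)),
                              index=[f"m{i}" for i in range(5)], columns=cols)
        counts.iloc[0] = 0
        res = de.nb_test(counts, groups)
        assert np.isnan(res["pvalue"].iloc[0]) and np.isnan(res["padj"].iloc[0])
        assert res["pvalue"].iloc[1:].notna().all()

    def test_poisson_limit_agrees_with_poisson_wald(self):
        """On Poisson data with enough replicates for the estimated
        dispersion to vanish, the NB Wald p-value approaches the
        pure-Poisson Wald p-value."""
        rng = np.random.default_rng(3)
        n = 100
        cols, groups = groups_for(n, n)
        counts = pd.DataFrame(rng.poisson(500.0, (300, 2 * n)),
                              index=[f"m{i}" for i in range(300)], columns=cols)
        res = de.nb_test(counts, groups)
        norm = counts / de.size_factors(counts)
        m1 = norm.iloc[:, :n].mean(axis=1).to_numpy()
        m2 = norm.iloc[:, n:].mean(axis=1).to_numpy()
        lfc = np.log2((m2 + 0.5) / (m1 + 0.5))
        se = np.sqrt((1 / (m1 * n) + 1 / (m2 * n))) / np.log(2)
        p_pois = 2 * stats.norm.sf(np.abs(lfc / se))
        mask = p_pois > 1e-6
        ratio = res["pvalue"].to_numpy()[mask] / p_pois[mask]
        assert np.median(np.abs(ratio - 1)) < 0.10

    def test_small_group_rejected(self):
        cols, groups = groups_for(1, 3)
        counts = pd.DataFrame(np.ones((3, 4), int), columns=cols,
                              index=list("abc"))
        with pytest.raises(ValueError, match="replicate"):
            de.nb_test(counts, groups)


def de_frame(rows):
    df = pd.DataFrame(rows).set_index("mirna")
    df["baseMean"] = (df["baseMean_group1"] + df["baseMean_group2"]) / 2
    return df


class TestSelectBiomarkers:
    def make_results(self):
        rows = []
        for i, (lfc, padj, base2) in enumerate(
            [
                (2.5, 0.01, 100), (2.0, 0.01, 50), (1.5, 0.01, 5),  # ups, one low
                (-2.2, 0.01, 80), (-1.4, 0.01, 40), (-1.2, 0.01, 9),  # downs
                (3.0, 0.20, 100),  # not significant
                (0.5, 0.001, 100),  # small effect
            ]
        ):
            rows.append({"mirna": f"m{i}", "log2fc": lfc, "padj": padj,
                         "pvalue": padj / 2, "baseMean_group1": 10.0,
                         "baseMean_group2": float(base2)})
        return de_frame(rows)

    def test_cascade_matches_sort_oracle(self):
        res = self.make_results()
        panel = de.select_biomarkers(res, min_base=10, n_up=2, n_down=1)
        assert panel.candidates_stage1 == ["m0", "m1", "m2", "m3", "m4", "m5"]
        assert panel.candidates_stage2 == ["m0", "m1", "m3", "m4"]
        # oracle: sort stage2 ups by (-lfc, name), downs by (lfc, name)
        assert panel.panel_up == ["m0", "m1"]
        assert panel.panel_down == ["m3"]

    def test_stage_nesting_enforced(self):
        panel = de.select_biomarkers(self.make_results())
        assert set(panel.panel) <= set(panel.candidates_stage2)
        assert set(panel.candidates_stage2) <= set(panel.candidates_stage1)

    def test_empty_panel_with_warning(self, caplog):
        res = self.make_results()
        res["padj"] = 0.9
        with caplog.at_level("WARNING"):
            panel = de.select_biomarkers(res)
        assert panel.panel == [] and "empty panel" in caplog.text

    def test_planted_cohort_panel_recovered(self, cohort):
        groups = dict(zip(cohort.meta["sample_id"], cohort.meta["group"]))
        cols = cohort.healthy_samples + cohort.hcc_samples
        res = de.nb_test(cohort.plasma.counts[cols],
                         {s: groups[s] for s in cols},
                         group_order=("healthy", "hcc"))
        panel = de.select_biomarkers(res)
        assert set(panel.panel) == set(cohort.truth["expected_panel"])


class TestClusterSamples:
    def test_two_separated_groups_recovered(self, cohort):
        order, cut = de.cluster_samples(
            cohort.plasma.rpm, cohort.truth["expected_panel"]
        )
        healthy = set(cohort.healthy_samples)
        labels = {cut[s] for s in healthy}
        assert len(labels) == 1
        assert {cut[s] for s in cohort.hcc_samples} != labels

    def test_single_sample_trivial_tree(self):
        rpm = pd.DataFrame({"only": [1.0, 2.0]}, index=["a", "b"])
        order, cut = de.cluster_samples(rpm)
        assert order == ["only"] and cut == {"only": 1}

    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(8)
        base = rng.random(10)
        rpm = pd.DataFrame({"a": base, "b": base, "c": rng.random(10)})
        order, _ = de.cluster_samples(rpm)
        ia, ib = order.index("a"), order.index("b")
        assert abs(ia - ib) == 1
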