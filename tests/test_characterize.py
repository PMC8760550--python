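"""Fisher r x c, clinical contrasts, differential abundance, shortlists,
fold changes and trait associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import hypergeom, kstest
from statsmodels.stats.multitest import multipletests

from plasmarch import (cluster_clinical_tests, differential_abundance,
                       fisher_exact_rxc, median_fold_change, shortlist,
                       trait_association)

from conftest import bh_stepup_bruteforce


class TestFisherRxC:
    @pytest.mark.parametrize("table", [
        [[3, 5], [7, 2]],
        [[10, 0], [0, 10]],
        [[27, 51], [155, 315]],
        [[1, 9], [11, 3]],
    ])
    def test_2x2_agrees_with_hypergeometric_closed_form(self, table):
        res = fisher_exact_rxc(table)
        assert abs(res.p - scipy_fisher(table)[1]) < 1e-12

    def test_perfectly_discordant_2x2(self):
        """[[10,0],[0,10]]: p = 2 / C(20,10) by direct enumeration."""
        res = fisher_exact_rxc([[10, 0], [0, 10]])
        expected = 2.0 / np.exp(gammaln(21) - 2 * gammaln(11))
        assert res.p == pytest.approx(expected, rel=1e-10)
        assert res.p == pytest.approx(1.0825e-5, rel=1e-3)

    def test_rxc_exact_vs_bruteforce_small(self):
        """Tiny 3x3: brute-force enumeration over the first two free rows."""
        table = np.array([[3, 1, 2], [2, 4, 1], [1, 2, 5]])
        rows, cols = table.sum(1), table.sum(0)
        n = table.sum()
        lg = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
              - gammaln(n + 1))

        def logp(t):
            return lg - gammaln(np.asarray(t) + 1.0).sum()

        p_obs = logp(table)
        total = 0.0
        for a in range(rows[0] + 1):
            for b in range(rows[0] + 1 - a):
                c = rows[0] - a - b
                for d in range(rows[1] + 1):
                    for e in range(rows[1] + 1 - d):
                        f = rows[1] - d - e
                        g, h, i = cols[0] - a - d, cols[1] - b - e, cols[2] - c - f
                        if min(g, h, i) < 0:
                            continue
                        lp = logp([[a, b, c], [d, e, f], [g, h, i]])
                        if lp <= p_obs + 1e-7:
                            total += np.exp(lp)
        res = fisher_exact_rxc(table)
        assert res.method == "exact"
        assert res.p == pytest.approx(min(total, 1.0), rel=1e-9)

    def test_montecarlo_converges_to_exact(self):
        table = [[12, 7, 9], [8, 14, 6]]
        exact = fisher_exact_rxc(table, method="exact")
        mc = fisher_exact_rxc(table, method="montecarlo", mc_draws=200_000,
                              seed=5)
        mc2 = fisher_exact_rxc(table, method="montecarlo", mc_draws=400_000,
                               seed=6)
        assert abs(mc.p - exact.p) < 4 * mc.mc_se
        assert abs(mc2.p - mc.p) < 3 * mc.mc_se

    def test_errors(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, 2]])
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -2], [3, 4]])


class TestClinicalTests:
    def test_null_pvalues_uniform(self):
        """Label-independent continuous variables: p uniform over many
        simulated variables (KS)."""
        rng = np.random.default_rng(0)
        n = 200
        labels = pd.Series(rng.integers(1, 4, n),
                           index=[f"S{i}" for i in range(n)])
        ann = pd.DataFrame({f"v{j}": rng.normal(size=n) for j in range(100)},
                           index=labels.index)
        res = cluster_clinical_tests(ann, labels, [f"v{j}" for j in range(100)])
        pv = [c.p for c in res if c.scope == "cluster_vs_rest"
              and c.groups == (1,)]
        assert len(pv) == 100
        assert kstest(pv, "uniform").pvalue > 0.01

    def test_constant_categorical_raises(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        ann = pd.DataFrame({"v": ["x", "x", "x", "x"]}, index=labels.index)
        with pytest.raises(ValueError):
            cluster_clinical_tests(ann, labels, ["v"])

    def test_planted_mht_enrichment_detected(self):
        """One small cluster enriched for MHT ever-use (odds ratio ~8) is
        separated from every other cluster by Fisher's test at n ~ 550."""
        rng = np.random.default_rng(1)
        sizes = {1: 20, 2: 130, 3: 130, 4: 130, 5: 140}
        labels, status = [], []
        for c, sz in sizes.items():
            p_ever = 0.85 if c == 1 else 0.41  # OR ~ 8
            labels += [c] * sz
            status += list(rng.choice(["before", "never"],
                                      p=[p_ever, 1 - p_ever], size=sz))
        idx = [f"S{i}" for i in range(len(labels))]
        ann = pd.DataFrame({"mht_status": status}, index=idx)
        res = cluster_clinical_tests(ann, pd.Series(labels, index=idx),
                                     ["mht_status"])
        pairwise_with_1 = [c for c in res if c.scope == "pairwise"
                           and 1 in c.groups]
        assert len(pairwise_with_1) == 4
        assert all(c.p < 0.05 for c in pairwise_with_1)


class TestDifferentialAbundance:
    def make_logmatrix(self, rng, n=60, p=100):
        vals = pd.DataFrame(rng.normal(7, 0.5, (n, p)),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"AB_{j}" for j in range(p)])
        return vals

    def test_null_permuted_labels_no_fdr_findings(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_seeds = 60
        for _ in range(n_seeds):
            vals = self.make_logmatrix(rng)
            labels = pd.Series(rng.permutation([1] * 15 + [2] * 45),
                               index=vals.index)
            res = differential_abundance(vals, labels, 1,
                                         raw=np.exp(vals))
            hits += (res.table["fdr"] < 0.05).any()
        assert hits <= 0.05 * n_seeds + 2

    def test_power_and_fdr_with_planted_shift(self):
        """1.5 log-sd shift on 40 of 200 antibodies: nearly all recovered,
        almost no false positives (median over seeds)."""
        rng = np.random.default_rng(3)
        tps, fps = [], []
        for _ in range(10):
            n, p = 60, 200
            vals = pd.DataFrame(rng.normal(0, 1.0, (n, p)),
                                index=[f"S{i}" for i in range(n)],
                                columns=[f"AB_{j}" for j in range(p)])
            members = vals.index[:15]
            shifted = vals.columns[:40]
            vals.loc[members, shifted] += 1.5
            labels = pd.Series([1] * 15 + [2] * 45, index=vals.index)
            res = differential_abundance(vals, labels, 1, raw=np.exp(vals))
            sig = res.table.index[res.table["fdr"] < 0.05]
            tps.append(len(set(sig) & set(shifted)))
            fps.append(len(set(sig) - set(shifted)))
        assert np.median(tps) >= 35
        assert np.median(fps) <= 2

    def test_identical_groups_all_p_near_one(self):
        rng = np.random.default_rng(4)
        block = rng.normal(7, 0.5, (20, 30))
        vals = pd.DataFrame(np.vstack([block, block]),
                            index=[f"S{i}" for i in range(40)],
                            columns=[f"AB_{j}" for j in range(30)])
        labels = pd.Series([1] * 20 + [2] * 20, index=vals.index)
        res = differential_abundance(vals, labels, 1, raw=np.exp(vals))
        assert (res.table["p"] > 0.999).all()
        assert not (res.table["fdr"] < 0.05).any()

    def test_bh_agrees_with_bruteforce_stepup(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            p = rng.uniform(size=rng.integers(3, 20))
            _, adj_expected = bh_stepup_bruteforce(p)
            adj = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adj, adj_expected, atol=1e-12)

    def test_degenerate_group_sizes_raise(self):
        vals = self.make_logmatrix(np.random.default_rng(6), n=10)
        labels = pd.Series([1] * 2 + [2] * 8, index=vals.index)
        with pytest.raises(ValueError):
            differential_abundance(vals, labels, 1)


class TestShortlistFoldChange:
    def make_result(self, p, diff):
        table = pd.DataFrame({
            "mean_diff": diff, "t_stat": diff, "p": p,
            "fdr": p, "fc_signed": np.sign(diff),
            "direction": np.where(np.asarray(diff) > 0, "higher_in_cluster",
                                  "lower_in_cluster"),
        }, index=[f"AB_{j}" for j in range(len(p))])
        from plasmarch.containers import DifferentialResult
        return DifferentialResult(table=table, cluster_id=1, n_cluster=5,
                                  n_rest=10)

    def test_identical_rankings_give_size_m(self):
        p = np.linspace(0.001, 0.5, 40)
        diff = np.linspace(2.0, 0.1, 40)  # same ordering as p
        res = self.make_result(p, diff)
        sl = shortlist(res, m=10)
        assert len(sl["higher"]) == 10

    def test_disjoint_rankings_give_size_2m(self):
        n = 40
        p = np.concatenate([np.linspace(1e-4, 1e-3, 10),
                            np.full(n - 10, 0.5)])
        diff = np.concatenate([np.full(10, 0.1),
                               np.linspace(3.0, 2.0, 10),
                               np.full(n - 20, 0.2)])
        res = self.make_result(p, diff)
        sl = shortlist(res, m=10)
        assert len(sl["higher"]) == 20

    def test_small_direction_falls_back_to_all(self, caplog):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        diff = np.array([1.0, 1.0, -1.0, -1.0])
        res = self.make_result(p, diff)
        sl = shortlist(res, m=10)
        assert sl["higher"] == {"AB_0", "AB_1"}

    def test_fold_change_conventions(self):
        vals = pd.DataFrame({
            "AB_equal": [10.0] * 8,
            "AB_double": [20.0] * 4 + [10.0] * 4,
            "AB_half": [5.0] * 4 + [10.0] * 4,
        }, index=[f"S{i}" for i in range(8)])
        labels = pd.Series([1] * 4 + [2] * 4, index=vals.index)
        fc = median_fold_change(vals, labels, 1)
        assert fc["AB_equal"] == pytest.approx(1.0)
        assert fc["AB_double"] == pytest.approx(2.0)
        assert fc["AB_half"] == pytest.approx(-2.0)

    def test_planted_linear_shift_recovered(self):
        rng = np.random.default_rng(7)
        fcs = []
        for _ in range(20):
            base = rng.lognormal(7, 0.05, (40, 1))
            vals = pd.DataFrame(base, index=[f"S{i}" for i in range(40)],
                                columns=["AB_0"])
            vals.iloc[:10] *= 1.5
            labels = pd.Series([1] * 10 + [2] * 30, index=vals.index)
            fcs.append(median_fold_change(vals, labels, 1)["AB_0"])
        assert np.median(fcs) == pytest.approx(1.5, abs=0.1)


class TestTraitAssociation:
    def annotations(self, rng, n):
        return pd.DataFrame({
            "dense_area": rng.gamma(1.3, 21, n),
            "bmi": rng.normal(25, 4, n),
            "age": rng.normal(60, 9, n),
            "mht_status": rng.choice(["never", "before", "current"],
                                     p=[0.47, 0.39, 0.14], size=n),
        }, index=[f"S{i}" for i in range(n)])

    def test_null_flag_rate_about_five_percent(self):
        rng = np.random.default_rng(8)
        n, p = 300, 100
        ann = self.annotations(rng, n)
        vals = pd.DataFrame(rng.normal(7, 0.5, (n, p)), index=ann.index,
                            columns=[f"AB_{j}" for j in range(p)])
        res = trait_association(vals, list(vals.columns), ann)
        rate = res[["dense_sig", "mht_sig"]].to_numpy().mean()
        assert 0.01 < rate < 0.10

    def test_planted_mht_effect_detected(self):
        """log-OR -1 per sd of protein: essentially always detected at
        n = 550."""
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(10):
            n = 550
            z = rng.normal(size=n)
            p_ever = 1 / (1 + np.exp(-(0.1 - 1.0 * z)))
            ever = rng.random(n) < p_ever
            ann = self.annotations(rng, n)
            ann["mht_status"] = np.where(ever, "before", "never")
            vals = pd.DataFrame({"AB_0": 7 + 0.5 * z}, index=ann.index)
            res = trait_association(vals, ["AB_0"], ann)
            hits += bool(res.loc["AB_0", "mht_p"] < 0.05)
        assert hits >= 9

    def test_all_missing_trait_raises(self):
        rng = np.random.default_rng(10)
        ann = self.annotations(rng, 20)
        ann["dense_area"] = np.nan
        vals = pd.DataFrame({"AB_0": rng.normal(7, 0.5, 20)}, index=ann.index)
        with pytest.raises(ValueError):
            trait_association(vals, ["AB_0"], ann)
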