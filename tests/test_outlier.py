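"""Weir–Cockerham FST, the Bayesian RJ-MCMC scan, q-values, PCA scan."""

import numpy as np
import pytest
from scipy import stats

from wingscan import (
    MCMCConfig,
    SimParams,
    bayescan_fit,
    filter_loci,
    pca,
    pcadapt_scan,
    qvalues_from_posteriors,
    simulate_genotypes,
    wc_fst,
)

from conftest import make_gm


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------


def wc_theta_oracle(pops):
    """Independent oracle: hierarchical ANOVA of allele indicators
    (gene copies within individuals within populations), variance
    components from the mean squares."""
    r = len(pops)
    n_i = [len(p) for p in pops]
    N = sum(n_i)

    def copies(g):
        return [1, 1] if g == 2 else ([0, 0] if g == 0 else [0, 1])

    ybar = sum(sum(sum(copies(g)) for g in p) for p in pops) / (2 * N)
    ybar_i = [sum(sum(copies(g)) for g in p) / (2 * len(p)) for p in pops]
    ssp = sum(2 * n_i[i] * (ybar_i[i] - ybar) ** 2 for i in range(r))
    ssi = sum(
        sum(2 * (sum(copies(g)) / 2 - ybar_i[i]) ** 2 for g in pops[i])
        for i in range(r)
    )
    ssg = sum(
        sum(sum((c - sum(copies(g)) / 2) ** 2 for c in copies(g)) for g in pops[i])
        for i in range(r)
    )
    msp, msi, msg = ssp / (r - 1), ssi / (N - r), ssg / N
    nc = (N - sum(n * n for n in n_i) / N) / (r - 1)
    s2g, s2i, s2p = msg, (msi - msg) / 2, (msp - msi) / (2 * nc)
    denom = s2p + s2i + s2g
    return s2p / denom if denom != 0 else float("nan")


class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[0]] * 10 + [[2]] * 10, ["a"] * 10 + ["b"] * 10)
        assert wc_fst(gm)[0] == pytest.approx(1.0)

    def test_null_expectation_near_zero(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.4, size=(400, 1))
        gm = make_gm(calls, ["a"] * 200 + ["b"] * 200)
        assert abs(wc_fst(gm)[0]) < 0.02

    def test_matches_anova_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 50:
            n1, n2 = rng.integers(3, 9, size=2)
            g1 = rng.integers(0, 3, n1)
            g2 = rng.integers(0, 3, n2)
            if len(set(g1) | set(g2)) == 1:
                continue  # monomorphic: both sides undefined
            gm = make_gm(
                np.concatenate([g1, g2])[:, None],
                ["a"] * int(n1) + ["b"] * int(n2),
            )
            mine = wc_fst(gm)[0]
            orc = wc_theta_oracle([list(g1), list(g2)])
            if np.isnan(orc):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(orc, abs=1e-10)
            checked += 1

    def test_missing_calls_excluded(self):
        from wingscan import MISSING

        gm = make_gm(
            [[0], [0], [MISSING], [2], [2], [MISSING]], ["a"] * 3 + ["b"] * 3
        )
        assert wc_fst(gm)[0] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        gm = make_gm([[0], [1]], ["a", "a"])
        with pytest.raises(ValueError):
            wc_fst(gm)


# ---------------------------------------------------------------------------
# q-values from posterior probabilities
# ---------------------------------------------------------------------------


class TestQvalues:
    def test_certain_outliers_get_zero(self):
        assert qvalues_from_posteriors(np.array([1.0, 1.0, 1.0])).tolist() == [0, 0, 0]

    def test_hand_computed_example(self):
        q = qvalues_from_posteriors(np.array([0.9, 0.5]))
        assert q.tolist() == pytest.approx([0.1, 0.3])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        q = qvalues_from_posteriors(p)
        order = np.argsort(-p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_ties_share_q(self):
        q = qvalues_from_posteriors(np.array([0.8, 0.8, 0.2]))
        assert q[0] == q[1]

    def test_bounds_and_self_consistency(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        q = qvalues_from_posteriors(p)
        assert (q >= 0).all() and (q <= 1 - p.min() + 1e-12).all()
        for x in (0.1, 0.3):
            sel = q <= x
            if sel.any():
                assert (1 - p[sel]).mean() <= x + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qvalues_from_posteriors(np.array([]))


# ---------------------------------------------------------------------------
# Bayesian RJ-MCMC scan
# ---------------------------------------------------------------------------


class TestBayescan:
    def test_planted_locus_has_top_posterior(self, planted_sim, fast_cfg):
        gm, truth = planted_sim
        res = bayescan_fit(gm, cfg=fast_cfg)
        planted = truth.assoc_locus_ids[0]
        assert res.table["posterior_prob"].idxmax() == planted
        assert res.table.loc[planted, "posterior_prob"] > 0.95

    def test_neutral_calibration_single_seed(self):
        gm, _ = simulate_genotypes(
            SimParams(n_group1=34, n_group2=31, n_loci=500, n_assoc=0, seed=21)
        )
        gm = filter_loci(gm, one_per_tag=False)
        res = bayescan_fit(gm, cfg=MCMCConfig.reduced(seed=22))
        assert (res.table["q_value"] <= 0.2).mean() <= 0.05

    def test_group_label_swap_symmetry(self, planted_sim):
        gm, truth = planted_sim
        cfg = MCMCConfig(n_output=1000, thinning=2, burn_in=400,
                         n_pilot=4, pilot_length=200, seed=9)
        r1 = bayescan_fit(gm, cfg=cfg)
        swapped = gm.copy()
        lv = gm.group_levels
        swapped.group_labels = [lv[1] if g == lv[0] else lv[0]
                                for g in gm.group_labels]
        r2 = bayescan_fit(swapped, groups=lv, cfg=cfg)
        dp = (r1.table["posterior_prob"] - r2.table["posterior_prob"]).abs()
        assert dp.max() < 0.05

    def test_allele_relabel_invariance_at_planted_locus(self, planted_sim):
        from wingscan import MISSING

        gm, truth = planted_sim
        cfg = MCMCConfig(n_output=1000, thinning=2, burn_in=400,
                         n_pilot=4, pilot_length=200, seed=9)
        planted = truth.assoc_locus_ids[0]
        flipped = gm.copy()
        j = flipped.locus_ids.index(planted)
        col = flipped.calls[:, j]
        flipped.calls[:, j] = np.where(col == MISSING, MISSING, 2 - col)
        r1 = bayescan_fit(gm, cfg=cfg)
        r2 = bayescan_fit(flipped, cfg=cfg)
        assert abs(
            r1.table.loc[planted, "posterior_prob"]
            - r2.table.loc[planted, "posterior_prob"]
        ) < 0.05

    def test_posterior_monotone_in_planted_divergence(self):
        medians = []
        for d in (0.0, 0.3, 0.6, 0.9):
            ps = []
            for s in range(3):
                gm, truth = simulate_genotypes(SimParams(
                    n_group1=34, n_group2=31, n_loci=300, n_assoc=1,
                    p_assoc_g1=0.5 - d / 2, p_assoc_g2=0.5 + d / 2, seed=20 + s))
                gm = filter_loci(gm, one_per_tag=False)
                lid = truth.assoc_locus_ids[0]
                if lid not in gm.locus_ids:
                    continue
                res = bayescan_fit(gm, cfg=MCMCConfig.reduced(seed=30 + s))
                ps.append(res.table.loc[lid, "posterior_prob"])
            medians.append(np.median(ps))
        assert (np.diff(medians) >= -0.02).all()

    def test_monomorphic_loci_rejected(self):
        gm = make_gm([[0, 1], [0, 0], [0, 2], [0, 1]], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="monomorphic"):
            bayescan_fit(gm, cfg=MCMCConfig.reduced(seed=1))

    def test_empty_group_at_locus_rejected(self):
        from wingscan import MISSING

        gm = make_gm([[0], [1], [MISSING], [MISSING]], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="both groups"):
            bayescan_fit(gm, cfg=MCMCConfig.reduced(seed=1))

    def test_diagnostics_recorded(self, planted_sim, fast_cfg):
        gm, _ = planted_sim
        res = bayescan_fit(gm, cfg=fast_cfg)
        assert len(res.diagnostics) == fast_cfg.n_output
        assert {"iteration", "log_posterior", "n_included"} <= set(
            res.diagnostics.columns
        )


# ---------------------------------------------------------------------------
# PCA-based scan
# ---------------------------------------------------------------------------


class TestPcadapt:
    def test_planted_loci_have_smallest_qvalues(self):
        gm, truth = simulate_genotypes(SimParams(
            n_group1=48, n_group2=48, n_loci=1000, n_assoc=5,
            p_assoc_g1=0.02, p_assoc_g2=0.98, missing_rate=0, seed=13))
        gm = filter_loci(gm, one_per_tag=False)
        res = pcadapt_scan(gm, K=1)
        top5 = set(res.nsmallest(5, "q_value").index)
        assert top5 == set(truth.assoc_locus_ids)

    def test_null_inflation_factor_near_one(self):
        gm, _ = simulate_genotypes(
            SimParams(n_loci=1000, n_assoc=0, missing_rate=0, seed=14)
        )
        gm = filter_loci(gm, one_per_tag=False)
        res = pcadapt_scan(gm, K=2)
        assert 0.8 <= res.attrs["lambda"] <= 1.2

    def test_null_pvalues_approximately_uniform(self):
        gm, _ = simulate_genotypes(
            SimParams(n_loci=2000, n_assoc=0, missing_rate=0, seed=15)
        )
        gm = filter_loci(gm, one_per_tag=False)
        res = pcadapt_scan(gm, K=2)
        ks = stats.kstest(res["p_value"].dropna(), "uniform").statistic
        assert ks < 0.05

    def test_k1_ranking_matches_group_association(self):
        """With PC1 essentially collinear with the group split, the D²
        ranking agrees with the squared group-association z-score ranking."""
        gm, _ = simulate_genotypes(SimParams(
            n_group1=40, n_group2=40, n_loci=400, n_assoc=60,
            p_assoc_g1=0.02, p_assoc_g2=0.98, missing_rate=0, seed=16))
        gm = filter_loci(gm, one_per_tag=False)
        res = pcadapt_scan(gm, K=1).dropna()
        sub = gm.subset_loci(list(res.index))
        # direct association oracle: regression z of each standardized SNP
        # on the centered group indicator
        y = np.where(np.asarray(sub.group_labels) == sub.group_levels[0], 1.0, -1.0)
        p = sub.alt_freq()
        x = np.where(sub.called_mask(), sub.calls - 2 * p, 0.0) / np.sqrt(
            2 * p * (1 - p)
        )
        pc1 = pca(sub, k_max=1).scores[:, 0]
        assert abs(stats.pearsonr(pc1, y)[0]) > 0.999
        design = np.column_stack([np.ones(len(y)), y])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        resid = x - design @ coef
        sigma2 = (resid**2).sum(axis=0) / (len(y) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[1, 1])
        z2 = (coef[1] / se) ** 2
        rho = stats.spearmanr(res["stat"].to_numpy(), z2).statistic
        assert rho > 0.995
        # the planted block tops both rankings identically
        k = 60
        assert set(res["stat"].nlargest(k).index) == set(
            res.assign(z2=z2)["z2"].nlargest(k).index
        )

    def test_k_bounds(self, planted_sim):
        gm, _ = planted_sim
        with pytest.raises(ValueError):
            pcadapt_scan(gm, K=0)
        with pytest.raises(ValueError):
            pcadapt_scan(gm, K=gm.n_individuals)
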