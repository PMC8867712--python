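import numpy as np
import pandas as pd
import pytest

from markertrait import assoc
from markertrait.genotypes import GenotypeMatrix, compute_maf
from markertrait.relatedness import centered_ibs_kinship
from markertrait.simulate import SimConfig, simulate_null_trait, simulate_trial


@pytest.fixture(scope="module")
def null_trial():
    cfg = SimConfig(seed=55, n_species=1, pops_per_species=4,
                    families_per_pop=4, offspring_per_family=12, n_loci=800)
    return simulate_null_trait(cfg)


class TestFdrAdjust:
    def test_step_up_hand_example(self):
        # BH on (0.01, 0.02, 0.03): q_i = min over j>=i of m*p_j/j
        q = assoc.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_order_invariance(self):
        assert assoc.fdr_adjust([0.2])[0] == pytest.approx(0.2)
        rng = np.random.default_rng(0)
        p = rng.uniform(size=30)
        q = assoc.fdr_adjust(p)
        perm = rng.permutation(30)
        q_perm = assoc.fdr_adjust(p[perm])
        assert np.allclose(q_perm, q[perm])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = assoc.fdr_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_missing_passed_through_empty_ok(self):
        q = assoc.fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])
        assert assoc.fdr_adjust([]).size == 0


class TestMlmScan:
    def test_null_scan_calibrated_naive_scan_inflated(self, null_trial):
        g, pheno = null_trial
        tab = assoc.mlm_scan(g, pheno["NULL"])
        p = tab["p"].dropna()
        lam_gc = assoc.genomic_control_lambda(p)
        assert 0.8 < lam_gc < 1.2
        naive = assoc.naive_scan(g, pheno["NULL"])["p"].dropna()
        assert assoc.genomic_control_lambda(naive) > 1.2

    def test_injected_qtl_attains_smallest_p(self, null_trial):
        g, pheno = null_trial
        K = centered_ibs_kinship(g)
        maf = compute_maf(g).to_numpy()
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(5):
            j = rng.choice(np.nonzero(maf > 0.2)[0])
            x = np.nan_to_num(g.calls[:, j])
            y = pheno["NULL"].to_numpy() * 0.0
            xc = x - x.mean()
            y = xc * np.sqrt(0.20 / xc.var()) \
                + rng.standard_normal(g.n_samples) * np.sqrt(0.8)
            tab = assoc.mlm_scan(g, y, K=K)
            hits += tab["p"].idxmin() == g.locus_ids[j]
        assert hits == 5

    def test_monomorphic_and_collinear_loci_flagged(self):
        rng = np.random.default_rng(3)
        n = 60
        base = rng.binomial(2, 0.4, size=(n, 20)).astype(float)
        covar = rng.binomial(2, 0.5, n).astype(float)
        calls = np.column_stack([base, np.zeros(n), covar])
        ids = [f"L{j}" for j in range(22)]
        g = GenotypeMatrix(calls, [f"s{i}" for i in range(n)], ids)
        y = rng.standard_normal(n)
        tab = assoc.mlm_scan(g, y, K=centered_ibs_kinship(g),
                             pcs=covar[:, None])
        assert tab.loc["L20", "flag"] == "monomorphic"
        assert np.isnan(tab.loc["L20", "p"])
        assert tab.loc["L21", "flag"] == "collinear"
        assert np.isnan(tab.loc["L21", "p"])

    def test_exact_mode_agrees_with_p3d_on_strong_signals(self, null_trial):
        g, pheno = null_trial
        K = centered_ibs_kinship(g)
        rng = np.random.default_rng(4)
        maf = compute_maf(g).to_numpy()
        j = int(np.nonzero(maf > 0.3)[0][0])
        xc = np.nan_to_num(g.calls[:, j])
        xc = xc - xc.mean()
        # a polygenic background keeps the variance components identifiable,
        # which is the regime where the P3D shortcut is trustworthy
        lam, U = np.linalg.eigh(K.values)
        lam = np.clip(lam, 0, None)
        lam = lam / lam.mean()
        others = [l for l in g.locus_ids[100:140] if l != g.locus_ids[j]]
        sub = g.take_loci(others + [g.locus_ids[j]])
        diffs = []
        for _rep in range(3):
            gv = U @ (np.sqrt(lam) * rng.standard_normal(g.n_samples))
            y = (xc * np.sqrt(0.10 / xc.var()) + np.sqrt(0.4) * gv
                 + rng.standard_normal(g.n_samples) * np.sqrt(0.5))
            # kinship from the full panel; no PCs so the marker is not absorbed
            p3d = assoc.mlm_scan(sub, y, K=K, mode="p3d", n_pcs=0)
            exact = assoc.mlm_scan(sub, y, K=K, mode="exact", n_pcs=0)
            for locus in p3d.index[p3d["p"] < 1e-3]:
                diffs.append(abs(np.log10(p3d.loc[locus, "p"])
                                 - np.log10(exact.loc[locus, "p"])))
        assert len(diffs) >= 1
        assert np.median(diffs) < 0.2
        assert max(diffs) < 0.5


class TestAssociationSuite:
    def test_common_qtl_found_with_and_without_maf_filter(self):
        cfg = SimConfig(seed=91, n_species=1, pops_per_species=4,
                        families_per_pop=4, offspring_per_family=12,
                        n_loci=400, missing_rate=0.0, lowcall_sample_rate=0.0)
        g, _, _ = simulate_trial(cfg)
        rng = np.random.default_rng(5)
        maf = compute_maf(g).to_numpy()
        j_common = int(rng.choice(np.nonzero(maf > 0.3)[0]))
        rare_pool = np.nonzero((maf > 0.01) & (maf < 0.04))[0]
        j_rare = int(rng.choice(rare_pool))
        xc = g.calls[:, j_common] - g.calls[:, j_common].mean()
        xr = g.calls[:, j_rare] - g.calls[:, j_rare].mean()
        y = (xc * np.sqrt(0.25 / xc.var()) + xr * np.sqrt(0.20 / xr.var())
             + rng.standard_normal(g.n_samples) * np.sqrt(0.55))
        pheno = pd.DataFrame({"T": y}, index=g.sample_ids)
        datasets = {"ALL": g.sample_ids}
        unfiltered = assoc.run_association_suite(g, pheno, datasets, ["T"])
        filtered = assoc.run_association_suite(g, pheno, datasets, ["T"],
                                               maf_filter=True)
        tab_u = unfiltered["tables"][("ALL", "T")]
        tab_f = filtered["tables"][("ALL", "T")]
        common_id = g.locus_ids[j_common]
        rare_id = g.locus_ids[j_rare]
        assert tab_u.loc[common_id, "significant"]
        assert tab_f.loc[common_id, "significant"]
        # the rare causal variant is only testable without the MAF filter
        assert tab_u.loc[rare_id, "significant"]
        assert rare_id not in tab_f.index
        assert (unfiltered["summary"]["n_loci_tested"]
                > filtered["summary"]["n_loci_tested"]).all()

    def test_small_dataset_warns(self, null_trial):
        g, pheno = null_trial
        tiny = g.sample_ids[:12]
        with pytest.warns(UserWarning, match="low"):
            assoc.run_association_suite(g, pheno, {"tiny": tiny}, ["NULL"])


class TestMlmm:
    def test_null_trait_gives_empty_model(self, null_trial):
        g, pheno = null_trial
        K = centered_ibs_kinship(g)
        res = assoc.mlmm(g, pheno["NULL"], K)
        assert res.selected_model == []
        assert res.criterion == pytest.approx(0.05 / res.m)

    def test_three_qtls_recovered(self, null_trial):
        g, _ = null_trial
        K = centered_ibs_kinship(g)
        rng = np.random.default_rng(6)
        maf = compute_maf(g).to_numpy()
        qtl = rng.choice(np.nonzero(maf > 0.2)[0], size=3, replace=False)
        X = np.nan_to_num(g.calls[:, qtl])
        Xc = X - X.mean(axis=0)
        y = sum(Xc[:, k] * np.sqrt(0.12 / Xc[:, k].var()) for k in range(3)) \
            + rng.standard_normal(g.n_samples) * np.sqrt(0.64)
        res = assoc.mlmm(g, y, K)
        truth = {g.locus_ids[j] for j in qtl}
        found = truth & set(res.selected_model)
        # at this modest n the kinship can absorb one structured QTL, so
        # require most of the architecture with no false cofactors
        assert len(found) >= 2
        assert set(res.selected_model) <= truth

    def test_duplicated_marker_enters_once_first_by_order(self, null_trial):
        g, _ = null_trial
        rng = np.random.default_rng(7)
        maf = compute_maf(g).to_numpy()
        j = int(np.nonzero(maf > 0.3)[0][0])
        x = np.nan_to_num(g.calls[:, j])
        calls = np.column_stack([x, x, np.nan_to_num(g.calls[:, :60])])
        ids = ["DUP_A", "DUP_B"] + g.locus_ids[:60]
        g2 = GenotypeMatrix(calls, g.sample_ids, ids, g.sample_meta)
        xc = x - x.mean()
        y = xc * np.sqrt(0.3 / xc.var()) + rng.standard_normal(g.n_samples)
        K = centered_ibs_kinship(g)  # full panel, not the 62-locus toy
        res = assoc.mlmm(g2, y, K, max_steps=4)
        assert "DUP_A" in res.selected_model
        assert "DUP_B" not in res.selected_model

    def test_step_path_prefix_and_criterion(self, null_trial):
        g, _ = null_trial
        rng = np.random.default_rng(8)
        maf = compute_maf(g).to_numpy()
        qtl = rng.choice(np.nonzero(maf > 0.2)[0], size=2, replace=False)
        X = np.nan_to_num(g.calls[:, qtl])
        Xc = X - X.mean(axis=0)
        y = sum(Xc[:, k] * np.sqrt(0.12 / Xc[:, k].var()) for k in range(2)) \
            + rng.standard_normal(g.n_samples)
        res = assoc.mlmm(g, y)
        assert len(res.step_path) >= 1
        assert all(p < res.criterion
                   for step in [res.step_path[-1]]
                   if step["cofactors"] == res.selected_model
                   for p in step["p_values"])
        with pytest.raises(ValueError):
            assoc.mlmm(g, y, max_steps=0)


class TestPower:
    def test_monotone_in_lambda_and_n(self):
        grid = np.geomspace(0.1, 10, 9)
        curve = assoc.power_estimate(400, lam=grid)
        assert np.all(np.diff(curve["power"]) < 0)
        p1 = assoc.power_estimate(200, lam=1.0).power
        p2 = assoc.power_estimate(400, lam=1.0).power
        assert p2 >= p1
        assert assoc.power_estimate(400, lam=0.0).power \
            > assoc.power_estimate(400, lam=10.0).power

    def test_power_bounds_and_validation(self):
        est = assoc.power_estimate(100, qtl_size=0.05, alpha=0.05, lam=5.0)
        assert 0.5 * est.alpha <= est.power <= 1.0
        with pytest.raises(ValueError):
            assoc.power_estimate(5)
        with pytest.raises(ValueError):
            assoc.power_estimate(100, qtl_size=1.0)
        with pytest.raises(ValueError):
            assoc.power_estimate(100, lam=-1.0)
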