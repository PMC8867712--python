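import numpy as np
import pandas as pd
import pytest

from markertrait import predict
from markertrait.genotypes import GenotypeMatrix, compute_maf
from markertrait.predict import (SNPSet, build_snp_set, external_assessment,
                                 fit_prediction_ols, fit_prediction_ridge,
                                 impute_family_mean, internal_assessment,
                                 random_matched_sets, selection_comparison,
                                 train_test_split)
from markertrait.simulate import SimConfig, simulate_independent_sites, simulate_trial


def _assoc_table(rows):
    df = pd.DataFrame(rows, columns=["locus_id", "q", "dataset_label",
                                     "trait_label", "maf_class"])
    return df.set_index("locus_id")


class TestBuildSnpSet:
    def _target(self, poly_loci, mono_loci):
        loci = poly_loci + mono_loci
        rng = np.random.default_rng(0)
        calls = np.column_stack(
            [rng.binomial(2, 0.3, 20).astype(float) for _ in poly_loci]
            + [np.zeros(20) for _ in mono_loci])
        return GenotypeMatrix(calls, [f"s{i}" for i in range(20)], loci)

    def test_monomorphic_targets_dropped_with_report(self):
        tab = _assoc_table([(f"L{i}", 0.01, "SY", "H2013", "common")
                            for i in range(5)])
        target = self._target(["L0", "L1", "L2"], ["L3", "L4"])
        s = build_snp_set([tab], {"SY": target})
        assert sorted(s.loci) == ["L0", "L1", "L2"]
        assert len(s.dropped) == 2
        assert set(s.dropped["locus_id"]) == {"L3", "L4"}

    def test_duplicate_locus_merges_provenance(self):
        t1 = _assoc_table([("L0", 0.01, "SY", "H2013", "common")])
        t2 = _assoc_table([("L0", 0.02, "MU-SY-UN", "I2013", "rare")])
        target = self._target(["L0"], [])
        s = build_snp_set([t1, t2], {"SY": target})
        assert s.loci == ["L0"]
        assert set(s.provenance["dataset_label"]) == {"SY", "MU-SY-UN"}

    def test_dataset_variants_nest(self):
        tabs = [_assoc_table([(f"L{i}", 0.01, ds, "H2013", "common")])
                for i, ds in enumerate(["SY", "MU-SY-UN", "MU-UN"])]
        target = self._target(["L0", "L1", "L2"], [])
        a = build_snp_set(tabs, {"t": target},
                          source_datasets=["SY", "MU-SY-UN", "MU-UN"])
        b = build_snp_set(tabs, {"t": target},
                          source_datasets=["SY", "MU-SY-UN"])
        c = build_snp_set(tabs, {"t": target}, source_datasets=["SY"])
        assert set(c.loci) <= set(b.loci) <= set(a.loci)

    def test_empty_set_errors_name_cause(self):
        tab = _assoc_table([("L0", 0.5, "SY", "H2013", "common")])
        target = self._target(["L0"], [])
        with pytest.raises(ValueError, match="no significant"):
            build_snp_set([tab], {"SY": target})
        tab2 = _assoc_table([("L3", 0.01, "SY", "H2013", "common")])
        target2 = self._target([], ["L3"])
        with pytest.raises(ValueError, match="monomorphic"):
            build_snp_set([tab2], {"SY": target2})


class TestImputation:
    def test_family_mean_then_population_then_global(self):
        calls = np.array([[0.0, np.nan],
                          [2.0, np.nan],
                          [np.nan, np.nan],
                          [1.0, 1.0],
                          [1.0, 1.0]])
        meta = pd.DataFrame({
            "species": ["S"] * 5,
            "population": ["P1", "P1", "P1", "P1", "P2"],
            "family": ["F1", "F1", "F1", "F2", "F3"],
        }, index=[f"s{i}" for i in range(5)])
        g = GenotypeMatrix(calls, list(meta.index), ["L1", "L2"], meta)
        out = impute_family_mean(g)
        assert out.loc["s2", "L1"] == pytest.approx(1.0)   # family mean of 0,2
        # family F1 all missing at L2 -> population P1 mean (only s3 typed)
        assert out.loc["s0", "L2"] == pytest.approx(1.0)
        assert not out.isna().any().any()

    def test_no_missing_is_identity(self, toy_genotypes):
        g = toy_genotypes
        complete = g.take_loci(["L3"])
        # L3 column has one NaN; use L1 which is complete
        out = impute_family_mean(g, ["L1"])
        assert np.allclose(out["L1"].to_numpy(), g.calls[:, 0])
        _ = complete


class TestOls:
    def _toy(self, n=40, p=3, seed=0):
        rng = np.random.default_rng(seed)
        calls = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        g = GenotypeMatrix(calls, [f"s{i}" for i in range(n)],
                           [f"L{j}" for j in range(p)])
        return g, rng

    def test_noiseless_coefficients_recovered(self):
        g, _ = self._toy()
        beta = np.array([2.0, -1.0, 0.5])
        y = 3.0 + g.calls @ beta
        m = fit_prediction_ols(g, y, SNPSet("s", list(g.locus_ids), None))
        assert m.intercept == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(m.coefficients.to_numpy(), beta, atol=1e-8)

    def test_locus_permutation_equivariance(self):
        g, rng = self._toy()
        y = rng.standard_normal(g.n_samples)
        m1 = fit_prediction_ols(g, y, SNPSet("s", ["L0", "L1", "L2"], None))
        m2 = fit_prediction_ols(g, y, SNPSet("s", ["L2", "L0", "L1"], None))
        for locus in g.locus_ids:
            assert m1.coefficients[locus] == pytest.approx(
                m2.coefficients[locus], abs=1e-10)

    def test_n_not_greater_than_p_errors(self):
        g, rng = self._toy(n=4, p=3)
        with pytest.raises(ValueError, match="ridge"):
            fit_prediction_ols(g, rng.standard_normal(4),
                               SNPSet("s", list(g.locus_ids), None))

    def test_constant_locus_raises_unless_dropped(self):
        g, rng = self._toy()
        calls = g.calls.copy()
        calls[:, 1] = 2.0
        g2 = GenotypeMatrix(calls, g.sample_ids, g.locus_ids)
        y = rng.standard_normal(g.n_samples)
        with pytest.raises(ValueError, match="L1"):
            fit_prediction_ols(g2, y, SNPSet("s", list(g2.locus_ids), None))
        m = fit_prediction_ols(g2, y, SNPSet("s", list(g2.locus_ids), None),
                               on_singular="drop")
        assert m.coefficients["L1"] == 0.0


class TestRidge:
    def test_marker_and_gblup_predictions_identical(self):
        cfg = SimConfig(seed=33, n_species=1, pops_per_species=2,
                        families_per_pop=3, offspring_per_family=10,
                        n_loci=200, missing_rate=0.0, lowcall_sample_rate=0.0)
        g, pheno, _ = simulate_trial(cfg)
        g = g.take_samples(g.sample_ids[:50])
        y = pheno["H2013"].reindex(g.sample_ids)
        m = fit_prediction_ridge(g, y)
        Z = impute_family_mean(g).to_numpy() - m.train_means.to_numpy()
        pred_marker = m.intercept + Z @ m.coefficients.to_numpy()
        G = Z @ Z.T
        alpha = np.linalg.solve(G + m.shrinkage * np.eye(len(y)),
                                (y - y.mean()).to_numpy())
        pred_gblup = m.intercept + G @ alpha
        assert np.abs(pred_marker - pred_gblup).max() < 1e-8

    def test_prediction_invariant_to_monomorphic_locus(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.4, size=(30, 40)).astype(float)
        g = GenotypeMatrix(calls, [f"s{i}" for i in range(30)],
                           [f"L{j}" for j in range(40)])
        y = rng.standard_normal(30)
        m1 = fit_prediction_ridge(g, y)
        calls2 = np.column_stack([calls, np.full(30, 2.0)])
        g2 = GenotypeMatrix(calls2, g.sample_ids, g.locus_ids + ["MONO"])
        m2 = fit_prediction_ridge(g2, y)
        p1 = m1.predict(g)
        p2 = m2.predict(g2)
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)

    def test_too_few_polymorphic_loci_rejected(self):
        g = GenotypeMatrix(np.zeros((10, 3)), [f"s{i}" for i in range(10)],
                           ["L0", "L1", "L2"])
        with pytest.raises(ValueError, match="polymorphic"):
            fit_prediction_ridge(g, np.arange(10.0))


class TestRandomSets:
    def test_composition_matches_reference(self, small_trial):
        g, _, _ = small_trial
        maf = compute_maf(g)
        common = [l for l in g.locus_ids if maf[l] >= 0.05][:6]
        rare = [l for l in g.locus_ids if 0 < maf[l] < 0.05][:8]
        ref = SNPSet("ref", common + rare, None)
        sets = random_matched_sets(g, ref, n_sets=10, seed=3)
        assert len(sets) == 10
        from markertrait.genotypes import classify_maf
        for s in sets:
            cls = classify_maf(maf.reindex(s.loci))
            assert (cls == "common").sum() == 6
            assert (cls == "rare").sum() == 8
        again = random_matched_sets(g, ref, n_sets=10, seed=3)
        assert [s.loci for s in again] == [s.loci for s in sets]

    def test_insufficient_pool_errors(self, toy_genotypes):
        ref = SNPSet("ref", ["L1", "L2", "L3"], None)
        with pytest.raises(ValueError, match="not enough"):
            random_matched_sets(toy_genotypes, ref, n_sets=2, seed=0)


class TestAssessment:
    def test_oracle_breeding_values_reach_sqrt_h2(self, small_trial):
        g, pheno, truth = small_trial
        rs = []
        for rep in range(10):
            res = internal_assessment(
                g, pheno["BS2010"], predictor=truth.breeding_values["budset"],
                seed=rep)
            rs.append(res.pearson_r)
        expected = np.sqrt(truth.realized_h2["BS2010"])
        assert np.mean(rs) == pytest.approx(expected, abs=0.08)

    def test_shuffled_trait_has_no_signal(self, small_trial):
        g, pheno, truth = small_trial
        rng = np.random.default_rng(9)
        y = pd.Series(rng.permutation(pheno["BS2010"].to_numpy()),
                      index=pheno.index)
        rs = [internal_assessment(g, y, predictor=truth.breeding_values["budset"],
                                  seed=rep).pearson_r for rep in range(10)]
        assert abs(np.mean(rs)) < 2 * np.std(rs) / np.sqrt(len(rs)) + 0.05

    def test_split_reproducible_and_family_stratified(self, small_trial):
        g, _, _ = small_trial
        a = train_test_split(g, 0.6, seed=5)
        b = train_test_split(g, 0.6, seed=5)
        assert a == b
        tr, te = train_test_split(g, 0.6, seed=5, family_stratified=True)
        fam = g.sample_meta["family"]
        for f, members in fam.groupby(fam):
            k = len(members)
            n_tr = sum(m in set(tr) for m in members.index)
            assert abs(n_tr - 0.6 * k) <= 1

    def test_tiny_test_set_rejected(self, small_trial):
        g, pheno, _ = small_trial
        with pytest.raises(ValueError, match="test set"):
            internal_assessment(g, pheno["BS2010"], train_fraction=0.999,
                                seed=0, predictor=pheno["BS2010"])

    def test_external_constant_phenotype_gives_missing_r(self, small_trial):
        g, pheno, _ = small_trial
        model = fit_prediction_ridge(g, pheno["H2013"])
        ph = pd.DataFrame({"FLAT": np.ones(g.n_samples)}, index=g.sample_ids)
        out = external_assessment(model, g, ph, site_label="X")
        assert np.isnan(out["pearson_r"].iloc[0])


class TestSelectionComparison:
    def test_k_equals_n_selects_everyone(self):
        ids = [f"t{i}" for i in range(6)]
        pred = pd.Series(np.arange(6.0), index=ids)
        early = pd.Series(np.arange(6.0)[::-1], index=ids)
        final = pd.Series([5.0, 9, 7, 8, 6, 10], index=ids)
        comp = selection_comparison(pred, early, final, k=6)
        for method in ("genomic", "phenotype"):
            assert comp.methods[method]["mean_final"] == pytest.approx(
                comp.site_mean_final)

    def test_constant_selection_cv_zero(self):
        ids = list("abcd")
        pred = pd.Series([4.0, 3, 2, 1], index=ids)
        final = pd.Series([5.0, 5, 5, 5], index=ids)
        comp = selection_comparison(pred, pred, final, k=2)
        assert comp.methods["genomic"]["cv"] == 0.0

    def test_k_larger_than_site_rejected(self):
        ids = list("ab")
        s = pd.Series([1.0, 2.0], index=ids)
        with pytest.raises(ValueError, match="exceeds"):
            selection_comparison(s, s, s, k=3)

    def test_ties_broken_by_id_order(self):
        ids = ["t1", "t2", "t3"]
        pred = pd.Series([1.0, 1.0, 0.0], index=ids)
        final = pd.Series([1.0, 2.0, 3.0], index=ids)
        comp = selection_comparison(pred, pred, final, k=1)
        assert comp.methods["genomic"]["selected"] == ["t1"]


class TestSignFlip:
    def test_budburst_external_r_signs_oppose_across_sites(self):
        cfg = SimConfig(seed=61, pops_per_species=5, families_per_pop=5,
                        offspring_per_family=8, n_loci=600,
                        phenology_flip=True)
        g, phc, _ = simulate_independent_sites(cfg)
        meta = g.sample_meta
        gh = list(meta.index[meta["site"] == "GH"])
        model = fit_prediction_ridge(g.take_samples(gh),
                                     phc["GH"]["BB2011"].reindex(gh))
        rs = []
        for site in ("S1", "S2"):
            ids = list(meta.index[meta["site"] == site])
            out = external_assessment(model, g.take_samples(ids), phc[site],
                                      traits=["BB_timing"], site_label=site)
            rs.append(out["pearson_r"].iloc[0])
        assert rs[0] > 0 > rs[1]
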