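"""Calibration and recovery experiments on synthetic trials.

Each function runs a self-contained simulation experiment against the
package's own estimators and returns a small dict of summary numbers:
type-I-error calibration of the mixed-model scan, empirical FDR of the BH
rule, GREML heritability recovery, MLMM cofactor recovery, the
RR-BLUP/GBLUP identity, the internal-assessment ordering of prediction
models, the cross-environment budburst sign flip, the genomic-vs-phenotype
selection comparison, and the power formula against a simulation oracle.
All randomness is driven by a single integer seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import assoc, predict, varcomp
from .genotypes import GenotypeMatrix, compute_maf
from .relatedness import centered_ibs_kinship
from .simulate import SimConfig, simulate_independent_sites, simulate_null_trait, simulate_trial

__all__ = ["type1_error_calibration", "fdr_calibration", "greml_recovery",
           "mlmm_recovery", "rrblup_identity", "prediction_ordering",
           "budburst_sign_flip", "selection_gain", "power_check",
           "pipeline_determinism"]


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2 ** 31))


def type1_error_calibration(seed: int, n_loci: int = 2000,
                            alpha: float = 0.05) -> dict:
    """Rejection rate of the MLM scan on one structured null trial (~n=400).

    Also reports the genomic-control lambda and, as the uncorrected
    contrast, the rejection rate of a naive per-locus OLS scan.
    """
    cfg = SimConfig(seed=_sub_seed(seed, 1), n_species=3, pops_per_species=4,
                    families_per_pop=4, offspring_per_family=8, n_loci=n_loci)
    g, pheno = simulate_null_trait(cfg)
    tab = assoc.mlm_scan(g, pheno["NULL"])
    p = tab["p"].dropna()
    naive = assoc.naive_scan(g, pheno["NULL"])["p"].dropna()
    return {"rejection_rate": float((p < alpha).mean()),
            "lambda_gc": assoc.genomic_control_lambda(p),
            "naive_rejection_rate": float((naive < alpha).mean()),
            "n": g.n_samples, "n_loci_tested": int(len(p))}


def fdr_calibration(seed: int, n_sims: int = 100, n_loci: int = 400,
                    causal_fraction: float = 0.05,
                    q_threshold: float = 0.05) -> dict:
    """Empirical FDR of the BH q < 0.05 rule with 5% true signals."""
    cfg = SimConfig(seed=_sub_seed(seed, 2), n_species=1, pops_per_species=5,
                    families_per_pop=5, offspring_per_family=20,
                    n_loci=n_loci, missing_rate=0.0, lowcall_sample_rate=0.0)
    g, _, _ = simulate_trial(cfg)
    K = centered_ibs_kinship(g)
    maf = compute_maf(g).to_numpy()
    candidates = np.nonzero(maf > 0.05)[0]
    n = g.n_samples
    n_causal = int(round(causal_fraction * n_loci))
    per_locus_var = 0.025   # each causal locus explains 2.5% of variance
    rng = np.random.default_rng(_sub_seed(seed, 3))
    fdps, powers = [], []
    for _ in range(n_sims):
        causal = rng.choice(candidates, size=n_causal, replace=False)
        Xc = np.nan_to_num(g.calls[:, causal])
        Xc = Xc - Xc.mean(axis=0)
        signal = sum(Xc[:, j] * np.sqrt(per_locus_var / Xc[:, j].var())
                     for j in range(n_causal))
        y = signal + rng.standard_normal(n) * np.sqrt(1.0 - per_locus_var * n_causal)
        tab = assoc.mlm_scan(g, y, K=K)
        tab["q"] = assoc.fdr_adjust(tab["p"])
        rejected = set(tab.index[tab["q"] < q_threshold])
        true = {g.locus_ids[j] for j in causal}
        fp = len(rejected - true)
        fdps.append(fp / max(len(rejected), 1))
        powers.append(len(rejected & true) / n_causal)
    return {"empirical_fdr": float(np.mean(fdps)),
            "mean_power": float(np.mean(powers)),
            "n": n, "n_sims": n_sims}


def greml_recovery(seed: int, n_sims: int = 100,
                   h2_values=(0.3, 0.5, 0.7)) -> dict:
    """Mean GREML bias for traits drawn at known h2 on a structured K (n=500)."""
    cfg = SimConfig(seed=_sub_seed(seed, 4), n_species=1, pops_per_species=5,
                    families_per_pop=5, offspring_per_family=20, n_loci=1500)
    g, _, _ = simulate_trial(cfg)
    K = centered_ibs_kinship(g)
    lam, U = np.linalg.eigh(K.values)
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.mean()  # mean-diagonal-1 scale: true h2 is per individual
    n = g.n_samples
    rng = np.random.default_rng(_sub_seed(seed, 5))
    biases = {}
    for h2 in h2_values:
        est = []
        for _ in range(n_sims):
            gvec = U @ (np.sqrt(lam) * rng.standard_normal(n))
            y = np.sqrt(h2) * gvec + np.sqrt(1 - h2) * rng.standard_normal(n)
            est.append(varcomp.greml(y, K, compute_se=False).h2)
        biases[h2] = float(np.mean(est) - h2)
    return {"bias": biases,
            "max_abs_bias": float(max(abs(b) for b in biases.values())),
            "n": n, "n_sims": n_sims}


def mlmm_recovery(seed: int, n_sims: int = 100, n_null_sims: int = 200,
                  n_loci: int = 500, n_qtl: int = 3,
                  qtl_var: float = 0.10) -> dict:
    """MLMM cofactor recovery (3 QTLs at 10% each, n=500) and null behaviour.

    The pure-null traits carry no genetic signal at all; the fraction of
    empty selected models measures the family-wise error control of the
    multiple-Bonferroni criterion, whose nominal level is 5%.
    """
    cfg = SimConfig(seed=_sub_seed(seed, 6), n_species=1, pops_per_species=5,
                    families_per_pop=5, offspring_per_family=20,
                    n_loci=n_loci, missing_rate=0.0, lowcall_sample_rate=0.0,
                    pop_mean_sd=0.3)
    g, _, _ = simulate_trial(cfg)
    K = centered_ibs_kinship(g)
    maf = compute_maf(g).to_numpy()
    candidates = np.nonzero(maf > 0.1)[0]
    n = g.n_samples
    rng = np.random.default_rng(_sub_seed(seed, 7))
    all_found = 0
    null_empty = 0
    for _ in range(n_sims):
        qtl = rng.choice(candidates, size=n_qtl, replace=False)
        Xq = np.nan_to_num(g.calls[:, qtl])
        Xq = Xq - Xq.mean(axis=0)
        signal = sum(Xq[:, j] * np.sqrt(qtl_var / Xq[:, j].var())
                     for j in range(n_qtl))
        y = signal + rng.standard_normal(n) * np.sqrt(1 - n_qtl * qtl_var)
        res = assoc.mlmm(g, y, K)
        truth = {g.locus_ids[j] for j in qtl}
        all_found += truth <= set(res.selected_model)
    for _ in range(n_null_sims):
        y0 = rng.standard_normal(n)
        null_empty += len(assoc.mlmm(g, y0, K).selected_model) == 0
    return {"frac_all_qtl_recovered": all_found / n_sims,
            "frac_null_empty": null_empty / n_null_sims,
            "n": n, "n_sims": n_sims, "n_null_sims": n_null_sims}


def rrblup_identity(seed: int, n: int = 50, n_loci: int = 200) -> dict:
    """Max |difference| between marker-effect and GBLUP predictions."""
    cfg = SimConfig(seed=_sub_seed(seed, 8), n_species=1, pops_per_species=2,
                    families_per_pop=3, offspring_per_family=10,
                    n_loci=n_loci, missing_rate=0.0, lowcall_sample_rate=0.0)
    g, pheno, _ = simulate_trial(cfg)
    g = g.take_samples(g.sample_ids[:n])
    y = pheno["H2013"].reindex(g.sample_ids)
    model = predict.fit_prediction_ridge(g, y)
    Z = (predict.impute_family_mean(g).to_numpy()
         - model.train_means.to_numpy())
    pred_marker = model.intercept + Z @ model.coefficients.to_numpy()
    yc = (y - y.mean()).to_numpy()
    G = Z @ Z.T
    pred_gblup = model.intercept + G @ np.linalg.solve(
        G + model.shrinkage * np.eye(len(y)), yc)
    return {"max_abs_diff": float(np.abs(pred_marker - pred_gblup).max()),
            "n": n, "n_loci": n_loci}


def prediction_ordering(seed: int, n_reps: int = 20) -> dict:
    """Fraction of replicates with r(ridge) > r(causal OLS) > r(random)."""
    wins = 0
    r_ridge_all, r_ols_all, r_rand_all = [], [], []
    for rep in range(n_reps):
        cfg = SimConfig(seed=_sub_seed(seed, 100 + rep), n_species=1,
                        pops_per_species=12, families_per_pop=5,
                        offspring_per_family=8, n_loci=2000)
        g, pheno, truth = simulate_trial(cfg)
        y = pheno["H2013"]
        maf = compute_maf(g)
        causal = [l for l in truth.qtl_ids("growth") if maf[l] > 0.01]
        sset = predict.SNPSet("causal", causal, None)
        split_seed = _sub_seed(seed, 200 + rep)
        r_ols = predict.internal_assessment(g, y, snpset=sset, method="ols",
                                            seed=split_seed).pearson_r
        r_ridge = predict.internal_assessment(g, y, method="ridge",
                                              seed=split_seed).pearson_r
        rand_sets = predict.random_matched_sets(g, sset, n_sets=10,
                                                seed=split_seed)
        r_rand = float(np.nanmean([
            predict.internal_assessment(g, y, snpset=s, method="ols",
                                        seed=split_seed).pearson_r
            for s in rand_sets]))
        wins += (r_ridge > r_ols > r_rand)
        r_ridge_all.append(r_ridge)
        r_ols_all.append(r_ols)
        r_rand_all.append(r_rand)
    return {"fraction_ordered": wins / n_reps,
            "mean_r_ridge": float(np.mean(r_ridge_all)),
            "mean_r_causal_ols": float(np.mean(r_ols_all)),
            "mean_r_random": float(np.mean(r_rand_all)),
            "n_reps": n_reps}


def budburst_sign_flip(seed: int, n_reps: int = 20) -> dict:
    """External budburst assessment with opposite signs at the two sites."""
    flips = 0
    r1_all, r2_all = [], []
    for rep in range(n_reps):
        cfg = SimConfig(seed=_sub_seed(seed, 300 + rep), pops_per_species=5,
                        families_per_pop=5, offspring_per_family=8,
                        n_loci=800, phenology_flip=True)
        g, phc, _ = simulate_independent_sites(cfg)
        meta = g.sample_meta
        gh_ids = list(meta.index[meta["site"] == "GH"])
        model = predict.fit_prediction_ridge(
            g.take_samples(gh_ids), phc["GH"]["BB2011"].reindex(gh_ids),
            training_trait="BB2011")
        rs = []
        for site in [s for s in dict.fromkeys(meta["site"]) if s != "GH"]:
            ids = list(meta.index[meta["site"] == site])
            ext = predict.external_assessment(model, g.take_samples(ids),
                                              phc[site], traits=["BB_timing"],
                                              site_label=site)
            rs.append(float(ext["pearson_r"].iloc[0]))
        flips += rs[0] > 0 > rs[1]
        r1_all.append(rs[0])
        r2_all.append(rs[1])
    return {"fraction_opposite_signs": flips / n_reps,
            "mean_r_site1": float(np.mean(r1_all)),
            "mean_r_site2": float(np.mean(r2_all)),
            "n_reps": n_reps}


def selection_gain(seed: int, n_sims: int = 50, k: int = 10) -> dict:
    """Genomic vs early-height selection under a strong year-1 maternal effect.

    The genomic method ranks trees by true breeding value (the oracle
    model); the phenotype method by first-year height, which is dominated
    by the maternal effect.  Reports the fraction of simulations where the
    genomic selection's mean final height is at least the phenotype
    selection's at the first field site.
    """
    wins = 0
    gains = []
    for rep in range(n_sims):
        cfg = SimConfig(seed=_sub_seed(seed, 400 + rep), pops_per_species=4,
                        families_per_pop=4, offspring_per_family=8,
                        n_loci=500, maternal_sd_year1=60.0)
        g, phc, truth = simulate_independent_sites(cfg)
        meta = g.sample_meta
        site = [s for s in dict.fromkeys(meta["site"]) if s != "GH"][0]
        ids = list(meta.index[meta["site"] == site])
        pred = truth.breeding_values["growth"].reindex(ids)
        comp = predict.selection_comparison(pred, phc[site]["H_early"],
                                            phc[site]["H_final"], k=k,
                                            site=site)
        gm = comp.methods["genomic"]["mean_final"]
        pm = comp.methods["phenotype"]["mean_final"]
        wins += gm >= pm
        gains.append(gm - pm)
    return {"fraction_genomic_ge_phenotype": wins / n_sims,
            "mean_height_gain_mm": float(np.mean(gains)),
            "n_sims": n_sims, "k": k}


def power_check(seed: int, n: int = 400, qtl_size: float = 0.05,
                alpha: float = 0.05, lam: float = 1.0,
                n_reps: int = 2000) -> dict:
    """Closed-form power vs an exact-test simulation oracle, plus monotonicity.

    The oracle simulates the closed form's generative model - marker
    explaining ``qtl_size`` of the phenotypic variance, a polygenic
    background of relative size ``lam`` acting as exchangeable noise on the
    non-QTL variance - and applies the 1-df test at the true variance, so
    the comparison isolates the formula itself from estimator noise.
    """
    lam_grid = np.geomspace(0.1, 10.0, 9)
    curve = assoc.power_estimate(n, qtl_size, alpha, lam_grid)["power"].to_numpy()
    monotone_lambda = bool(np.all(np.diff(curve) < 0))
    p_small = assoc.power_estimate(n, qtl_size, alpha, lam).power
    p_big = assoc.power_estimate(2 * n, qtl_size, alpha, lam).power
    monotone_n = bool(p_big >= p_small)
    rng = np.random.default_rng(_sub_seed(seed, 9))
    crit = stats.chi2.isf(alpha, df=1)
    noise_var = (1.0 - qtl_size) * (1.0 + lam)
    hits = 0
    for _ in range(n_reps):
        x = rng.binomial(2, 0.3, size=n).astype(float)
        xc = x - x.mean()
        b = np.sqrt(qtl_size / xc.var())
        y = xc * b + rng.standard_normal(n) * np.sqrt(noise_var)
        # exact GLS at the true (scalar) covariance: 1-df chi-square
        bhat = (xc @ y) / (xc @ xc)
        z2 = bhat ** 2 * (xc @ xc) / noise_var
        hits += z2 > crit
    sim_power = hits / n_reps
    mc_se = float(np.sqrt(sim_power * (1 - sim_power) / n_reps))
    return {"closed_form_power": float(p_small),
            "simulated_power": float(sim_power),
            "abs_difference": float(abs(sim_power - p_small)),
            "mc_se": mc_se,
            "monotone_in_lambda": monotone_lambda,
            "monotone_in_n": monotone_n,
            "n": n, "n_reps": n_reps}


DEMO_SIM = {"n_species": 3, "pops_per_species": 3, "families_per_pop": 3,
            "offspring_per_family": 6, "n_loci": 600}


def pipeline_determinism(seed: int, workdir) -> dict:
    """Run the bundled demo configuration twice; compare manifest hashes."""
    from pathlib import Path

    from .pipeline import PipelineConfig, run

    workdir = Path(workdir)
    cfg = PipelineConfig(seed=int(seed) % (2 ** 31), sim=dict(DEMO_SIM))
    hashes = []
    for tag in ("run1", "run2"):
        out = workdir / tag
        manifests = run(cfg, outdir=out)
        hashes.append({stage: m["outputs"] for stage, m in manifests.items()})
    return {"identical_hashes": hashes[0] == hashes[1],
            "n_stages": len(hashes[0])}
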