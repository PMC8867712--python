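"""Mixed-model association: per-locus MLM, BH FDR, stepwise MLMM, power.

The per-locus engine follows the EMMA-style eigen-rotation: the null model
y = X b + g + e with cov(g) = sigma2_g K is fitted once by REML (P3D,
"population parameters previously determined"), the data are whitened with
the resulting covariance, and every marker is then tested by ordinary least
squares in the rotated space - an O(loci) scan.  An exact mode re-optimizes
the variance components per marker for small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, classify_maf, compute_maf
from .relatedness import KinshipMatrix, centered_ibs_kinship, pca_covariates
from .varcomp import greml

__all__ = ["mlm_scan", "fdr_adjust", "genomic_control_lambda", "naive_scan",
           "run_association_suite", "mlmm", "MLMMResult", "power_estimate",
           "PowerEstimate"]


# -- helpers ---------------------------------------------------------------

def _aligned_inputs(g: GenotypeMatrix, y, K, pcs, n_pcs):
    if isinstance(y, pd.Series):
        y = y.reindex(g.sample_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float).ravel()
    if y.size != g.n_samples:
        raise ValueError("phenotype length does not match genotypes")
    keep = ~np.isnan(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 phenotyped samples")
    if not keep.all():
        g = g.take_samples([s for s, k in zip(g.sample_ids, keep) if k])
        y = y[keep]
    if K is None:
        K = centered_ibs_kinship(g)
    elif isinstance(K, KinshipMatrix):
        K = K.align(g.sample_ids)
    else:
        K = KinshipMatrix(np.asarray(K, dtype=float), g.sample_ids)
    if pcs is None and n_pcs and n_pcs > 0:
        pcs = pca_covariates(g, min(n_pcs, g.n_samples - 2)).scores
    elif pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
    return g, y, K, pcs


def _imputed_calls(g: GenotypeMatrix) -> np.ndarray:
    X = g.calls.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    nan = np.isnan(X)
    X[nan] = np.take(mean, np.nonzero(nan)[1])
    return X


def _whitener(K: KinshipMatrix, sg2: float, se2: float):
    lam, U = np.linalg.eigh(K.values)
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.mean()  # same mean-diagonal-1 convention as greml
    w = sg2 * lam + se2
    return (U / np.sqrt(w)).T  # A such that A V A' = I


def _scan_transformed(Gs, ys, X0s):
    """Marker tests by partitioned OLS in the whitened space."""
    Q, _ = np.linalg.qr(X0s)
    yr = ys - Q @ (Q.T @ ys)
    Gr = Gs - Q @ (Q.T @ Gs)
    denom = np.einsum("ij,ij->j", Gr, Gr)
    num = Gr.T @ yr
    n, p = X0s.shape
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        b = num / denom
        rss = float(yr @ yr) - b * num
        sigma2 = rss / df
        se = np.sqrt(sigma2 / denom)
        fstat = (b / se) ** 2
    pvals = stats.f.sf(fstat, 1, df)
    bad = denom <= 1e-8 * max(float(np.max(denom, initial=0.0)), 1.0)
    b[bad] = np.nan
    se[bad] = np.nan
    fstat[bad] = np.nan
    pvals[bad] = np.nan
    return b, se, fstat, pvals, bad


def mlm_scan(g: GenotypeMatrix, y, K: KinshipMatrix | None = None,
             pcs=None, n_pcs: int = 5, mode: str = "p3d") -> pd.DataFrame:
    """Per-locus mixed-linear-model association scan.

    Tests H0: marker effect = 0 in ``y = mu + PC g + x b + g + e`` with
    cov(g) proportional to the kinship matrix.  ``p3d`` estimates the
    variance components once on the null model and reuses them for every
    marker; ``exact`` re-optimizes per marker (slow; small problems only).
    Monomorphic loci and loci collinear with the covariates are flagged
    with missing statistics rather than failing the scan.

    Returns a DataFrame indexed by locus id with columns effect, se, fstat,
    p, maf, maf_class and flag.
    """
    g, y, K, pcs = _aligned_inputs(g, y, K, pcs, n_pcs)
    X0 = np.ones((g.n_samples, 1)) if pcs is None \
        else np.column_stack([np.ones(g.n_samples), pcs])
    maf = compute_maf(g)
    mono = (maf.to_numpy() == 0) | maf.isna().to_numpy()
    Ximp = _imputed_calls(g)
    if mode == "p3d":
        fit = greml(y, K, X0, compute_se=False)
        A = _whitener(K, fit.sigma2_g, fit.sigma2_e)
        b, se, fstat, pvals, collinear = _scan_transformed(A @ Ximp, A @ y, A @ X0)
    elif mode == "exact":
        n = g.n_samples
        b = np.full(g.n_loci, np.nan)
        se = np.full(g.n_loci, np.nan)
        fstat = np.full(g.n_loci, np.nan)
        pvals = np.full(g.n_loci, np.nan)
        collinear = np.zeros(g.n_loci, dtype=bool)
        for j in range(g.n_loci):
            if mono[j]:
                continue
            X = np.column_stack([X0, Ximp[:, j]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                collinear[j] = True
                continue
            fitj = greml(y, K, X, compute_se=False)
            A = _whitener(K, fitj.sigma2_g, fitj.sigma2_e)
            Xs, ys_ = A @ X, A @ y
            XtX = Xs.T @ Xs
            beta = np.linalg.solve(XtX, Xs.T @ ys_)
            r = ys_ - Xs @ beta
            df = n - X.shape[1]
            s2 = float(r @ r) / df
            cov = s2 * np.linalg.inv(XtX)
            b[j] = beta[-1]
            se[j] = np.sqrt(cov[-1, -1])
            fstat[j] = (b[j] / se[j]) ** 2
            pvals[j] = stats.f.sf(fstat[j], 1, df)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    flag = np.where(mono, "monomorphic", np.where(collinear, "collinear", ""))
    b = np.where(mono, np.nan, b)
    se = np.where(mono, np.nan, se)
    fstat = np.where(mono, np.nan, fstat)
    pvals = np.where(mono, np.nan, pvals)
    return pd.DataFrame({"effect": b, "se": se, "fstat": fstat, "p": pvals,
                         "maf": maf.to_numpy(),
                         "maf_class": classify_maf(maf).to_numpy(),
                         "flag": flag},
                        index=pd.Index(g.locus_ids, name="locus_id"))


def naive_scan(g: GenotypeMatrix, y) -> pd.DataFrame:
    """Per-locus OLS regression with no structure correction (diagnostic)."""
    g, y, _, _ = _aligned_inputs(g, y, np.eye(g.n_samples), None, 0)
    X0 = np.ones((g.n_samples, 1))
    maf = compute_maf(g)
    mono = (maf.to_numpy() == 0) | maf.isna().to_numpy()
    b, se, fstat, pvals, _ = _scan_transformed(_imputed_calls(g), y, X0)
    pvals = np.where(mono, np.nan, pvals)
    return pd.DataFrame({"effect": b, "se": se, "fstat": fstat, "p": pvals},
                        index=pd.Index(g.locus_ids, name="locus_id"))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (missing passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def genomic_control_lambda(p_values) -> float:
    """Genomic-control inflation factor: median chi2 over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def run_association_suite(g: GenotypeMatrix, pheno: pd.DataFrame,
                          datasets: dict[str, list[str]], traits: list[str],
                          maf_filter: bool = False, n_pcs: int = 5,
                          fdr_threshold: float = 0.05,
                          min_samples_warn: int = 30) -> dict:
    """MLM scans per dataset x trait with BH adjustment per run.

    With ``maf_filter`` on, loci rare (MAF < 0.05) in the dataset are
    excluded before both the scan and the kinship/PC computation for that
    run, so the structure correction itself changes - significant sets may
    legitimately differ from the unfiltered analysis.

    Returns ``{"tables": {(dataset, trait): AssocTable}, "summary": DataFrame}``
    where each table carries q, significance, dataset and trait columns.
    """
    tables = {}
    rows = []
    for label, sample_ids in datasets.items():
        sub = g.take_samples(sample_ids)
        if sub.n_samples < min_samples_warn:
            warnings.warn(f"dataset {label!r} has {sub.n_samples} samples: "
                          "association power will be low")
        maf = compute_maf(sub)
        poly = maf.to_numpy() > 0
        if maf_filter:
            poly &= maf.to_numpy() >= 0.05
        run_g = sub.take_loci([l for l, k in zip(sub.locus_ids, poly) if k])
        K = centered_ibs_kinship(run_g)
        pcs = pca_covariates(run_g, min(n_pcs, run_g.n_samples - 2)).scores \
            if n_pcs > 0 else None
        for trait in traits:
            tab = mlm_scan(run_g, pheno[trait], K=K, pcs=pcs)
            tab["q"] = fdr_adjust(tab["p"])
            tab["significant"] = tab["q"] < fdr_threshold
            tab["dataset_label"] = label
            tab["trait_label"] = trait
            tables[(label, trait)] = tab
            sig = tab[tab["significant"]]
            rows.append({"dataset_label": label, "trait_label": trait,
                         "maf_filter": maf_filter,
                         "n_loci_tested": int(tab["p"].notna().sum()),
                         "n_significant": int(len(sig)),
                         "n_common": int((sig["maf_class"] == "common").sum()),
                         "n_rare": int((sig["maf_class"] == "rare").sum())})
    return {"tables": tables, "summary": pd.DataFrame(rows)}


# -- multi-locus mixed model ----------------------------------------------

@dataclass
class MLMMResult:
    """Stepwise path and the multiple-Bonferroni-selected cofactor set."""

    step_path: list = field(default_factory=list)   # per step: cofactors + p's
    selected_model: list = field(default_factory=list)
    criterion: float = np.nan                        # 0.05 / m
    m: int = 0


def _cofactor_pvalues(A, Xbase, cof_cols, y):
    """Joint-model t-test p-value for each cofactor given the others."""
    X = np.column_stack([Xbase] + [c[:, None] for c in cof_cols])
    Xs, ys = A @ X, A @ y
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    r = ys - Xs @ beta
    df = Xs.shape[0] - Xs.shape[1]
    s2 = float(r @ r) / df
    cov = s2 * np.linalg.inv(XtX)
    k = Xbase.shape[1]
    tvals = beta[k:] / np.sqrt(np.diag(cov)[k:])
    return 2.0 * stats.t.sf(np.abs(tvals), df)


def mlmm(g: GenotypeMatrix, y, K: KinshipMatrix | None = None,
         max_steps: int = 10, entry_p: float = 1e-3,
         alpha: float = 0.05) -> MLMMResult:
    """Forward-backward multi-locus mixed model with kinship only (no PCs).

    At each forward step the most significant marker (below the ``entry_p``
    screen) joins the fixed cofactors and the variance components are
    re-estimated; cofactors whose joint-model p rises above the screen are
    dropped again.  The selected model is the largest cofactor set along
    the path whose members all satisfy p < alpha / m, with m the number of
    polymorphic markers tested (the multiple-Bonferroni criterion).  Ties
    in the minimum p are broken by locus order; of two perfectly collinear
    markers only the first can enter.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    g, y, K, _ = _aligned_inputs(g, y, K, None, 0)
    maf = compute_maf(g)
    poly = maf.to_numpy() > 0
    m = int(poly.sum())
    if m == 0:
        raise ValueError("no polymorphic loci")
    bonf = alpha / m
    Ximp = _imputed_calls(g)
    ones = np.ones((g.n_samples, 1))
    locus_ids = np.asarray(g.locus_ids)
    cofactors: list[int] = []
    result = MLMMResult(criterion=bonf, m=m)
    for _step in range(max_steps):
        Xbase = np.column_stack([ones] + [Ximp[:, j][:, None] for j in cofactors])
        if np.linalg.matrix_rank(Xbase) < Xbase.shape[1]:
            break
        fit = greml(y, K, Xbase, compute_se=False)
        A = _whitener(K, fit.sigma2_g, fit.sigma2_e)
        b, se, fstat, pvals, bad = _scan_transformed(A @ Ximp, A @ y, A @ Xbase)
        pvals = np.where(poly & ~bad, pvals, np.nan)
        pvals[cofactors] = np.nan
        if np.all(np.isnan(pvals)):
            break
        j = int(np.nanargmin(pvals))
        if not pvals[j] < entry_p:
            break
        cofactors.append(j)
        # backward: drop cofactors no longer supported in the joint model
        while len(cofactors) > 1:
            cols = [Ximp[:, c] for c in cofactors]
            ps = _cofactor_pvalues(A, ones, cols, y)
            worst = int(np.argmax(ps))
            if ps[worst] <= entry_p:
                break
            cofactors.pop(worst)
        cols = [Ximp[:, c] for c in cofactors]
        ps = _cofactor_pvalues(A, ones, cols, y)
        result.step_path.append({
            "cofactors": [str(locus_ids[c]) for c in cofactors],
            "p_values": [float(v) for v in ps]})
    best: list[str] = []
    for step in result.step_path:
        if all(p < bonf for p in step["p_values"]) and len(step["cofactors"]) > len(best):
            best = list(step["cofactors"])
    result.selected_model = best
    return result


# -- statistical power -----------------------------------------------------

@dataclass
class PowerEstimate:
    n: int
    alpha: float
    qtl_size: float
    lam: float
    power: float


def power_estimate(n: int, qtl_size: float = 0.05, alpha: float = 0.05,
                   lam=1.0):
    """Power to detect a QTL under a polygenic background of ratio lambda.

    The closed form treats the marker test as a 1-df chi-square with
    noncentrality ``n * qtl_size / (1 - qtl_size) / (1 + lambda)``, where
    ``qtl_size`` is the fraction of phenotypic variance explained by the
    QTL and ``lambda`` the polygenic variance expressed as a multiple of
    the phenotypic variance.  Accepts a scalar or a grid of lambda values;
    a grid returns a DataFrame.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not 0 < qtl_size < 1:
        raise ValueError("qtl_size must be in (0, 1)")
    lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be non-negative")
    crit = stats.chi2.isf(alpha, df=1)
    ncp = n * qtl_size / (1.0 - qtl_size) / (1.0 + lam_arr)
    power = stats.ncx2.sf(crit, df=1, nc=ncp)
    if np.isscalar(lam) or np.asarray(lam).ndim == 0:
        return PowerEstimate(n=int(n), alpha=float(alpha),
                             qtl_size=float(qtl_size), lam=float(lam),
                             power=float(power[0]))
    return pd.DataFrame({"n": n, "alpha": alpha, "qtl_size": qtl_size,
                         "lambda": lam_arr, "power": power})
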