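"""Prediction models: SNP sets, imputation, OLS and RR-BLUP, assessment.

A prediction model maps allele counts at a fixed SNP set to a trait value.
Small sets of trait-associated SNPs are fitted by multiple linear
regression; the all-polymorphic-SNP model uses ridge regression with the
RR-BLUP shrinkage (lambda = sigma2_e / sigma2_u estimated by REML on the
marker-based relationship matrix), which is algebraically identical to
GBLUP on the same markers.  Missing genotypes are imputed by family means
with population and dataset-mean fallbacks before fitting or predicting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, classify_maf, compute_maf
from .relatedness import KinshipMatrix
from .varcomp import greml

__all__ = ["SNPSet", "PredictionModel", "EvaluationResult", "SelectionComparison",
           "build_snp_set", "impute_family_mean", "fit_prediction_ols",
           "fit_prediction_ridge", "random_matched_sets", "internal_assessment",
           "external_assessment", "selection_comparison", "train_test_split"]


@dataclass
class SNPSet:
    """A named set of loci with provenance and a dropout report."""

    name: str
    loci: list[str]
    provenance: pd.DataFrame          # columns: locus_id, dataset_label, trait_label, maf_class
    dropped: pd.DataFrame = None      # columns: locus_id, reason

    def __len__(self):
        return len(self.loci)


@dataclass
class PredictionModel:
    intercept: float
    coefficients: pd.Series           # indexed by locus id
    method: str                       # "OLS" | "ridge"
    training_trait: str = ""
    snpset_name: str = ""
    shrinkage: float = 0.0            # ridge only
    train_means: pd.Series = None     # locus means used for centring (ridge)
    imputation: str = "family_mean"

    def predict(self, g: GenotypeMatrix) -> pd.Series:
        """Predicted trait values for samples in ``g`` (family-mean imputed)."""
        X = impute_family_mean(g, list(self.coefficients.index))
        vals = X.to_numpy()
        if self.train_means is not None:
            vals = vals - self.train_means.reindex(self.coefficients.index).to_numpy()
        return pd.Series(self.intercept + vals @ self.coefficients.to_numpy(),
                         index=X.index, name="predicted")


@dataclass
class EvaluationResult:
    label: str
    trait_label: str
    pearson_r: float
    p_value: float
    n: int


@dataclass
class SelectionComparison:
    site: str
    k: int
    site_mean_final: float
    methods: dict = field(default_factory=dict)
    # methods[name] = {selected, mean_final, cv, overlap_with_top_k}


# -- SNP-set assembly ------------------------------------------------------

def _monomorphic_in(g: GenotypeMatrix, loci: list[str]) -> np.ndarray:
    sub = g.take_loci(loci)
    maf = compute_maf(sub).to_numpy()
    return (maf == 0) | np.isnan(maf)


def build_snp_set(assoc_tables, target_genotypes: dict[str, GenotypeMatrix],
                  source_datasets: list[str] | None = None,
                  alpha: float = 0.05, name: str = "snpset") -> SNPSet:
    """Union of significant loci over datasets, minus target monomorphics.

    ``assoc_tables`` are association tables carrying ``q``,
    ``dataset_label``, ``trait_label`` and ``maf_class`` columns.  Loci
    significant (q < alpha) in any table whose dataset is in
    ``source_datasets`` are pooled with merged provenance; any locus
    monomorphic (or untyped) in any of the ``target_genotypes`` is removed
    and reported, mirroring the dropout applied before model construction.
    """
    prov_rows = []
    for tab in assoc_tables:
        if source_datasets is not None and \
                tab["dataset_label"].iloc[0] not in source_datasets:
            continue
        sig = tab[(tab["q"] < alpha) & tab["q"].notna()]
        for locus, row in sig.iterrows():
            prov_rows.append({"locus_id": locus,
                              "dataset_label": row["dataset_label"],
                              "trait_label": row["trait_label"],
                              "maf_class": row.get("maf_class", pd.NA)})
    if not prov_rows:
        raise ValueError(f"SNP set {name!r} is empty: no significant loci in "
                         "the chosen datasets")
    prov = pd.DataFrame(prov_rows)
    loci = list(dict.fromkeys(prov["locus_id"]))
    dropped = []
    for target_name, tg in target_genotypes.items():
        known = set(tg.locus_ids)
        for locus in loci:
            if locus not in known:
                dropped.append({"locus_id": locus,
                                "reason": f"absent in {target_name}"})
        present = [l for l in loci if l in known]
        if present:
            mono = _monomorphic_in(tg, present)
            for locus, m in zip(present, mono):
                if m:
                    dropped.append({"locus_id": locus,
                                    "reason": f"monomorphic in {target_name}"})
    dropped_ids = {d["locus_id"] for d in dropped}
    kept = [l for l in loci if l not in dropped_ids]
    if not kept:
        raise ValueError(f"SNP set {name!r} is empty: all {len(loci)} "
                         "significant loci were monomorphic in a target dataset")
    return SNPSet(name=name, loci=kept,
                  provenance=prov[prov["locus_id"].isin(kept)].reset_index(drop=True),
                  dropped=pd.DataFrame(dropped, columns=["locus_id", "reason"]))


# -- imputation ------------------------------------------------------------

def impute_family_mean(g: GenotypeMatrix, loci: list[str] | None = None
                       ) -> pd.DataFrame:
    """Replace missing calls by family means (population/dataset fallbacks).

    Returns a complete samples x loci DataFrame of allele counts.  The
    fallback chain family -> population -> dataset mean makes the function
    total whenever at least one sample is typed at the locus; a locus with
    no calls at all imputes to 0.
    """
    sub = g if loci is None else g.take_loci(loci)
    df = pd.DataFrame(sub.calls, index=sub.sample_ids, columns=sub.locus_ids)
    meta = sub.sample_meta
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for level in ("family", "population"):
            if df.isna().any().any() and level in meta.columns:
                means = df.groupby(meta[level]).transform("mean")
                df = df.fillna(means)
        df = df.fillna(df.mean(axis=0)).fillna(0.0)
    df.index.name = "individual_id"
    return df


# -- model fitting ---------------------------------------------------------

def fit_prediction_ols(g_train: GenotypeMatrix, y_train, snpset: SNPSet,
                       training_trait: str = "",
                       on_singular: str = "raise") -> PredictionModel:
    """Multiple linear regression of the trait on imputed allele counts.

    ``on_singular='raise'`` (default) errors on a rank-deficient design,
    naming constant loci; ``'drop'`` zeroes the coefficient of loci constant
    in the training set and resolves remaining collinearity by the
    minimum-norm solution, matching how R's ``lm`` NA's such terms.
    """
    loci = snpset.loci if isinstance(snpset, SNPSet) else list(snpset)
    name = snpset.name if isinstance(snpset, SNPSet) else "custom"
    y = _aligned_y(g_train, y_train)
    ok = ~np.isnan(y)
    X = impute_family_mean(g_train, loci).to_numpy()[ok]
    y = y[ok]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"training n = {n} <= number of SNPs + 1 = {p + 1}; "
                         "use ridge regression for wide sets")
    used = list(range(p))
    Xd = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        sd = X.std(axis=0)
        flat = [loci[j] for j in np.nonzero(sd == 0)[0]]
        if on_singular == "raise":
            raise ValueError("rank-deficient design; collinear or constant loci: "
                             f"{flat if flat else 'correlated pair(s) among set'}")
        used = [j for j in range(p) if sd[j] > 0]
        Xd = np.column_stack([np.ones(n), X[:, used]])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    coef = pd.Series(0.0, index=loci)
    coef.iloc[used] = beta[1:]
    return PredictionModel(intercept=float(beta[0]),
                           coefficients=coef,
                           method="OLS", training_trait=training_trait,
                           snpset_name=name)


def fit_prediction_ridge(g_train: GenotypeMatrix, y_train,
                         loci: list[str] | None = None,
                         training_trait: str = "") -> PredictionModel:
    """RR-BLUP on all (or the given) polymorphic SNPs.

    Marker effects are ``u = Z'(ZZ' + lambda I)^-1 (y - ybar)`` with
    ``lambda = sigma2_e / sigma2_u`` from REML on the marker-based
    relationship matrix; for loci >> samples this is the GBLUP-equivalent
    form and predictions from the two parameterizations are identical.
    """
    y = _aligned_y(g_train, y_train)
    ok = ~np.isnan(y)
    ids = [s for s, k in zip(g_train.sample_ids, ok) if k]
    sub = g_train.take_samples(ids)
    y = y[ok]
    X = impute_family_mean(sub, loci)
    means = X.mean(axis=0)
    Z = X.to_numpy() - means.to_numpy()
    sd = Z.std(axis=0)
    if (sd > 0).sum() < 2:
        raise ValueError("need >= 2 polymorphic loci for ridge regression")
    G = Z @ Z.T
    m_diag = float(np.trace(G)) / len(y)  # scale to mean diagonal 1
    K = KinshipMatrix(G / m_diag, sub.sample_ids)
    try:
        fit = greml(y, K, compute_se=False)
    except ValueError as exc:
        raise ValueError(f"ridge shrinkage estimation failed: {exc}") from exc
    if fit.sigma2_g <= 0 or fit.h2 < 1e-6:
        warnings.warn("zero genetic variance estimate; returning intercept-only model")
        coef = pd.Series(0.0, index=X.columns)
        return PredictionModel(intercept=float(np.mean(y)), coefficients=coef,
                               method="ridge", training_trait=training_trait,
                               snpset_name="all_snps", shrinkage=np.inf,
                               train_means=means)
    sigma2_u = fit.sigma2_g / m_diag  # marker-effect variance: cov(g)=sigma2_u ZZ'
    lam = fit.sigma2_e / sigma2_u
    yc = y - y.mean()
    alpha = np.linalg.solve(Z @ Z.T + lam * np.eye(len(y)), yc)
    u = Z.T @ alpha
    return PredictionModel(intercept=float(np.mean(y)),
                           coefficients=pd.Series(u, index=X.columns),
                           method="ridge", training_trait=training_trait,
                           snpset_name="all_snps", shrinkage=float(lam),
                           train_means=means)


def _aligned_y(g: GenotypeMatrix, y) -> np.ndarray:
    if isinstance(y, pd.Series):
        return y.reindex(g.sample_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != g.n_samples:
        raise ValueError("phenotype length does not match genotypes")
    return y


# -- controls and assessment ----------------------------------------------

def random_matched_sets(g: GenotypeMatrix, reference: SNPSet,
                        maf: pd.Series | None = None, n_sets: int = 10,
                        seed: int = 0) -> list[SNPSet]:
    """Random SNP sets matching the reference's common/rare composition.

    Samples without replacement from the polymorphic loci of ``g``,
    stratified so every set has exactly the reference's count of common and
    rare loci (MAF classes from ``maf``, by default computed on ``g``).
    """
    rng = np.random.default_rng(seed)
    if maf is None:
        maf = compute_maf(g)
    cls = classify_maf(maf)
    ref_cls = classify_maf(maf.reindex(reference.loci))
    want = {"common": int((ref_cls == "common").sum()),
            "rare": int((ref_cls == "rare").sum())}
    pools = {c: [l for l in g.locus_ids
                 if cls.get(l) == c and maf.get(l, 0) > 0] for c in want}
    for c, k in want.items():
        if len(pools[c]) < k:
            raise ValueError(f"not enough {c} polymorphic loci "
                             f"({len(pools[c])} < {k})")
    out = []
    for i in range(n_sets):
        loci = []
        for c, k in want.items():
            loci += list(rng.choice(pools[c], size=k, replace=False))
        prov = pd.DataFrame({"locus_id": loci, "dataset_label": "random",
                             "trait_label": "random",
                             "maf_class": [cls.get(l) for l in loci]})
        out.append(SNPSet(name=f"random_{i + 1}", loci=loci, provenance=prov))
    return out


def train_test_split(g: GenotypeMatrix, train_fraction: float = 0.6,
                     seed: int = 0, family_stratified: bool = False):
    """Seeded random split of sample ids (optionally within families)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(g.sample_ids)
    if family_stratified and "family" in g.sample_meta.columns:
        train = []
        for _, members in pd.Series(ids).groupby(
                g.sample_meta["family"].to_numpy()):
            arr = members.to_numpy()
            rng.shuffle(arr)
            k = int(round(train_fraction * len(arr)))
            train += list(arr[:k])
        train_set = set(train)
    else:
        perm = rng.permutation(len(ids))
        k = int(round(train_fraction * len(ids)))
        train_set = set(ids[perm[:k]])
    train_ids = [s for s in ids if s in train_set]
    test_ids = [s for s in ids if s not in train_set]
    return train_ids, test_ids


def _pearson_eval(pred: np.ndarray, obs: np.ndarray, label: str,
                  trait: str) -> EvaluationResult:
    ok = ~(np.isnan(pred) | np.isnan(obs))
    n = int(ok.sum())

    def _flat(v):
        return np.std(v) <= 1e-12 * (np.abs(v).mean() + 1.0)

    if n < 3 or _flat(pred[ok]) or _flat(obs[ok]):
        return EvaluationResult(label, trait, np.nan, np.nan, n)
    r, p = stats.pearsonr(pred[ok], obs[ok])
    return EvaluationResult(label, trait, float(r), float(p), n)


def internal_assessment(g: GenotypeMatrix, y, snpset: SNPSet | None = None,
                        method: str = "ols", train_fraction: float = 0.6,
                        seed: int = 0, family_stratified: bool = False,
                        predictor: pd.Series | None = None,
                        trait_label: str = "") -> EvaluationResult:
    """Train/test split assessment of a prediction model.

    Fits the requested model on a seeded random ``train_fraction`` split
    (60/40 by default) and reports the Pearson correlation between
    predicted and observed values on the held-out samples.  ``predictor``
    bypasses fitting and evaluates externally supplied per-sample values
    (e.g. true breeding values as an oracle).
    """
    yv = pd.Series(_aligned_y(g, y), index=g.sample_ids)
    train_ids, test_ids = train_test_split(g, train_fraction, seed,
                                           family_stratified)
    test_ids = [s for s in test_ids if not np.isnan(yv[s])]
    if len(test_ids) < 3:
        raise ValueError("test set smaller than 3 after removing missing traits")
    if predictor is not None:
        pred = predictor.reindex(test_ids).to_numpy(dtype=float)
    else:
        g_train = g.take_samples(train_ids)
        y_train = yv.reindex(train_ids)
        if method == "ols":
            model = fit_prediction_ols(g_train, y_train, snpset,
                                       training_trait=trait_label,
                                       on_singular="drop")
        elif method == "ridge":
            loci = snpset.loci if snpset is not None else None
            model = fit_prediction_ridge(g_train, y_train, loci,
                                         training_trait=trait_label)
        else:
            raise ValueError(f"unknown method {method!r}")
        pred = model.predict(g.take_samples(test_ids)).to_numpy()
    obs = yv.reindex(test_ids).to_numpy(dtype=float)
    return _pearson_eval(pred, obs, "internal", trait_label)


def external_assessment(model: PredictionModel, g_site: GenotypeMatrix,
                        pheno_site: pd.DataFrame,
                        traits: list[str] | None = None,
                        site_label: str = "") -> pd.DataFrame:
    """Predicted-vs-observed Pearson r per trait at an independent site."""
    pred = model.predict(g_site)
    traits = list(pheno_site.columns) if traits is None else traits
    rows = []
    for trait in traits:
        if trait not in pheno_site.columns:
            rows.append({"site": site_label, "trait_label": trait,
                         "pearson_r": np.nan, "p_value": np.nan, "n": 0})
            continue
        obs = pheno_site[trait].reindex(pred.index).to_numpy(dtype=float)
        res = _pearson_eval(pred.to_numpy(), obs, site_label, trait)
        rows.append({"site": site_label, "trait_label": trait,
                     "pearson_r": res.pearson_r, "p_value": res.p_value,
                     "n": res.n})
    return pd.DataFrame(rows)


def selection_comparison(predicted: pd.Series, early: pd.Series,
                         final: pd.Series, k: int = 10,
                         site: str = "") -> SelectionComparison:
    """Genomic vs phenotype selection of the top k trees at a site.

    Genomic selection takes the k highest model-predicted trees; phenotype
    selection the k tallest before the second growing season.  For each
    method the mean final height, coefficient of variation (SD/mean x 100)
    and overlap with the true final top-k are reported.  Ties at rank k are
    broken by id order.
    """
    ids = predicted.index
    final = final.reindex(ids)
    early = early.reindex(ids)
    n = len(ids)
    if k > n:
        raise ValueError(f"k = {k} exceeds site size {n}")

    def top_k(values: pd.Series) -> list[str]:
        df = pd.DataFrame({"v": values.to_numpy()}, index=values.index)
        df = df.sort_values(["v"], ascending=False, kind="mergesort")
        # stable sort on descending value; ids already in storage order
        return list(df.index[:k])

    true_top = set(top_k(final.dropna()))
    out = SelectionComparison(site=site, k=k,
                              site_mean_final=float(final.mean()))
    for name, score in (("genomic", predicted), ("phenotype", early)):
        sel = top_k(score.dropna())
        fin = final.reindex(sel).dropna()
        mean = float(fin.mean())
        cv = float(fin.std(ddof=1) / mean * 100.0) if mean != 0 and len(fin) > 1 else 0.0
        if len(fin) > 1 and float(fin.std(ddof=1)) == 0.0:
            cv = 0.0
        out.methods[name] = {"selected": sel, "mean_final": mean, "cv": cv,
                             "overlap_with_top_k": len(set(sel) & true_top)}
    return out
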