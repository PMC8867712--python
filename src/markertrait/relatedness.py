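"""Kinship, genetic distance and stratification covariates.

The kinship estimator is the centred identity-by-state (IBS) genomic
relationship matrix: genotype columns are centred at twice the sample
allele frequency and the cross-product is scaled by ``sum_l 2 p_l (1-p_l)``
so that the expected diagonal is ~1 + F.  Downstream mixed models are
invariant to the global scale of K; the scaling convention matters only for
reading coefficients off the matrix itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["KinshipMatrix", "centered_ibs_kinship", "dagostino_skewness",
           "pca_covariates", "ibs_distance_matrix"]


class KinshipMatrix:
    """Symmetric PSD sample-covariance matrix with sample ids."""

    def __init__(self, values: np.ndarray, sample_ids):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("kinship must be square")
        if len(sample_ids) != values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = 0.5 * (values + values.T)
        self.sample_ids = [str(s) for s in sample_ids]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def align(self, sample_ids) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[str(s)] for s in sample_ids])
        return KinshipMatrix(self.values[np.ix_(idx, idx)], list(sample_ids))

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinshipMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index))


def _centered_imputed(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Locus-mean-imputed, locus-centred call matrix and allele freqs."""
    X = g.calls.copy()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    nan = np.isnan(X)
    X[nan] = np.take(mean, np.nonzero(nan)[1])
    return X - mean, mean / 2.0


def centered_ibs_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Centred-IBS genomic kinship: K = W W' / sum_l 2 p_l (1 - p_l).

    Missing calls are mean-imputed per locus for this computation only,
    which keeps K a Gram matrix and hence positive semidefinite.
    Monomorphic loci contribute nothing; a matrix with no polymorphic locus
    is an error.
    """
    W, p = _centered_imputed(g)
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("all loci monomorphic: kinship scaling constant is 0")
    K = W @ W.T / c
    return KinshipMatrix(K, g.sample_ids)


def dagostino_skewness(values) -> tuple[float, float]:
    """D'Agostino's skewness test: z statistic and two-sided normal p.

    Requires n >= 8 (the normalizing transform is undefined below) and a
    non-degenerate sample.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValueError(f"D'Agostino skewness test needs n >= 8, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance sample: skewness undefined")
    res = stats.skewtest(x)
    return float(res.statistic), float(res.pvalue)


class PCScores:
    """Principal-component coordinates (n x k) with eigenvalues."""

    def __init__(self, scores: np.ndarray, eigenvalues: np.ndarray, sample_ids):
        self.scores = np.asarray(scores, dtype=float)
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.sample_ids = [str(s) for s in sample_ids]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca_covariates(g: GenotypeMatrix, k: int) -> PCScores:
    """Top-k principal components of the centred, mean-imputed genotypes.

    Scores are eigenvectors scaled by singular values, the usual
    stratification covariates for association models.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= g.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    W, _ = _centered_imputed(g)
    W = W - W.mean(axis=0)  # exact column centring after imputation
    U, s, _ = np.linalg.svd(W, full_matrices=False)
    scores = U[:, :k] * s[:k]
    eig = s ** 2 / max(g.n_samples - 1, 1)
    return PCScores(scores, eig[:k], g.sample_ids)


def ibs_distance_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - mean IBS sharing over loci typed in both samples of a pair.

    Sharing at a locus is ``1 - |x_i - x_j| / 2``.  A pair with no shared
    typed locus gets a missing distance.  The measure is not guaranteed
    metric; triangle-inequality violations are possible.
    """
    X = g.calls
    n = g.n_samples
    D = np.zeros((n, n))
    ok = ~np.isnan(X)
    Xz = np.where(ok, X, 0.0)
    for i in range(n):
        shared = ok[i] & ok[i + 1:]
        diff = np.abs(Xz[i] - Xz[i + 1:]) * shared
        cnt = shared.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (diff.sum(axis=1) / 2.0) / cnt
        d[cnt == 0] = np.nan
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return pd.DataFrame(D, index=g.sample_ids, columns=g.sample_ids)
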