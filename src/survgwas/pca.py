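"""Genotype principal components for population-stratification adjustment.

Standard GWAS convention: per-variant mean imputation of missing calls,
centering at 2p and scaling by sqrt(2p(1-p)) (the binomial SD of an allele
dosage), then the leading eigenvectors of the subject-by-subject covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, ValidationError


class GenotypePCA(BaseEstimator):
    """Top-k genotype principal components (EIGENSTRAT-style scaling).

    Attributes (after fit)
    ----------------------
    components_ : ndarray (n_subjects, k) — subject scores, orthonormal columns
    explained_variance_ratio_ : ndarray (k,)
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, g: GenotypeMatrix, y=None) -> "GenotypePCA":
        k = self.n_components
        if g.n_subjects < k + 1:
            raise ValidationError(f"need at least {k + 1} subjects for {k} components")
        if g.n_variants < k:
            raise ValidationError(f"need at least {k} variants for {k} components")
        Z = self._standardise(g)
        # subject-space eigenvectors via SVD of the standardised matrix
        u, s, _ = np.linalg.svd(Z, full_matrices=False)
        ev = s ** 2
        rank = int(np.sum(s > s[0] * 1e-9)) if len(s) else 0
        if k > rank:
            raise ValidationError(f"requested {k} components but matrix rank is {rank}")
        u = u[:, :k]
        # deterministic sign: largest-magnitude loading of each component positive
        for j in range(k):
            i = np.argmax(np.abs(u[:, j]))
            if u[i, j] < 0:
                u[:, j] = -u[:, j]
        self.components_ = u
        total = ev.sum()
        self.explained_variance_ratio_ = ev[:k] / total if total > 0 else np.zeros(k)
        return self

    @staticmethod
    def _standardise(g: GenotypeMatrix) -> np.ndarray:
        X = g.dosage.copy()
        p = np.nanmean(X, axis=0) / 2.0
        mu = 2.0 * p
        sd = np.sqrt(2.0 * p * (1.0 - p))
        idx = np.where(np.isnan(X))
        X[idx] = np.take(mu, idx[1])  # per-variant mean imputation
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (X - mu) / sd
        Z[:, (sd == 0) | ~np.isfinite(sd)] = 0.0  # monomorphic: no information
        return Z

    def transform(self, g: GenotypeMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            self.components_,
            columns=[f"PC{j + 1}" for j in range(self.n_components)],
            index=pd.Index(g.subject_ids, name="subject_id"),
        )

    def fit_transform(self, g: GenotypeMatrix, y=None) -> pd.DataFrame:
        return self.fit(g).transform(g)


def genotype_pca(g: GenotypeMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k genotype PCs as a subject-indexed table plus explained-variance shares."""
    pca = GenotypePCA(n_components=k)
    pcs = pca.fit_transform(g)
    return pcs, pca.explained_variance_ratio_
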