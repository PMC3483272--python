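"""Ancestry coordinate space: LD pruning and principal components.

Genome-wide ancestry is summarized by the leading principal components of an
LD-pruned genotype matrix ("3PC-space" with the default of three
components). Pruning removes SNPs in high linkage disequilibrium within
sliding windows so that a few dense, highly correlated genomic regions do
not dominate the subject clustering; PCA is then run on the mean-imputed,
standardized dosage matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "GenotypeMatrix",
    "PCProjection",
    "ld_prune",
    "compute_pcs",
    "LDPruner",
    "AncestryPCA",
]


@dataclass
class GenotypeMatrix:
    """Additive-coded dosage matrix (subjects x SNPs).

    ``dosages`` holds counts of the alternate allele in {0, 1, 2}, with
    missing calls as NaN (never a dosage value). SNP columns are assumed
    ordered by genomic position.
    """

    subjects: list[str]
    snps: list[str]
    dosages: np.ndarray
    fids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.fids is not None and len(self.fids) != len(self.subjects):
            raise ValueError("fids length mismatch")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class PCProjection:
    """Subjects projected on the leading principal components."""

    subjects: list[str]
    coords: np.ndarray
    explained_variance: np.ndarray


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed on subjects non-missing for both SNPs; monomorphic columns
    (zero variance) yield r^2 = 0 with a warning.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if xs.size < 2:
        return 0.0
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        warnings.warn("monomorphic SNP in LD window; treating r^2 as 0", stacklevel=3)
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


class LDPruner(BaseEstimator, TransformerMixin):
    """Sliding-window LD pruning of a dosage matrix (indep-pairwise style).

    Within each ``window`` SNPs the pruner repeatedly removes the later SNP
    of any retained pair with r^2 above ``r2_threshold``; the window then
    slides by ``step`` SNPs. Removal is recursive: a removed SNP never
    blocks later windows. Defaults follow standard GWAS practice (50-SNP
    window, 5-SNP step, r^2 > 0.1).

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_snps,)
        Mask of retained SNP columns.
    """

    def __init__(self, window: int = 50, step: int = 5, r2_threshold: float = 0.1):
        self.window = window
        self.step = step
        self.r2_threshold = r2_threshold

    def fit(self, X, y=None):
        if not (self.window > self.step > 0):
            raise ValueError("require window > step > 0")
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        m = X.shape[1]
        keep = np.ones(m, dtype=bool)
        start = 0
        while True:
            stop = min(start + self.window, m)
            idx = [j for j in range(start, stop) if keep[j]]
            changed = True
            while changed:
                changed = False
                for u in range(len(idx)):
                    if not keep[idx[u]]:
                        continue
                    for v in range(u + 1, len(idx)):
                        if not keep[idx[v]]:
                            continue
                        if _pairwise_r2(X[:, idx[u]], X[:, idx[v]]) > self.r2_threshold:
                            keep[idx[v]] = False  # drop the later SNP
                            changed = True
            if stop >= m:
                break
            start += self.step
        self.support_ = keep
        self.n_features_in_ = m
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.support_]

    def get_support(self):
        return self.support_


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.1,
) -> list[str]:
    """Retained SNP IDs after sliding-window LD pruning (input order kept)."""
    pruner = LDPruner(window=window_snps, step=step_snps, r2_threshold=r2_threshold)
    pruner.fit(g.dosages)
    return [s for s, k in zip(g.snps, pruner.support_) if k]


class AncestryPCA(BaseEstimator, TransformerMixin):
    """PCA of a mean-imputed, standardized dosage matrix.

    Missing dosages are imputed with the per-SNP mean; each SNP column is
    centered and scaled to unit variance (zero-variance columns are left
    centered only); components are the leading right singular vectors.
    Signs are fixed by requiring each component's largest-magnitude loading
    to be positive, so outputs are reproducible up to nothing.

    Attributes
    ----------
    mean_ : ndarray
        Per-SNP imputation/centering means.
    scale_ : ndarray
        Per-SNP standard deviations (1 where zero).
    components_ : ndarray of shape (n_components, n_snps)
    explained_variance_ : ndarray
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, y=None):
        self._fit(np.asarray(X, dtype=float))
        return self

    def _fit(self, X: np.ndarray) -> np.ndarray:
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > min(X.shape):
            raise ValueError(
                f"n_components={k} exceeds matrix dimensions {X.shape}"
            )
        all_missing = np.all(np.isnan(X), axis=0)
        if all_missing.any():
            warnings.warn(
                f"excluding {int(all_missing.sum())} all-missing SNP column(s)",
                stacklevel=3,
            )
        self.column_support_ = ~all_missing
        X = X[:, self.column_support_]
        mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), mean, X)
        sd = X.std(axis=0)
        scale = np.where(sd > 0, sd, 1.0)
        Z = (X - mean) / scale
        if not np.any(Z):
            raise ValueError("degenerate genotype matrix: zero total variance")
        rank = np.linalg.matrix_rank(Z)
        if k > rank:
            raise ValueError(f"n_components={k} exceeds matrix rank {rank}")
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Z)
        comps = pca.components_
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
        flip[flip == 0] = 1.0
        comps = comps * flip[:, None]
        scores = scores * flip[None, :]
        self.mean_ = mean
        self.scale_ = scale
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_features_in_ = self.column_support_.size
        return scores

    def fit_transform(self, X, y=None):
        return self._fit(np.asarray(X, dtype=float))

    def transform(self, X):
        X = np.asarray(X, dtype=float)[:, self.column_support_]
        X = np.where(np.isnan(X), self.mean_, X)
        return ((X - self.mean_) / self.scale_) @ self.components_.T


def compute_pcs(
    g: GenotypeMatrix, retained: list[str] | None = None, k: int = 3
) -> PCProjection:
    """Project subjects on the top ``k`` PCs of the (pruned) dosage matrix."""
    if retained is None:
        cols = np.arange(g.n_snps)
    else:
        pos = {s: i for i, s in enumerate(g.snps)}
        cols = np.array([pos[s] for s in retained], dtype=int)
    est = AncestryPCA(n_components=k)
    coords = est.fit_transform(g.dosages[:, cols])
    return PCProjection(
        subjects=list(g.subjects),
        coords=coords,
        explained_variance=est.explained_variance_,
    )
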