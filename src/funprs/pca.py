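"""Principal components of the genotype matrix for population structure.

Genotypes are variance-standardized per variant ((d - 2p)/sqrt(2p(1-p)) with
p the counted-allele frequency), missing entries set to 0 after centering,
and decomposed by SVD.  Eigenvalues follow the population-genetics
convention: eigenvalues of (1/m) X Xᵀ, the samples x samples covariance of
the standardized matrix across m variants.  Component scores (U·S) are
mean-zero and mutually orthogonal, with a deterministic sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, InputError

logger = logging.getLogger("funprs")


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # nonincreasing
    scores: np.ndarray  # samples x components (U * S)
    loadings: np.ndarray  # variants x components (V)
    n_components: int
    sample_ids: list[str]
    variant_ids: list[str]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{k + 1}" for k in range(self.n_components)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def standardize_genotypes(
    matrix: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant standardization; returns (standardized matrix, kept index).

    Monomorphic variants (zero variance) are dropped with a report.  Missing
    entries become 0 after centering, i.e. mean imputation.
    """
    d = matrix.dosage
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1))
    keep = (n_obs > 0) & (p > 0) & (p < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("standardize_genotypes: dropped %d monomorphic/empty variants",
                       n_dropped)
    p = p[keep]
    x = d[:, keep] - 2 * p[None, :]
    x = np.where(np.isnan(x), 0.0, x)
    x /= np.sqrt(2 * p * (1 - p))[None, :]
    return x, np.flatnonzero(keep)


def genotype_pca(
    standardized: np.ndarray,
    n_components: int = 20,
    sample_ids: list[str] | None = None,
    variant_ids: list[str] | None = None,
) -> PcaResult:
    """Top-k decomposition of the standardized genotype matrix.

    Eigenvalues are s_k^2 / m (of the samples-covariance (1/m) X Xᵀ); scores
    are U·S.  Signs are fixed so the largest-magnitude loading of each
    component is positive.  Rank-deficient inputs return the achievable
    number of components with a warning.
    """
    x = np.asarray(standardized, dtype=float)
    n, m = x.shape
    if n < n_components:
        raise InputError(f"n_components={n_components} exceeds {n} samples")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("rank-deficient input: returning %d of %d components",
                       k, n_components)
    u, s, v = u[:, :k], s[:k], vt[:k].T
    # deterministic signs: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    return PcaResult(
        eigenvalues=s**2 / m,
        scores=u * s[None, :],
        loadings=v,
        n_components=k,
        sample_ids=list(sample_ids or [f"S{i}" for i in range(n)]),
        variant_ids=list(variant_ids or [f"V{j}" for j in range(m)]),
    )


def shifted_sqrt(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Square-root transform of a shifted-positive copy of a covariate.

    Returns (sqrt(values - min + eps), shift used).  Applying it is the
    caller's choice; the shift is returned so it can be recorded.
    """
    values = np.asarray(values, dtype=float)
    shift = float(values.min())
    return np.sqrt(values - shift), shift
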