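"""Principal component analysis of genotype matrices with breed centroids.

SNP-wise normalization follows the standard for genotype PCA: centre each
SNP by its mean call and scale by sqrt(2 p (1-p)) with p the sample allele
frequency (the drift-variance unit), set missing calls to zero after
centring (mean imputation), then eigendecompose the individual-by-
individual covariance.  With many breeds on one plot, per-breed centroids
of the first two components summarize structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = ["PcaResult", "pca_genotypes", "breed_centroids"]


@dataclass
class PcaResult:
    """Scores, explained-variance fractions and per-breed centroids."""

    scores: np.ndarray  # individuals x components
    explained_fraction: np.ndarray  # per component, non-increasing
    individuals: list[tuple[str, str]]
    centroids: pd.DataFrame | None = None


def _normalized_matrix(gm: GenotypeMatrix) -> np.ndarray:
    x = gm.calls.astype(float)
    x[gm.calls == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    p = mu / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = np.isfinite(scale) & (scale > 0)
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic SNPs")
    x = x[:, poly]
    x = np.where(np.isnan(x), mu[poly], x) - mu[poly]
    return x / scale[poly]


def pca_genotypes(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of a genotype matrix (normalized as in SNP-PCA practice).

    Components are ordered by eigenvalue; each component's sign is fixed by
    forcing its largest-magnitude SNP loading positive, so results do not
    depend on numerical sign conventions.
    """
    if gm.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    z = _normalized_matrix(gm)
    n, m = z.shape
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(k):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u[:, :k] * s[:k]
    var = s**2
    explained = var[:k] / var.sum()
    return PcaResult(scores, explained, list(gm.individuals))


def breed_centroids(result: PcaResult) -> pd.DataFrame:
    """Unweighted per-breed mean of (PC1, PC2) scores."""
    if result.scores.shape[1] < 2:
        raise ValueError("need at least two components for centroids")
    df = pd.DataFrame(
        {
            "breed_id": [b for _, b in result.individuals],
            "pc1": result.scores[:, 0],
            "pc2": result.scores[:, 1],
        }
    )
    cent = df.groupby("breed_id", sort=False).mean().reset_index()
    result.centroids = cent
    return cent
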