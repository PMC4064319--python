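"""Population-stratification PCA of the genotype matrix.

Sites are normalized the way the classic stratification-PCA programs do:
each site (row) is centered by twice its estimated allele frequency and
scaled by the binomial standard deviation sqrt(p(1-p)); the principal
components are then the eigenvectors of the resulting sample-by-sample
covariance.  Missing genotypes are mean-imputed per site.

The allele-frequency estimate defaults to the shrunk form
(1 + sum g) / (2 + 2n), which stabilizes the scaling of rare variants on
small cohorts; ``shrink=False`` switches to the plain MLE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class PCAInputError(ValueError):
    pass


@dataclass
class PCAResult:
    coords: np.ndarray  # (n_samples, k) sample coordinates
    eigenvalues: np.ndarray  # (k,) non-increasing
    retained_sites: np.ndarray  # indices of rows actually used
    samples: Optional[list[str]] = None


def filter_sites_for_pca(
    n_carriers: Sequence[int],
    coverage_by_site: Optional[Sequence[float]] = None,
    min_coverage: float = 10.0,
    require_carrier: bool = True,
) -> np.ndarray:
    """Indices of sites eligible for PCA.

    A site is retained when its coverage in the anchoring cohort is
    *strictly* greater than ``min_coverage`` and (by default) at least
    one individual carries the variant.  When no coverage is available
    the coverage filter is skipped with a warning.
    """
    n_carriers = np.asarray(n_carriers)
    keep = np.ones(n_carriers.shape[0], dtype=bool)
    if coverage_by_site is None:
        warnings.warn("no per-site coverage supplied; coverage filter skipped")
    else:
        cov = np.asarray(coverage_by_site, dtype=float)
        keep &= np.nan_to_num(cov, nan=-np.inf) > min_coverage
    if require_carrier:
        keep &= n_carriers >= 1
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("site filter retained no sites")
    return idx


def eigenstrat_pca(
    genotypes: np.ndarray,
    k: int = 10,
    shrink: bool = True,
    samples: Optional[list[str]] = None,
) -> PCAResult:
    """PCA of a sites-by-samples 0/1/2 dosage matrix.

    Missing entries may be NaN or negative; they are imputed with the
    site mean.  Sites monomorphic after imputation carry no information
    and are dropped with a warning.  Component signs are canonicalized so
    the largest-magnitude loading of each component is positive.
    """
    G = np.array(genotypes, dtype=float)
    if G.ndim != 2:
        raise PCAInputError("genotypes must be a 2-D sites x samples array")
    G[G < 0] = np.nan
    n_sites, n_samples = G.shape
    if n_sites < 2 or n_samples < 3:
        raise PCAInputError("need >=2 sites and >=3 samples for PCA")

    row_mean = np.nanmean(G, axis=1)
    inds = np.where(np.isnan(G))
    G[inds] = np.take(row_mean, inds[0])

    mle = row_mean / 2.0
    poly = (mle > 0.0) & (mle < 1.0)
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic site(s) before PCA")
    G = G[poly]
    row_mean = row_mean[poly]
    retained = np.flatnonzero(poly)
    if G.shape[0] < 2:
        raise PCAInputError("fewer than 2 polymorphic sites after filtering")

    if shrink:
        p_hat = (1.0 + G.sum(axis=1)) / (2.0 + 2.0 * n_samples)
    else:
        p_hat = row_mean / 2.0
    scale = np.sqrt(p_hat * (1.0 - p_hat))
    X = (G - row_mean[:, None]) / scale[:, None]

    cov = X.T @ X / X.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    k = min(k, n_samples)
    coords = eigvecs[:, :k].copy()
    for j in range(k):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    # numerical zeros can come out slightly negative from eigh
    eigvals = np.where(np.abs(eigvals) < 1e-10, 0.0, eigvals)
    return PCAResult(
        coords=coords,
        eigenvalues=eigvals[:k],
        retained_sites=retained,
        samples=samples,
    )


def coordinates_frame(result: PCAResult, panel=None):
    """Sample-coordinate table (sample, population, group, PC1..PCk)."""
    import pandas as pd

    k = result.coords.shape[1]
    df = pd.DataFrame(result.coords, columns=[f"PC{i+1}" for i in range(k)])
    if result.samples is not None:
        df.insert(0, "sample", result.samples)
        if panel is not None:
            df.insert(1, "population", [panel.population[s] for s in result.samples])
            df.insert(2, "group", [panel.group[s] for s in result.samples])
    return df
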