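"""PCA visualization of tumors in a signature gene space, with model-based
clustering (Gaussian mixture, BIC-selected k) to confirm visually
identified groups. Cross-projection between two cohorts' signatures uses
the same operation with swapped inputs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import DataError, ExpressionMatrix

__all__ = ["ProjectionResult", "pca_scores", "gmm_cluster"]


@dataclass
class ProjectionResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # genes x components
    n_components: int
    dropped_genes: list[str]

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-12):
            raise DataError("explained-variance fractions must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-12):
            raise DataError("explained-variance fractions must be non-increasing")


def pca_scores(
    X: ExpressionMatrix,
    genes: list[str],
    k: int = 2,
    standardize: bool = False,
) -> ProjectionResult:
    """Sample scores on the first k principal components of the matrix
    restricted to ``genes``.

    Covariance-mode PCA on the log2 data by default (``standardize=True``
    switches to correlation mode). Computed by SVD of the column-centered
    samples x genes matrix; each component's sign is fixed by making its
    largest-magnitude gene loading positive. Genes missing from the matrix
    are dropped with a warning.
    """
    present = [g for g in genes if g in set(X.probe_ids)]
    dropped = [g for g in genes if g not in set(X.probe_ids)]
    if dropped:
        warnings.warn(f"{len(dropped)} requested genes absent from matrix; dropped")
    if len(present) < 2 or len(present) < k:
        raise DataError(f"need >= max(2, k) usable genes, got {len(present)}")
    M = X.subset_probes(present).values.T  # samples x genes
    M = M - M.mean(axis=0, keepdims=True)
    if standardize:
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise DataError("zero-variance gene under correlation-mode PCA")
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    k_eff = min(k, S.size)
    total_var = float((S**2).sum())
    evr = (S[:k_eff] ** 2) / total_var if total_var > 0 else np.zeros(k_eff)
    # sign convention: largest-magnitude loading of each component positive
    signs = np.ones(k_eff)
    for c in range(k_eff):
        lead = np.argmax(np.abs(Vt[c]))
        if Vt[c, lead] < 0:
            signs[c] = -1.0
    scores = U[:, :k_eff] * S[:k_eff] * signs
    loadings = Vt[:k_eff].T * signs
    comp_names = [f"PC{i+1}" for i in range(k_eff)]
    return ProjectionResult(
        scores=pd.DataFrame(scores, index=X.sample_ids, columns=comp_names),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(loadings, index=present, columns=comp_names),
        n_components=k_eff,
        dropped_genes=dropped,
    )


def gmm_cluster(
    scores: pd.DataFrame | np.ndarray,
    k_range: range = range(1, 6),
    seed: int | None = None,
) -> tuple[np.ndarray, dict[int, float], int]:
    """Model-based clustering of PCA scores: full-covariance Gaussian
    mixtures fit by EM for each k, best k chosen by BIC.

    Returns (labels, {k: bic}, chosen_k). Deterministic given seed.
    """
    pts = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    if pts.shape[0] < max(k_range):
        raise DataError(
            f"need >= {max(k_range)} points for k up to {max(k_range)}, got {pts.shape[0]}"
        )
    bics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-6,
            n_init=5,
            random_state=None if seed is None else int(seed) % (2**31),
        )
        gm.fit(pts)
        bics[k] = float(gm.bic(pts))
        fits[k] = gm
    best_k = min(bics, key=lambda k: (bics[k], k))
    labels = fits[best_k].predict(pts)
    return labels, bics, best_k
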