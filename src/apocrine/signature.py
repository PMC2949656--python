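"""Two-group probe-signature derivation.

The procedure mirrors supervised analysis practice for small-cohort
microarray contrasts:

1. per-probe Welch t-test between the two sample groups;
2. screening at a p-value threshold (default 0.01), with the local
   false-discovery rate achieved at that boundary reported alongside
   (estimated from a two-component mixture on the probit scale:
   f(z) = pi0 * phi(z) + (1 - pi0) * f1(z), z = Phi^{-1}(p), phi the
   standard normal null, f1 a weighted Gaussian-kernel density refit at
   each EM step);
3. random-forest ranking of the screened probes by Breiman's
   out-of-bag permutation importance, keeping the top ``n_keep``.

All stochastic steps are fully determined by an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .io import DataError, ExpressionMatrix, ProbeAnnotation

__all__ = [
    "SignatureResult",
    "welch_t",
    "welch_t_matrix",
    "local_fdr",
    "forest_select",
    "derive_signature",
]


@dataclass
class SignatureResult:
    """Outcome of a two-group signature derivation."""

    contrast: str
    screen_size: int
    selected_probes: list[str]
    table: pd.DataFrame  # per-probe: t, df, p, local_fdr, direction, importance, selected
    genes_up: list[str] = field(default_factory=list)
    genes_down: list[str] = field(default_factory=list)
    screen_genes_up: list[str] = field(default_factory=list)
    screen_genes_down: list[str] = field(default_factory=list)
    pi0: float = float("nan")
    lfdr_at_threshold: float = float("nan")
    lfdr_report: float = float("nan")


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p). t is positive when
    mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("Welch t-test needs >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t between two probes x samples blocks."""
    na, nb = A.shape[1], B.shape[1]
    if na < 2 or nb < 2:
        raise DataError("Welch t-test needs >= 2 observations per group")
    va = A.var(ddof=1, axis=1)
    vb = B.var(ddof=1, axis=1)
    se2 = va / na + vb / nb
    diff = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)),
            float(na + nb - 2),
        )
    p = np.where(se2 > 0, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, df, p


def _silverman_bandwidth(z: np.ndarray) -> float:
    n = z.size
    sd = z.std(ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-0.2)


def local_fdr(
    p_values: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-5,
    n_grid: int = 1024,
) -> tuple[np.ndarray, float]:
    """Local false-discovery rate from a probit-scale kernel mixture.

    p-values are mapped to z = Phi^{-1}(p) so that null p-values are
    standard normal. The marginal density f is modeled as
    pi0 * phi + (1 - pi0) * f1 with f1 a Gaussian-kernel density whose
    case weights are re-estimated by EM. Returns (lfdr per input, pi0).
    Degenerate inputs (no spread in p) yield lfdr = 1 everywhere, pi0 = 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 200:
        raise DataError(f"local FDR needs >= 200 p-values, got {p.size}")
    eps = np.finfo(float).eps
    n_out = int(np.sum((p <= 0) | (p >= 1)))
    if n_out:
        warnings.warn(f"{n_out} p-values outside (0,1) clamped to machine bounds")
    p = np.clip(p, eps, 1 - eps)
    z = stats.norm.ppf(p)

    if z.std(ddof=1) < 1e-8:
        warnings.warn("degenerate p-value distribution; returning lfdr = 1")
        return np.ones_like(p), 1.0

    h = _silverman_bandwidth(z)
    lo, hi = z.min() - 4 * h, z.max() + 4 * h
    grid = np.linspace(lo, hi, n_grid)
    step = grid[1] - grid[0]
    # deposit each observation's weight in its nearest grid cell
    cell = np.clip(np.round((z - lo) / step).astype(int), 0, n_grid - 1)
    kernel_halfwidth = int(np.ceil(4 * h / step))
    kx = np.arange(-kernel_halfwidth, kernel_halfwidth + 1) * step
    kernel = stats.norm.pdf(kx, scale=h)
    phi_z = stats.norm.pdf(z)

    # Storey-type initial null proportion at lambda = 0.5
    pi0 = min(1.0, float(np.mean(p > 0.5) / 0.5))
    pi0 = max(pi0, 0.05)
    tau = np.full(p.size, pi0)
    f1_z = phi_z.copy()

    for _ in range(max_iter):
        f_z = pi0 * phi_z + (1 - pi0) * f1_z
        tau = np.clip(pi0 * phi_z / np.maximum(f_z, 1e-300), 0.0, 1.0)
        new_pi0 = float(np.mean(tau))
        w = 1.0 - tau
        wsum = w.sum()
        if wsum > 1e-8:
            hist = np.bincount(cell, weights=w, minlength=n_grid)
            dens = np.convolve(hist, kernel, mode="same") / wsum
            f1_grid = np.maximum(dens, 0.0)
            area = np.trapezoid(f1_grid, grid)
            if area > 0:
                f1_grid = f1_grid / area
            f1_z = np.interp(z, grid, f1_grid)
        else:
            f1_z = phi_z.copy()
        if abs(new_pi0 - pi0) < tol:
            pi0 = new_pi0
            break
        pi0 = new_pi0

    f_z = pi0 * phi_z + (1 - pi0) * f1_z
    lfdr = np.clip(pi0 * phi_z / np.maximum(f_z, 1e-300), 0.0, 1.0)
    return lfdr, float(pi0)


def _oob_permutation_importance(
    model: BaggingClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breiman out-of-bag permutation importance, averaged over trees.

    For each tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature at a time; only features the tree
    actually splits on are perturbed (others contribute zero). Per-tree
    feature subsets (bagging ``max_features``) are mapped back to the full
    feature space.
    """
    n, p = X.shape
    imp = np.zeros(p)
    all_idx = np.arange(n)
    for tree, samples, feats in zip(
        model.estimators_, model.estimators_samples_, model.estimators_features_
    ):
        oob = np.setdiff1d(all_idx, samples)
        if oob.size == 0:
            continue
        X_oob = X[np.ix_(oob, feats)]
        y_oob = y[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for f in used:
            Xp = X_oob.copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            acc = np.mean(tree.predict(Xp) == y_oob)
            imp[feats[f]] += base - acc
    return imp / len(model.estimators_)


def forest_select(
    X: ExpressionMatrix,
    labels: dict[str, str] | pd.Series,
    candidates: list[str],
    n_keep: int = 200,
    n_trees: int = 2000,
    seed: int | None = None,
    feature_fraction: float = 0.1,
) -> pd.DataFrame:
    """Rank candidate probes by out-of-bag permutation importance of a
    random forest and return the top ``n_keep``.

    The forest is a bagged ensemble of decision trees with sqrt(p)
    features per split; in addition each tree is grown on a random
    ``feature_fraction`` subset of the candidates, which spreads split
    usage across correlated strong features and stabilizes the
    out-of-bag importance ranking when trees would otherwise stay very
    shallow. Ties in importance break by probe id. Returns a DataFrame
    (index probe_id) with columns importance and rank.
    """
    if seed is None:
        raise DataError("forest_select requires an explicit seed")
    labels = pd.Series(labels)
    missing = [c for c in candidates if c not in set(X.probe_ids)]
    if missing:
        raise DataError(f"candidates absent from matrix: {missing[:5]}")
    if n_keep > len(candidates):
        warnings.warn(
            f"n_keep={n_keep} exceeds candidate count {len(candidates)}; returning all"
        )
        n_keep = len(candidates)
    Xs = X.subset_probes(candidates)
    y = labels.reindex(Xs.sample_ids).to_numpy()
    if pd.isna(y).any():
        raise DataError("labels missing for some samples")
    levels, y_enc = np.unique(y, return_inverse=True)
    if len(levels) != 2:
        raise DataError("forest_select needs exactly two label groups")
    M = Xs.values.T  # samples x probes

    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt", random_state=0),
        n_estimators=n_trees,
        bootstrap=True,
        max_features=max(feature_fraction, 2.0 / max(len(candidates), 1)),
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(M, y_enc)
    rng = np.random.default_rng(seed)
    imp = _oob_permutation_importance(model, M, y_enc, rng)
    table = pd.DataFrame(
        {"probe_id": candidates, "importance": imp}
    ).sort_values(
        by=["importance", "probe_id"], ascending=[False, True], kind="mergesort"
    ).set_index("probe_id")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.head(n_keep)


def derive_signature(
    X: ExpressionMatrix,
    groups: dict[str, str] | pd.Series,
    ann: ProbeAnnotation | None = None,
    p_thresh: float = 0.01,
    lfdr_report: float = 0.2,
    n_keep: int = 200,
    n_trees: int = 2000,
    seed: int | None = None,
    contrast: str = "A_vs_B",
) -> SignatureResult:
    """Full screen-then-select signature derivation for a two-group contrast.

    ``groups`` maps sample_id to one of exactly two group labels; group A
    (the alphabetically first label) is the reference for direction:
    direction='up' means higher in group A.
    """
    groups = pd.Series(groups)
    y = groups.reindex(X.sample_ids)
    if y.isna().any():
        raise DataError("group labels missing for some samples")
    levels = sorted(y.unique())
    if len(levels) != 2:
        raise DataError(f"groups must partition samples into 2 groups, got {levels}")
    a_mask = (y == levels[0]).to_numpy()
    na, nb = int(a_mask.sum()), int((~a_mask).sum())
    if min(na, nb) < 4:
        warnings.warn(
            f"small group sizes ({na} vs {nb}); Welch df may drop below 2 and "
            "p-values are unstable"
        )
    A = X.values[:, a_mask]
    B = X.values[:, ~a_mask]
    t, df, p = welch_t_matrix(A, B)
    try:
        lfdr, pi0 = local_fdr(p)
    except DataError:
        lfdr = np.full(p.shape, np.nan)
        pi0 = float("nan")

    screen_mask = p < p_thresh
    screen = [pid for pid, m in zip(X.probe_ids, screen_mask) if m]
    if not screen:
        raise DataError(f"no probes pass the p < {p_thresh} screen")
    # achieved local fdr at the screen boundary: largest lfdr among screened probes
    boundary = np.nanmax(lfdr[screen_mask]) if np.isfinite(lfdr).any() else float("nan")

    ranked = forest_select(X, y, screen, n_keep=n_keep, n_trees=n_trees, seed=seed)
    selected = list(ranked.index)

    table = pd.DataFrame(
        {
            "t_statistic": t,
            "welch_df": df,
            "p_value": p,
            "local_fdr": lfdr,
            "direction": np.where(t >= 0, "up", "down"),
            "importance": np.nan,
            "selected": False,
        },
        index=pd.Index(X.probe_ids, name="probe_id"),
    )
    table.loc[ranked.index, "importance"] = ranked["importance"]
    table.loc[selected, "selected"] = True

    def gene_lists(probes: list[str]) -> tuple[list[str], list[str]]:
        if ann is None:
            return [], []
        up = [pid for pid in probes if table.at[pid, "direction"] == "up"]
        down = [pid for pid in probes if table.at[pid, "direction"] == "down"]
        return ann.genes_for(up), ann.genes_for(down)

    genes_up, genes_down = gene_lists(selected)
    screen_up, screen_down = gene_lists(screen)

    return SignatureResult(
        contrast=contrast,
        screen_size=len(screen),
        selected_probes=selected,
        table=table,
        genes_up=genes_up,
        genes_down=genes_down,
        screen_genes_up=screen_up,
        screen_genes_down=screen_down,
        pi0=pi0,
        lfdr_at_threshold=float(boundary),
        lfdr_report=lfdr_report,
    )
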