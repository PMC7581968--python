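"""Imaging transcriptomics: PLS regression of regional gene expression
against a regional WM-loss map, with spatially constrained significance.

The predictor block is a regions x genes expression matrix (left-hemisphere
cortical regions); the response is the per-region WM-loss score for one
connection type. Partial least squares finds latent components maximising
the covariance between expression and loss; the component explaining the
most response variance is carried forward. Its significance is assessed
against a spin-permutation null — the loss map is rotated on the spherical
projection of the cortex, preserving spatial autocorrelation while breaking
alignment with expression — and per-gene weight variability is estimated by
bootstrap resampling of regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .group_stats import bh_fdr

__all__ = [
    "PLSFit",
    "SpinSet",
    "SpinNull",
    "standardize_expression",
    "pls_fit",
    "make_spins",
    "spin_null",
    "spin_pvalue",
    "bootstrap_weights",
    "rank_genes",
    "top_fraction",
    "roi_weights",
    "moran_i",
]


def standardize_expression(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across regions, dropping zero-variance genes."""
    X = X.astype(float)
    if X.isna().any().any():
        raise ValueError("expression matrix contains NaN")
    sd = X.std(axis=0, ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance genes")
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    return (X - X.mean(axis=0)) / sd


@dataclass
class PLSFit:
    """Fitted PLS regression of y (loss map) on X (expression).

    ``weights`` are the unit-norm gene weight vectors (genes x components),
    ``scores`` the region scores, ``r2`` the incremental proportion of
    response variance explained per component, ``component`` the index of
    the component with the largest r2. Each component is oriented so its
    region scores correlate positively with y.
    """

    weights: np.ndarray
    scores: np.ndarray
    rotations: np.ndarray
    r2: np.ndarray
    component: int
    genes: pd.Index
    regions: pd.Index

    @property
    def chosen_weights(self) -> pd.Series:
        return pd.Series(self.weights[:, self.component], index=self.genes,
                         name="pls_weight")

    @property
    def chosen_r2(self) -> float:
        return float(self.r2[self.component])


def _fit_pls_arrays(Xs: np.ndarray, y: np.ndarray, n_components: int):
    """Core fit on pre-standardised arrays; returns oriented arrays."""
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y.reshape(-1, 1))
    T = pls.x_scores_                     # regions x K, orthogonal columns
    W = pls.x_weights_                    # genes x K, unit norm
    R = pls.x_rotations_
    c = pls.y_loadings_.ravel()           # K
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    r2 = (c**2) * (T**2).sum(axis=0) / ss_y
    # orient every component so region scores correlate positively with y
    sign = np.sign(T.T @ yc)
    sign[sign == 0] = 1.0
    return W * sign, T * sign, R * sign, r2


def pls_fit(X: pd.DataFrame, y: pd.Series, n_components: int = 5) -> PLSFit:
    """PLS regression of the loss map on standardised expression.

    ``X`` rows must align with ``y``'s regions; genes are z-scored across
    regions internally. The chosen component is the one explaining the most
    response variance.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 regions for PLS")
    if not X.index.equals(y.index):
        X = X.loc[y.index]
    n_components = min(n_components, len(X) - 1, X.shape[1])
    Xs = standardize_expression(X)
    W, T, R, r2 = _fit_pls_arrays(Xs.to_numpy(), y.to_numpy(float), n_components)
    return PLSFit(weights=W, scores=T, rotations=R, r2=r2,
                  component=int(np.argmax(r2)), genes=Xs.columns, regions=X.index)


# ---------------------------------------------------------------------------
# Spin permutations
# ---------------------------------------------------------------------------


@dataclass
class SpinSet:
    """Spherical-rotation permutations of a set of cortical regions."""

    rotations: np.ndarray   # n_perm x 3 x 3
    mappings: np.ndarray    # n_perm x n_regions, each row a permutation

    @property
    def n_perm(self) -> int:
        return self.mappings.shape[0]

    def apply(self, values: np.ndarray, i: int) -> np.ndarray:
        return np.asarray(values)[self.mappings[i]]


def _greedy_assign(cost: np.ndarray) -> np.ndarray:
    """One-to-one assignment, greedily taking globally smallest costs."""
    n = cost.shape[0]
    mapping = np.full(n, -1)
    row_free = np.ones(n, bool)
    col_free = np.ones(n, bool)
    order = np.argsort(cost, axis=None)
    remaining = n
    for flat in order:
        i, j = divmod(int(flat), n)
        if row_free[i] and col_free[j]:
            mapping[i] = j
            row_free[i] = col_free[j] = False
            remaining -= 1
            if remaining == 0:
                break
    return mapping


def make_spins(centroids, n_perm: int, seed: int | None = None) -> SpinSet:
    """Generate spin permutations from uniformly random sphere rotations.

    Each permutation rotates the unit-sphere centroids by a random rotation
    and matches every region to a rotated centroid by greedy one-to-one
    nearest-neighbour assignment, so the spun map is a permutation of the
    original values. The identity rotation yields the identity mapping.
    """
    xyz = np.asarray(centroids, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("centroids must be n x 3")
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() == 0:
        raise ValueError("duplicate centroids")
    rng = np.random.default_rng(seed)
    rots = stats.special_ortho_group.rvs(3, size=n_perm, random_state=rng)
    rots = rots.reshape(n_perm, 3, 3)
    mappings = np.empty((n_perm, len(xyz)), dtype=int)
    for k in range(n_perm):
        rotated = xyz @ rots[k].T
        cost = -(xyz @ rotated.T)  # monotone in geodesic distance
        mappings[k] = _greedy_assign(cost)
    return SpinSet(rotations=rots, mappings=mappings)


@dataclass
class SpinNull:
    """Null distribution from refitting PLS on spun loss maps."""

    r2: np.ndarray        # n_perm: max response variance explained per spin
    weights: np.ndarray   # n_perm x genes: chosen-component weights per spin


def spin_null(X: pd.DataFrame, y: pd.Series, spins: SpinSet,
              n_components: int = 5) -> SpinNull:
    """Refit the PLS on every spun loss map.

    For each spin the component-selection rule (max response variance) and
    sign convention are applied exactly as for the observed fit, keeping the
    null statistics exchangeable with the observed ones.
    """
    n_components = min(n_components, len(X) - 1, X.shape[1])
    Xs = standardize_expression(X).to_numpy()
    yv = y.to_numpy(float)
    r2_null = np.empty(spins.n_perm)
    w_null = np.empty((spins.n_perm, Xs.shape[1]))
    for k in range(spins.n_perm):
        ys = yv[spins.mappings[k]]
        W, _, _, r2 = _fit_pls_arrays(Xs, ys, n_components)
        j = int(np.argmax(r2))
        r2_null[k] = r2[j]
        w_null[k] = W[:, j]
    return SpinNull(r2=r2_null, weights=w_null)


def spin_pvalue(fit: PLSFit, null: SpinNull) -> float:
    """Permutation p for the chosen component's variance explained."""
    obs = fit.chosen_r2
    return float((1 + np.sum(null.r2 >= obs)) / (1 + len(null.r2)))


# ---------------------------------------------------------------------------
# Bootstrap gene-weight variability
# ---------------------------------------------------------------------------


def bootstrap_weights(X: pd.DataFrame, y: pd.Series, fit: PLSFit,
                      n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Bootstrap SE and z for each gene's chosen-component weight.

    Regions are resampled with replacement and the PLS refit; the bootstrap
    component at the chosen index is aligned to the original by the sign of
    the correlation between its score vector (evaluated on the full region
    set) and the original scores, removing the reflection ambiguity.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    Xs = standardize_expression(X.loc[fit.regions])[fit.genes].to_numpy()
    yv = y.loc[fit.regions].to_numpy(float)
    n = len(yv)
    k = fit.component
    t0 = fit.scores[:, k]
    boots = np.empty((n_boot, Xs.shape[1]))
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            yb = yv[idx]
            if yb.std() == 0:
                continue
            try:
                W, _, R, _ = _fit_pls_arrays(Xs[idx], yb, fit.weights.shape[1])
            except Exception:
                continue
            t_full = (Xs - Xs.mean(axis=0)) @ R[:, k]
            if np.allclose(t_full.std(), 0):
                continue
            sign = np.sign(np.corrcoef(t_full, t0)[0, 1]) or 1.0
            boots[b] = W[:, k] * sign
            break
        else:
            raise RuntimeError("degenerate bootstrap resamples (10 retries)")
    se = boots.std(axis=0, ddof=1)
    w = fit.weights[:, k]
    out = pd.DataFrame({"weight": w, "se": se, "z": w / se}, index=fit.genes)
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# Gene ranking
# ---------------------------------------------------------------------------


def rank_genes(fit: PLSFit, boot: pd.DataFrame, null: SpinNull,
               alpha: float = 0.05) -> pd.DataFrame:
    """Spin-null significance, FDR, and directional ranking of gene weights.

    Each gene's two-sided empirical p compares |weight| with its own
    spin-null weight distribution; BH-FDR is applied across genes. Survivors
    are split by sign — downweighted (negative: lower expression where
    connectivity loss is greater) and upweighted (positive) — and ranked by
    |weight| within direction.
    """
    w = fit.weights[:, fit.component]
    n_perm = null.weights.shape[0]
    p = (1 + np.sum(np.abs(null.weights) >= np.abs(w)[None, :], axis=0)) / (1 + n_perm)
    q = bh_fdr(p)
    out = boot.copy()
    out["p"] = p
    out["q"] = q
    out["direction"] = np.where(w < 0, "downweighted", "upweighted")
    out["survives_fdr"] = q < alpha
    out["rank"] = np.nan
    for direction in ("downweighted", "upweighted"):
        m = out["survives_fdr"] & (out["direction"] == direction)
        order = out.loc[m, "weight"].abs().sort_values(ascending=False)
        out.loc[order.index, "rank"] = np.arange(1, m.sum() + 1)
    return out


def top_fraction(ranking: pd.DataFrame, direction: str,
                 fraction: float = 0.2) -> list[str]:
    """Top-``fraction`` most extreme FDR-surviving genes of one direction.

    With 790 survivors and fraction 0.2 this returns floor(0.2 * 790) = 158
    genes, the gene-list size convention used for enrichment.
    """
    sub = ranking[(ranking["direction"] == direction) & ranking["survives_fdr"]]
    n = int(np.floor(fraction * len(sub)))
    return sub.sort_values("rank").index[:n].tolist()


def roi_weights(fit: PLSFit, names: pd.Series | None = None) -> pd.Series:
    """Region scores of the chosen component, for map reporting."""
    s = pd.Series(fit.scores[:, fit.component], index=fit.regions,
                  name="roi_weight")
    if names is not None:
        s.index = names.loc[fit.regions]
    return s


def moran_i(values: np.ndarray, centroids: np.ndarray) -> float:
    """Moran's I spatial autocorrelation with inverse-geodesic weights."""
    x = np.asarray(values, float)
    xyz = np.asarray(centroids, float)
    ang = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    with np.errstate(divide="ignore"):
        w = 1.0 / ang
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    num = z @ w @ z
    return float(len(x) / w.sum() * num / (z @ z))
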