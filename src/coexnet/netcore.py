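"""Robust correlation, soft-thresholded adjacency, connectivity and TOM.

The network core follows the standard weighted co-expression recipe:
biweight midcorrelation between all gene pairs, |r|^beta (unsigned) or
((1+r)/2)^beta (signed) adjacency, per-gene connectivity k_i = sum_j
a_ij, a scale-free topology fit index used to choose beta, and the
topological overlap matrix whose complement is the clustering
dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coexnet.types import ExpressionMatrix

#: Observations further than this many (raw) MADs from the median get
#: zero weight in the biweight midcorrelation.
BICOR_MAD_CONST = 9.0


def _bicor_weights(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Tukey biweights for one vector; returns (weights, used_fallback).

    u_i = (x_i - med) / (9 * MAD) with the raw (unscaled) MAD;
    w_i = (1 - u_i^2)^2 for |u_i| < 1, else 0. When MAD = 0 the weights
    are undefined and the vector falls back to uniform weights, i.e.
    median-centered Pearson.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.ones_like(x), True
    u = (x - med) / (BICOR_MAD_CONST * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return w, False


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors.

    Robust alternative to Pearson correlation: observations are centered
    on the median and down-weighted by Tukey biweights so single
    outliers cannot dominate. Falls back to median-centered Pearson for
    a vector whose MAD is zero. Raises for vectors shorter than 3 or
    when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation of a constant vector is undefined")
    wx, _ = _bicor_weights(x)
    wy, _ = _bicor_weights(y)
    xt = (x - np.median(x)) * wx
    yt = (y - np.median(y)) * wy
    return float(xt @ yt / (np.linalg.norm(xt) * np.linalg.norm(yt)))


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene biweight midcorrelations in [-1, 1]."""

    r: pd.DataFrame
    fallback_genes: list[str]  # genes scored with median-centered Pearson

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.index)


def correlation_matrix(em: ExpressionMatrix) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation of the expression rows.

    Vectorized: each gene row is median-centered, biweight-weighted and
    unit-normalized, after which the correlation matrix is a single
    matrix product. Genes with zero MAD (recorded in
    ``fallback_genes``) use uniform weights, i.e. median-centered
    Pearson for every pair they participate in.
    """
    X = em.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    const = np.ptp(X, axis=1) == 0
    if const.any():
        bad = [g for g, c in zip(em.gene_ids, const) if c][:10]
        raise ValueError(f"constant gene rows (filter them first): {bad}")

    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    fallback = mad[:, 0] == 0
    safe_mad = np.where(mad > 0, mad, 1.0)
    u = dev / (BICOR_MAD_CONST * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    w[fallback] = 1.0
    Xt = dev * w
    Xt /= np.linalg.norm(Xt, axis=1, keepdims=True)
    r = Xt @ Xt.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=em.gene_ids, columns=em.gene_ids),
        fallback_genes=[g for g, f in zip(em.gene_ids, fallback) if f],
    )


@dataclass
class AdjacencyMatrix:
    """Soft-thresholded adjacency a_ij in [0, 1] with its beta and mode."""

    a: pd.DataFrame
    beta: int
    mode: str  # "unsigned" | "signed"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.a.index)


def adjacency(r: CorrelationMatrix, beta: int = 12, mode: str = "unsigned") -> AdjacencyMatrix:
    """Raise correlations to the soft-thresholding power beta.

    unsigned: a_ij = |r_ij|^beta (anticorrelated genes remain adjacent);
    signed:   a_ij = ((1 + r_ij)/2)^beta.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if mode == "unsigned":
        a = np.abs(r.r.to_numpy()) ** beta
    elif mode == "signed":
        a = ((1.0 + r.r.to_numpy()) / 2.0) ** beta
    else:
        raise ValueError(f"mode must be 'unsigned' or 'signed', got {mode!r}")
    return AdjacencyMatrix(
        a=pd.DataFrame(a, index=r.r.index, columns=r.r.columns),
        beta=int(beta),
        mode=mode,
    )


def connectivity(a: AdjacencyMatrix) -> pd.Series:
    """Per-gene connectivity k_i = sum of adjacency to all other genes."""
    arr = a.a.to_numpy()
    k = arr.sum(axis=1) - np.diag(arr)
    return pd.Series(k, index=a.gene_ids, name="connectivity")


def scale_free_fit(k, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit index of a connectivity distribution.

    Bins k into ``n_bins`` equal-width intervals, then regresses
    log10(bin frequency) on log10(bin mean k) over bins with positive
    frequency and positive mean. Returns (R^2, slope): R^2 is the
    squared Pearson correlation of the regression (reported unsigned),
    and a negative slope indicates the high-connectivity tail decays as
    in a power law.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal; binning is degenerate")
    if k.size < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} genes for {n_bins} bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs = np.bincount(idx, minlength=n_bins) / k.size
    means = np.array(
        [k[idx == b].mean() if (idx == b).any() else 0.0 for b in range(n_bins)]
    )
    ok = (freqs > 0) & (means > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable bins")
    logk = np.log10(means[ok])
    logp = np.log10(freqs[ok])
    fit = stats.linregress(logk, logp)
    return float(fit.rvalue**2), float(fit.slope)


@dataclass
class ScaleFreeFit:
    """Scale-free fit across a beta grid plus the chosen beta."""

    table: pd.DataFrame  # beta, r_squared, slope, mean_k
    chosen_beta: int
    reached_target: bool


def pick_soft_threshold(
    r: CorrelationMatrix,
    beta_grid=range(1, 21),
    target_r2: float = 0.9,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> ScaleFreeFit:
    """Choose the soft threshold from a scale-free topology criterion.

    The chosen beta is the smallest grid value whose fit reaches
    ``target_r2`` with a negative slope; if none qualifies the beta with
    maximal R^2 (negative slope preferred) is returned with a warning
    flag (``reached_target=False``).
    """
    betas = list(beta_grid)
    if not betas:
        raise ValueError("empty beta grid")
    rows = []
    for b in betas:
        a = adjacency(r, beta=b, mode=mode)
        k = connectivity(a).to_numpy()
        try:
            r2, slope = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2, slope = float("nan"), float("nan")
        rows.append(
            {"beta": b, "r_squared": r2, "slope": slope, "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    qualifying = table[(table.r_squared >= target_r2) & (table.slope < 0)]
    if len(qualifying):
        chosen = int(qualifying.beta.iloc[0])
        reached = True
    else:
        neg = table[table.slope < 0]
        pool = neg if len(neg) else table
        chosen = int(pool.loc[pool.r_squared.idxmax(), "beta"])
        reached = False
    return ScaleFreeFit(table=table, chosen_beta=chosen, reached_target=reached)


@dataclass
class TOMMatrix:
    """Topological overlap similarity and its dissimilarity complement."""

    tom: pd.DataFrame

    @property
    def diss(self) -> pd.DataFrame:
        return 1.0 - self.tom

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tom.index)


def tom(a: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap matrix of a weighted adjacency.

    tom_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where L_ij is
    the shared-neighbor weight sum over u != i, j of a_iu * a_uj. Two
    genes overlap strongly when they are adjacent *and* share
    neighbors. Diagonal is 1 by convention; diss = 1 - tom.
    """
    arr = a.a.to_numpy().copy()
    np.fill_diagonal(arr, 0.0)
    k = arr.sum(axis=1)
    L = arr @ arr  # zero diagonal makes this exclude u in {i, j}
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (L + arr) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.clip(t, 0.0, 1.0, out=t)
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 1.0)
    return TOMMatrix(tom=pd.DataFrame(t, index=a.gene_ids, columns=a.gene_ids))
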