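"""Topographic similarity metrics: spatial correlation, GFP, GEV.

A *topography* is the vector of voltages across all electrodes at one
time-point.  Spatial correlation (Pearson across channels) measures map
shape similarity independent of overall strength; global field power (GFP)
is the across-channel standard deviation (map strength); global explained
variance (GEV) is the GFP-weighted squared spatial correlation between each
map and its cluster template, normalized by total squared GFP.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spatial_correlation", "gfp", "gev", "correlation_matrix"]


class UndefinedCorrelationError(ValueError):
    """A map with zero across-channel variance has no spatial correlation."""


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two topographies across channels."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("need two equal-length 1-D maps with >= 2 channels")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise UndefinedCorrelationError("zero-variance topography")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def _standardize_rows(X: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Center each row and scale to unit norm; zero-variance rows become 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    safe = np.where(norms > eps, norms, 1.0)
    out = Xc / safe
    out[norms[:, 0] <= eps] = 0.0
    return out


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise spatial correlations between rows; zero-variance rows → 0."""
    Z = _standardize_rows(np.asarray(X, dtype=float))
    return np.clip(Z @ Z.T, -1.0, 1.0)


def row_template_correlation(X: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """(n, k) spatial correlations of each row with each template row."""
    Z = _standardize_rows(np.asarray(X, dtype=float))
    T = _standardize_rows(np.asarray(templates, dtype=float))
    return np.clip(Z @ T.T, -1.0, 1.0)


def gfp(topography: np.ndarray) -> float:
    """Global field power: population standard deviation across channels."""
    t = np.asarray(topography, dtype=float)
    return float(np.std(t))


def gev(
    X: np.ndarray,
    labels: np.ndarray,
    templates: np.ndarray,
    polarity_invariant: bool = False,
) -> float:
    """Global explained variance of a labeling with per-cluster templates.

    ``Σ_t (gfp(x_t) · corr(x_t, template_{label_t}))² / Σ_t gfp(x_t)²``.
    ``labels`` are 1-based cluster ids indexing ``templates`` (k, f).  The
    squared correlation makes the value insensitive to template polarity, so
    the same formula serves the polarity-invariant variant.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    gfps = np.std(X, axis=1)
    denom = float(np.sum(gfps**2))
    if denom == 0:
        raise ValueError("all-zero data: GEV undefined")
    corr = row_template_correlation(X, templates)  # (n, k)
    c = corr[np.arange(X.shape[0]), labels - 1]
    return float(np.sum((gfps * c) ** 2) / denom)
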