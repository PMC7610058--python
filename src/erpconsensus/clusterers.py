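"""Base clustering methods for topography time series.

Rows of ``X`` are time-points, columns are channels; every method returns a
hard :class:`Partition` with canonical 1..k labels (first-occurrence order),
so partitions from different methods compare cleanly.

Correlation-based methods (``hierarchical_corr``, ``modified_kmeans``,
``aahc``) operate on average-referenced rows, matching microstate
convention; Euclidean methods (``kmeans``, ``fcm``, ``som``,
``diffusion_spectral``) see the raw rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .metrics import correlation_matrix, gev, row_template_correlation

logger = logging.getLogger(__name__)

METHOD_NAMES = (
    "kmeans",
    "hierarchical_corr",
    "fcm",
    "som",
    "diffusion_spectral",
    "modified_kmeans",
    "aahc",
)

#: Methods whose output depends on the seed; the rest are deterministic.
STOCHASTIC_METHODS = frozenset({"kmeans", "fcm", "som", "diffusion_spectral", "modified_kmeans"})


@dataclass(frozen=True)
class Partition:
    """Hard assignment of each time-point to one of ``k`` clusters."""

    labels: np.ndarray  # (n,) ints in 1..k
    k: int
    method: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        present = np.unique(labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError(f"labels outside 1..{self.k}")
        if present.size < self.k:
            logger.debug(
                "%s partition is degenerate: %d of %d clusters occupied",
                self.method or "unnamed",
                present.size,
                self.k,
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_occupied(self) -> int:
        return int(np.unique(self.labels).size)

    def relabeled(self) -> "Partition":
        return Partition(
            labels=canonical_labels(self.labels), k=self.k, method=self.method, seed=self.seed
        )


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first occurrence."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass(frozen=True)
class MethodParams:
    """Configuration of one base method; knobs unused by a method are ignored."""

    method: str
    restarts: int = 5
    max_iter: int = 100
    tolerance: float = 1e-6
    fuzziness: float = 2.0  # FCM exponent m
    polarity_invariant: bool = False  # modified k-means template update
    som_epochs: int = 30
    diffusion_time: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHOD_NAMES}")
        if min(self.restarts, self.max_iter) < 1 or self.tolerance <= 0:
            raise ValueError("restarts, max_iter must be >= 1 and tolerance > 0")
        if self.fuzziness <= 1:
            raise ValueError("FCM fuzziness must be > 1")

    @property
    def is_stochastic(self) -> bool:
        return self.method in STOCHASTIC_METHODS


def _avg_reference(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _check_inputs(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (time-points x channels)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={X.shape[0]}")
    return X


def run_base(method: MethodParams | str, X: np.ndarray, k: int, seed: int = 0) -> Partition:
    """Dispatch to one base clustering method by name; canonical output."""
    params = MethodParams(method=method) if isinstance(method, str) else method
    X = _check_inputs(X, k)
    fn = {
        "kmeans": _euclidean_kmeans,
        "hierarchical_corr": _hierarchical_corr,
        "fcm": _fcm,
        "som": _som,
        "diffusion_spectral": _diffusion_spectral,
        "modified_kmeans": _modified_kmeans_impl,
        "aahc": lambda X, k, seed, p: aahc(X, k),
    }[params.method]
    labels = fn(X, k, seed, params)
    if isinstance(labels, Partition):
        labels = labels.labels
    return Partition(labels=canonical_labels(labels), k=k, method=params.method, seed=seed)


# ---------------------------------------------------------------- k-means


def _euclidean_kmeans(X, k, seed, params: MethodParams):
    km = KMeans(
        n_clusters=k,
        n_init=params.restarts,
        max_iter=params.max_iter,
        tol=params.tolerance,
        random_state=seed,
    )
    return km.fit_predict(X) + 1


# ---------------------------------------------------- hierarchical (1 - r)


def _corr_linkage(X: np.ndarray):
    D = 1.0 - correlation_matrix(X)
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method="average")


def _hierarchical_corr(X, k, seed, params: MethodParams):
    Z = _corr_linkage(_avg_reference(X))
    return fcluster(Z, t=k, criterion="maxclust")


# -------------------------------------------------------------------- FCM


def _fcm(X, k, seed, params: MethodParams):
    """Fuzzy c-means, defuzzified by maximal membership; best of restarts."""
    rng = np.random.default_rng(seed)
    m = params.fuzziness
    best_obj, best_labels = np.inf, None
    for _ in range(params.restarts):
        U = rng.dirichlet(np.ones(k), size=X.shape[0])  # (n, k)
        obj = np.inf
        for _ in range(params.max_iter):
            Um = U**m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = (
                np.sum(X**2, axis=1)[:, None]
                - 2 * X @ centers.T
                + np.sum(centers**2, axis=1)[None, :]
            )
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))
            U_new = inv / inv.sum(axis=1, keepdims=True)
            obj = float(np.sum((U_new**m) * d2))
            if np.max(np.abs(U_new - U)) < params.tolerance:
                U = U_new
                break
            U = U_new
        if obj < best_obj:
            best_obj, best_labels = obj, np.argmax(U, axis=1) + 1
    return best_labels


# -------------------------------------------------------------------- SOM


def _som(X, k, seed, params: MethodParams):
    """Batch self-organizing map on a 1 x k grid; each unit is one cluster."""
    rng = np.random.default_rng(seed)
    # initialize units along the first principal axis for a stable 1-D ordering
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    proj = np.linspace(np.min(Xc @ vt[0]), np.max(Xc @ vt[0]), k)
    units = X.mean(axis=0) + proj[:, None] * vt[0][None, :]
    units = units + 1e-6 * rng.standard_normal(units.shape)
    grid = np.arange(k, dtype=float)
    sigma0, sigma_end = max(k / 2.0, 1.0), 0.25
    epochs = params.som_epochs
    for epoch in range(epochs):
        sigma = sigma0 * (sigma_end / sigma0) ** (epoch / max(epochs - 1, 1))
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2 * X @ units.T
            + np.sum(units**2, axis=1)[None, :]
        )
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2) / (2 * sigma**2))  # (k, n)
        mass = H.sum(axis=1)
        updated = mass > 1e-12
        units[updated] = (H @ X)[updated] / mass[updated, None]
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        - 2 * X @ units.T
        + np.sum(units**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1) + 1


# ---------------------------------------------------- diffusion / spectral


def _diffusion_spectral(X, k, seed, params: MethodParams):
    """Diffusion-map embedding + Euclidean k-means in the embedding.

    Gaussian affinity with median-pairwise-distance bandwidth; the top-k
    eigenvectors of the row-normalized diffusion operator (computed via its
    symmetric conjugate), scaled by eigenvalue**diffusion_time.
    """
    d = pdist(X)
    sigma = np.median(d)
    if sigma == 0:
        sigma = 1.0
    W = np.exp(-squareform(d) ** 2 / (2 * sigma**2))
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = W * inv_sqrt[:, None] * inv_sqrt[None, :]
    n = S.shape[0]
    vals, vecs = eigh(S, subset_by_index=[n - k, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = (vecs * inv_sqrt[:, None]) * (vals[None, :] ** params.diffusion_time)
    km = KMeans(n_clusters=k, n_init=params.restarts, random_state=seed)
    return km.fit_predict(psi) + 1


# ------------------------------------------------------- modified k-means


def modified_kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    polarity_invariant: bool = False,
    restarts: int = 5,
    max_iter: int = 100,
) -> Partition:
    """Microstate k-means with correlation assignment and template refit.

    Assignment maximizes the spatial correlation with each template (squared
    correlation when ``polarity_invariant``); templates are refit as cluster
    mean maps, or as the dominant eigenvector of the members' channelwise
    scatter when polarity-invariant.  Best of ``restarts`` by GEV.
    """
    X = _check_inputs(X, k)
    params = MethodParams(
        method="modified_kmeans",
        restarts=restarts,
        max_iter=max_iter,
        polarity_invariant=polarity_invariant,
    )
    labels = _modified_kmeans_impl(X, k, seed, params)
    return Partition(
        labels=canonical_labels(labels), k=k, method="modified_kmeans", seed=seed
    )


def _modified_kmeans_impl(X, k, seed, params: MethodParams):
    Xc = _avg_reference(X)
    n = Xc.shape[0]
    rng = np.random.default_rng(seed)
    best_gev, best_labels = -np.inf, None
    for _ in range(params.restarts):
        idx = rng.choice(n, size=k, replace=False)
        templates = Xc[idx].copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(params.max_iter):
            corr = row_template_correlation(Xc, templates)
            fit = corr**2 if params.polarity_invariant else corr
            new_labels = np.argmax(fit, axis=1) + 1
            # re-seed empty clusters from the worst-fit time-point
            for w in range(1, k + 1):
                if not np.any(new_labels == w):
                    worst = int(np.argmin(np.max(fit, axis=1)))
                    new_labels[worst] = w
                    templates[w - 1] = Xc[worst]
                    logger.debug("re-seeded empty cluster %d from point %d", w, worst)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for w in range(1, k + 1):
                members = Xc[labels == w]
                if members.shape[0] == 0:
                    continue
                if params.polarity_invariant:
                    # dominant eigenvector of the channelwise scatter
                    _, _, vt = np.linalg.svd(members, full_matrices=False)
                    templates[w - 1] = vt[0]
                else:
                    templates[w - 1] = members.mean(axis=0)
        try:
            score = gev(Xc, labels, templates, polarity_invariant=params.polarity_invariant)
        except ValueError:
            score = -np.inf
        if score > best_gev:
            best_gev, best_labels = score, labels
    return best_labels


# ------------------------------------------------------------------- AAHC


def aahc(X: np.ndarray, k: int) -> Partition:
    """Atomize-and-agglomerate hierarchical clustering, cut at ``k``.

    Starts from singleton clusters; repeatedly dissolves the cluster whose
    GEV contribution is least and reassigns each freed time-point to the
    remaining cluster whose mean-map template it correlates with best.
    Deterministic: no randomness anywhere.
    """
    X = _check_inputs(X, k)
    Xc = _avg_reference(X)
    n, f = Xc.shape
    gfps = np.std(Xc, axis=1)

    members: list[list[int]] = [[i] for i in range(n)]
    templates = Xc.copy()  # (n_clusters, f), row per live cluster
    contributions = gfps**2  # singleton: corr with itself is 1 (or 0 if flat)
    contributions = contributions.copy()
    contributions[gfps == 0] = 0.0

    def cluster_stats(idx_list: list[int]) -> tuple[np.ndarray, float]:
        tmpl = Xc[idx_list].mean(axis=0)
        corr = row_template_correlation(Xc[idx_list], tmpl[None, :])[:, 0]
        contrib = float(np.sum((gfps[idx_list] * corr) ** 2))
        return tmpl, contrib

    while len(members) > k:
        victim = int(np.argmin(contributions))
        freed = members.pop(victim)
        templates = np.delete(templates, victim, axis=0)
        contributions = np.delete(contributions, victim)
        corr = row_template_correlation(Xc[freed], templates)  # (m, K)
        targets = np.argmax(corr, axis=1)
        touched = set()
        for point, tgt in zip(freed, targets):
            members[int(tgt)].append(point)
            touched.add(int(tgt))
        for c in touched:
            members[c].sort()
            templates[c], contributions[c] = cluster_stats(members[c])

    labels = np.empty(n, dtype=int)
    for c, idx_list in enumerate(members, start=1):
        labels[idx_list] = c
    return Partition(labels=canonical_labels(labels), k=k, method="aahc", seed=None)
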