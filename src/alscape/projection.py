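"""2D embedding of fingerprint space: metric MDS and Neuroscale.

Both methods minimize a stress between pairwise Tanimoto distances and
Euclidean distances of the 2D image. MDS is non-parametric (SMACOF stress
majorization, whose per-iteration stress is provably non-increasing);
Neuroscale is parametric: a radial-basis-function network maps fingerprints
to the plane via Gaussian activations on Tanimoto distances to a set of
centers, so unseen compounds can be projected without re-embedding. The RBF
count is selected by seven-fold cross-validated held-out stress.

Reported stress is the normalized Kruskal form
``sqrt(Σ_{i<j} (d̂_ij − d_ij)² / Σ_{i<j} d_ij²)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .compound_data import Fingerprint, _pairwise_tc

__all__ = [
    "Embedding2D",
    "NeuroscaleModel",
    "stress",
    "mds_project",
    "neuroscale_fit",
    "neuroscale_transform",
    "canonical_orient",
    "validate_distance_matrix",
    "write_embedding_csv",
]


def validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0) or np.any(d > 1 + 1e-12):
        raise ValueError("Tanimoto distances must lie in [0, 1]")
    return d


@dataclass
class Embedding2D:
    """2D coordinates plus the stress of the embedding they realize."""

    coords: np.ndarray  # (n, 2)
    stress: float
    method: str
    converged: bool = True
    stress_history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.stress < 0:
            raise ValueError("stress must be ≥ 0")


def stress(coords: np.ndarray, d: np.ndarray) -> float:
    """Normalized Kruskal stress between embedded and target distances."""
    d = validate_distance_matrix(d)
    coords = np.asarray(coords, dtype=float)
    n = d.shape[0]
    if coords.shape[0] != n:
        raise ValueError("coordinate count does not match distance matrix size")
    if n < 2:
        raise ValueError("stress needs at least 2 points")
    dhat = pdist(coords)
    dvec = squareform(d, checks=False)
    denom = float(np.sum(dvec**2))
    if denom == 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - dvec) ** 2) / denom))


# ---------------------------------------------------------------------------
# Metric MDS by SMACOF majorization
# ---------------------------------------------------------------------------

def _smacof_single(d, init, max_iter, tol):
    """One SMACOF run; returns (coords, raw-stress history, converged)."""
    n = d.shape[0]
    X = init.copy()
    history = []
    converged = False
    old = None
    for _ in range(max_iter):
        delta = squareform(pdist(X), checks=False)
        raw = 0.5 * float(np.sum((d - delta) ** 2))
        history.append(raw)
        if raw < 1e-14 or (old is not None and old - raw < tol * max(old, 1e-30)):
            converged = True
            break
        old = raw
        # Guttman transform: X ← (1/n) B(X) X
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, d / delta, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    return X, np.array(history), converged


def mds_project(
    d: np.ndarray,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Embedding2D:
    """Metric MDS into the plane by SMACOF-style stress majorization.

    Runs ``n_restarts`` seeded random initializations and keeps the lowest
    final stress. Raw stress is non-increasing within each run (recorded in
    ``stress_history``); non-convergence returns the best configuration with
    ``converged=False``.
    """
    d = validate_distance_matrix(d)
    n = d.shape[0]
    if n < 3:
        raise ValueError("MDS needs at least 3 points")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        init = rng.normal(scale=d.max() or 1.0, size=(n, 2))
        X, history, conv = _smacof_single(d, init, max_iter, tol)
        if best is None or history[-1] < best[1][-1]:
            best = (X, history, conv)
    X, history, converged = best
    if not converged:
        warnings.warn("MDS did not converge within max_iter; returning best configuration")
    return Embedding2D(
        coords=X, stress=stress(X, d), method="MDS",
        converged=converged, stress_history=history,
    )


# ---------------------------------------------------------------------------
# Neuroscale
# ---------------------------------------------------------------------------

@dataclass
class NeuroscaleModel:
    """RBF-network projection: Gaussian units on Tanimoto distance to centers."""

    centers: np.ndarray  # (k, n_bits) bool — center fingerprints
    width: float
    weights: np.ndarray  # (k + 1, 2), last row is the bias
    n_rbf: int
    train_stress: float = float("nan")
    cv_table: dict | None = None

    def __post_init__(self) -> None:
        if self.n_rbf < 1:
            raise ValueError("n_rbf must be ≥ 1")
        if self.width <= 0:
            raise ValueError("width must be > 0")


def _fp_matrix(fps: list[Fingerprint]) -> np.ndarray:
    lengths = {len(fp) for fp in fps}
    if len(lengths) != 1:
        raise ValueError(f"mixed fingerprint lengths {lengths}")
    return np.array([fp.bits for fp in fps])


def _kmedoids(d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50) -> np.ndarray:
    """Plain alternating k-medoids on a precomputed distance matrix."""
    n = d.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new[j] = members[np.argmin(within)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.unique(medoids)


def _activations(fp_mat: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """(n, k+1) design matrix: Gaussian RBF of Tanimoto distance, plus bias."""
    dist = 1.0 - _pairwise_tc(fp_mat, centers)
    phi = np.exp(-(dist**2) / (2.0 * width**2))
    return np.column_stack([phi, np.ones(phi.shape[0])])


def _fit_weights(phi: np.ndarray, d: np.ndarray, seed: int, max_iter: int = 200) -> np.ndarray:
    """Weights minimizing raw stress of the composed map, L-BFGS refined.

    Initialized by least-squares regression of the RBF features onto an MDS
    embedding of the same distances — a good starting point that makes the
    subsequent descent short and deterministic.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # init only; refined below
        target = mds_project(d, seed=seed, n_restarts=2).coords
    W0, *_ = np.linalg.lstsq(phi, target, rcond=None)
    dvec = squareform(d, checks=False)
    n = phi.shape[0]
    iu = np.triu_indices(n, k=1)

    def objective(w_flat):
        W = w_flat.reshape(-1, 2)
        Y = phi @ W
        diff = Y[iu[0]] - Y[iu[1]]
        delta = np.sqrt(np.sum(diff**2, axis=1) + 1e-12)
        resid = delta - dvec
        value = float(np.sum(resid**2))
        # dvalue/dY accumulated pairwise, then chain rule through phi
        coef = (2.0 * resid / delta)[:, None] * diff
        G = np.zeros_like(Y)
        np.add.at(G, iu[0], coef)
        np.add.at(G, iu[1], -coef)
        return value, (phi.T @ G).ravel()

    res = minimize(objective, W0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter})
    return res.x.reshape(-1, 2)


def neuroscale_fit(
    fps: list[Fingerprint],
    d: np.ndarray,
    candidate_counts: list[int] | None = None,
    seed: int = 0,
    n_folds: int = 7,
) -> NeuroscaleModel:
    """Fit a Neuroscale model, selecting the RBF count by n-fold CV.

    For each candidate count the network is fit on the training folds and the
    held-out stress is measured over all pairs involving a held-out compound;
    the count minimizing mean CV stress wins and the model is refit on all
    data. With a single candidate the CV comparison is skipped.
    """
    d = validate_distance_matrix(d)
    fp_mat = _fp_matrix(fps)
    n = fp_mat.shape[0]
    if n != d.shape[0]:
        raise ValueError("fingerprint count does not match distance matrix")
    if candidate_counts is None:
        candidate_counts = [c for c in (5, 10, 20, 40) if c <= n // 2] or [max(1, n // 2)]
    if not candidate_counts:
        raise ValueError("candidate_counts must be nonempty")
    if n < 2 * n_folds:
        raise ValueError(
            f"n={n} too small for {n_folds}-fold cross validation; "
            "pass a smaller n_folds"
        )
    rng = np.random.default_rng(seed)

    def build(sub_idx: np.ndarray, k: int, fit_seed: int):
        sub_d = d[np.ix_(sub_idx, sub_idx)]
        medoid_local = _kmedoids(sub_d, min(k, sub_idx.size), rng)
        centers = fp_mat[sub_idx[medoid_local]]
        cd = 1.0 - _pairwise_tc(centers, centers)
        off = cd[np.triu_indices(cd.shape[0], k=1)]
        width = float(np.median(off)) if off.size else 0.5
        width = max(width, 1e-3)
        phi = _activations(fp_mat[sub_idx], centers, width)
        W = _fit_weights(phi, sub_d, seed=fit_seed)
        return centers, width, W

    cv_table: dict[int, float] = {}
    if len(candidate_counts) > 1:
        order = rng.permutation(n)
        folds = np.array_split(order, n_folds)
        for k in candidate_counts:
            scores = []
            for fi, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(order, test_idx)
                centers, width, W = build(train_idx, k, fit_seed=seed + fi)
                Y = _activations(fp_mat, centers, width) @ W
                # stress restricted to pairs touching the held-out fold
                dhat = pdist(Y)
                dv = squareform(d, checks=False)
                mask = np.zeros((n, n), dtype=bool)
                mask[test_idx, :] = True
                mask[:, test_idx] = True
                mvec = squareform(mask & ~np.eye(n, dtype=bool), checks=False).astype(bool)
                denom = np.sum(dv[mvec] ** 2)
                scores.append(np.sqrt(np.sum((dhat[mvec] - dv[mvec]) ** 2) / max(denom, 1e-30)))
            cv_table[k] = float(np.mean(scores))
        best_k = min(cv_table, key=cv_table.get)
    else:
        best_k = candidate_counts[0]

    centers, width, W = build(np.arange(n), best_k, fit_seed=seed)
    Y = _activations(fp_mat, centers, width) @ W
    return NeuroscaleModel(
        centers=centers, width=width, weights=W, n_rbf=centers.shape[0],
        train_stress=stress(Y, d), cv_table=cv_table or None,
    )


def neuroscale_transform(model: NeuroscaleModel, fps: list[Fingerprint]) -> Embedding2D:
    """Deterministically map fingerprints through the fitted RBF network."""
    fp_mat = _fp_matrix(fps)
    if fp_mat.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"fingerprint length {fp_mat.shape[1]} does not match "
            f"training length {model.centers.shape[1]}"
        )
    Y = _activations(fp_mat, model.centers, model.width) @ model.weights
    if fp_mat.shape[0] >= 2:
        d = 1.0 - _pairwise_tc(fp_mat, fp_mat)
        np.fill_diagonal(d, 0.0)
        s = stress(Y, d)
    else:
        s = 0.0
    return Embedding2D(coords=Y, stress=s, method="Neuroscale")


# ---------------------------------------------------------------------------
# Canonical orientation
# ---------------------------------------------------------------------------

def canonical_orient(e: Embedding2D) -> Embedding2D:
    """Fix the rotation/reflection/translation gauge of an embedding.

    Centers at the centroid, rotates onto principal axes (largest variance
    first), and resolves each axis reflection by requiring non-negative skew
    (third central moment) of the coordinate; a zero-skew axis falls back to
    the sign of its maximum-magnitude coordinate. Idempotent; degenerate
    all-identical configurations are returned unchanged with a warning.
    """
    X = e.coords - e.coords.mean(axis=0)
    if np.allclose(X, 0.0):
        warnings.warn("degenerate embedding (all points identical); orientation unchanged")
        return Embedding2D(coords=e.coords.copy(), stress=e.stress, method=e.method,
                           converged=e.converged)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    Y = X @ Vt.T
    for axis in range(2):
        skew = float(np.mean(Y[:, axis] ** 3))
        if abs(skew) > 1e-12:
            sign = np.sign(skew)
        else:
            extreme = Y[np.argmax(np.abs(Y[:, axis])), axis]
            sign = np.sign(extreme) if extreme != 0 else 1.0
        Y[:, axis] *= sign
    return Embedding2D(coords=Y, stress=e.stress, method=e.method,
                       converged=e.converged, stress_history=e.stress_history)


def write_embedding_csv(e: Embedding2D, ids: list[str], path) -> None:
    """Serialize an embedding to CSV: id, x, y, method, stress."""
    pd.DataFrame({
        "id": ids, "x": e.coords[:, 0], "y": e.coords[:, 1],
        "method": e.method, "stress": e.stress,
    }).to_csv(path, index=False)
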