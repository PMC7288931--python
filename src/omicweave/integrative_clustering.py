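"""Joint latent-variable integrative clustering.

Gaussian factor model shared across data modalities: each standardized
matrix X_t (features x samples) is modeled as W_t Z + eps_t with a common
latent matrix Z of dimension d = C - 1, diagonal per-feature noise, and a
lasso penalty on the loadings. Fitting is EM with an exact
coordinate-descent M-step (so the penalized log-likelihood is
nondecreasing); cluster labels come from k-means on E[Z].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .omics_io import SubtypeAssignment

logger = logging.getLogger(__name__)

_PSI_FLOOR = 1e-6


@dataclass
class IntegrativeModel:
    modalities: list[str]
    W: dict[str, np.ndarray]  # per modality: features_t x d
    psi: dict[str, np.ndarray]  # per modality: features_t
    Z: np.ndarray  # d x samples (posterior mean)
    d: int
    C: int
    lam: float
    loglik_trace: np.ndarray  # penalized observed-data log-likelihood
    labels: pd.Series
    seed: int
    converged: bool

    def nonzero_loadings(self) -> int:
        return int(sum(np.count_nonzero(w) for w in self.W.values()))


@dataclass
class StabilityReport:
    C: int
    repeats: int
    pairwise_ari: np.ndarray
    mean_ari: float


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _penalized_loglik(
    X: np.ndarray, W: np.ndarray, psi: np.ndarray, pen: float
) -> float:
    """Observed-data Gaussian log-likelihood of N(0, WW' + diag(psi)) via the
    Woodbury identity, minus pen * ||W||_1."""
    p, n = X.shape
    d = W.shape[1]
    psi_inv = 1.0 / psi
    Wp = W * psi_inv[:, None]  # Psi^-1 W
    M = np.eye(d) + W.T @ Wp
    sign, logdet_M = np.linalg.slogdet(M)
    logdet_sigma = logdet_M + np.sum(np.log(psi))
    # tr(Sigma^-1 S), S = XX'/n
    U = Wp.T @ X  # d x n
    Minv_U = np.linalg.solve(M, U)
    tr = (np.sum((X**2) * psi_inv[:, None]) - np.sum(U * Minv_U)) / n
    ll = -0.5 * n * (logdet_sigma + tr + p * np.log(2 * np.pi))
    return float(ll - pen * np.abs(W).sum())


def _cd_lasso_rows(
    W: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    psi: np.ndarray,
    pen: float,
    sweeps: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Coordinate descent on the rows of W for the penalized M-step.

    Minimizes, per feature f: (1/(2 psi_f)) (w' A w - 2 b_f' w) + pen |w|_1,
    which keeps the overall EM step an ascent step on the penalized
    objective. A is E[ZZ'] summed over samples, B holds b_f = (X E[Z]')_f.
    """
    d = A.shape[0]
    W = W.copy()
    thresh = pen * psi  # per-feature soft threshold
    for _ in range(sweeps):
        max_delta = 0.0
        for j in range(d):
            # residual correlation for coordinate j, all features at once
            r = B[:, j] - W @ A[:, j] + W[:, j] * A[j, j]
            new = np.sign(r) * np.maximum(np.abs(r) - thresh, 0.0) / A[j, j]
            max_delta = max(max_delta, float(np.max(np.abs(new - W[:, j]), initial=0.0)))
            W[:, j] = new
        if max_delta < tol:
            break
    return W


def icluster_fit(
    X_list: list[pd.DataFrame],
    C: int,
    lam: float = 0.2,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    modality_names: list[str] | None = None,
    init: str = "random",
    kmeans_restarts: int = 20,
) -> IntegrativeModel:
    """Fit the joint latent model on stacked standardized modalities.

    ``lam`` in [0, 1] scales the lasso penalty on the loadings (0 = plain
    probabilistic PCA). Latent dimension is ``C - 1``. Labels are k-means
    on the columns of E[Z] with deterministic farthest-point initialization
    (so relabeling is equivariant under sample permutation).
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    if not X_list:
        raise ValueError("no data matrices supplied")
    samples = list(X_list[0].columns)
    for X in X_list[1:]:
        if list(X.columns) != samples:
            raise ValueError("modalities must share an identical sample set/order")
    names = modality_names or [f"m{i}" for i in range(len(X_list))]
    d = C - 1
    n = len(samples)
    blocks = [_standardize_rows(X.to_numpy(dtype=float)) for X in X_list]
    sizes = [b.shape[0] for b in blocks]
    Xs = np.vstack(blocks)
    p = Xs.shape[0]
    pen = lam * n  # so the per-sample penalty scale is O(1) vs unit-variance rows

    rng = np.random.default_rng(seed)
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    W_svd = U[:, :d] * (s[:d] / np.sqrt(n))
    if init == "svd":
        W = W_svd
    elif init == "random":
        # SVD basis under a seeded random rotation plus jitter: strong enough
        # to survive the lasso threshold, different across seeds
        Q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        W = W_svd @ Q + rng.normal(scale=0.05, size=(p, d))
    else:
        raise ValueError(f"unknown init {init!r}")
    psi = np.ones(p)

    trace = [_penalized_loglik(Xs, W, psi, pen)]
    converged = False
    EZ = None
    row_ss = (Xs**2).sum(axis=1)
    for _ in range(max_iter):
        # E-step
        psi_inv = 1.0 / psi
        Wp = W * psi_inv[:, None]
        M = np.eye(d) + W.T @ Wp
        Minv = np.linalg.inv(M)
        EZ = Minv @ (Wp.T @ Xs)  # d x n
        EZZ = n * Minv + EZ @ EZ.T  # summed second moment
        # M-step: lasso rows of W by coordinate descent, then exact psi
        B = Xs @ EZ.T  # p x d
        W = _cd_lasso_rows(W, EZZ, B, psi, pen)
        quad = np.einsum("fd,de,fe->f", W, EZZ, W)
        psi = np.maximum((row_ss - 2 * np.sum(W * B, axis=1) + quad) / n, _PSI_FLOOR)
        trace.append(_penalized_loglik(Xs, W, psi, pen))
        denom = max(abs(trace[-2]), 1.0)
        if abs(trace[-1] - trace[-2]) / denom < tol:
            converged = True
            break

    labels = _kmeans_labels(EZ, C, rng, kmeans_restarts)
    label_series = pd.Series(labels, index=samples)
    offsets = np.cumsum([0] + sizes)
    W_by_mod = {
        name: W[offsets[i]: offsets[i + 1]] for i, name in enumerate(names)
    }
    psi_by_mod = {
        name: psi[offsets[i]: offsets[i + 1]] for i, name in enumerate(names)
    }
    return IntegrativeModel(
        modalities=names,
        W=W_by_mod,
        psi=psi_by_mod,
        Z=EZ,
        d=d,
        C=C,
        lam=lam,
        loglik_trace=np.array(trace),
        labels=label_series,
        seed=seed,
        converged=converged,
    )


def _kmeans_labels(
    EZ: np.ndarray, C: int, rng: np.random.Generator, restarts: int
) -> np.ndarray:
    """k-means on latent columns, deterministic farthest-point init plus
    seeded random restarts; the best inertia wins."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    pts = EZ.T  # n x d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        centers = _farthest_point_init(pts, C)
        best = KMeans(n_clusters=C, init=centers, n_init=1, max_iter=300).fit(pts)
        for _ in range(max(0, restarts - 1)):
            km = KMeans(
                n_clusters=C,
                init="k-means++",
                n_init=1,
                max_iter=300,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(pts)
            if km.inertia_ < best.inertia_ - 1e-12:
                best = km
    return best.labels_


def _farthest_point_init(pts: np.ndarray, C: int) -> np.ndarray:
    norms = np.einsum("ij,ij->i", pts, pts)
    idx = [int(np.argmax(norms))]
    for _ in range(C - 1):
        d2 = np.min(
            ((pts[:, None, :] - pts[idx][None, :, :]) ** 2).sum(-1), axis=1
        )
        idx.append(int(np.argmax(d2)))
    return pts[idx]


def _stability_fits(
    X_list: list[pd.DataFrame],
    C: int,
    lam: float,
    repeats: int,
    rng: np.random.Generator,
    max_iter: int,
    feature_frac: float = 0.8,
) -> list[IntegrativeModel]:
    """Refit on random feature subsamples (per modality) with fresh seeds;
    the labels' agreement across these perturbed fits is the stability
    score. Pure-noise data yields near-chance agreement because no latent
    subspace is shared between feature subsets."""
    fits = []
    for _ in range(repeats):
        sub = []
        for X in X_list:
            n_keep = max(2, int(round(feature_frac * X.shape[0])))
            rows = rng.choice(X.shape[0], size=n_keep, replace=False)
            sub.append(X.iloc[np.sort(rows)])
        fits.append(
            icluster_fit(
                sub, C, lam=lam, seed=int(rng.integers(0, 2**31 - 1)),
                max_iter=max_iter,
            )
        )
    return fits


def _pairwise_ari(label_sets: list[np.ndarray]) -> np.ndarray:
    r = len(label_sets)
    out = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = adjusted_rand_score(label_sets[i], label_sets[j])
    return out


def tune_lambda(
    X_list: list[pd.DataFrame],
    C: int,
    n_points: int = 10,
    repeats: int = 5,
    seed: int = 0,
    max_iter: int = 60,
) -> tuple[float, pd.DataFrame]:
    """Grid-search lambda over ``n_points`` uniform points in [0, 1],
    scoring each by label reproducibility (mean pairwise ARI over seeded
    random-restart fits). Returns the best lambda and the full grid report."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if repeats < 2:
        raise ValueError("repeats must be >= 2 (stability undefined otherwise)")
    grid = np.linspace(0.0, 1.0, n_points)
    rng = np.random.default_rng(seed)
    rows = []
    for lam in grid:
        fits = _stability_fits(X_list, C, float(lam), repeats, rng, max_iter)
        aris = _pairwise_ari([f.labels.to_numpy() for f in fits])
        off_diag = aris[np.triu_indices_from(aris, k=1)]
        rows.append(
            {
                "lambda": float(lam),
                "mean_ari": float(off_diag.mean()),
                "mean_nonzero_loadings": float(
                    np.mean([f.nonzero_loadings() for f in fits])
                ),
                "mean_loglik": float(np.mean([f.loglik_trace[-1] for f in fits])),
            }
        )
    report = pd.DataFrame(rows)
    best_idx = report["mean_ari"].round(12).idxmax()  # ties -> smaller lambda
    return float(report.loc[best_idx, "lambda"]), report


def select_cluster_count(
    X_list: list[pd.DataFrame],
    C_candidates: tuple[int, ...] = (3, 4),
    repeats: int = 20,
    lam: float = 0.2,
    seed: int = 0,
    max_iter: int = 60,
) -> tuple[int, dict[int, StabilityReport]]:
    """Choose the cluster count with the most reproducible labels across
    seeded refits (highest mean pairwise ARI; ties toward smaller C)."""
    if len(C_candidates) < 2:
        raise ValueError("need >= 2 candidate cluster counts")
    rng = np.random.default_rng(seed)
    reports: dict[int, StabilityReport] = {}
    for C in C_candidates:
        fits = _stability_fits(X_list, C, lam, repeats, rng, max_iter)
        aris = _pairwise_ari([f.labels.to_numpy() for f in fits])
        off_diag = aris[np.triu_indices_from(aris, k=1)]
        reports[C] = StabilityReport(
            C=C, repeats=repeats, pairwise_ari=aris, mean_ari=float(off_diag.mean())
        )
    ordered = sorted(C_candidates)
    best = max(ordered, key=lambda c: (round(reports[c].mean_ari, 12), -c))
    return best, reports


def icluster_subtype(
    X_list: list[pd.DataFrame],
    C: int,
    lam: float,
    seed: int = 0,
    modality_names: list[str] | None = None,
    max_iter: int = 100,
) -> tuple[SubtypeAssignment, IntegrativeModel]:
    """Fit at the chosen (C, lambda) and emit labels iC1..iCk ordered by
    decreasing cluster size."""
    model = icluster_fit(
        X_list, C, lam=lam, seed=seed, modality_names=modality_names,
        max_iter=max_iter,
    )
    ordered = model.labels.value_counts().index
    rename = {old: f"iC{i + 1}" for i, old in enumerate(ordered)}
    assignment = SubtypeAssignment(
        labels=model.labels.map(rename),
        method="icluster",
        diagnostics={"C": C, "lambda": lam, "final_loglik": float(model.loglik_trace[-1])},
    )
    return assignment, model
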