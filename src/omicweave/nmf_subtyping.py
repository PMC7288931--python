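"""Consensus NMF subtyping.

Nonnegative matrix factorization with multiplicative updates for the
Kullback-Leibler objective ("brunet" variant), multi-restart consensus
clustering, cophenetic/silhouette diagnostics and rank selection with a
minimum-subclass-size rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .omics_io import SubtypeAssignment

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class NmfFit:
    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    objective_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool


@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # samples x samples in [0,1]
    cophenetic: float
    mean_silhouette: float
    labels: pd.Series  # sample -> cluster id (int)
    min_cluster_size: int = 0

    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts()


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) with the 0*log(0) = 0 convention."""
    WH = W @ H
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - V.sum() + WH.sum())


def nmf_fit(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NmfFit:
    """Factorize V ~= W H by Brunet multiplicative updates on the KL objective.

    Rows of all zeros are dropped (with a warning) before fitting since they
    carry no information and break the updates. Initialization is uniform
    random from ``seed``; iteration stops when the relative objective change
    falls below ``tol`` or at ``max_iter``.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    zero_rows = ~(V > 0).any(axis=1)
    if zero_rows.any():
        logger.warning("nmf_fit: dropping %d all-zero rows", int(zero_rows.sum()))
        V = V[~zero_rows]
    if V.shape[0] == 0:
        raise ValueError("no nonzero rows left in NMF input")
    rng = np.random.default_rng(seed)
    n, m = V.shape
    W = rng.uniform(_EPS, 1.0, size=(n, k))
    H = rng.uniform(_EPS, 1.0, size=(k, m))
    trace = [kl_divergence(V, W, H)]
    converged = False
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = kl_divergence(V, W, H)
        trace.append(obj)
        denom = max(abs(trace[-2]), _EPS)
        if abs(trace[-2] - obj) / denom < tol:
            converged = True
            break
    return NmfFit(
        W=W, H=H, objective_trace=np.array(trace), seed=seed,
        n_iter=len(trace) - 1, converged=converged,
    )


def _labels_from_H(H: np.ndarray) -> np.ndarray:
    return np.argmax(H, axis=0)


def consensus_cluster(
    V: pd.DataFrame,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Run NMF ``n_runs`` times from random restarts and cluster samples by
    their co-assignment frequency.

    Per run, a sample joins the cluster of the largest entry in its H
    column. The consensus matrix holds co-assignment fractions; final
    labels come from average-linkage hierarchical clustering of
    1 - consensus cut at k. Cophenetic correlation and mean silhouette of
    the consensus distances are reported as stability diagnostics.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    samples = list(V.columns)
    arr = V.to_numpy(dtype=float)
    if (arr < 0).any():  # shift to nonnegativity (CNV matrices contain losses)
        logger.info("consensus_cluster: shifting matrix by %.4g", -arr.min())
        arr = arr - arr.min()
    m = arr.shape[1]
    co = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    for s in run_seeds:
        fit = nmf_fit(arr, k, seed=int(s), max_iter=max_iter, tol=tol)
        lab = _labels_from_H(fit.H)
        co += lab[:, None] == lab[None, :]
    consensus = co / n_runs
    np.fill_diagonal(consensus, 1.0)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    coph_corr, _ = cophenet(Z, condensed)
    if np.isnan(coph_corr):  # zero-variance distances (perfectly stable runs)
        coph_corr = 1.0
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")
    label_series = pd.Series(labels, index=samples)
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        cophenetic=float(coph_corr),
        mean_silhouette=sil,
        labels=label_series,
        min_cluster_size=int(label_series.value_counts().min()),
    )


@dataclass
class RankSelection:
    chosen_k: int
    diagnostics: pd.DataFrame  # per k: cophenetic, silhouette, min size, admissible
    results: dict[int, ConsensusResult] = field(default_factory=dict)


def select_rank(
    results: dict[int, ConsensusResult], min_size: int = 10
) -> RankSelection:
    """Among candidate ranks whose smallest cluster has >= ``min_size``
    members, pick the one maximizing mean silhouette (ties toward smaller k)."""
    if len(results) < 2:
        raise ValueError("need >= 2 candidate ranks")
    rows = []
    for k in sorted(results):
        r = results[k]
        rows.append(
            {
                "k": k,
                "cophenetic": r.cophenetic,
                "mean_silhouette": r.mean_silhouette,
                "min_cluster_size": r.min_cluster_size,
                "admissible": r.min_cluster_size >= min_size,
            }
        )
    diag = pd.DataFrame(rows).set_index("k")
    admissible = diag[diag["admissible"]]
    if admissible.empty:
        raise ValueError(
            f"every candidate rank has a cluster smaller than {min_size}; relax min_size"
        )
    best = admissible["mean_silhouette"].round(12).idxmax()  # idxmax ties -> first (smallest k)
    return RankSelection(chosen_k=int(best), diagnostics=diag, results=results)


def nmf_subtype(
    V: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    n_runs: int = 50,
    min_size: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[SubtypeAssignment, RankSelection]:
    """Full NMF subtyping: consensus clustering over a rank range, rank
    selection, and a labeled assignment ordered by decreasing cluster size."""
    results = {
        k: consensus_cluster(V, k, n_runs=n_runs, seed=seed + k, max_iter=max_iter, tol=tol)
        for k in range(k_min, k_max + 1)
    }
    sel = select_rank(results, min_size=min_size)
    chosen = results[sel.chosen_k]
    ordered = chosen.labels.value_counts().index
    rename = {old: f"N{i + 1}" for i, old in enumerate(ordered)}
    labels = chosen.labels.map(rename)
    assignment = SubtypeAssignment(
        labels=labels,
        method="nmf_consensus",
        diagnostics={
            "chosen_k": sel.chosen_k,
            "table": sel.diagnostics.to_dict(orient="index"),
        },
    )
    return assignment, sel
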