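"""Cis-regulatory correlation screening.

Per-gene Spearman correlation of copy number (or promoter methylation)
against expression, a log-ratio z transform ``z = ln((1+rho)/(1-rho))``
(equal to ``2*atanh(rho)``), significance screening at ``p < 1e-5``, and a
sign constraint at the 95% confidence interval of z: positively-driven
genes for the copy-number signature, negatively-driven genes for the
methylation signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import AnnotationSet, GeneMatrix, ValidationError

logger = logging.getLogger(__name__)

_RHO_CLAMP = 1.0 - 1e-12
#: scale constant of the z transform: Var(z) = C^2 / (n-3) asymptotically
_Z_SCALE = 2.0


def z_transform(rho: float | np.ndarray) -> float | np.ndarray:
    """``ln((1+rho)/(1-rho))``, with rho clamped to +/-(1 - 1e-12)."""
    r = np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)
    return np.log((1.0 + r) / (1.0 - r))


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    modality: str  # CNV or MET_BETA
    rho: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class SignatureSet:
    """Screen results: full significant sets, sign-constrained signatures,
    their overlap, and z-distribution skewness."""

    cnv_g_all: list[str]
    met_g_all: list[str]
    cnv_g_sig: list[str]
    met_g_sig: list[str]
    skewness_cnv: float
    skewness_met: float
    records: dict[str, list[CorrelationRecord]] = field(default_factory=dict)

    @property
    def overlap(self) -> list[str]:
        return sorted(set(self.cnv_g_sig) & set(self.met_g_sig))

    def summary(self) -> dict:
        n_overlap = len(self.overlap)
        return {
            "n_cnv_g_all": len(self.cnv_g_all),
            "n_met_g_all": len(self.met_g_all),
            "n_cnv_g_sig": len(self.cnv_g_sig),
            "n_met_g_sig": len(self.met_g_sig),
            "n_overlap": n_overlap,
            "overlap_ratio_cnv": n_overlap / len(self.cnv_g_sig) if self.cnv_g_sig else float("nan"),
            "overlap_ratio_met": n_overlap / len(self.met_g_sig) if self.met_g_sig else float("nan"),
            "skewness_cnv": self.skewness_cnv,
            "skewness_met": self.skewness_met,
        }


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation with n-2 df."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def gene_correlation(
    x: GeneMatrix, expr: GeneMatrix, exact_perm_below: int = 0
) -> list[CorrelationRecord]:
    """Spearman correlation of each shared gene's x-row vs expression row.

    Ties get average ranks. p-values come from the t approximation on rho
    with n-2 df (exact permutation optionally below ``exact_perm_below``
    samples). Constant rows are dropped with a logged reason.
    """
    if x.modality not in ("CNV", "MET_BETA"):
        raise ValidationError(f"unsupported modality {x.modality}")
    shared_samples = [s for s in x.sample_ids if s in set(expr.sample_ids)]
    if len(shared_samples) < 3:
        raise ValidationError(
            f"need >=3 shared samples, found {len(shared_samples)}"
        )
    shared_genes = [g for g in x.gene_ids if g in set(expr.gene_ids)]
    xv = x.values.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    ev = expr.values.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    n = len(shared_samples)
    records: list[CorrelationRecord] = []
    n_dropped = 0
    # rank both matrices row-wise, then Pearson on ranks == Spearman
    xr = stats.rankdata(xv, axis=1)
    er = stats.rankdata(ev, axis=1)
    xr_c = xr - xr.mean(axis=1, keepdims=True)
    er_c = er - er.mean(axis=1, keepdims=True)
    x_ss = (xr_c**2).sum(axis=1)
    e_ss = (er_c**2).sum(axis=1)
    for i, gene in enumerate(shared_genes):
        if x_ss[i] == 0 or e_ss[i] == 0:
            n_dropped += 1
            continue
        rho = float((xr_c[i] * er_c[i]).sum() / math.sqrt(x_ss[i] * e_ss[i]))
        rho = max(-1.0, min(1.0, rho))
        if n < exact_perm_below and n < 10:
            p = _exact_spearman_p(xv[i], ev[i])
        else:
            p = _spearman_p(rho, n)
        z = float(z_transform(rho))
        half = 1.96 * _Z_SCALE / math.sqrt(n - 3) if n > 3 else float("inf")
        records.append(
            CorrelationRecord(
                gene_id=gene,
                modality=x.modality,
                rho=rho,
                z=z,
                p=max(p, np.nextafter(0, 1)),
                ci_low=z - half,
                ci_high=z + half,
                n=n,
            )
        )
    if n_dropped:
        logger.info(
            "gene_correlation(%s): dropped %d constant genes", x.modality, n_dropped
        )
    return records


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value; only sensible for tiny n."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(len(y))):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def _sample_skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness g1*sqrt(n(n-1))/(n-2)."""
    return float(stats.skew(values, bias=False))


def select_signatures(
    records: list[CorrelationRecord], p_thresh: float = 1e-5
) -> SignatureSet:
    """Two-stage screen: ``p < p_thresh`` defines the full CNV/MET gene
    sets; the signatures additionally require the 95% CI of z to exclude 0
    on the expected side (positive for CNV, negative for MET)."""
    if not records:
        raise ValidationError("no correlation records")
    by_mod: dict[str, list[CorrelationRecord]] = {"CNV": [], "MET_BETA": []}
    for rec in records:
        by_mod[rec.modality].append(rec)

    cnv_all = [r for r in by_mod["CNV"] if r.p < p_thresh]
    met_all = [r for r in by_mod["MET_BETA"] if r.p < p_thresh]
    cnv_sig = [r for r in cnv_all if r.ci_low > 0]
    met_sig = [r for r in met_all if r.ci_high < 0]

    def _skew(recs: list[CorrelationRecord]) -> float:
        if len(recs) < 3:
            return float("nan")
        return _sample_skewness(np.array([r.z for r in recs]))

    return SignatureSet(
        cnv_g_all=sorted(r.gene_id for r in cnv_all),
        met_g_all=sorted(r.gene_id for r in met_all),
        cnv_g_sig=sorted(r.gene_id for r in cnv_sig),
        met_g_sig=sorted(r.gene_id for r in met_sig),
        skewness_cnv=_skew(cnv_all),
        skewness_met=_skew(met_all),
        records={"CNV": by_mod["CNV"], "MET_BETA": by_mod["MET_BETA"]},
    )


def summarize_signature_geography(
    sig_genes: list[str], ann: AnnotationSet
) -> dict[str, dict[str, int]]:
    """Count signature genes per chromosome and per gene type; genes absent
    from the annotation are tallied under 'unmapped'."""
    by_chrom: dict[str, int] = {}
    by_type: dict[str, int] = {}
    unmapped = 0
    for gid in sig_genes:
        if gid not in ann:
            unmapped += 1
            continue
        g = ann[gid]
        by_chrom[g.chrom] = by_chrom.get(g.chrom, 0) + 1
        by_type[g.gene_type] = by_type.get(g.gene_type, 0) + 1
    return {
        "by_chromosome": by_chrom,
        "by_gene_type": by_type,
        "unmapped": {"count": unmapped},
    }


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "modality": [r.modality for r in records],
            "rho": [r.rho for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "n": [r.n for r in records],
        }
    )
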