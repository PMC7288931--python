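"""Raw-table preprocessing: CNV segment merging and gene aggregation,
methylation probe filtering/imputation/promoter mapping, expression and
mutation filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omics_io import (
    AnnotationSet,
    GeneMatrix,
    MutationTable,
    ProbeManifest,
    REGION_CLASSES,
    SegmentTable,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds for the four preprocessing procedures."""

    min_probes: int = 5
    overlap_frac: float = 0.5
    reciprocal_overlap: bool = True
    weighted_merge: bool = True
    met_missing_frac: float = 0.7
    knn_k: int = 10
    tss_upstream: int = 2000
    tss_downstream: int = 200
    expr_zero_frac: float = 0.5

    def __post_init__(self) -> None:
        for name in ("overlap_frac", "met_missing_frac", "expr_zero_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if self.tss_upstream <= 0 or self.tss_downstream <= 0:
            raise ValueError("TSS window sizes must be positive")


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------


def _overlap_len(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def _should_merge(
    s1: int, e1: int, s2: int, e2: int, frac: float, reciprocal: bool
) -> bool:
    ov = _overlap_len(s1, e1, s2, e2)
    if ov <= 0:
        return False
    f1 = ov / (e1 - s1 + 1)
    f2 = ov / (e2 - s2 + 1)
    if reciprocal:
        return f1 >= frac and f2 >= frac
    return f1 >= frac or f2 >= frac


def _merge_group(group: pd.DataFrame, cfg: PreprocessConfig) -> list[dict]:
    """Merge one sample+chromosome group of segments to a fixed point."""
    segs = group.sort_values(["start", "end"]).to_dict("records")
    changed = True
    while changed:
        changed = False
        out: list[dict] = []
        for seg in segs:
            if out and _should_merge(
                out[-1]["start"],
                out[-1]["end"],
                seg["start"],
                seg["end"],
                cfg.overlap_frac,
                cfg.reciprocal_overlap,
            ):
                prev = out[-1]
                n = prev["n_probes"] + seg["n_probes"]
                if cfg.weighted_merge and n > 0:
                    value = (
                        prev["value"] * prev["n_probes"] + seg["value"] * seg["n_probes"]
                    ) / n
                else:
                    value = (prev["value"] + seg["value"]) / 2
                prev.update(
                    start=min(prev["start"], seg["start"]),
                    end=max(prev["end"], seg["end"]),
                    n_probes=n,
                    value=value,
                )
                changed = True
            else:
                out.append(dict(seg))
        segs = sorted(out, key=lambda r: (r["start"], r["end"]))
    return segs


def merge_cnv_segments(segs: SegmentTable, cfg: PreprocessConfig) -> SegmentTable:
    """Drop low-probe-support segments, then merge overlapping ones.

    Segments with fewer than ``cfg.min_probes`` probes are removed first.
    Within each sample+chromosome, any pair with (reciprocal) overlap
    fraction >= ``cfg.overlap_frac`` is merged into its union, with the
    value a probe-count-weighted mean; merging iterates to a fixed point,
    so the operation is idempotent.
    """
    df = segs.df[segs.df["n_probes"] >= cfg.min_probes]
    if df.empty:
        return SegmentTable(df.iloc[0:0])
    merged: list[dict] = []
    for (sample, chrom), group in df.groupby(["sample_id", "chrom"], sort=True):
        for rec in _merge_group(group, cfg):
            rec["sample_id"] = sample
            rec["chrom"] = chrom
            merged.append(rec)
    return SegmentTable(pd.DataFrame(merged))


def segments_to_gene_cnv(segs: SegmentTable, ann: AnnotationSet) -> GeneMatrix:
    """Aggregate merged segments to a gene-level CNV matrix.

    A gene's value in a sample is the unweighted mean of the values of all
    segments overlapping its body by >= 1 bp; genes covered by no segment
    get 0 (neutral / diploid baseline).
    """
    if len(ann) == 0:
        raise ValidationError("empty annotation")
    samples = sorted(segs.df["sample_id"].unique())
    gene_ids = [g.gene_id for g in ann]
    mat = np.zeros((len(gene_ids), len(samples)))
    genes_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, g in enumerate(ann):
        genes_by_chrom.setdefault(g.chrom, []).append((g.gene_start, g.gene_end, idx))
    sample_pos = {s: j for j, s in enumerate(samples)}
    for (sample, chrom), group in segs.df.groupby(["sample_id", "chrom"]):
        genes = genes_by_chrom.get(chrom)
        if not genes:
            continue
        j = sample_pos[sample]
        gstart = np.array([g[0] for g in genes])
        gend = np.array([g[1] for g in genes])
        gidx = np.array([g[2] for g in genes])
        sums = np.zeros(len(genes))
        counts = np.zeros(len(genes))
        for start, end, value in zip(group["start"], group["end"], group["value"]):
            hit = (gstart <= end) & (gend >= start)
            sums[hit] += value
            counts[hit] += 1
        covered = counts > 0
        mat[gidx[covered], j] = sums[covered] / counts[covered]
    return GeneMatrix("CNV", pd.DataFrame(mat, index=gene_ids, columns=samples))


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def filter_met_probes(beta: pd.DataFrame, cfg: PreprocessConfig) -> pd.DataFrame:
    """Drop probes whose missing fraction exceeds ``met_missing_frac`` (strict)."""
    frac_na = beta.isna().mean(axis=1)
    keep = frac_na <= cfg.met_missing_frac
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_met_probes: removed %d probes", n_drop)
    return beta.loc[keep]


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill each missing beta with the mean of the k nearest probe rows.

    Distance is Euclidean over mutually observed samples, normalized by the
    number of shared samples so rows with different missingness patterns are
    comparable. Imputed values are clipped to [0, 1].
    """
    arr = beta.to_numpy(dtype=float)
    mask = ~np.isnan(arr)
    all_missing = ~mask.any(axis=1)
    if all_missing.any():
        probe = beta.index[np.nonzero(all_missing)[0][0]]
        raise ValidationError(f"probe {probe!r} has no observed values")
    if mask.all():
        return beta.copy()
    n = arr.shape[0]
    if k >= n:
        logger.warning("knn_impute: k=%d >= %d probes; using all other rows", k, n)
        k = n - 1
    # pairwise squared distances over shared observed samples, mean-normalized;
    # float32 suffices since distances only rank neighbors
    filled = np.where(mask, arr, 0.0).astype(np.float32)
    maskf = mask.astype(np.float32)
    shared = maskf @ maskf.T
    cross = filled @ filled.T
    own = (filled**2) @ maskf.T
    d2 = own + own.T
    d2 -= 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 /= shared
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    out = arr.copy()
    rows_with_na = np.nonzero(~mask.all(axis=1))[0]
    col_means = np.nanmean(arr, axis=0)
    for i in rows_with_na:
        neighbors = np.argpartition(d2[i], k - 1)[:k]
        cols = np.nonzero(~mask[i])[0]
        nb_vals = arr[np.ix_(neighbors, cols)]
        obs = ~np.isnan(nb_vals)
        n_obs = obs.sum(axis=0)
        sums = np.where(obs, nb_vals, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            means = sums / n_obs
        # neighbors all missing at a column -> fall back to the column mean
        means = np.where(n_obs == 0, col_means[cols], means)
        out[i, cols] = np.clip(means, 0.0, 1.0)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def probes_to_gene_met(
    beta: pd.DataFrame,
    manifest: ProbeManifest,
    ann: AnnotationSet,
    cfg: PreprocessConfig,
) -> tuple[GeneMatrix, pd.Series]:
    """Map promoter-window probes to genes; return the gene matrix and a
    census of retained probes by CpG-region class.

    A probe is retained for a gene iff it lies within ``tss_upstream`` bp
    upstream to ``tss_downstream`` bp downstream of the TSS in transcription
    direction (window boundaries inclusive, strand-aware).
    """
    probe_rows = {p: i for i, p in enumerate(beta.index)}
    gene_probe_idx: dict[str, list[int]] = {}
    census = {rc: 0 for rc in REGION_CLASSES}
    n_skipped = 0
    for rec in manifest.df.itertuples():
        if rec.probe_id not in probe_rows:
            continue
        retained_for_any = False
        for gid in rec.gene_ids:
            if gid not in ann:
                n_skipped += 1
                continue
            g = ann[gid]
            if g.chrom != rec.chrom:
                n_skipped += 1
                continue
            if g.strand == "+":
                lo, hi = g.tss - cfg.tss_upstream, g.tss + cfg.tss_downstream
            else:
                lo, hi = g.tss - cfg.tss_downstream, g.tss + cfg.tss_upstream
            if lo <= rec.pos <= hi:
                gene_probe_idx.setdefault(gid, []).append(probe_rows[rec.probe_id])
                retained_for_any = True
        if retained_for_any:
            census[rec.region_class] += 1
    if n_skipped:
        logger.info("probes_to_gene_met: skipped %d probe-gene links", n_skipped)
    arr = beta.to_numpy(dtype=float)
    gene_ids = sorted(gene_probe_idx)
    mat = np.vstack([arr[gene_probe_idx[g]].mean(axis=0) for g in gene_ids]) if gene_ids else np.empty((0, arr.shape[1]))
    gm = GeneMatrix(
        "MET_BETA", pd.DataFrame(mat, index=gene_ids, columns=beta.columns)
    )
    return gm, pd.Series(census, name="n_probes")


# ---------------------------------------------------------------------------
# Expression and mutations
# ---------------------------------------------------------------------------


def filter_low_expression(expr: GeneMatrix, cfg: PreprocessConfig) -> GeneMatrix:
    """Keep genes whose zero-FPKM sample fraction is < ``expr_zero_frac``."""
    if expr.modality != "EXPR_FPKM":
        raise ValidationError("filter_low_expression expects an FPKM matrix")
    zero_frac = (expr.values == 0).mean(axis=1)
    keep = zero_frac < cfg.expr_zero_frac
    return GeneMatrix("EXPR_FPKM", expr.values.loc[keep])


def filter_mutations(muts: MutationTable) -> tuple[MutationTable, pd.Series]:
    """Remove silent and intronic records; keep per-sample silent counts
    for burden reporting."""
    is_silent = muts.df["is_silent"].astype(bool)
    is_intronic = muts.df["is_intronic"].astype(bool)
    silent_counts = (
        muts.df[is_silent].groupby("sample_id").size().rename("n_silent")
    )
    keep = ~(is_silent | is_intronic)
    return MutationTable(muts.df[keep]), silent_counts
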