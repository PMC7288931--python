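"""Subtype association statistics and survival analysis.

Contingency chi-square tests for clinical features, per-gene Fisher exact
mutation-spectrum screens with Benjamini-Hochberg control, Kaplan-Meier /
log-rank survival comparisons, single-gene marker reports, and a two-group
rank-sum differential-expression screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .omics_io import GeneMatrix, MutationTable, SubtypeAssignment, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    n_low_expected: int  # cells with expected count < 5


def chi2_contingency(
    observed: pd.DataFrame | np.ndarray, drop_levels: list[str] | None = None
) -> ContingencyResult:
    """Pearson chi-square without continuity correction.

    ``drop_levels`` removes named rows before testing (used e.g. to exclude
    an 'unknown' category). Cells with expected count < 5 are counted and
    reported as a warning, not an error.
    """
    obs = pd.DataFrame(observed).astype(float)
    if drop_levels:
        missing = [lv for lv in drop_levels if lv not in obs.index]
        if missing:
            raise ValidationError(f"drop_levels not present: {missing}")
        obs = obs.drop(index=drop_levels)
    if (obs.to_numpy() < 0).any():
        raise ValidationError("negative counts")
    zero_rows = obs.index[obs.sum(axis=1) == 0]
    zero_cols = obs.columns[obs.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        raise ValidationError(
            f"zero margins: rows={list(zero_rows)} cols={list(zero_cols)}"
        )
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table")
    chi2, p, df, expected = stats.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    n_low = int((expected < 5).sum())
    if n_low:
        logger.warning("chi2_contingency: %d cells with expected count < 5", n_low)
    return ContingencyResult(
        observed=obs, expected=exp, chi2=float(chi2), df=int(df), p=float(p),
        n_low_expected=n_low,
    )


def fisher_exact_2x2(table: np.ndarray | list[list[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns the sample (unconditional) odds ratio ``ad/bc`` and the p-value
    from summing hypergeometric probabilities <= that of the observed table.
    Tables with a zero margin return p = 1 by convention (flagged in logs);
    a zero in b or c gives an infinite odds ratio.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact_2x2 expects a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact_2x2: zero margin, p=1 by convention")
        a, b, c, d = t.ravel()
        orat = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        return orat, 1.0
    orat, p = stats.fisher_exact(t, alternative="two-sided")
    return float(orat), float(p)


# ---------------------------------------------------------------------------
# Mutation spectrum
# ---------------------------------------------------------------------------


@dataclass
class MutationSpectrumResult:
    table: pd.DataFrame  # per gene: counts, fisher_p, odds_ratio, fdr_bh, passes
    group_a: list[str]
    group_b: list[str]
    fdr_thresh: float

    @property
    def flagged_genes(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(pvals, method="fdr_bh")[1]


def mutation_spectrum(
    muts: MutationTable,
    labels: SubtypeAssignment,
    group_a_labels: list[str],
    group_b_labels: list[str],
    fdr_thresh: float = 0.001,
) -> MutationSpectrumResult:
    """Per-gene 2x2 Fisher screen of mutation presence in group A vs B.

    Genes mutated in no sample of either group are excluded. BH-adjusted
    p-values are compared against ``fdr_thresh``.
    """
    lab = labels.labels
    samples_a = [s for s in lab.index if lab[s] in set(group_a_labels)]
    samples_b = [s for s in lab.index if lab[s] in set(group_b_labels)]
    if not samples_a or not samples_b:
        raise ValidationError("both groups must be nonempty")
    mutated = (
        muts.df[["sample_id", "gene_id"]]
        .drop_duplicates()
        .groupby("gene_id")["sample_id"]
        .apply(set)
    )
    set_a, set_b = set(samples_a), set(samples_b)
    rows = []
    for gene, carriers in mutated.items():
        a_mut = len(carriers & set_a)
        b_mut = len(carriers & set_b)
        if a_mut + b_mut == 0:
            continue
        tab = [[a_mut, len(samples_a) - a_mut], [b_mut, len(samples_b) - b_mut]]
        orat, p = fisher_exact_2x2(tab)
        rows.append(
            {"gene_id": gene, "mut_a": a_mut, "wt_a": len(samples_a) - a_mut,
             "mut_b": b_mut, "wt_b": len(samples_b) - b_mut,
             "odds_ratio": orat, "fisher_p": p}
        )
    if not rows:
        raise ValidationError("no mutated genes in either group")
    table = pd.DataFrame(rows).set_index("gene_id").sort_index()
    table["fdr_bh"] = bh_fdr(table["fisher_p"].to_numpy())
    table["passes"] = table["fdr_bh"] < fdr_thresh
    return MutationSpectrumResult(
        table=table, group_a=samples_a, group_b=samples_b, fdr_thresh=fdr_thresh
    )


def silent_nonsilent_counts(
    muts_unfiltered: MutationTable,
) -> pd.DataFrame:
    """Per-sample silent and nonsilent mutation totals (intronic excluded)."""
    df = muts_unfiltered.df
    nonintronic = df[~df["is_intronic"]]
    silent = nonintronic[nonintronic["is_silent"]].groupby("sample_id").size()
    nonsilent = nonintronic[~nonintronic["is_silent"]].groupby("sample_id").size()
    out = pd.DataFrame({"n_silent": silent, "n_nonsilent": nonsilent}).fillna(0)
    return out.astype(int)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    groups: pd.Series
    times: pd.Series
    events: pd.Series
    km_curves: dict[str, pd.DataFrame]  # per group: time, survival
    logrank_chi2: float
    logrank_df: int
    logrank_p: float


def km_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> SurvivalComparison:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    idx = times.index
    if not (events.index.equals(idx) and groups.index.equals(idx)):
        raise ValidationError("times/events/groups must share an index")
    keep = times.notna() & events.notna() & groups.notna()
    times, events, groups = times[keep], events[keep], groups[keep]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    for g in levels:
        if (groups == g).sum() == 0:
            raise ValidationError(f"group {g} is empty")
    if events.sum() == 0:
        raise ValidationError("no events in any group; log-rank undefined")
    curves = {}
    for g in levels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(times, groups, events)
    return SurvivalComparison(
        groups=groups, times=times, events=events, km_curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_df=len(levels) - 1,
        logrank_p=float(res.p_value),
    )


def pairwise_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Log-rank p-value for every pair of groups."""
    levels = sorted(groups.dropna().unique())
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            mask = groups.isin([a, b])
            cmp = km_logrank(times[mask], events[mask], groups[mask])
            rows.append({"group_a": a, "group_b": b, "chi2": cmp.logrank_chi2,
                         "p": cmp.logrank_p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Marker analysis
# ---------------------------------------------------------------------------


@dataclass
class MarkerReport:
    gene_id: str
    met_expr_rho: float
    met_expr_p: float
    cnv_expr_rho: float
    cnv_expr_p: float
    subtype_expression: pd.DataFrame  # per subtype: n, median, q1, q3
    km: SurvivalComparison  # high vs low expression at the median
    kruskal_p: float


def marker_analysis(
    gene_id: str,
    expr: GeneMatrix,
    met: GeneMatrix,
    cnv: GeneMatrix,
    times: pd.Series,
    events: pd.Series,
    labels: SubtypeAssignment,
) -> MarkerReport:
    """Single-gene report: methylation/CNV vs expression correlation,
    per-subtype expression summaries, and a median-split KM comparison
    (ties at the median go to the 'low' group)."""
    for name, mat in (("expression", expr), ("methylation", met), ("CNV", cnv)):
        if gene_id not in mat.values.index:
            raise ValidationError(f"gene {gene_id!r} absent from the {name} matrix")
    samples = [
        s for s in expr.sample_ids
        if s in set(met.sample_ids) and s in set(cnv.sample_ids)
    ]
    e = expr.values.loc[gene_id, samples]
    m = met.values.loc[gene_id, samples]
    c = cnv.values.loc[gene_id, samples]
    if e.nunique() <= 1:
        raise ValidationError("constant expression; median split impossible")
    me_rho, me_p = stats.spearmanr(m, e)
    if c.nunique() <= 1:
        ce_rho, ce_p = float("nan"), float("nan")
    else:
        ce_rho, ce_p = stats.spearmanr(c, e)

    lab = labels.labels.reindex(samples).dropna()
    rows = []
    groups_expr = []
    for g in sorted(lab.unique()):
        vals = e[lab.index[lab == g]].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"subtype": g, "n": len(vals), "median": med, "q1": q1, "q3": q3})
        groups_expr.append(vals)
    kruskal_p = (
        float(stats.kruskal(*groups_expr)[1]) if len(groups_expr) >= 2 else float("nan")
    )

    median = e.median()
    hl = pd.Series(np.where(e > median, "high", "low"), index=e.index)
    surv_idx = [s for s in samples if s in times.index]
    km = km_logrank(times[surv_idx], events[surv_idx], hl[surv_idx])
    return MarkerReport(
        gene_id=gene_id,
        met_expr_rho=float(me_rho), met_expr_p=float(me_p),
        cnv_expr_rho=float(ce_rho), cnv_expr_p=float(ce_p),
        subtype_expression=pd.DataFrame(rows),
        km=km,
        kruskal_p=kruskal_p,
    )


# ---------------------------------------------------------------------------
# Differential expression (rank-sum substitute)
# ---------------------------------------------------------------------------


def diff_expr_screen(
    expr: GeneMatrix,
    labels: SubtypeAssignment,
    group_a_labels: list[str],
    group_b_labels: list[str],
    fc_thresh: float = 2.0,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Two-group screen: Wilcoxon rank-sum p per gene, log2 fold change of
    group means (pseudocount 1), BH FDR; the pass flag requires
    ``|log2FC| >= log2(fc_thresh)`` and ``fdr < fdr_thresh``."""
    lab = labels.labels
    a = [s for s in expr.sample_ids if lab.get(s) in set(group_a_labels)]
    b = [s for s in expr.sample_ids if lab.get(s) in set(group_b_labels)]
    if not a or not b:
        raise ValidationError("both groups must be nonempty")
    A = expr.values[a].to_numpy(dtype=float)
    B = expr.values[b].to_numpy(dtype=float)
    log2fc = np.log2(A.mean(axis=1) + 1.0) - np.log2(B.mean(axis=1) + 1.0)
    pvals = np.ones(len(log2fc))
    for i in range(len(pvals)):
        if np.ptp(A[i]) == 0 and np.ptp(B[i]) == 0 and A[i][0] == B[i][0]:
            continue
        pvals[i] = stats.mannwhitneyu(A[i], B[i], alternative="two-sided").pvalue
    fdr = bh_fdr(pvals)
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": pvals, "fdr": fdr}, index=expr.gene_ids
    )
    out["passes"] = (np.abs(out["log2fc"]) >= np.log2(fc_thresh)) & (
        out["fdr"] < fdr_thresh
    )
    return out
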