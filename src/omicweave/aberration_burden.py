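"""Per-sample aberration burden counts and their pairwise correlations.

A gene counts as Gain when its CNV value is > 0.3, Loss when < -0.3;
MetHyper when its beta value is > 0.8, MetHypo when < 0.2 — strict
inequalities exactly as defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import GeneMatrix, SubtypeAssignment, ValidationError

logger = logging.getLogger(__name__)

BURDEN_TYPES = ("n_gain", "n_loss", "n_methyper", "n_methypo")


@dataclass(frozen=True)
class BurdenThresholds:
    gain: float = 0.3
    loss: float = -0.3
    methyper: float = 0.8
    methypo: float = 0.2


def compute_burdens(
    cnv: GeneMatrix, met: GeneMatrix, thresholds: BurdenThresholds = BurdenThresholds()
) -> pd.DataFrame:
    """Count Gain/Loss/MetHyper/MetHypo genes per sample (strict thresholds)."""
    if cnv.modality != "CNV" or met.modality != "MET_BETA":
        raise ValidationError("compute_burdens expects a CNV and a MET_BETA matrix")
    met_arr = met.values.to_numpy()
    if np.isnan(met_arr).any() or met_arr.min() < 0 or met_arr.max() > 1:
        raise ValidationError("MET matrix must be complete with values in [0,1]")
    samples = [s for s in cnv.sample_ids if s in set(met.sample_ids)]
    cnv_v = cnv.values[samples]
    met_v = met.values[samples]
    t = thresholds
    return pd.DataFrame(
        {
            "n_gain": (cnv_v > t.gain).sum(axis=0),
            "n_loss": (cnv_v < t.loss).sum(axis=0),
            "n_methyper": (met_v > t.methyper).sum(axis=0),
            "n_methypo": (met_v < t.methypo).sum(axis=0),
        },
        index=samples,
    )


def burden_correlations(
    burdens: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation (rho) and p-value matrices over the four burden types.

    Pairs involving a constant column are reported as NaN.
    """
    if len(burdens) < 3:
        raise ValidationError("need >= 3 samples for burden correlations")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    cols = list(BURDEN_TYPES)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            a = burdens[cols[i]].to_numpy(dtype=float)
            b = burdens[cols[j]].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            if method == "spearman":
                r, p = stats.spearmanr(a, b)
            else:
                r, p = stats.pearsonr(a, b)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def burdens_by_group(
    burdens: pd.DataFrame, labels: SubtypeAssignment, min_group: int = 2
) -> tuple[pd.DataFrame, pd.Series]:
    """Median/IQR of each burden type per subtype plus a Kruskal-Wallis
    p-value across subtypes; groups with fewer than ``min_group`` samples
    are excluded with a warning."""
    lab = labels.labels.reindex(burdens.index).dropna()
    sizes = lab.value_counts()
    small = sizes[sizes < min_group].index
    if len(small):
        logger.warning("burdens_by_group: excluding small groups %s", list(small))
        lab = lab[~lab.isin(small)]
    groups = sorted(lab.unique())
    rows = []
    pvals = {}
    for btype in BURDEN_TYPES:
        per_group = [
            burdens.loc[lab.index[lab == g], btype].to_numpy(dtype=float)
            for g in groups
        ]
        for g, vals in zip(groups, per_group):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"burden": btype, "group": g, "n": len(vals), "median": med,
                 "q1": q1, "q3": q3}
            )
        if len(groups) >= 2 and any(np.ptp(v) > 0 for v in per_group):
            _, p = stats.kruskal(*per_group)
            pvals[btype] = float(p)
        else:
            pvals[btype] = float("nan")
    return pd.DataFrame(rows), pd.Series(pvals, name="kruskal_p")
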