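import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from omicweave.association_survival import (
    bh_fdr,
    chi2_contingency,
    diff_expr_screen,
    fisher_exact_2x2,
    km_logrank,
    marker_analysis,
    mutation_spectrum,
    pairwise_logrank,
    silent_nonsilent_counts,
)
from omicweave.omics_io import (
    GeneMatrix,
    MutationTable,
    SubtypeAssignment,
    ValidationError,
)


class TestChi2Contingency:
    def test_independence_gives_zero(self):
        res = chi2_contingency([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_margins_preserved(self):
        res = chi2_contingency([[5, 10, 2], [8, 1, 9]])
        assert np.allclose(res.observed.sum(axis=1), res.expected.sum(axis=1))
        assert np.allclose(res.observed.sum(axis=0), res.expected.sum(axis=0))
        manual = ((res.observed - res.expected) ** 2 / res.expected).to_numpy().sum()
        assert res.chi2 == pytest.approx(manual)

    def test_df(self):
        res = chi2_contingency([[5, 10, 2], [8, 1, 9]])
        assert res.df == 2

    def test_drop_levels(self):
        obs = pd.DataFrame(
            [[5, 10], [8, 1], [2, 2]], index=["a", "b", "drop_me"], columns=["x", "y"]
        )
        res = chi2_contingency(obs, drop_levels=["drop_me"])
        assert list(res.observed.index) == ["a", "b"]
        with pytest.raises(ValidationError, match="not present"):
            chi2_contingency(obs, drop_levels=["nope"])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="zero margins"):
            chi2_contingency([[0, 0], [5, 5]])

    def test_low_expected_warning_counted(self):
        res = chi2_contingency([[1, 2], [3, 4]])
        assert res.n_low_expected == 4


class TestFisherExact:
    def fisher_oracle(self, table):
        """Full enumeration: sum P(tables with the same margins) whose
        hypergeometric probability <= that of the observed table."""
        (a, b), (c, d) = table
        r1, r2 = a + b, c + d
        c1 = a + c
        n = r1 + r2
        p_obs = hypergeom.pmf(a, n, r1, c1)
        total = 0.0
        for x in range(max(0, c1 - r2), min(r1, c1) + 1):
            p = hypergeom.pmf(x, n, r1, c1)
            if p <= p_obs * (1 + 1e-9):
                total += p
        return min(total, 1.0)

    def test_diagonal_table(self):
        orat, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)
        assert orat == np.inf

    def test_symmetric_table(self):
        _, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        _, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    def test_matches_enumeration_oracle(self):
        # every 2x2 table with margins <= 10
        for a, b, c, d in itertools.product(range(5), repeat=4):
            table = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(self.fisher_oracle(table), rel=1e-9), table

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestBH:
    def test_hand_computed(self):
        fdr = bh_fdr(np.array([0.001, 0.02, 0.9]))
        assert fdr == pytest.approx([0.003, 0.03, 0.9])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        f1 = bh_fdr(p)
        f2 = bh_fdr(np.minimum(p * 1.5, 1.0))
        assert (f2 >= f1 - 1e-12).all()

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        assert (bh_fdr(p) >= p - 1e-12).all()


def make_muts(rows):
    return MutationTable(
        pd.DataFrame(
            rows,
            columns=["sample_id", "gene_id", "variant_classification",
                     "is_silent", "is_intronic"],
        )
    )


class TestMutationSpectrum:
    def labels(self, n_a=50, n_b=50):
        lab = pd.Series(
            ["A"] * n_a + ["B"] * n_b,
            index=[f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
        )
        return SubtypeAssignment(lab)

    def test_strong_enrichment_flagged(self):
        rows = [(f"a{i}", "gene1", "Missense_Mutation", False, False) for i in range(30)]
        rows += [(f"b{0}", "gene2", "Missense_Mutation", False, False)]
        res = mutation_spectrum(make_muts(rows), self.labels(), ["A"], ["B"],
                                fdr_thresh=0.001)
        assert res.table.loc["gene1", "fisher_p"] < 1e-6
        assert "gene1" in res.flagged_genes

    def test_balanced_gene_p_one(self):
        rows = [(f"a{i}", "g", "Missense_Mutation", False, False) for i in range(5)]
        rows += [(f"b{i}", "g", "Missense_Mutation", False, False) for i in range(5)]
        res = mutation_spectrum(make_muts(rows), self.labels(), ["A"], ["B"])
        assert res.table.loc["g", "fisher_p"] == pytest.approx(1.0)

    def test_fdr_at_least_p(self):
        rng = np.random.default_rng(2)
        rows = []
        for gi in range(20):
            for s in rng.choice(100, size=rng.integers(1, 20), replace=False):
                prefix = "a" if s < 50 else "b"
                rows.append((f"{prefix}{s % 50}", f"g{gi}", "Missense_Mutation",
                             False, False))
        res = mutation_spectrum(make_muts(rows), self.labels(), ["A"], ["B"])
        assert (res.table["fdr_bh"] >= res.table["fisher_p"] - 1e-12).all()
        tot = len(res.group_a) + len(res.group_b)
        sums = res.table[["mut_a", "wt_a", "mut_b", "wt_b"]].sum(axis=1)
        assert (sums == tot).all()

    def test_empty_group_rejected(self):
        rows = [("a0", "g", "Missense_Mutation", False, False)]
        with pytest.raises(ValidationError):
            mutation_spectrum(make_muts(rows), self.labels(), ["A"], ["Z"])

    def test_silent_nonsilent_counts(self):
        rows = [
            ("s1", "g1", "Missense_Mutation", False, False),
            ("s1", "g2", "Silent", True, False),
            ("s1", "g3", "Intron", False, True),
            ("s2", "g1", "Silent", True, False),
        ]
        out = silent_nonsilent_counts(make_muts(rows))
        assert out.loc["s1", "n_nonsilent"] == 1
        assert out.loc["s1", "n_silent"] == 1  # intron not counted either way
        assert out.loc["s2", "n_silent"] == 1


def logrank_oracle(times, events, groups):
    """Brute-force two-group log-rank score test computed from first
    principles (hypergeometric moments at each distinct event time)."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    g_levels = sorted(df["g"].unique())
    assert len(g_levels) == 2
    O1 = E1 = V = 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        n1 = (at_risk["g"] == g_levels[0]).sum()
        d = ((at_risk["t"] == t) & (at_risk["e"] == 1)).sum()
        d1 = ((at_risk["t"] == t) & (at_risk["e"] == 1) & (at_risk["g"] == g_levels[0])).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        times = pd.Series([5, 10, 15, 5, 10, 15], index=list("abcdef"), dtype=float)
        events = pd.Series([1, 0, 1, 1, 0, 1], index=list("abcdef"))
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
        cmp = km_logrank(times, events, groups)
        assert cmp.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert cmp.logrank_p == pytest.approx(1.0)

    def test_no_events_rejected(self):
        idx = list("abcd")
        with pytest.raises(ValidationError, match="no events"):
            km_logrank(
                pd.Series([1.0, 2, 3, 4], index=idx),
                pd.Series([0, 0, 0, 0], index=idx),
                pd.Series(["x", "x", "y", "y"], index=idx),
            )

    def test_six_subject_toy_matches_bruteforce(self):
        idx = list("abcdef")
        times = pd.Series([3.0, 5, 7, 2, 9, 11], index=idx)
        events = pd.Series([1, 1, 0, 1, 1, 1], index=idx)
        groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=idx)
        cmp = km_logrank(times, events, groups)
        assert cmp.logrank_chi2 == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_random_data_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        idx = [f"s{i}" for i in range(n)]
        times = pd.Series(rng.exponential(10, n).round(3), index=idx)
        events = pd.Series(rng.integers(0, 2, n), index=idx)
        if events.sum() == 0:
            events.iloc[0] = 1
        groups = pd.Series(rng.choice(["x", "y"], n), index=idx)
        cmp = km_logrank(times, events, groups)
        assert cmp.logrank_chi2 == pytest.approx(
            logrank_oracle(times, events, groups), abs=1e-10
        )

    def test_km_curve_closed_form(self):
        idx = list("abcde")
        times = pd.Series([1.0, 2, 3, 4, 5], index=idx)
        events = pd.Series([1, 1, 0, 1, 1], index=idx)
        groups = pd.Series(["x"] * 5 + [], index=idx)
        groups2 = pd.Series(["x", "x", "x", "y", "y"], index=idx)
        cmp = km_logrank(times, events, groups2)
        curve = cmp.km_curves["x"].set_index("time")["survival"]
        # hand product-limit: events at t=1 (n=3), t=2 (n=2); censored at 3
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(2 / 3 * 1 / 2)
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()
        assert curve.iloc[0] <= 1.0

    def test_pairwise(self):
        rng = np.random.default_rng(5)
        n = 60
        idx = [f"s{i}" for i in range(n)]
        groups = pd.Series(np.repeat(["a", "b", "c"], n // 3), index=idx)
        haz = groups.map({"a": 1.0, "b": 4.0, "c": 1.0})
        times = pd.Series(rng.exponential(10 / haz), index=idx)
        events = pd.Series(np.ones(n, dtype=int), index=idx)
        pw = pairwise_logrank(times, events, groups)
        assert len(pw) == 3
        ab = pw[(pw.group_a == "a") & (pw.group_b == "b")]["p"].iloc[0]
        ac = pw[(pw.group_a == "a") & (pw.group_b == "c")]["p"].iloc[0]
        assert ab < 0.01 and ac > 0.05


class TestMarkerAnalysis:
    def build(self, small_sim):
        d = small_sim
        expr = d.expr_fpkm
        labels = SubtypeAssignment(d.truth.labels)
        return d, expr, labels

    def test_planted_met_driver_signature(self, small_sim):
        d, expr, labels = self.build(small_sim)
        gene = d.truth.met_driver_ids[0]
        rep = marker_analysis(
            gene, expr, d.gene_met, d.gene_cnv,
            d.clinical.df["os_time"], d.clinical.df["os_event"], labels,
        )
        assert rep.met_expr_rho < 0
        assert rep.met_expr_p < 0.01
        assert abs(rep.cnv_expr_rho) < 0.4 or np.isnan(rep.cnv_expr_rho)

    def test_absent_gene_errors(self, small_sim):
        d, expr, labels = self.build(small_sim)
        with pytest.raises(ValidationError, match="expression"):
            marker_analysis(
                "NOPE", expr, d.gene_met, d.gene_cnv,
                d.clinical.df["os_time"], d.clinical.df["os_event"], labels,
            )

    def test_constant_expression_errors(self, small_sim):
        d, expr, labels = self.build(small_sim)
        gene = d.truth.met_driver_ids[0]
        flat = GeneMatrix(
            "EXPR_FPKM",
            pd.DataFrame(
                np.ones((1, len(expr.sample_ids))), index=[gene],
                columns=expr.sample_ids,
            ),
        )
        with pytest.raises(ValidationError, match="median split"):
            marker_analysis(
                gene, flat, d.gene_met, d.gene_cnv,
                d.clinical.df["os_time"], d.clinical.df["os_event"], labels,
            )

    def test_median_ties_go_low(self, small_sim):
        d, expr, labels = self.build(small_sim)
        gene = d.truth.met_driver_ids[0]
        vals = np.full(len(expr.sample_ids), 1.0)
        vals[:10] = 5.0  # 10 high, rest exactly at the median
        tied = GeneMatrix(
            "EXPR_FPKM",
            pd.DataFrame(vals[None, :], index=[gene], columns=expr.sample_ids),
        )
        rep = marker_analysis(
            gene, tied, d.gene_met, d.gene_cnv,
            d.clinical.df["os_time"], d.clinical.df["os_event"], labels,
        )
        sizes = rep.km.groups.value_counts()
        assert sizes["high"] == 10
        assert sizes["low"] == len(expr.sample_ids) - 10


class TestDiffExprScreen:
    def matrix(self, arr, samples):
        return GeneMatrix(
            "EXPR_FPKM",
            pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                         columns=samples),
        )

    def labels(self, n_a, n_b):
        idx = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        return SubtypeAssignment(pd.Series(["A"] * n_a + ["B"] * n_b, index=idx)), idx

    def test_identical_distribution_not_flagged(self):
        labels, idx = self.labels(20, 20)
        rng = np.random.default_rng(0)
        arr = np.tile(rng.uniform(1, 5, size=(10, 20)), (1, 2))
        out = diff_expr_screen(self.matrix(arr, idx), labels, ["A"], ["B"])
        assert not out["passes"].any()

    def test_planted_fourfold_shift_flagged(self):
        labels, idx = self.labels(50, 50)
        rng = np.random.default_rng(1)
        arr = rng.uniform(10, 12, size=(20, 100))
        arr[0, :50] *= 4.0
        out = diff_expr_screen(self.matrix(arr, idx), labels, ["A"], ["B"])
        assert bool(out.loc["g0", "passes"])
        assert out.loc["g0", "log2fc"] > 1.5

    def test_null_false_positive_control(self):
        labels, idx = self.labels(30, 30)
        rng = np.random.default_rng(2)
        arr = rng.lognormal(2, 1, size=(1000, 60))
        out = diff_expr_screen(self.matrix(arr, idx), labels, ["A"], ["B"])
        assert out["passes"].mean() <= 0.05
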