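import itertools

import numpy as np
import pandas as pd
import pytest

from gutload import disruptors
from gutload.annotations import DISRUPTOR_SIGNATURE, builtin_annotations
from gutload.datamodel import ValidationError
from gutload.pipeline import quantify
from gutload.synthetic import CohortConfig, generate_cohort
from tests.conftest import make_abs_table


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, pvals[idx] * m / (rank + 1))
        q[idx] = min(running, 1.0)
    return q


class TestSpearmanBH:
    def _fixture(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        return pd.DataFrame({
            "a": x,
            "b": x + rng.normal(scale=0.3, size=60),
            "c": rng.normal(size=60),
            "d": -x + rng.normal(scale=0.5, size=60),
            "e": rng.normal(size=60),
        })

    def test_symmetry_diagonal_and_range(self):
        res = disruptors.spearman_bh(self._fixture())
        rho = res.rho.to_numpy()
        assert np.allclose(rho, rho.T, equal_nan=True)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.nanmax(np.abs(rho)) <= 1.0
        assert res.significant.equals(res.significant.T)

    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(1, 10, 30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        res = disruptors.spearman_bh(df)
        assert res.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_q_values_match_stepup_oracle(self):
        res = disruptors.spearman_bh(self._fixture())
        cols = res.variables
        pairs = list(itertools.combinations(range(len(cols)), 2))
        pvals = np.array([res.p.iloc[i, j] for i, j in pairs])
        expected = bh_oracle(pvals)
        observed = np.array([res.q.iloc[i, j] for i, j in pairs])
        np.testing.assert_allclose(observed, expected, rtol=1e-10)

    def test_constant_variable_reported_missing(self):
        df = self._fixture()
        df["const"] = 1.0
        res = disruptors.spearman_bh(df)
        assert np.isnan(res.rho.loc["const", "a"])
        assert not res.significant.loc["const", "a"]


class TestTopAbundant:
    def test_single_highest_mean(self):
        table = make_abs_table({"s1": {"big": 100.0, "small": 1.0},
                                "s2": {"big": 50.0, "small": 2.0}})
        assert disruptors.top_abundant_taxa(table, k=1) == ["big"]

    def test_scaling_invariance(self):
        table = make_abs_table({"s1": {"a": 3.0, "b": 2.0, "c": 1.0}})
        doubled = make_abs_table({"s1": {"a": 6.0, "b": 4.0, "c": 2.0}})
        assert disruptors.top_abundant_taxa(table, 3) == disruptors.top_abundant_taxa(doubled, 3)

    def test_tie_break_lexicographic(self):
        table = make_abs_table({"s1": {"zeta": 1.0, "alpha": 1.0}})
        assert disruptors.top_abundant_taxa(table, 2) == ["alpha", "zeta"]

    def test_k_too_large_errors(self):
        table = make_abs_table({"s1": {"a": 1.0}})
        with pytest.raises(ValidationError):
            disruptors.top_abundant_taxa(table, 2)


class TestMotifs:
    def test_total_load_tracker_is_motif_one(self):
        rng = np.random.default_rng(0)
        total = 10 ** rng.uniform(4, 8, 80)
        df = pd.DataFrame({
            "tracker": total * 0.3,
            "noise1": rng.normal(size=80),
            "noise2": rng.normal(size=80),
            "noise3": rng.normal(size=80),
            "noise4": rng.normal(size=80),
            disruptors.TOTAL_LOAD_VARIABLE: total,
        })
        res = disruptors.spearman_bh(df)
        motifs = disruptors.classify_motifs(res)
        assert motifs["tracker"] == "total_load_coupled"

    def test_coupled_pair_is_motif_two(self):
        rng = np.random.default_rng(1)
        pair = rng.normal(size=100)
        total = 10 ** rng.uniform(4, 8, 100)
        df = pd.DataFrame({
            "p1": pair + rng.normal(scale=0.1, size=100),
            "p2": pair + rng.normal(scale=0.1, size=100),
            "n1": 0.4 * np.log10(total) + rng.normal(scale=1.2, size=100),
            "n2": 0.4 * np.log10(total) + rng.normal(scale=1.2, size=100),
            disruptors.TOTAL_LOAD_VARIABLE: total,
        })
        res = disruptors.spearman_bh(df)
        motifs = disruptors.classify_motifs(res)
        assert motifs["p1"] == "pair_coupled"
        assert motifs["p2"] == "pair_coupled"

    def test_isolated_bloom_taxon_is_motif_three(self):
        """With co-blooms disabled, planted disruptors correlate with almost
        nothing and classify as mutually exclusive."""
        bundle = generate_cohort(
            CohortConfig(n_paired_saliva=0, co_bloom_probability=0.0), 3
        )
        duo = quantify(bundle.duodenum_counts, bundle.dpcr_records, seed=3)
        top = disruptors.top_abundant_taxa(duo.table, 20)
        res = disruptors.cocorrelation_matrix(duo.table, top)
        motifs = disruptors.classify_motifs(res)
        in_top = [t for t in DISRUPTOR_SIGNATURE if t in top]
        assert in_top, "no planted disruptor reached the top-20 list"
        exclusive = [t for t in in_top if motifs[t] == "mutually_exclusive"]
        assert len(exclusive) >= len(in_top) // 2


class TestDisruptorRank:
    def test_constant_taxon_scores_zero(self):
        table = make_abs_table({"s1": {"flat": 5.0, "x": 1.0},
                                "s2": {"flat": 5.0, "x": 9.0}})
        report = disruptors.disruptor_rank(table)
        assert report.scores["flat"] == 0.0

    def test_single_presence_closed_form(self):
        n, load = 5, 1000.0
        rows = {f"s{i}": {"rare": 0.0, "pad": 1.0} for i in range(n)}
        rows["s0"]["rare"] = load
        report = disruptors.disruptor_rank(make_abs_table(rows))
        assert report.scores["rare"] == pytest.approx(load * (1 - 1 / n))

    def test_absent_sample_increases_score(self):
        base = {"s1": {"t": 100.0, "pad": 1.0}, "s2": {"t": 0.0, "pad": 1.0}}
        more = dict(base, s3={"t": 0.0, "pad": 1.0})
        s_base = disruptors.disruptor_rank(make_abs_table(base)).scores["t"]
        s_more = disruptors.disruptor_rank(make_abs_table(more)).scores["t"]
        assert s_more > s_base

    def test_planted_disruptors_occupy_top_ranks(self, quantified):
        report = disruptors.disruptor_rank(quantified.table)
        assert len(set(report.top_k) & set(DISRUPTOR_SIGNATURE)) >= 7


class TestSignatureCluster:
    def test_anticorrelated_blocks_recovered(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=40)
        loads = {}
        for i in range(40):
            row = {}
            for j in range(3):
                row[f"up{j}"] = 100 * np.exp(z[i]) * (1 + 0.05 * rng.normal())
            for j in range(3):
                row[f"down{j}"] = 100 * np.exp(-z[i]) * (1 + 0.05 * rng.normal())
            loads[f"s{i}"] = row
        table = make_abs_table(loads)
        report = disruptors.disruptor_rank(table, top_k=6)
        clustered = disruptors.signature_cluster(report, table, {}, exclusions=())
        groups = {}
        for taxon, sig in clustered.signatures.items():
            groups.setdefault(sig, set()).add(taxon)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"up0", "up1", "up2"}), frozenset({"down0", "down1", "down2"})}

    def test_sample_and_taxon_order_invariance(self, cohort, quantified):
        table = quantified.table
        report = disruptors.disruptor_rank(table)
        ref = disruptors.signature_cluster(report, table, cohort.annotations)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.loads.index)
        shuffled = table.subset_samples(perm)
        shuffled.loads = shuffled.loads[rng.permutation(table.loads.columns)]
        report2 = disruptors.disruptor_rank(shuffled)
        out = disruptors.signature_cluster(report2, shuffled, cohort.annotations)
        assert set(out.candidate_set) == set(ref.candidate_set)
        assert set(out.final_set) == set(ref.final_set)

    def test_lactobacillus_excluded_from_final_set(self, cohort, quantified):
        report = disruptors.disruptor_rank(quantified.table)
        out = disruptors.signature_cluster(report, quantified.table, cohort.annotations)
        assert "Lactobacillus" in out.candidate_set
        assert "Lactobacillus" not in out.final_set
        assert set(out.final_set) == set(out.candidate_set) - {"Lactobacillus"}


class TestDifferentialVolcano:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.uniform(1, 100, (40, 4)),
                            index=[f"s{i}" for i in range(40)], columns=list("abcd"))
        data.iloc[20:] = data.iloc[:20].to_numpy()
        labels = pd.Series([True] * 20 + [False] * 20, index=data.index)
        res = disruptors.differential_volcano(data, labels)
        assert np.allclose(res["effect_log10_ratio"], 0.0)
        assert not res["significant"].any()

    def test_group_exclusive_taxon(self):
        rng = np.random.default_rng(3)
        n = 60
        data = pd.DataFrame({
            "only_a": np.r_[10 ** rng.uniform(4, 6, n // 2), np.zeros(n // 2)],
            "both": 10 ** rng.uniform(3, 5, n),
        }, index=[f"s{i}" for i in range(n)])
        labels = pd.Series([True] * (n // 2) + [False] * (n // 2), index=data.index)
        res = disruptors.differential_volcano(data, labels)
        assert res.loc["only_a", "effect_log10_ratio"] > 2
        assert res.loc["only_a", "p"] < 1e-6

    def test_kruskal_matches_hand_ranked_statistic(self):
        # groups {1, 3, 5} vs {2, 4}: ranks 1..5, H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
        a, b = [1.0, 3.0, 5.0], [2.0, 4.0]
        data = pd.DataFrame({"t": a + b}, index=[f"s{i}" for i in range(5)])
        labels = pd.Series([True, True, True, False, False], index=data.index)
        res = disruptors.differential_volcano(data, labels)
        from scipy import stats
        h_expected, p_expected = stats.kruskal(a, b)
        assert res.loc["t", "p"] == pytest.approx(p_expected)

    def test_empty_group_errors(self):
        data = pd.DataFrame({"t": [1.0, 2.0]}, index=["s1", "s2"])
        labels = pd.Series([True, True], index=data.index)
        with pytest.raises(ValidationError):
            disruptors.differential_volcano(data, labels)
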