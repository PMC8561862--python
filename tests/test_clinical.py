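import itertools

import numpy as np
import pandas as pd
import pytest

from gutload import clinical
from gutload.annotations import DEFAULT_DISRUPTOR_EXCLUSIONS, DISRUPTOR_SIGNATURE
from gutload.datamodel import QPCRRecord, SampleRecord, ValidationError
from tests.conftest import make_abs_table

FINAL_SET = [t for t in DISRUPTOR_SIGNATURE if t not in DEFAULT_DISRUPTOR_EXCLUSIONS]


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def record(sid, cfu=None, symptoms=None):
    return SampleRecord(sample_id=sid, subject_id=f"p_{sid}", site="duodenum",
                        aerobic_cfu_per_ml=cfu, symptom_scores=symptoms or {})


class TestClassifySibo:
    def _table(self, loads):
        return make_abs_table({s: {"Enterobacteriaceae": v, "pad": 1.0}
                               for s, v in loads.items()})

    def test_culture_threshold_inclusive(self):
        table = self._table({"s1": 0.0})
        calls = clinical.classify_sibo([record("s1", cfu=1e3)], table, ["Enterobacteriaceae"])
        assert calls.calls[0].by_culture is True
        calls = clinical.classify_sibo([record("s1", cfu=999.9)], table, ["Enterobacteriaceae"])
        assert calls.calls[0].by_culture is False

    def test_zero_disruptor_load_is_negative(self):
        table = self._table({"s1": 0.0})
        calls = clinical.classify_sibo([record("s1", cfu=10.0)], table, ["Enterobacteriaceae"])
        assert calls.calls[0].by_disruptor is False

    def test_threshold_limits(self):
        table = self._table({"s1": 500.0, "s2": 0.0})
        recs = [record("s1", cfu=1.0), record("s2", cfu=1.0)]
        inf_calls = clinical.classify_sibo(recs, table, ["Enterobacteriaceae"],
                                           load_threshold=np.inf)
        assert all(not c.by_disruptor for c in inf_calls.calls)
        tiny_calls = clinical.classify_sibo(recs, table, ["Enterobacteriaceae"],
                                            load_threshold=1e-12)
        assert [c.by_disruptor for c in tiny_calls.calls] == [True, False]

    def test_empty_disruptor_set_errors(self):
        with pytest.raises(ValidationError):
            clinical.classify_sibo([record("s1")], self._table({"s1": 1.0}), [])

    def test_cohort_agreement_above_chance(self, cohort, quantified):
        calls = clinical.classify_sibo(cohort.sample_records, quantified.table, FINAL_SET)
        assert calls.agreement is not None and calls.agreement > 0.8
        p = clinical.agreement_permutation_p(calls, n_permutations=500, seed=0)
        assert p < 0.05


class TestROC:
    def test_perfect_separation(self):
        scores = pd.Series([0.1, 0.2, 0.8, 0.9], index=list("abcd"))
        labels = pd.Series([False, False, True, True], index=list("abcd"))
        _, auc = clinical.roc_curve(scores, labels)
        assert auc == 1.0

    def test_four_point_toy(self):
        scores = pd.Series([0.9, 0.8, 0.7, 0.1], index=list("abcd"))
        labels = pd.Series([True, False, True, False], index=list("abcd"))
        _, auc = clinical.roc_curve(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            scores = rng.integers(0, 6, 40).astype(float)  # heavy ties
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            s = pd.Series(scores, index=[f"s{i}" for i in range(40)])
            l = pd.Series(labels, index=s.index)
            _, auc = clinical.roc_curve(s, l)
            assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(9)
        aucs = []
        for _ in range(30):
            scores = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
            labels = pd.Series(rng.random(60) < 0.5, index=scores.index)
            if labels.nunique() < 2:
                continue
            aucs.append(clinical.roc_curve(scores, labels)[1])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_errors(self):
        scores = pd.Series([0.1, 0.9], index=list("ab"))
        with pytest.raises(ValidationError):
            clinical.roc_curve(scores, pd.Series([True, True], index=list("ab")))

    def test_disruptor_load_separates_culture_sibo(self, cohort, quantified):
        calls = clinical.classify_sibo(cohort.sample_records, quantified.table, FINAL_SET)
        frame = calls.frame().dropna(subset=["by_culture"])
        _, auc = clinical.roc_curve(frame["disruptor_load"], frame["by_culture"].astype(bool))
        assert auc > 0.9


class TestSymptoms:
    def test_identical_scores_nobody_severe(self):
        recs = [record(f"s{i}", symptoms={"bloating": 50.0}) for i in range(5)]
        severe, medians = clinical.binarize_symptoms(recs)
        assert medians["bloating"] == 50.0
        assert not severe["severe_bloating"].any()

    def test_strictly_above_median_is_severe(self):
        recs = [record(f"s{i}", symptoms={"bloating": v}) for i, v in enumerate([0.0, 50.0, 100.0])]
        severe, _ = clinical.binarize_symptoms(recs)
        assert severe["severe_bloating"].tolist() == [False, False, True]

    def test_severe_fraction_at_most_half(self):
        rng = np.random.default_rng(10)
        recs = [record(f"s{i}", symptoms={"bloating": float(v), "diarrhea": float(w)})
                for i, (v, w) in enumerate(zip(rng.uniform(0, 100, 101), rng.uniform(0, 100, 101)))]
        severe, _ = clinical.binarize_symptoms(recs)
        for col in ["severe_bloating", "severe_diarrhea"]:
            assert severe[col].mean() <= 0.5

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(11)
        raw = rng.uniform(0, 100, 40)
        recs = [record(f"s{i}", symptoms={"bloating": float(v)}) for i, v in enumerate(raw)]
        rescaled = [record(f"s{i}", symptoms={"bloating": float(v**0.5 * 10)})
                    for i, v in enumerate(raw)]
        a, _ = clinical.binarize_symptoms(recs)
        b, _ = clinical.binarize_symptoms(rescaled)
        assert a["severe_count"].tolist() == b["severe_count"].tolist()


class TestSymptomBurden:
    def test_all_zero_load_asymptomatic(self):
        load = pd.Series({"s1": 0.0, "s2": 0.0})
        count = pd.Series({"s1": 0, "s2": 0})
        out = clinical.symptom_burden_by_disruptor_bin(load, count)
        assert out.loc["zero", "pct_zero"] == 100.0
        assert out.loc["zero", "n"] == 2

    def test_percentages_sum_to_hundred(self, cohort, quantified):
        severe, _ = clinical.binarize_symptoms(
            [r for r in cohort.sample_records if r.symptom_scores])
        load = clinical.disruptor_loads(quantified.table, FINAL_SET)
        shared = severe.index.intersection(load.index)
        out = clinical.symptom_burden_by_disruptor_bin(load.loc[shared],
                                                       severe.loc[shared, "severe_count"])
        filled = out[out["n"] > 0]
        np.testing.assert_allclose(
            filled[["pct_zero", "pct_mid", "pct_high"]].sum(axis=1), 100.0)

    def test_severe_burden_rises_with_disruptor_load(self, cohort, quantified):
        """The generator links severe-symptom probability to disruptor load, so
        the high-burden share climbs from the zero-load bin to the top bins."""
        severe, _ = clinical.binarize_symptoms(
            [r for r in cohort.sample_records if r.symptom_scores])
        load = clinical.disruptor_loads(quantified.table, FINAL_SET)
        shared = severe.index.intersection(load.index)
        out = clinical.symptom_burden_by_disruptor_bin(load.loc[shared],
                                                       severe.loc[shared, "severe_count"])
        filled = out[out["n"] >= 5]
        assert filled["pct_high"].iloc[-1] > filled["pct_high"].loc["zero"]
        ranks = np.arange(len(filled))
        from scipy import stats
        assert stats.spearmanr(ranks, filled["pct_high"])[0] > 0.5


class TestCountTrend:
    def test_single_group_no_test(self):
        counts = pd.Series({"s1": 0, "s2": 0})
        loads = pd.Series({"s1": 1e5, "s2": 1e6})
        summary, p = clinical.disruptor_count_load_trend(counts, loads)
        assert p is None
        assert summary.loc[0, "n"] == 2

    def test_strict_per_taxon_threshold_enumeration(self):
        table = make_abs_table({
            "s1": {"Enterobacteriaceae": 1e4, "Enterococcus": 2e4, "pad": 1.0},
            "s2": {"Enterobacteriaceae": 1e4 + 1, "Enterococcus": 0.0, "pad": 1.0},
        })
        counts = clinical.disruptor_counts(table, ["Enterobacteriaceae", "Enterococcus"])
        # strict > 1e4: s1 counts only Enterococcus; the boundary value does not count
        assert counts["s1"] == 1
        assert counts["s2"] == 1

    def test_blooms_raise_total_load(self, cohort, quantified):
        counts = clinical.disruptor_counts(quantified.table, FINAL_SET)
        _, p = clinical.disruptor_count_load_trend(counts, quantified.table.total_loads)
        assert p is not None and p < 0.01


class TestKlebsiella:
    def test_constructed_one_to_one(self):
        loads = {}
        qpcr = []
        for i, e in enumerate([1e6, 1e7, 1e8, 3e6, 3e7]):
            sid = f"s{i}"
            loads[sid] = {"Enterobacteriaceae": e, "pad": 1.0}
            # Klebsiella genomes equal Enterobacteriaceae genomes (16S/8)
            genomes_per_ml = e / 8
            conc = genomes_per_ml * 1.0 / 100.0
            cq = 22.4 - np.log2(conc / 1000.0)
            qpcr.append(QPCRRecord(sample_id=sid, cq=float(cq), dilution_factor=1.0,
                                   extract_volume=100.0, collected_sample_volume=1.0))
        res = clinical.klebsiella_analysis(make_abs_table(loads), qpcr)
        assert res.pearson_r == pytest.approx(1.0)
        np.testing.assert_allclose(res.paired["klebsiella_genomes"],
                                   res.paired["entero_genomes"], rtol=1e-6)

    def test_no_amplification_counts_in_detection_fraction(self):
        loads = {f"s{i}": {"Enterobacteriaceae": 1e6, "pad": 1.0} for i in range(4)}
        qpcr = [QPCRRecord(sample_id=f"s{i}", cq=(20.0 if i < 3 else None),
                           collected_sample_volume=1.0) for i in range(4)]
        res = clinical.klebsiella_analysis(make_abs_table(loads), qpcr)
        assert res.n_tested == 4 and res.n_detected == 3
        assert res.detection_fraction == pytest.approx(0.75)

    def test_trigger_excludes_low_entero_samples(self):
        loads = {"hi": {"Enterobacteriaceae": 1e6, "pad": 1.0},
                 "lo": {"Enterobacteriaceae": 1e4, "pad": 1.0}}
        qpcr = [QPCRRecord(sample_id=s, cq=20.0, collected_sample_volume=1.0)
                for s in loads]
        res = clinical.klebsiella_analysis(make_abs_table(loads), qpcr)
        assert res.n_tested == 1

    def test_synthetic_subcohort_recovers_fixed_fraction(self, cohort, quantified):
        res = clinical.klebsiella_analysis(quantified.table, cohort.qpcr_records)
        assert res.pearson_r > 0.8
        assert 0 < res.detection_fraction <= 1


class TestSubgroupTests:
    def test_identical_groups_large_p(self):
        rng = np.random.default_rng(12)
        loads = pd.Series(rng.uniform(1, 100, 40), index=[f"s{i}" for i in range(40)])
        flags = pd.DataFrame({"flag": [True, False] * 20}, index=loads.index)
        loads[flags.index[flags["flag"]]] = loads[flags.index[~flags["flag"]]].to_numpy()
        out = clinical.subgroup_load_tests(loads, flags)
        assert out.loc["flag", "p"] > 0.5

    def test_shifted_groups_small_p(self):
        rng = np.random.default_rng(13)
        base = 10 ** rng.normal(6, 1, 200)
        loads = pd.Series(base, index=[f"s{i}" for i in range(200)])
        flags = pd.DataFrame({"flag": [True] * 100 + [False] * 100}, index=loads.index)
        loads.iloc[:100] *= 30
        out = clinical.subgroup_load_tests(loads, flags)
        assert out.loc["flag", "p"] < 1e-4
        assert out.loc["flag", "median_true"] > out.loc["flag", "median_false"]
        assert out.loc["flag", "n_true"] == 100

    def test_single_level_flag_skipped(self):
        loads = pd.Series({"s1": 1.0, "s2": 2.0})
        flags = pd.DataFrame({"allsame": [True, True]}, index=loads.index)
        out = clinical.subgroup_load_tests(loads, flags)
        assert np.isnan(out.loc["allsame", "p"])
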