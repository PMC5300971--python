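"""Tests of frequency matrices, stratification and maturation summaries."""

import numpy as np
import pandas as pd
import pytest

import nkstrat as nk
from nkstrat import synthetic as syn
from nkstrat.cohort import split_sample_id
from nkstrat.metacluster import Metacluster

MARKERS = list(nk.DEFAULT_PANEL.nk_markers)


def make_metas(spec):
    """spec: list of (id, name, retained, [(sample, cluster), ...])."""
    return [
        Metacluster(
            id=i, members=list(members), signature=dict.fromkeys(MARKERS, 0.0),
            name=name, retained=retained,
        )
        for i, name, retained, members in spec
    ]


def make_table(rows):
    """rows: list of (sample_id, cluster_id, event_count)."""
    return pd.DataFrame(
        [
            {"sample_id": s, "cluster_id": c,
             **dict.fromkeys(MARKERS, 0.0), "event_count": n}
            for s, c, n in rows
        ]
    )


class TestPopulationFrequencies:
    def test_single_population_is_100(self):
        table = make_table([("p1_T0", 0, 80), ("p1_T0", 1, 20)])
        metas = make_metas([(0, "A", True, [("p1_T0", 0), ("p1_T0", 1)])])
        fm = nk.population_frequencies(table, metas)
        assert fm.frequencies.loc["p1_T0", "A"] == 100.0

    def test_simple_arithmetic(self):
        table = make_table(
            [("p1_T0", 0, 25), ("p1_T0", 1, 25), ("p1_T0", 2, 50)]
        )
        metas = make_metas(
            [
                (0, "A", True, [("p1_T0", 0)]),
                (1, "B", True, [("p1_T0", 1)]),
                (2, "C", True, [("p1_T0", 2)]),
            ]
        )
        fm = nk.population_frequencies(table, metas)
        assert list(fm.frequencies.loc["p1_T0", ["A", "B", "C"]]) == [25, 25, 50]

    def test_same_name_metaclusters_pool_additively(self):
        table = make_table([("p1_T0", 0, 30), ("p1_T0", 1, 20), ("p1_T0", 2, 50)])
        split = make_metas(
            [
                (0, "A", True, [("p1_T0", 0)]),
                (1, "A", True, [("p1_T0", 1)]),
                (2, "B", True, [("p1_T0", 2)]),
            ]
        )
        merged = make_metas(
            [
                (0, "A", True, [("p1_T0", 0), ("p1_T0", 1)]),
                (2, "B", True, [("p1_T0", 2)]),
            ]
        )
        fm_split = nk.population_frequencies(table, split)
        fm_merged = nk.population_frequencies(table, merged)
        pd.testing.assert_frame_equal(fm_split.frequencies, fm_merged.frequencies)

    def test_unretained_mass_stays_in_denominator(self):
        table = make_table([("p1_T0", 0, 90), ("p1_T0", 1, 10)])
        metas = make_metas(
            [
                (0, "A", True, [("p1_T0", 0)]),
                (1, "rare", False, [("p1_T0", 1)]),
            ]
        )
        fm = nk.population_frequencies(table, metas)
        assert fm.frequencies.loc["p1_T0", "A"] == 90.0
        assert np.isclose(fm.unassigned_pct()["p1_T0"], 10.0)

    def test_empty_sample_flagged(self):
        table = make_table([("p1_T0", 0, 0), ("p2_T0", 0, 50)])
        metas = make_metas(
            [(0, "A", True, [("p1_T0", 0), ("p2_T0", 0)])]
        )
        fm = nk.population_frequencies(table, metas)
        assert fm.empty_samples == ["p1_T0"]
        assert np.isnan(fm.frequencies.loc["p1_T0", "A"])

    def test_uncovered_cluster_rejected(self):
        table = make_table([("p1_T0", 0, 10)])
        with pytest.raises(ValueError, match="not covered"):
            nk.population_frequencies(table, [])


class TestExcludeRare:
    def _fm(self, means):
        freq = pd.DataFrame(
            {f"pop{i}": [m, m] for i, m in enumerate(means)},
            index=["p1_T0", "p2_T0"],
        )
        return nk.FrequencyMatrix(
            frequencies=freq,
            total_events=pd.Series(100, index=freq.index),
            empty_samples=[],
        )

    def test_13_to_12(self):
        fm = self._fm([10.0] * 12 + [0.3])
        out = nk.exclude_rare_populations(fm)
        assert len(out.populations) == 12
        assert "pop12" not in out.populations

    def test_zero_threshold_drops_nothing(self):
        fm = self._fm([5.0, 0.01])
        out = nk.exclude_rare_populations(fm, threshold=0.0)
        assert out.populations == fm.populations

    def test_boundary_is_strict(self):
        fm = self._fm([5.0, 0.5])
        out = nk.exclude_rare_populations(fm, threshold=0.5)
        assert "pop1" in out.populations

    def test_all_dropped_is_error(self):
        fm = self._fm([0.1, 0.2])
        with pytest.raises(ValueError):
            nk.exclude_rare_populations(fm, threshold=50.0)


class TestStratify:
    def test_zero_noise_exact_recovery(self):
        rows, labels = [], {}
        vectors = {"X": [30.0, 5.0, 10.0], "Y": [10.0, 25.0, 8.0], "Z": [8.0, 5.0, 40.0]}
        cols = [syn.P_A, syn.P_57, syn.P_TN]
        for g, v in vectors.items():
            for i in range(5):
                pid = f"{g}{i}"
                rows.append(pd.Series(dict(zip(cols, v)), name=pid))
                labels[pid] = g
        freq = pd.DataFrame(rows)
        grouping = nk.stratify_patients(freq, n_groups=3)
        assert grouping.labels_named
        assert grouping.assignments == labels

    def test_invariant_to_row_and_column_order(self, rng, pipeline_result):
        t0 = pipeline_result.frequencies.timepoint_view("T0")
        t0 = t0.loc[[p for p in t0.index if not p.startswith("HD")]]
        g1 = nk.stratify_patients(t0, 3)
        shuffled = t0.sample(frac=1, random_state=1)[
            list(t0.columns[::-1])
        ]
        g2 = nk.stratify_patients(shuffled, 3)
        assert g1.assignments == g2.assignments

    def test_recovers_planted_groups(self, pipeline_result, truth_grouping):
        from sklearn.metrics import adjusted_rand_score

        assign = pipeline_result.grouping.assignments
        patients = sorted(assign)
        ari = adjusted_rand_score(
            [truth_grouping[p] for p in patients],
            [assign[p] for p in patients],
        )
        assert ari >= 0.8

    def test_too_few_patients_rejected(self):
        freq = pd.DataFrame({"A": [1.0, 2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError):
            nk.stratify_patients(freq, n_groups=3)


class TestMaturation:
    def test_cd57_additivity(self):
        freq = pd.DataFrame(
            {syn.P_57: [40.0], syn.P_C57: [10.0], syn.P_A: [50.0]},
            index=["p1_T0"],
        )
        out = nk.maturation_summary(freq)
        assert out.loc["p1_T0", "cd57_total"] == 50.0
        assert out.loc["p1_T0", "Mature"] == 50.0
        assert out.loc["p1_T0", "Effectors"] == 50.0

    def test_empty_category_is_zero(self):
        freq = pd.DataFrame({syn.P_A: [100.0]}, index=["p1_T0"])
        out = nk.maturation_summary(freq)
        assert out.loc["p1_T0", "Progenitors"] == 0.0

    def test_unmapped_population_rejected_by_name(self):
        freq = pd.DataFrame({"mystery population": [10.0]}, index=["p1_T0"])
        with pytest.raises(ValueError, match="mystery population"):
            nk.maturation_summary(freq)

    def test_m3_shift_recovered(self, small_cohort, truth_grouping):
        """Planted CD57+ kinetics: group X summed CD57+ rises by the
        configured shift between T0 and M3 (checked on planted truth)."""
        truth = small_cohort.truth_frequencies
        cd57_cols = [p for p in syn.DEFAULT_PHENOTYPE_NAMES if "CD57+" in p]
        x_patients = [p for p, g in truth_grouping.items() if g == "X"]
        med = {}
        for tp in ("T0", "M3"):
            rows = truth[(truth["timepoint"] == tp)
                         & truth["patient_id"].isin(x_patients)]
            med[tp] = rows[cd57_cols].sum(axis=1).median()
        shift = small_cohort.config.m3_shift["X"]
        assert med["M3"] - med["T0"] == pytest.approx(shift, abs=2.5)


class TestSuppression:
    def _meta(self, values):
        return pd.DataFrame(
            [
                {"patient_id": p, "timepoint": "M3", "hiv_rna": v}
                for p, v in values.items()
            ]
        )

    def test_seven_of_ten_is_70pct(self):
        values = {f"p{i}": (1.4 if i < 7 else 2.5) for i in range(10)}
        meta = self._meta(values)
        table = nk.suppression_table(meta, dict.fromkeys(values, "Y"))
        row = table.set_index("group").loc["Y"]
        assert (row["n_suppressed"], row["n"], row["pct"]) == (7, 10, 70.0)

    def test_one_of_four_is_25pct(self):
        values = {"a": 1.4, "b": 2.0, "c": 2.1, "d": 3.0}
        table = nk.suppression_table(self._meta(values), dict.fromkeys(values, "Z"))
        assert table.set_index("group").loc["Z", "pct"] == 25.0

    def test_zero_of_n_is_0pct(self):
        values = {"a": 2.4, "b": 2.0}
        table = nk.suppression_table(self._meta(values), dict.fromkeys(values, "X"))
        assert table.set_index("group").loc["X", "pct"] == 0.0

    def test_combined_groups(self):
        values = {"a": 1.4, "b": 2.0, "c": 1.3, "d": 3.0}
        grouping = {"a": "X", "b": "X", "c": "Z", "d": "Z"}
        table = nk.suppression_table(
            self._meta(values), grouping, combine={"X+Z": ["X", "Z"]}
        )
        row = table.set_index("group").loc["X+Z"]
        assert (row["n_suppressed"], row["n"], row["pct"]) == (2, 4, 50.0)


class TestConservation:
    def test_named_plus_unassigned_mass_is_100(self, pipeline_result):
        fm = pipeline_result.frequencies_all
        sums = fm.frequencies.sum(axis=1) + fm.unassigned_pct()
        computed = sums.dropna()
        np.testing.assert_allclose(computed, 100.0, atol=1e-9)

    def test_total_events_match_gated_counts(self, small_cohort, pipeline_result):
        for sample in small_cohort.samples:
            sid = sample.sample_id
            if sid in pipeline_result.failed_samples:
                continue
            gate = nk.gate_nk(sample, small_cohort.gate_thresholds)
            assert pipeline_result.frequencies.total_events[sid] == gate.n_kept


def test_split_sample_id():
    assert split_sample_id("P01_T0") == ("P01", "T0")
    with pytest.raises(ValueError):
        split_sample_id("noseparator")
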