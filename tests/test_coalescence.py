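import numpy as np
import pandas as pd
import pytest

from coalescekit.coalescence import (
    classify_coalescence,
    concordant_dominations,
    detect_dominations,
    intra_patient_pairs,
    oral_taxa_site_comparison,
    pair_distances,
    shared_unique_ratio,
)
from coalescekit.data_io import TaxonomyMap
from coalescekit.diversity import DistanceMatrix, bray_curtis
from conftest import make_table


def pairs_frame(minima, n_pairs=3):
    """Synthetic per-patient pair lists whose minima are the given values."""
    rows = []
    for i, m in enumerate(minima):
        pid = f"p{i:03d}"
        for k in range(n_pairs):
            rows.append(
                {
                    "patient_id": pid,
                    "oral_sample": f"{pid}_o{k}",
                    "stool_sample": f"{pid}_s{k}",
                    "oral_day": k,
                    "stool_day": k + 1,
                    "distance": m + 0.2 * k,
                }
            )
    return pd.DataFrame(rows)


class TestIntraPatientPairs:
    def _table_and_dm(self):
        counts = np.ones((5, 3), dtype=int)
        table = make_table(
            counts,
            sites=["oral", "oral", "oral", "stool", "stool"],
            patients=["p1"] * 5,
            days=[0, 3, 6, 0, 3],
        )
        rng = np.random.default_rng(0)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        return table, DistanceMatrix(v, table.sample_ids)

    def test_three_by_two_gives_six_pairs(self):
        table, d = self._table_and_dm()
        pairs = intra_patient_pairs(table, d)
        assert len(pairs) == 6

    def test_distances_equal_matrix_lookup(self):
        table, d = self._table_and_dm()
        pairs = intra_patient_pairs(table, d)
        for _, row in pairs.iterrows():
            assert row["distance"] == d[row["oral_sample"], row["stool_sample"]]

    def test_single_site_patient_has_no_pairs(self):
        table = make_table(np.ones((2, 3), dtype=int), sites=["oral", "oral"])
        v = np.array([[0, 0.5], [0.5, 0]])
        pairs = intra_patient_pairs(table, DistanceMatrix(v, table.sample_ids))
        assert pairs.empty

    def test_pair_distances_matches_global_matrix(self, small_cohort):
        _, cohort = small_cohort
        sub_ids = [s for s in cohort.table.sample_ids
                   if cohort.table.meta.loc[s, "patient_id"] in cohort.table.patients[:4]]
        table = cohort.table.subset_samples(sub_ids)
        d_global = bray_curtis(table)
        expected = intra_patient_pairs(table, d_global)
        got = pair_distances(table, metric="braycurtis")
        merged = expected.merge(got, on=["patient_id", "oral_sample", "stool_sample"],
                                suffixes=("_a", "_b"))
        assert len(merged) == len(expected)
        np.testing.assert_allclose(merged["distance_a"], merged["distance_b"], atol=1e-12)


class TestClassifier:
    def test_92_eligible_yields_23_coalesced(self):
        rng = np.random.default_rng(1)
        minima = rng.permutation(np.linspace(0.005, 0.6, 92))
        calls = classify_coalescence(pairs_frame(minima))
        assert int(calls["eligible"].sum()) == 92
        assert int(calls["coalesced"].sum()) == 23

    def test_8_patients_two_smallest_coalesce(self):
        minima = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        calls = classify_coalescence(pairs_frame(minima))
        coal = calls[calls["coalesced"]].sort_values("min_distance")
        assert len(coal) == 2
        np.testing.assert_allclose(coal["min_distance"], [0.1, 0.2])

    def test_insufficient_pairs_marks_ineligible(self):
        pairs = pairs_frame([0.1, 0.2, 0.3, 0.4, 0.5])
        pairs = pairs[~((pairs["patient_id"] == "p000") & (pairs["oral_day"] > 1))]
        calls = classify_coalescence(pairs, min_pairs=3)
        row = calls[calls["patient_id"] == "p000"].iloc[0]
        assert not row["eligible"] and not row["coalesced"]
        assert "2 pairs" in row["exclusion_reason"]
        assert int(calls["eligible"].sum()) == 4

    def test_fewer_than_four_eligible_is_an_error(self):
        with pytest.raises(ValueError, match="quartile"):
            classify_coalescence(pairs_frame([0.1, 0.2, 0.3]))

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        pairs = pairs_frame(rng.random(12))
        shuffled = pairs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = classify_coalescence(pairs).reset_index(drop=True)
        b = classify_coalescence(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_ranks_are_permutation_and_event_day_is_later_day(self):
        calls = classify_coalescence(pairs_frame([0.4, 0.1, 0.3, 0.2]))
        assert sorted(calls["rank"]) == [1, 2, 3, 4]
        # minimizing pair is k=0 with oral_day 0, stool_day 1
        assert set(calls["event_day"]) == {1}

    def test_tie_break_prefers_earlier_event_day_then_id(self):
        rows = []
        for pid, days in (("pB", (5, 6)), ("pA", (1, 2)), ("pC", (1, 2))):
            for k in range(3):
                rows.append({"patient_id": pid, "oral_sample": f"{pid}o{k}",
                             "stool_sample": f"{pid}s{k}", "oral_day": days[0] + k,
                             "stool_day": days[1] + k, "distance": 0.1 if k == 0 else 0.5})
        for k in range(3):
            rows.append({"patient_id": "pD", "oral_sample": f"Do{k}", "stool_sample": f"Ds{k}",
                         "oral_day": k, "stool_day": k, "distance": 0.9})
        calls = classify_coalescence(pd.DataFrame(rows)).set_index("patient_id")
        # three patients tie at 0.1; earlier event day wins, then id
        assert calls.loc["pA", "rank"] == 1
        assert calls.loc["pC", "rank"] == 2
        assert calls.loc["pB", "rank"] == 3
        assert bool(calls.loc["pA", "coalesced"]) and not bool(calls.loc["pC", "coalesced"])


class TestSharedUniqueRatio:
    def _paired_table(self, oral_counts, stool_counts):
        return make_table(
            np.array([oral_counts, stool_counts]),
            sites=["oral", "stool"],
            days=[4, 5],
            otu_ids=list("ABCDE"),
        )

    def test_set_arithmetic_example(self):
        # oral {A,B,C}, stool {B,C,D,E} -> shared 2, unique 3
        t = self._paired_table([1, 2, 3, 0, 0], [0, 1, 1, 4, 2])
        out = shared_unique_ratio(t)
        row = out.iloc[0]
        assert (row["shared"], row["unique"]) == (2, 3)
        assert row["ratio"] == pytest.approx(2 / 3)

    def test_identical_presence_sets_flagged_undefined(self):
        t = self._paired_table([1, 2, 0, 0, 0], [5, 9, 0, 0, 0])
        row = shared_unique_ratio(t).iloc[0]
        assert not row["defined"] and np.isnan(row["ratio"])

    def test_disjoint_sets_ratio_zero(self):
        t = self._paired_table([1, 1, 0, 0, 0], [0, 0, 2, 2, 2])
        assert shared_unique_ratio(t).iloc[0]["ratio"] == 0.0

    def test_window_excludes_distant_days(self):
        t = make_table(
            np.ones((2, 3), dtype=int), sites=["oral", "stool"], days=[0, 10]
        )
        assert shared_unique_ratio(t, window=3).empty
        assert len(shared_unique_ratio(t, window=10)) == 1


class TestDominations:
    tax = TaxonomyMap(
        {
            "o0": "B;F;Bac;L;S;Streptococcus",
            "o1": "B;F;Bac;L;S;Streptococcus",
            "o2": "B;B;Bacteroidia;B;B;Bacteroides",
            "o3": "B",  # unclassified at genus level
        }
    )

    def test_exact_threshold_is_not_an_event(self):
        t = make_table([[30, 0, 70, 0]], sites=["oral"])
        events = detect_dominations(t, self.tax, threshold=0.30)
        assert set(events["genus"]) == {"Bacteroides"}

    def test_concordant_domination_across_sites(self):
        t = make_table(
            [[52, 0, 20, 28], [61, 0, 10, 29]],
            sites=["oral", "stool"],
            days=[7, 10],
        )
        events = detect_dominations(t, self.tax)
        conc = concordant_dominations(events)
        assert list(conc["genus"]) == ["Streptococcus"]

    def test_unclassified_never_dominates(self):
        t = make_table([[0, 0, 10, 90]], sites=["oral"])
        events = detect_dominations(t, self.tax)
        assert "unclassified" not in set(events["genus"])

    def test_at_most_three_events_per_sample(self):
        rng = np.random.default_rng(3)
        tax = TaxonomyMap({f"o{j}": f"B;F;C;O;Fam;G{j}" for j in range(6)})
        for _ in range(30):
            t = make_table(rng.integers(0, 100, size=(1, 6)) + 1, sites=["oral"])
            events = detect_dominations(t, tax)
            assert len(events) <= 3


class TestSiteComparison:
    def test_record_bookkeeping(self, small_cohort):
        _, cohort = small_cohort
        sub = cohort.table.subset_samples(cohort.table.sample_ids[:40])
        records = oral_taxa_site_comparison(sub, cohort.taxonomy, ["Streptococcus"])
        assert set(records["timepoint"]) <= {1, 2, 3, 4}
        counted = records.groupby(["patient_id", "site"]).size()
        assert (counted <= 4).all()

    def test_unknown_genus_skipped_with_warning(self, small_cohort, caplog):
        import logging

        _, cohort = small_cohort
        sub = cohort.table.subset_samples(cohort.table.sample_ids[:10])
        with caplog.at_level(logging.WARNING):
            records = oral_taxa_site_comparison(sub, cohort.taxonomy, ["NotAGenus"])
        assert records.empty
        assert "NotAGenus" in caplog.text
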