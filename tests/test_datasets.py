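"""Curation funnel: filtering, partition, deduplication, labeling,
censored augmentation, decoy balancing and whole-funnel invariants."""

import numpy as np
import pandas as pd
import pytest

from cdk9screen import datasets as D


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["compound_id", "smiles", "activity_type", "relation", "value", "units"]
    )


class TestCuration:
    def test_exact_and_censored_routing(self):
        table = make_table(
            [
                ("a", "CCO", "IC50", "=", 500.0, "nM"),
                ("b", "CCN", "IC50", ">", 10.0, "uM"),
            ]
        )
        exact, censored, rejects = D.curate_records(table)
        assert list(exact.compound_id) == ["a"]
        assert list(censored.compound_id) == ["b"]
        assert rejects.empty

    def test_pactivity_is_neg_log10_molar(self):
        table = make_table([("a", "CCO", "IC50", "=", 1.0, "uM")])
        exact, _, _ = D.curate_records(table)
        assert exact.pActivity.iloc[0] == pytest.approx(6.0, abs=1e-9)

    @pytest.mark.parametrize(
        "row, reason",
        [
            (("x", "CCO", "IC50", "=", 500.0, "pM"), "unknown_unit"),
            (("x", "CCO", "AC50", "=", 500.0, "nM"), "unknown_activity_type"),
            (("x", "CCO", "IC50", "<", 500.0, "nM"), "unknown_relation"),
            (("x", "CCO", "IC50", "=", -5.0, "nM"), "missing_or_nonpositive_value"),
            (("x", "CCO", "IC50", "=", None, "nM"), "missing_or_nonpositive_value"),
            (("x", "", "IC50", "=", 500.0, "nM"), "empty_smiles"),
            (("x", "C1CC", "IC50", "=", 500.0, "nM"), "unparseable_smiles"),
        ],
    )
    def test_reject_reasons(self, row, reason):
        _, _, rejects = D.curate_records(make_table([row]))
        assert rejects.reason.tolist() == [reason]

    def test_salt_forms_share_std_key(self):
        table = make_table(
            [
                ("free", "CCN", "IC50", "=", 100.0, "nM"),
                ("salt", "CCN.Cl", "IC50", "=", 200.0, "nM"),
            ]
        )
        exact, _, _ = D.curate_records(table)
        assert exact.std_key.nunique() == 1


class TestPartitionAndDedup:
    def test_ic50_preferred_for_training(self):
        table = make_table(
            [
                ("a", "CCO", "IC50", "=", 100.0, "nM"),
                ("a", "CCO", "Ki", "=", 80.0, "nM"),
                ("b", "CCN", "Kd", "=", 50.0, "nM"),
            ]
        )
        exact, _, _ = D.curate_records(table)
        train, test = D.partition_by_type(exact)
        assert train.compound_id.tolist() == ["a"]
        assert train.activity_type.tolist() == ["IC50"]
        assert test.compound_id.tolist() == ["b"]  # the Ki row of "a" is dropped

    def test_duplicate_exact_values_collapse_to_median(self):
        table = make_table(
            [
                ("a", "CCO", "IC50", "=", 1.0, "uM"),  # pActivity 6.0
                ("a", "CCO", "IC50", "=", 0.1, "uM"),  # pActivity 7.0
            ]
        )
        exact, _, _ = D.curate_records(table)
        pool = D.deduplicate(exact)
        assert len(pool) == 1
        assert pool.pActivity.iloc[0] == pytest.approx(6.5, abs=1e-9)

    def test_distinct_structures_untouched(self):
        table = make_table(
            [
                ("a", "CCO", "IC50", "=", 100.0, "nM"),
                ("b", "CCN", "IC50", "=", 100.0, "nM"),
            ]
        )
        exact, _, _ = D.curate_records(table)
        assert len(D.deduplicate(exact)) == 2

    def test_cross_pool_overlap_resolves_to_train(self):
        train = pd.DataFrame({"std_key": ["K1", "K2"]})
        test = pd.DataFrame({"std_key": ["K2", "K3"]})
        out = D.drop_train_overlap(train, test)
        assert out.std_key.tolist() == ["K3"]


class TestLabeling:
    @pytest.mark.parametrize(
        "scheme, pactivity, expected",
        [
            (D.LEAD_ORIENTED, 6.2, "active"),
            (D.LEAD_ORIENTED, 6.0, "active"),  # boundary inclusive
            (D.LEAD_ORIENTED, 5.7, None),  # exclusion window
            (D.LEAD_ORIENTED, 5.30, "inactive"),  # boundary inclusive
            (D.LEAD_ORIENTED, 4.0, "inactive"),
            (D.POTENCY_ORIENTED, 7.5, "active"),
            (D.POTENCY_ORIENTED, 6.8, None),
            (D.POTENCY_ORIENTED, 5.5, "inactive"),
        ],
    )
    def test_threshold_application(self, scheme, pactivity, expected):
        pool = pd.DataFrame(
            {
                "std_key": ["k"],
                "parent_smiles": ["CCO"],
                "pActivity": [pactivity],
            }
        )
        labeled = D.assign_labels(pool, scheme)
        if expected is None:
            assert labeled.empty
        else:
            assert labeled.label.tolist() == [expected]

    def test_scheme_window_must_be_nonempty(self):
        with pytest.raises(ValueError):
            D.SchemeParams("bad", active_min_p=5.0, inactive_max_p=6.0,
                           inactive_min_conc_um=1.0)


class TestCensoredAugmentation:
    def _censored(self, value_um):
        return pd.DataFrame(
            {
                "compound_id": ["c"],
                "std_key": ["k"],
                "parent_smiles": ["CCO"],
                "activity_type": ["IC50"],
                "value_molar": [value_um * 1e-6],
            }
        )

    @pytest.mark.parametrize(
        "scheme, value_um, kept",
        [
            (D.LEAD_ORIENTED, 10.0, True),  # > 10 uM certifies LO inactivity
            (D.LEAD_ORIENTED, 2.0, False),  # bound below the 5 uM cutoff
            (D.LEAD_ORIENTED, 5.0, True),  # boundary inclusive
            (D.POTENCY_ORIENTED, 3.2, True),  # boundary inclusive
            (D.POTENCY_ORIENTED, 1.0, False),
        ],
    )
    def test_cutoff_rule(self, scheme, value_um, kept):
        out = D.augment_censored_inactives(self._censored(value_um), scheme)
        if kept:
            assert out.label.tolist() == ["inactive"]
            assert out.source.tolist() == ["censored_gt"]
        else:
            assert out.empty


class TestDecoyBalancing:
    def _dataset(self, n_active, n_inactive):
        return pd.DataFrame(
            {
                "std_key": [f"k{i}" for i in range(n_active + n_inactive)],
                "parent_smiles": ["CCO"] * (n_active + n_inactive),
                "label": ["active"] * n_active + ["inactive"] * n_inactive,
                "source": ["measured"] * (n_active + n_inactive),
                "pActivity": [7.0] * n_active + [4.0] * n_inactive,
            }
        )

    def _pool(self, n):
        return pd.DataFrame(
            {"std_key": [f"d{i}" for i in range(n)], "parent_smiles": ["CCOC"] * n}
        )

    def test_exact_fill(self):
        out, remaining = D.balance_with_decoys(self._dataset(100, 60), self._pool(500), seed=1)
        assert (out.label == "active").sum() == (out.label == "inactive").sum() == 100
        assert (out.source == "decoy").sum() == 40
        assert len(remaining) == 460

    def test_already_balanced_adds_nothing(self):
        out, remaining = D.balance_with_decoys(self._dataset(5, 5), self._pool(10), seed=1)
        assert (out.source == "decoy").sum() == 0
        assert len(remaining) == 10

    def test_seeded_determinism(self):
        a, _ = D.balance_with_decoys(self._dataset(30, 10), self._pool(100), seed=9)
        b, _ = D.balance_with_decoys(self._dataset(30, 10), self._pool(100), seed=9)
        assert a.equals(b)

    def test_pool_too_small_is_fatal(self):
        with pytest.raises(ValueError, match="too small"):
            D.balance_with_decoys(self._dataset(50, 0), self._pool(10), seed=1)

    def test_inactive_majority_is_fatal(self):
        with pytest.raises(ValueError, match="exceeds"):
            D.balance_with_decoys(self._dataset(5, 10), self._pool(10), seed=1)


class TestWholeFunnel:
    def test_two_balanced_disjoint_pairs(self, dataset_pairs):
        pairs, _ = dataset_pairs
        assert [p.scheme.name for p in pairs] == ["LO", "PO"]
        for pair in pairs:
            n_active = (pair.train.label == "active").sum()
            n_inactive = (pair.train.label == "inactive").sum()
            assert n_active == n_inactive > 0
            assert (pair.test.label == "active").sum() == (
                pair.test.label == "inactive"
            ).sum() > 0
            assert not set(pair.train.std_key) & set(pair.test.std_key)
            assert pair.train.std_key.is_unique and pair.test.std_key.is_unique

    def test_funnel_conservation(self, dataset_pairs, activity_table):
        _, report = dataset_pairs
        c = report.counts
        assert (
            c["exact_records"] + c["censored_records"] + c["rejected"]
            == c["input_records"]
            == len(activity_table)
        )
        assert (
            c["train_pool_records"]
            + c["test_pool_records"]
            + c["dropped_nonic50_of_trained_compounds"]
            == c["exact_records"]
        )

    def test_measured_labels_rederivable_from_thresholds(self, dataset_pairs):
        pairs, _ = dataset_pairs
        for pair in pairs:
            for frame in (pair.train, pair.test):
                measured = frame[frame.source == "measured"]
                expected = np.where(
                    measured.pActivity >= pair.scheme.active_min_p,
                    "active",
                    np.where(
                        measured.pActivity <= pair.scheme.inactive_max_p,
                        "inactive",
                        "window",
                    ),
                )
                assert (measured.label == expected).all()

    def test_censored_and_decoys_always_inactive(self, dataset_pairs):
        pairs, _ = dataset_pairs
        for pair in pairs:
            for frame in (pair.train, pair.test):
                aug = frame[frame.source.isin(["censored_gt", "decoy"])]
                assert (aug.label == "inactive").all()

    def test_planted_cross_pool_duplicates_removed(self):
        # same structure with IC50 (train) and Ki (test) measurements:
        # IC50 preference removes it from the test pool entirely
        table = make_table(
            [
                ("a", "c1ccc(CCN)cc1", "IC50", "=", 10.0, "nM"),
                ("a2", "c1ccc(CCN)cc1", "Ki", "=", 12.0, "nM"),
                ("b", "c1ccc(CCO)cc1", "Kd", "=", 11.0, "nM"),
                ("c", "Clc1ccc(CCO)cc1", "IC50", "=", 100.0, "uM"),
                ("d", "Brc1ccc(CCO)cc1", "Kd", "=", 90.0, "uM"),
            ]
        )
        decoys = [f"{'C' * k}c1ccccc1CCOCC(=O)NCc1ccccc1" for k in range(1, 6)]
        pairs, _ = D.build_datasets(table, decoys, schemes=[D.LEAD_ORIENTED], seed=0)
        pair = pairs[0]
        all_keys = pd.concat([pair.train, pair.test]).std_key
        assert all_keys.is_unique

    def test_empty_class_is_fatal_and_names_stage(self, activity_table):
        # all-active table: no measured inactives and no censored records
        actives = activity_table[
            (activity_table.relation == "=") & (activity_table.value < 100)
        ]
        actives = actives[actives.units == "nM"]
        with pytest.raises(ValueError, match="inactive"):
            D.build_datasets(actives, ["CCOCC"], schemes=[D.LEAD_ORIENTED], seed=0)

    def test_inactive_majority_downsampled_to_balance(self):
        # 2 actives vs 4 measured inactives: funnel down-samples the
        # inactives rather than failing, and reports how many it dropped
        rows = [
            ("a1", "Nc1ncnc2ccccc12", "IC50", "=", 1.0, "nM"),
            ("a2", "Nc1nc2ccccc2s1", "IC50", "=", 2.0, "nM"),
            ("i1", "c1ccccc1CCO", "IC50", "=", 100.0, "uM"),
            ("i2", "Cc1ccccc1CCO", "IC50", "=", 110.0, "uM"),
            ("i3", "CCc1ccccc1CCO", "IC50", "=", 120.0, "uM"),
            ("i4", "OCc1ccccc1CCO", "IC50", "=", 130.0, "uM"),
            ("t1", "Clc1ccccc1CCN", "Ki", "=", 1.0, "nM"),
            ("t2", "Brc1ccccc1CCO", "Ki", "=", 200.0, "uM"),
        ]
        pairs, report = D.build_datasets(
            make_table(rows), ["CCCCOc1ccccc1CC(=O)NCc1ccccc1"],
            schemes=[D.LEAD_ORIENTED], seed=0,
        )
        train = pairs[0].train
        assert (train.label == "active").sum() == (train.label == "inactive").sum() == 2
        assert report.counts["LO"]["train_inactive_downsampled"] == 2

    def test_dataset_csv_writer(self, dataset_pairs, tmp_path):
        pairs, _ = dataset_pairs
        D.write_dataset_csvs(pairs[0], tmp_path)
        out = pd.read_csv(tmp_path / "LO_train.csv")
        assert list(out.columns) == ["std_key", "parent_smiles", "label", "source"]
        assert len(out) == len(pairs[0].train)
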