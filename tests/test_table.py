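"""Feature-table loading, validity audit, cleaning, stratified splitting and
class balancing."""

import numpy as np
import pandas as pd
import pytest

from radpipe.balance import balance
from radpipe.fixtures import TableSpec, imbalanced_cohort, make_table
from radpipe.table import FeatureTable, drop_invalid, load_table, stratified_split


def write_csv(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


CLEAN = """CaseID,label,f1,f2,f3
a,0,1.0,2.0,3.0
b,1,4.0,5.0,6.0
c,0,7.0,8.0,9.0
d,1,1.5,2.5,3.5
"""


class TestLoad:
    def test_clean_table(self, tmp_path):
        table, report = load_table(write_csv(tmp_path, CLEAN))
        assert report.clean
        assert table.n_cases == 4
        assert table.feature_names == ["f1", "f2", "f3"]
        assert table.labels.tolist() == [0, 1, 0, 1]

    def test_non_numeric_cell_recorded(self, tmp_path):
        text = CLEAN.replace("5.0", "oops")
        table, report = load_table(write_csv(tmp_path, text))
        assert ("b", "f2", "non-numeric") in report.bad_cells
        assert report.bad_cases == ["b"]
        assert np.isnan(table.features.loc["b", "f2"])

    def test_null_and_infinite_cells(self, tmp_path):
        text = CLEAN.replace("2.0", "").replace("9.0", "inf")
        _, report = load_table(write_csv(tmp_path, text))
        reasons = {(c, f): r for c, f, r in report.bad_cells}
        assert reasons[("a", "f2")] == "null"
        assert reasons[("c", "f3")] == "infinite"

    def test_nonbinary_labels_error_names_value(self, tmp_path):
        text = CLEAN.replace("b,1", "b,2")
        with pytest.raises(ValueError, match="2"):
            load_table(write_csv(tmp_path, text))

    def test_missing_label_column(self, tmp_path):
        text = CLEAN.replace("label", "outcome")
        with pytest.raises(ValueError, match="label"):
            load_table(write_csv(tmp_path, text))

    def test_case_insensitive_label_fallback(self, tmp_path):
        text = CLEAN.replace("label", "Label")
        table, _ = load_table(write_csv(tmp_path, text))
        assert table.labels.tolist() == [0, 1, 0, 1]

    def test_duplicate_case_ids_rejected(self, tmp_path):
        text = CLEAN.replace("d,1", "a,1")
        with pytest.raises(ValueError, match="duplicate"):
            load_table(write_csv(tmp_path, text))

    def test_roundtrip_bit_identical(self, tmp_path):
        p = write_csv(tmp_path, CLEAN)
        table, _ = load_table(p)
        out = tmp_path / "out.csv"
        table.save(out)
        reloaded, report = load_table(out)
        assert report.clean
        out2 = tmp_path / "out2.csv"
        reloaded.save(out2)
        assert out.read_bytes() == out2.read_bytes()


class TestDropInvalid:
    def test_drop_cases_and_features(self, tmp_path):
        text = CLEAN.replace("5.0", "x")
        table, report = load_table(write_csv(tmp_path, text))
        by_case = drop_invalid(table, report, "cases")
        assert by_case.n_cases == 3 and "b" not in by_case.case_ids
        by_feat = drop_invalid(table, report, "features")
        assert by_feat.feature_names == ["f1", "f3"]

    def test_clean_table_idempotent(self, tmp_path):
        table, report = load_table(write_csv(tmp_path, CLEAN))
        out = drop_invalid(table, report, "cases")
        assert out.case_ids == table.case_ids

    def test_emptying_removal_rejected(self, tmp_path):
        text = "CaseID,label,f1\na,0,x\nb,1,y\n"
        table, report = load_table(write_csv(tmp_path, text))
        with pytest.raises(ValueError):
            drop_invalid(table, report, "cases")


class TestStratifiedSplit:
    def test_cohort_68_184_at_70_percent_training(self):
        table, _ = imbalanced_cohort(seed=1)
        train, test = stratified_split(table, test_fraction=0.3, seed=7)
        assert train.n_cases == 177 and test.n_cases == 75
        assert train.class_counts() == (129, 48)  # (neg, pos)
        assert test.class_counts() == (55, 20)

    def test_symmetric_split(self):
        table, _ = make_table(TableSpec(n_positive=10, n_negative=10, n_features=3, n_informative=1))
        train, test = stratified_split(table, 0.5, seed=0)
        assert train.class_counts() == (5, 5)
        assert test.class_counts() == (5, 5)

    def test_partition_and_determinism(self):
        table, _ = make_table(TableSpec(n_positive=20, n_negative=30, n_features=4, n_informative=1))
        t1a, t1b = stratified_split(table, 0.3, seed=5)
        t2a, t2b = stratified_split(table, 0.3, seed=5)
        assert t1a.case_ids == t2a.case_ids and t1b.case_ids == t2b.case_ids
        assert set(t1a.case_ids) | set(t1b.case_ids) == set(table.case_ids)
        assert not set(t1a.case_ids) & set(t1b.case_ids)
        assert t1a.role == "train" and t1b.role == "test"

    def test_tiny_class_rejected(self):
        table = FeatureTable(
            ["a", "b", "c"], np.array([0, 0, 1]),
            pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]),
        )
        with pytest.raises(ValueError):
            stratified_split(table, 0.3, seed=0)


class TestBalance:
    @pytest.fixture
    def imbalanced(self):
        table, _ = make_table(
            TableSpec(n_positive=20, n_negative=60, n_features=5, seed=3)
        )
        return table

    def test_downsampling(self, imbalanced):
        out = balance(imbalanced, "down", seed=0)
        assert out.class_counts() == (20, 20)
        # original minority rows untouched
        assert set(out.case_ids) <= set(imbalanced.case_ids)

    def test_upsampling(self, imbalanced):
        out = balance(imbalanced, "up", seed=0)
        assert out.class_counts() == (60, 60)
        originals = out.features.loc[imbalanced.case_ids]
        assert np.allclose(originals.to_numpy(), imbalanced.features.to_numpy())

    def test_smote_counts_and_convexity(self, imbalanced):
        out = balance(imbalanced, "smote", seed=0)
        assert out.class_counts() == (60, 60)
        X_min = imbalanced.features[imbalanced.labels == 1].to_numpy()
        synth = out.features.loc[[c for c in out.case_ids if c.startswith("smote_")]]
        # every synthetic point lies on a segment between two minority points
        for s in synth.to_numpy():
            on_segment = False
            for i in range(len(X_min)):
                for j in range(len(X_min)):
                    if i == j:
                        continue
                    a, b = X_min[i], X_min[j]
                    gap = np.linalg.norm(a - s) + np.linalg.norm(s - b) - np.linalg.norm(a - b)
                    if abs(gap) < 1e-8:
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_smote_adds_only_minority_rows(self, imbalanced):
        out = balance(imbalanced, "smote", seed=1)
        added = [c for c in out.case_ids if c not in imbalanced.case_ids]
        labels = dict(zip(out.case_ids, out.labels))
        assert all(labels[c] == 1 for c in added)

    def test_smotetomek_balanced_after_link_removal(self, imbalanced):
        out = balance(imbalanced, "smotetomek", seed=0)
        neg, pos = out.class_counts()
        assert neg == pos  # links remove one case of each class

    def test_already_balanced_unchanged(self):
        table, _ = make_table(TableSpec(n_positive=15, n_negative=15, n_features=3, n_informative=1))
        for method in ("down", "up"):
            out = balance(table, method, seed=0)
            assert sorted(out.case_ids) == sorted(table.case_ids)

    def test_test_table_refused(self, imbalanced):
        train, test = stratified_split(imbalanced, 0.3, seed=0)
        with pytest.raises(ValueError, match="test"):
            balance(test, "down", seed=0)

    def test_single_class_rejected(self):
        table = FeatureTable(
            ["a", "b"], np.array([1, 1]),
            pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"]),
        )
        with pytest.raises(ValueError):
            balance(table, "down", seed=0)
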