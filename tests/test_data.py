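import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import admitsem as a
from admitsem.data import SchemaError, ValidationError


class TestReadWrite:
    def test_round_trip_preserves_counts_and_reals(self, tiny_table, tmp_path):
        path = tmp_path / "t.csv"
        a.write_practice_table(tiny_table, path)
        back = a.read_practice_table(path)
        assert back.I == 3 and back.J == 2 and back.K == 2
        np.testing.assert_array_equal(back.Z, tiny_table.Z)
        np.testing.assert_array_equal(back.W, tiny_table.W)
        np.testing.assert_array_equal(back.Y, tiny_table.Y)
        np.testing.assert_allclose(back.D, tiny_table.D, atol=1e-12)
        np.testing.assert_allclose(back.E, tiny_table.E, atol=1e-12)
        assert back.practice_id == tiny_table.practice_id

    def test_generated_table_dimensions(self, small_sim, tmp_path):
        path = tmp_path / "sim.csv"
        a.write_practice_table(small_sim.table, path)
        back = a.read_practice_table(path)
        assert (back.I, back.J, back.K) == (40, 4, 4)

    def test_numerator_exceeding_denominator_names_practice(self, tiny_table, tmp_path):
        df = tiny_table.to_dataframe()
        df.loc[1, "z1"] = 12  # n1 is 10
        with pytest.raises(ValidationError, match="beta"):
            a.PracticeTable.from_dataframe(df)

    def test_missing_column_names_it(self, tiny_table):
        df = tiny_table.to_dataframe().drop(columns=["y"])
        with pytest.raises(SchemaError, match="'y'"):
            a.PracticeTable.from_dataframe(df)

    def test_non_integer_count_rejected(self, tiny_table):
        df = tiny_table.to_dataframe().astype({"z1": float})
        df.loc[0, "z1"] = 7.5
        with pytest.raises(ValidationError, match="integer"):
            a.PracticeTable.from_dataframe(df)

    def test_schema_remapping(self, tiny_table, tmp_path):
        df = tiny_table.to_dataframe().rename(columns={"y": "admissions"})
        got = a.PracticeTable.from_dataframe(df, schema={"y": "admissions"})
        np.testing.assert_array_equal(got.Y, tiny_table.Y)


class TestStandardize:
    def test_symmetric_triple(self, tiny_table):
        std, rec = a.standardize_covariates(tiny_table)
        np.testing.assert_allclose(std.D, [-1.0, 0.0, 1.0], atol=1e-12)
        assert rec.means["D"] == 2.0 and rec.sds["D"] == 1.0

    def test_idempotent(self, tiny_table):
        once, _ = a.standardize_covariates(tiny_table)
        twice, _ = a.standardize_covariates(once)
        for name in ("D", "Mrate", "S1", "S2"):
            np.testing.assert_allclose(getattr(twice, name), getattr(once, name), atol=1e-12)

    def test_against_two_pass_oracle(self, small_sim):
        std, rec = a.standardize_covariates(small_sim.table)
        x = small_sim.table.Mrate
        # independently coded two-pass mean/variance
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        np.testing.assert_allclose(rec.means["Mrate"], mean, rtol=1e-12)
        np.testing.assert_allclose(rec.sds["Mrate"], var**0.5, rtol=1e-12)
        assert abs(std.Mrate.mean()) < 1e-12
        assert abs(std.Mrate.std(ddof=1) - 1.0) < 1e-12

    def test_zero_variance_errors(self, tiny_table):
        from dataclasses import replace

        flat = replace(tiny_table, S1=np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValidationError, match="S1"):
            a.standardize_covariates(flat)

    def test_record_round_trip(self, tiny_table):
        _, rec = a.standardize_covariates(tiny_table)
        back = a.StandardizationRecord.from_json(rec.to_json())
        assert back.means == rec.means and back.sds == rec.sds


class TestExpectedCounts:
    def _table(self, Y, N_rows):
        I = len(Y)
        return a.PracticeTable(
            practice_id=[f"p{i}" for i in range(I)],
            Z=np.zeros((I, 1), int),
            N=np.asarray(N_rows).reshape(I, 1),
            W=np.zeros((I, 1), int),
            V=np.ones((I, 1), int),
            Y=np.asarray(Y),
            D=np.arange(I, dtype=float),
            Mrate=np.arange(I, dtype=float),
            S1=np.arange(I, dtype=float) + 1,
            S2=np.arange(I, dtype=float) + 1,
        )

    def test_equal_basis_splits_equally(self):
        t = a.compute_expected_counts(self._table([2, 2], [10, 10]))
        np.testing.assert_allclose(t.E, [2.0, 2.0])

    def test_proportional_allocation(self):
        t = a.compute_expected_counts(self._table([0, 4], [10, 30]))
        np.testing.assert_allclose(t.E, [1.0, 3.0])

    def test_list_size_basis(self, tiny_table):
        t = a.compute_expected_counts(tiny_table, basis="list_size")
        np.testing.assert_allclose(t.E, tiny_table.S2 * tiny_table.Y.sum() / tiny_table.S2.sum())

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_conserves_admission_total(self, seed):
        sim = a.simulate_practice_table(a.GeneratorConfig(I=12), seed=seed)
        t = a.compute_expected_counts(sim.table)
        assert abs(t.E.sum() - t.Y.sum()) < 1e-9
        t2 = a.compute_expected_counts(sim.table, basis="list_size")
        assert abs(t2.E.sum() - t2.Y.sum()) < 1e-9


class TestCrosswalk:
    def test_rows_renormalized_with_coverage(self):
        xw = a.CrosswalkMatrix(
            area_id=["a", "b"],
            practice_id=["p", "q"],
            weights=np.array([[0.4, 0.4], [0.3, 0.6]]),
        )
        np.testing.assert_allclose(xw.weights.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(xw.covered_fraction, [0.8, 0.9])

    def test_long_csv_round_trip(self, tmp_path):
        xw = a.generate_crosswalk(a.GeneratorConfig(I=5), L=7, seed=3)
        path = tmp_path / "xw.csv"
        a.write_crosswalk(xw, path)
        back = a.read_crosswalk(path, practice_order=xw.practice_id)
        np.testing.assert_allclose(back.weights, xw.weights, atol=1e-9)
        assert back.area_id == xw.area_id

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            a.CrosswalkMatrix(area_id=["a"], practice_id=["p", "q"], weights=np.array([[-0.1, 1.1]]))

    def test_unknown_practice_in_csv(self, tmp_path):
        path = tmp_path / "xw.csv"
        pd.DataFrame({"area_id": ["a"], "practice_id": ["nope"], "weight": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="nope"):
            a.read_crosswalk(path, practice_order=["p1"])
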