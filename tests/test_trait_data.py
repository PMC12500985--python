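import numpy as np
import pandas as pd
import pytest

from droughtrank.errors import (
    FormatError,
    IntegrityError,
    ParseError,
    SpecError,
)
from droughtrank.trait_data import (
    DEFAULT_INDEX_SPECS,
    IndexSpec,
    TraitMatrix,
    means_to_trait_matrix,
    read_index_spec,
    read_trait_table,
    read_wide_means,
    write_index_spec,
    write_trait_table,
)

from conftest import make_tidy


class TestConstruction:
    def test_two_by_one_matrix_has_twelve_values(self):
        tm = TraitMatrix.from_tidy(make_tidy(("A", "B"), ("PH",), replicates=3))
        assert len(tm.data) == 12
        assert tm.genotypes == ["A", "B"]
        assert tm.indices == ["PH"]

    def test_first_appearance_order_preserved(self):
        df = make_tidy(("Z9", "A1", "M5"), ("LW", "PH"))
        tm = TraitMatrix.from_tidy(df)
        assert tm.genotypes == ["Z9", "A1", "M5"]
        assert tm.indices == ["LW", "PH"]

    def test_missing_column_is_format_error(self):
        df = make_tidy().drop(columns=["condition"])
        with pytest.raises(FormatError, match="condition"):
            TraitMatrix.from_tidy(df)

    def test_non_numeric_value_reports_row(self):
        df = make_tidy()
        df["value"] = df["value"].astype(object)
        df.loc[5, "value"] = "oops"
        with pytest.raises(ParseError, match="row 6"):
            TraitMatrix.from_tidy(df)

    def test_duplicate_key_names_the_key(self):
        df = make_tidy()
        df.loc[len(df)] = ["G1", "PH", "control", 1, 3.3]
        with pytest.raises(IntegrityError, match="'G1'.*'PH'.*'control'"):
            TraitMatrix.from_tidy(df)

    def test_missing_cell_is_integrity_error(self):
        df = make_tidy()
        df = df[~((df.genotype == "G2") & (df.condition == "treatment"))]
        with pytest.raises(IntegrityError, match="missing cell"):
            TraitMatrix.from_tidy(df)

    def test_unknown_condition_rejected(self):
        df = make_tidy()
        df.loc[0, "condition"] = "drought"
        with pytest.raises(FormatError, match="drought"):
            TraitMatrix.from_tidy(df)

    def test_index_absent_from_spec_is_spec_error(self):
        df = make_tidy(indices=("PH", "XX"))
        with pytest.raises(SpecError, match="XX"):
            TraitMatrix.from_tidy(df, spec=DEFAULT_INDEX_SPECS)

    def test_bad_direction_rejected(self):
        with pytest.raises(SpecError):
            IndexSpec("PH", direction="sideways")


class TestRoundTrip:
    def test_write_then_read_identical(self, tmp_path, tiny_matrix):
        path = tmp_path / "panel.csv"
        write_trait_table(tiny_matrix, path)
        again = read_trait_table(path)
        assert again == tiny_matrix

    def test_round_trip_preserves_awkward_floats(self, tmp_path):
        vals = iter([0.1, 1 / 3, 1e-17, 123456.789012345, 2.5, 7.0, 0.30000000000000004, 9.9])
        df = make_tidy(("A", "B"), ("PH",), replicates=2,
                       value_fn=lambda *a: next(vals))
        tm = TraitMatrix.from_tidy(df)
        path = tmp_path / "x.csv"
        write_trait_table(tm, path)
        assert read_trait_table(path) == tm

    def test_row_order_does_not_matter(self):
        df = make_tidy(("A", "B"), ("PH", "LW"))
        shuffled = df.sample(frac=1.0, random_state=1)
        a = TraitMatrix.from_tidy(df)
        # first-appearance order differs, so compare value content per key
        b = TraitMatrix.from_tidy(shuffled)
        key = ["genotype", "index", "condition", "replicate"]
        pd.testing.assert_frame_equal(
            a.data.sort_values(key).reset_index(drop=True),
            b.data.sort_values(key).reset_index(drop=True),
        )


class TestCellMeans:
    def test_mean_and_sample_sd(self):
        vals = iter([1.0, 2.0, 3.0] * 2)
        df = make_tidy(("A",), ("PH",), replicates=3, value_fn=lambda *a: next(vals))
        means = TraitMatrix.from_tidy(df).cell_means()
        row = means[(means.genotype == "A") & (means.condition == "control")].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # ddof=1

    def test_single_replicate_sd_zero(self):
        df = make_tidy(("A",), ("PH",), replicates=1, value_fn=lambda *a: 5.5)
        means = TraitMatrix.from_tidy(df).cell_means()
        assert (means["mean"] == 5.5).all()
        assert (means["sd"] == 0.0).all()

    def test_aggregation_idempotent_on_single_replicates(self):
        df = make_tidy(("A", "B"), ("PH",), replicates=1)
        tm = TraitMatrix.from_tidy(df)
        m1 = tm.cell_means()
        tm2 = means_to_trait_matrix(m1)
        m2 = tm2.cell_means()
        np.testing.assert_allclose(
            m1.sort_values(["genotype", "condition"])["mean"].to_numpy(),
            m2.sort_values(["genotype", "condition"])["mean"].to_numpy(),
        )

    def test_permutation_invariant_over_replicates(self, rng):
        df = make_tidy(("A",), ("PH",), replicates=5)
        tm1 = TraitMatrix.from_tidy(df)
        shuf = df.copy()
        # permute replicate ids within a cell: means and sd must not change
        shuf["replicate"] = shuf.groupby(["genotype", "condition"])["replicate"].transform(
            lambda s: rng.permutation(s.to_numpy())
        )
        tm2 = TraitMatrix.from_tidy(shuf)
        cols = ["genotype", "index", "condition"]
        pd.testing.assert_frame_equal(
            tm1.cell_means().sort_values(cols).reset_index(drop=True),
            tm2.cell_means().sort_values(cols).reset_index(drop=True),
        )

    def test_published_s22_control_chl_mean(self, daylily):
        tm = means_to_trait_matrix(daylily.pigment_means)
        assert tm.mean_matrix("control").loc["S22", "Chl"] == pytest.approx(1.144)


class TestWideAndSpecIO:
    def test_wide_reader_normalizes_to_tidy(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "genotype,PH_control,PH_treatment\nA,10,8\nB,12,9\n", encoding="utf-8"
        )
        tm = read_wide_means(path)
        assert tm.genotypes == ["A", "B"]
        assert tm.mean_matrix("treatment").loc["A", "PH"] == 8.0

    def test_wide_reader_rejects_bad_column(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text("genotype,PHcontrol\nA,10\n", encoding="utf-8")
        with pytest.raises(FormatError, match="PHcontrol"):
            read_wide_means(path)

    def test_index_spec_yaml_round_trip(self, tmp_path):
        path = tmp_path / "spec.yaml"
        write_index_spec(DEFAULT_INDEX_SPECS, path)
        again = read_index_spec(path)
        assert again == DEFAULT_INDEX_SPECS
        assert again["EL"].direction == "negative"
        assert again["MDA"].direction == "negative"
        assert again["RWC"].direction == "positive"
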