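"""Case-table processing: loading, sub-dataset filters, demography,
seasonality, bite-type shares."""

import numpy as np
import pandas as pd
import pytest

from snakerisk.cases import (
    SeasonDefinition,
    admin_counts,
    bite_type_shares,
    demography,
    load_cases,
    seasonal_summary,
    subdataset,
    write_cases,
)


def table(rows):
    df = pd.DataFrame(rows, columns=["age", "sex", "bite_date", "bite_type",
                                     "district", "subdistrict", "longitude", "latitude"])
    df["bite_date"] = pd.to_datetime(df["bite_date"])
    return df


ROW = (25, "male", "2001-07-15", "cobra", "d1", "s1", 91.5, 22.5)


class TestLoadCases:
    def test_blank_fields_become_missing(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "age,sex,bite_date,bite_type\n"
            "25,male,2001-07-15,cobra\n"
            "30,,2001-08-01,krait\n"
            "41,female,2002-01-10,non_envenoming\n"
        )
        df = load_cases(p)
        assert len(df) == 3 and df["sex"].isna().sum() == 1

    def test_unknown_bite_type_rejected_with_value(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("age,sex,bite_date,bite_type\n25,male,2001-07-15,viper???\n")
        with pytest.raises(ValueError, match="viper"):
            load_cases(p)

    def test_round_trip(self, tmp_path):
        df = table([ROW, (np.nan, "female", "2002-01-10", "krait", None, None, np.nan, np.nan)])
        write_cases(df, tmp_path / "c.csv")
        back = load_cases(tmp_path / "c.csv")
        assert len(back) == 2
        assert back["sex"].tolist() == ["male", "female"]
        assert back["bite_date"].equals(df["bite_date"])

    def test_column_mapping_and_xlsx(self, tmp_path):
        src = pd.DataFrame({"Age (yrs)": [20], "Gender": ["male"],
                            "Date": ["2000-06-01"], "Type": ["cobra"]})
        src.to_excel(tmp_path / "c.xlsx", index=False)
        df = load_cases(tmp_path / "c.xlsx", column_map={
            "Age (yrs)": "age", "Gender": "sex", "Date": "bite_date", "Type": "bite_type"})
        assert df.loc[0, "age"] == 20 and df.loc[0, "bite_type"] == "cobra"

    def test_unmappable_required_column_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("age,sex,bite_date\n25,male,2001-07-15\n")
        with pytest.raises(ValueError, match="bite_type"):
            load_cases(p)


class TestSubdataset:
    @pytest.fixture
    def ten_rows(self):
        rows = [ROW] * 7 + [(25, "male", None, "cobra", "d1", "s1", 91.5, 22.5)] * 3
        return table(rows)

    def test_require_date_keeps_seven(self, ten_rows):
        kept, audit = subdataset(ten_rows, ["bite_date"])
        assert len(kept) == 7
        assert audit == {"n_input": 10, "missing_bite_date": 3, "n_kept": 7, "n_dropped": 3}

    def test_empty_requirement_is_identity(self, ten_rows):
        kept, audit = subdataset(ten_rows, [])
        assert len(kept) == 10 and audit["n_kept"] == 10

    def test_idempotent_and_monotone(self, ten_rows):
        once, _ = subdataset(ten_rows, ["bite_date"])
        twice, _ = subdataset(once, ["bite_date"])
        assert once.equals(twice)
        fewer, _ = subdataset(ten_rows, ["bite_date", "sex", "age"])
        assert len(fewer) <= len(once)

    def test_unknown_field_rejected(self, ten_rows):
        with pytest.raises(KeyError):
            subdataset(ten_rows, ["species"])


class TestDemography:
    def test_two_male_one_female(self):
        df = table([ROW, ROW, (30, "female", "2001-08-01", "krait", None, None, None, None)])
        d = demography(df)
        assert d["counts"] == {"male": 2, "female": 1}
        assert d["shares"]["male"] == pytest.approx(2 / 3)

    def test_pyramid_counts_sum_and_binning(self):
        rows = [(5, "male", "2001-01-01", "cobra", None, None, None, None),
                (15, "female", "2001-01-01", "cobra", None, None, None, None),
                (64, "male", "2001-01-01", "cobra", None, None, None, None),
                (np.nan, "male", "2001-01-01", "cobra", None, None, None, None)]
        d = demography(table(rows))
        pyr = d["pyramid"]
        assert pyr.to_numpy().sum() == 3  # ageless row excluded from pyramid
        assert pyr.loc["0-9", "male"] == 1
        assert pyr.loc["10-19", "female"] == 1
        assert pyr.loc["60+", "male"] == 1

    def test_no_sexed_records_rejected(self):
        df = table([(25, None, "2001-07-15", "cobra", None, None, None, None)])
        with pytest.raises(ValueError):
            demography(df)


class TestSeasonal:
    def test_all_july_is_all_rainy(self):
        df = table([ROW] * 5)
        out = seasonal_summary(df)
        assert out["shares"]["rainy"] == 1.0

    def test_one_record_per_month_gives_thirds(self):
        rows = [(20, "male", f"2001-{m:02d}-10", "cobra", None, None, None, None)
                for m in range(1, 13)]
        out = seasonal_summary(table(rows))
        assert out["shares"] == {"summer": pytest.approx(4 / 12),
                                 "rainy": pytest.approx(4 / 12),
                                 "winter": pytest.approx(4 / 12)}

    def test_undated_rows_audited(self):
        df = table([ROW, (20, "male", None, "cobra", None, None, None, None)])
        out = seasonal_summary(df)
        assert out["audit"] == {"n_input": 2, "n_dated": 1, "n_undated": 1}

    def test_cross_table_margins_conserved(self, rng):
        months = rng.integers(1, 13, 60)
        types = rng.choice(["cobra", "krait", "green_pit_viper"], 60)
        rows = [(20, "male", f"2001-{m:02d}-05", t, None, None, None, None)
                for m, t in zip(months, types)]
        out = seasonal_summary(table(rows), by_bite_type=True)
        tab = out["by_bite_type"]
        for season, count in out["counts"].items():
            assert tab.loc[season].sum() == count
        assert tab.to_numpy().sum() == 60

    def test_custom_season_definition_must_cover_year(self):
        with pytest.raises(ValueError):
            SeasonDefinition(month_to_season={1: "winter"})


class TestBiteTypeShares:
    def test_single_year_twelve_percent_cobra(self):
        rows = [(20, "male", "2001-07-01", "cobra", None, None, None, None)] * 12
        rows += [(20, "male", "2001-07-01", "non_envenoming", None, None, None, None)] * 88
        shares = bite_type_shares(table(rows), denominator="all_records")
        assert shares["cobra"] == pytest.approx(0.12)

    def test_equal_counts_give_fifths(self):
        types = ["cobra", "green_pit_viper", "krait", "non_envenoming", "other_envenoming"]
        rows = [(20, "male", "2001-07-01", t, None, None, None, None) for t in types * 4]
        shares = bite_type_shares(table(rows))
        for t in types:
            assert shares[t] == pytest.approx(0.2)

    def test_envenoming_only_denominator_excludes_dry_bites(self):
        rows = [(20, "male", "2001-07-01", "cobra", None, None, None, None)] * 3
        rows += [(20, "male", "2001-07-01", "non_envenoming", None, None, None, None)] * 7
        shares = bite_type_shares(table(rows), denominator="envenoming_only")
        assert shares["cobra"] == pytest.approx(1.0)

    def test_yearly_averaging(self):
        # 10% cobra in year 1, 30% in year 2 -> mean yearly share 20%
        rows = [(20, "m", "2001-07-01", "cobra", None, None, None, None)] * 1
        rows += [(20, "m", "2001-07-01", "krait", None, None, None, None)] * 9
        rows += [(20, "m", "2002-07-01", "cobra", None, None, None, None)] * 3
        rows += [(20, "m", "2002-07-01", "krait", None, None, None, None)] * 7
        df = table(rows)
        df["sex"] = "male"
        shares = bite_type_shares(df)
        assert shares["cobra"] == pytest.approx(0.2)


def test_admin_counts_sorted():
    rows = [ROW] * 3 + [(20, "male", "2001-07-01", "cobra", "d2", "s9", None, None)]
    out = admin_counts(table(rows), "district")
    assert out.iloc[0]["district"] == "d1" and out.iloc[0]["n_cases"] == 3
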