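"""Sighting-table parsing, validation, daily de-dup, filters and the GBI."""

import io

import numpy as np
import pandas as pd
import pytest

from podsoc.sightings import (
    ValidationError,
    apply_inclusion_filters,
    build_gbi,
    daily_dedup,
    read_sightings,
    residence_class,
    residence_profiles,
    write_sightings,
)

from conftest import make_table


def row(date, gid, ind, sex="F", age="A", size=2, nid=2, net=False):
    return (date, gid, ind, sex, age, size, nid, net)


class TestReadValidate:
    def test_parses_small_fixture(self):
        csv = io.StringIO(
            "date,group_id,individual_id,sex,age_class,"
            "group_size_observed,n_identified,trammel_net\n"
            "2020-06-01,g1,PHD1,F,A,2,2,False\n"
            "2020-06-01,g1,PHD2,M,A,2,2,False\n"
            "2020-06-02,g1,PHD1,F,A,1,1,True\n"
        )
        table = read_sightings(csv)
        assert table.n_groups == 2
        assert table.individuals == ["PHD1", "PHD2"]

    def test_column_dialect_mapping(self):
        csv = io.StringIO(
            "Day,Grp,ID,sex,age_class,group_size_observed,n_identified,trammel_net\n"
            "2020-06-01,g1,PHD1,F,A,1,1,False\n"
        )
        table = read_sightings(
            csv, dialect={"Day": "date", "Grp": "group_id", "ID": "individual_id"}
        )
        assert table.individuals == ["PHD1"]

    def test_missing_column_is_configuration_error(self):
        csv = io.StringIO("date,group_id\n2020-06-01,g1\n")
        with pytest.raises(ValidationError, match="missing mandatory columns"):
            read_sightings(csv)

    def test_contradictory_sex_names_individual(self):
        with pytest.raises(ValidationError, match="PHD1"):
            make_table([
                row("2020-06-01", "g1", "PHD1", sex="F"),
                row("2020-06-02", "g1", "PHD1", sex="M"),
            ])

    def test_n_identified_cannot_exceed_group_size(self):
        with pytest.raises(ValidationError, match="n_identified"):
            make_table([row("2020-06-01", "g1", "PHD1", size=2, nid=3)])

    def test_attribute_override_reclassifies_estimated_males(self):
        csv = io.StringIO(
            "date,group_id,individual_id,sex,age_class,"
            "group_size_observed,n_identified,trammel_net\n"
            "2020-06-01,g1,PHD2,M,A,1,1,False\n"
        )
        table = read_sightings(
            csv, attribute_overrides={"PHD2": {"sex": "UN"}}
        )
        assert table.attributes().loc["PHD2", "sex"] == "UN"

    def test_write_read_round_trip(self, tmp_path, default_table):
        _, table = default_table
        path = tmp_path / "sightings.csv"
        write_sightings(table, path)
        back = read_sightings(path)
        pd.testing.assert_frame_equal(
            back.data.drop(columns="time", errors="ignore"),
            table.data.drop(columns="time", errors="ignore"),
            check_dtype=False,
        )


class TestDailyDedup:
    def test_first_group_retained(self):
        table = make_table([
            row("2020-06-01", "g1", "A"),
            row("2020-06-01", "g1", "B"),
            row("2020-06-01", "g2", "A"),
            row("2020-06-01", "g2", "C"),
        ])
        out = daily_dedup(table)
        groups = out.data.groupby("group_id")["individual_id"].apply(set)
        assert groups["g1"] == {"A", "B"}
        assert groups["g2"] == {"C"}          # A dropped from later group only

    def test_explicit_time_overrides_group_id_order(self):
        table = make_table([
            row("2020-06-01", "g2", "A") + (1,),
            row("2020-06-01", "g9", "A") + (0,),
        ], time_col=True)
        out = daily_dedup(table)
        assert out.data["group_id"].tolist() == ["g9"]

    def test_noop_when_one_sighting_per_day(self):
        table = make_table(
            [row(f"2020-06-{d:02d}", "g1", "A", size=1, nid=1) for d in range(1, 6)]
        )
        out = daily_dedup(table)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_idempotent_and_bounded_on_random_days(self):
        rng = np.random.default_rng(7)
        rows = []
        for day in range(3):
            for g in range(3):
                members = rng.choice(10, size=4, replace=False)
                rows.extend(
                    row(f"2020-06-{day + 1:02d}", f"g{g}", f"I{m}", size=4, nid=4)
                    for m in members
                )
        table = make_table(rows)
        once = daily_dedup(table)
        twice = daily_dedup(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        counts = once.data.groupby(["date", "individual_id"]).size()
        assert (counts <= 1).all()


class TestInclusionFilters:
    def base_rows(self):
        # 7 individuals seen 6 times each (small groups), plus extras below
        rows = []
        for d in range(6):
            for g, members in enumerate((list("ABCD"), list("EFG"))):
                for m in members:
                    rows.append(
                        row(f"2020-06-{d + 1:02d}", f"g{g}", m,
                            size=len(members), nid=len(members))
                    )
        return rows

    def test_requires_dedup_first(self):
        table = make_table(self.base_rows())
        with pytest.raises(ValidationError, match="daily_dedup"):
            apply_inclusion_filters(table)

    def test_large_poorly_identified_group_excluded(self):
        rows = self.base_rows()
        # group of 10 with 7 identified -> below the 80% rule
        rows += [row("2020-07-01", "g9", m, size=10, nid=7) for m in "ABCDEFG"]
        table = daily_dedup(make_table(rows))
        filtered, report = apply_inclusion_filters(table)
        assert ("g9" not in filtered.data["group_id"].values)
        assert len(report.groups_low_identified) == 1

    def test_boundary_group_of_eight_retained(self):
        rows = self.base_rows()
        rows += [row("2020-07-01", "g8", m, size=8, nid=4) for m in "ABCD"]
        table = daily_dedup(make_table(rows))
        filtered, report = apply_inclusion_filters(table)
        assert "g8" in filtered.data["group_id"].values     # 8 is not > 8
        assert not report.groups_low_identified

    def test_calves_and_rare_individuals_removed(self):
        rows = self.base_rows()
        rows += [row("2020-07-02", "g1", "CALF", age="C", size=1, nid=1)]
        rows += [row("2020-07-03", "g1", "RARE", size=1, nid=1)]
        table = daily_dedup(make_table(rows))
        filtered, report = apply_inclusion_filters(table)
        assert report.calves == ["CALF"]
        assert "RARE" in report.below_min_sightings
        assert set(filtered.individuals) == set("ABCDEFG")

    def test_never_increases_sighting_counts(self, default_table):
        _, table = default_table
        deduped = daily_dedup(table)
        filtered, _ = apply_inclusion_filters(deduped)
        before = deduped.sighting_counts()
        after = filtered.sighting_counts()
        assert all(after[i] <= before[i] for i in after.index)

    def test_matches_brute_force_recount(self, default_table):
        """Filtered individual set equals an independent recount of the rules."""
        _, table = default_table
        deduped = daily_dedup(table)
        df = deduped.data
        frac = df["n_identified"] / df["group_size_observed"]
        bad = set(map(tuple, df.loc[
            (df["group_size_observed"] > 8) & (frac < 0.8), ["date", "group_id"]
        ].values))
        keep = df[[tuple(k) not in bad for k in df[["date", "group_id"]].values]]
        keep = keep[keep["age_class"] != "C"]
        counts = keep["individual_id"].value_counts()
        expected = sorted(counts.index[counts >= 6])
        filtered, _ = apply_inclusion_filters(deduped)
        assert filtered.individuals == expected

    def test_empty_result_raises(self):
        table = daily_dedup(make_table([row("2020-06-01", "g1", "A", size=1, nid=1)]))
        with pytest.raises(ValidationError, match="no analysable individuals"):
            apply_inclusion_filters(table)


class TestBuildGbi:
    def test_direct_construction(self):
        table = make_table([
            row("2020-06-01", "g1", "A"), row("2020-06-01", "g1", "B"),
            row("2020-06-02", "g1", "B"), row("2020-06-02", "g1", "C"),
        ])
        gbi = build_gbi(table)
        assert gbi.individuals == ("A", "B", "C")
        assert gbi.matrix.tolist() == [[1, 1, 0], [0, 1, 1]]
        assert gbi.sighting_counts().tolist() == [1, 2, 1]

    def test_conservation_and_ground_truth_counts(self, default_table):
        _, table = default_table
        gbi = build_gbi(table)
        assert gbi.matrix.sum() == len(table.data)
        expected = table.sighting_counts()
        for ind, j in zip(gbi.individuals, range(gbi.n_individuals)):
            assert gbi.matrix[:, j].sum() == expected[ind]

    def test_deterministic(self, default_table):
        _, table = default_table
        a = build_gbi(table)
        b = build_gbi(table)
        assert a.individuals == b.individuals
        assert np.array_equal(a.matrix, b.matrix)


class TestResidence:
    @pytest.mark.parametrize(
        "n,label",
        [(37, "very_frequent"), (22, "very_frequent"), (21, "frequent"),
         (14, "frequent"), (13, "low_frequent"), (10, "low_frequent"),
         (9, "rare"), (4, "rare"), (3, "occasional"), (1, "occasional")],
    )
    def test_class_bins(self, n, label):
        assert residence_class(n) == label

    def test_annual_residence_hand_fixture(self):
        rows = (
            [row(f"2020-06-{d:02d}", "g1", "A", size=1, nid=1) for d in (1, 2, 3)]
            + [row("2020-06-04", "g1", "B", size=1, nid=1)]
            + [row("2021-06-01", "g1", "A", size=1, nid=1)]
        )
        profiles = {p.individual_id: p for p in residence_profiles(make_table(rows))}
        assert profiles["A"].annual_residence == {2020: 3 / 4, 2021: 1.0}
        assert profiles["B"].annual_residence == {2020: 1 / 4}
        assert profiles["A"].n_sightings == 4
        assert profiles["A"].residence_class == "rare"

    def test_group_size_cutoff_from_pooled_mean(self):
        rows = [
            row("2020-06-01", "g1", "A", size=2, nid=1),
            row("2020-06-02", "g1", "A", size=8, nid=1),
        ]
        (profile,) = residence_profiles(make_table(rows))
        # pooled mean 5 -> one of two sightings above it
        assert profile.pct_large_groups == 0.5
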