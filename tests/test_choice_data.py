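import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from fledgechoice.choice_data import (
    ALL_COVARIATES,
    ChoiceSet,
    Dataset,
    Location,
    SchemaError,
    assign_stage,
    convert_spreadsheet,
    filter_one_per_brood,
    read_choice_table,
    standardize_covariates,
)
from fledgechoice.synthetic_data import SimConfig, generate_dataset

from conftest import make_choice_set, make_location


class TestLocationAndChoiceSet:
    def test_role_and_range_validation(self):
        with pytest.raises(ValueError):
            make_location(role="chosen")
        with pytest.raises(ValueError, match="canopy_cover"):
            make_location(canopy_cover=130.0)
        with pytest.raises(ValueError, match="edge_distance"):
            make_location(edge_distance=-5.0)

    def test_choice_set_needs_exactly_one_used(self):
        locs = tuple(make_location(role="available") for _ in range(3))
        with pytest.raises(ValueError, match="one used"):
            ChoiceSet(set_id="x", species="s", individual_id="i", brood_id="b",
                      stage="nest", locations=locs, used_index=0)

    def test_used_index_must_point_at_used_location(self):
        locs = (make_location(role="used"), make_location(), make_location())
        with pytest.raises(ValueError, match="used_index"):
            ChoiceSet(set_id="x", species="s", individual_id="i", brood_id="b",
                      stage="nest", locations=locs, used_index=1)

    def test_nest_sets_have_no_day(self):
        with pytest.raises(ValueError, match="day_postfledge"):
            make_choice_set(stage="nest", day=4)


class TestReader:
    def test_three_complete_sets_grouped(self, canonical_frame, tmp_path):
        p = tmp_path / "t.csv"
        canonical_frame.to_csv(p, index=False)
        ds = read_choice_table(p)
        assert len(ds) == 3
        assert ds.n_excluded_incomplete == 0
        # used_index is derived from the role column, not position
        for cs in ds.sets:
            assert cs.locations[cs.used_index].role == "used"

    def test_incomplete_set_excluded_and_counted(self, canonical_frame, tmp_path):
        short = canonical_frame.iloc[:-1]  # last set has 2 rows
        p = tmp_path / "t.csv"
        short.to_csv(p, index=False)
        ds = read_choice_table(p)
        assert len(ds) == 2
        assert ds.n_excluded_incomplete == 1

    def test_duplicate_used_rows_raise(self, canonical_frame, tmp_path):
        bad = canonical_frame.copy()
        bad.loc[bad["set_id"] == "set_0", "role"] = "used"
        p = tmp_path / "t.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(SchemaError, match="used"):
            read_choice_table(p)

    def test_missing_column_named_in_error(self, canonical_frame, tmp_path):
        p = tmp_path / "t.csv"
        canonical_frame.drop(columns=["canopy_cover"]).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="canopy_cover"):
            read_choice_table(p)

    def test_schema_mapping_renames_columns(self, canonical_frame, tmp_path):
        renamed = canonical_frame.rename(columns={"canopy_cover": "CanopyPct"})
        p = tmp_path / "t.csv"
        renamed.to_csv(p, index=False)
        ds = read_choice_table(p, schema={"CanopyPct": "canopy_cover"})
        assert len(ds) == 3

    def test_percent_understory_rescaled(self, canonical_frame, tmp_path):
        pct = canonical_frame.assign(
            understory_density=canonical_frame["understory_density"] * 100)
        p = tmp_path / "t.csv"
        pct.to_csv(p, index=False)
        ds = read_choice_table(p, understory_unit="percent")
        orig = read_choice_table_orig = canonical_frame["understory_density"].to_numpy()
        got = ds.to_frame()["understory_density"].to_numpy()
        assert np.allclose(np.sort(got), np.sort(orig))

    def test_group_flatten_round_trip(self, tmp_path):
        dataset, _ = generate_dataset(SimConfig(n_individuals_per_stage=5, seed=3))
        p = tmp_path / "rt.csv"
        dataset.to_csv(p)
        back = read_choice_table(p)
        pd.testing.assert_frame_equal(
            back.to_frame().sort_values(["set_id", "role"]).reset_index(drop=True),
            dataset.to_frame().sort_values(["set_id", "role"]).reset_index(drop=True),
        )

    def test_spreadsheet_converter(self, canonical_frame, tmp_path):
        xlsx = tmp_path / "s1.xlsx"
        canonical_frame.to_excel(xlsx, index=False)
        csv = convert_spreadsheet(xlsx, tmp_path / "s1.csv")
        ds = read_choice_table(csv)
        assert len(ds) == 3


class TestStageAssignment:
    @pytest.mark.parametrize(
        "day,independent,expected",
        [
            (0, False, "early_dependent"),
            (3, False, "early_dependent"),
            (7, False, "early_dependent"),
            (8, False, "late_dependent"),
            (15, False, "late_dependent"),
            (25, True, "independent"),
            (2, True, "independent"),
        ],
    )
    def test_stage_boundaries(self, day, independent, expected):
        assert assign_stage(day, independent) == expected

    def test_negative_day_rejected(self):
        with pytest.raises(ValueError):
            assign_stage(-1)

    @hyp_settings(max_examples=60, derandomize=True)
    @given(d1=st.integers(0, 60), d2=st.integers(0, 60), ind=st.booleans())
    def test_total_and_monotone_in_day(self, d1, d2, ind):
        order = ["early_dependent", "late_dependent", "independent"]
        s1, s2 = assign_stage(d1, ind), assign_stage(d2, ind)
        assert s1 in order and s2 in order
        if d1 <= d2:
            assert order.index(s1) <= order.index(s2)


class TestBroodFilter:
    def _dataset(self):
        sets = []
        for brood, inds in (("bA", ["i1", "i2"]), ("bB", ["i3", "i4"]), ("bC", ["i5"])):
            for ind in inds:
                for k in range(2):
                    sets.append(make_choice_set(
                        set_id=f"{ind}_{k}", individual=ind, brood=brood,
                        stage="early_dependent", day=4,
                        rng=np.random.default_rng(hash((ind, k)) % 2**31)))
        return Dataset(sets=sets, species="synthetic")

    def test_one_individual_retained_per_brood(self):
        d = self._dataset()
        out = filter_one_per_brood(d, seed=1)
        broods = {cs.brood_id for cs in out.sets}
        assert broods == {"bA", "bB", "bC"}
        for brood in broods:
            inds = {cs.individual_id for cs in out.sets if cs.brood_id == brood}
            assert len(inds) == 1

    def test_deterministic_given_seed(self):
        d = self._dataset()
        a = {cs.set_id for cs in filter_one_per_brood(d, seed=9).sets}
        b = {cs.set_id for cs in filter_one_per_brood(d, seed=9).sets}
        assert a == b

    def test_single_individual_brood_unchanged(self):
        d = self._dataset()
        out = filter_one_per_brood(d, seed=2)
        assert {cs.set_id for cs in out.sets if cs.brood_id == "bC"} == \
            {cs.set_id for cs in d.sets if cs.brood_id == "bC"}

    def test_individual_count_halves_for_two_bird_broods(self):
        d = self._dataset()
        out = filter_one_per_brood(d, seed=3)
        assert len(out.individuals()) == 3  # from 5


class TestStandardization:
    def test_zscore_pools_all_locations(self):
        dataset, _ = generate_dataset(SimConfig(n_individuals_per_stage=10, seed=1))
        std, record = standardize_covariates(dataset)
        frame = std.to_frame()
        for c in ALL_COVARIATES:
            v = frame[c].to_numpy()
            assert abs(v.mean()) < 1e-10
            assert abs(v.std() - 1) < 1e-10

    def test_round_trip_through_scaling_record(self):
        dataset, _ = generate_dataset(SimConfig(n_individuals_per_stage=6, seed=2))
        std, record = standardize_covariates(dataset)
        orig = dataset.to_frame()
        back = std.to_frame()
        for c in ALL_COVARIATES:
            assert np.allclose(record.inverse(c, back[c].to_numpy()),
                               orig[c].to_numpy(), atol=1e-9)

    def test_scheme_none_is_identity(self):
        dataset, _ = generate_dataset(SimConfig(n_individuals_per_stage=4, seed=3))
        same, record = standardize_covariates(dataset, scheme="none")
        pd.testing.assert_frame_equal(same.to_frame(), dataset.to_frame())
        assert record.transform("canopy_cover", 55.0) == 55.0

    def test_zero_variance_covariate_rejected(self):
        rng = np.random.default_rng(5)
        sets = [make_choice_set(set_id=f"s{i}", rng=rng) for i in range(3)]
        const_sets = []
        for cs in sets:
            locs = tuple(
                Location(**{**loc.covariates(), "litter_depth": 2.0}, role=loc.role)
                for loc in cs.locations
            )
            const_sets.append(ChoiceSet(
                set_id=cs.set_id, species=cs.species, individual_id=cs.individual_id,
                brood_id=cs.brood_id, stage=cs.stage, locations=locs,
                used_index=cs.used_index))
        d = Dataset(sets=const_sets, species="synthetic")
        with pytest.raises(ValueError, match="litter_depth"):
            standardize_covariates(d)
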