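import numpy as np
import pandas as pd
import pytest
import shapely

from urbantol.errors import CurationGapError, ParameterError
from urbantol.filtering import (CurationTable, apply_filters, filter_curation,
                                filter_geoprivacy, filter_quality,
                                reclassify_subspecies)


def make_records(rows):
    defaults = dict(taxon_name="sp A", group="g", latitude=0.5, longitude=0.5,
                    observed_on="2015-06-01", quality_grade="research",
                    geoprivacy="open", user_id=1)
    return pd.DataFrame([{**defaults, **r} for r in rows])


BOX = shapely.box(0.0, 0.0, 1.0, 1.0)


class TestQuality:
    def test_record_just_before_window_dropped(self):
        recs = make_records([{"observed_on": "2010-12-31"},
                             {"observed_on": "2011-01-01"}])
        out = filter_quality(recs, window=("2011-01-01", "2021-12-31"))
        assert len(out.records) == 1
        assert out.dropped["outside_window"] == 1

    def test_hand_counted_toy_set(self):
        recs = make_records([
            {"quality_grade": "casual"},
            {"latitude": 5.0},  # outside region
            {}, {}, {},
        ])
        out = filter_quality(recs, region=BOX)
        assert len(out.records) == 3
        assert out.dropped == {"not_research_grade": 1, "bad_coordinates": 0,
                               "outside_window": 0, "outside_region": 1}

    def test_all_passing_is_identity(self):
        recs = make_records([{}, {}, {}])
        out = filter_quality(recs, region=BOX)
        pd.testing.assert_frame_equal(out.records, recs)

    def test_region_boundary_is_inclusive(self):
        recs = make_records([{"latitude": 0.0, "longitude": 0.0},
                             {"latitude": 1.0, "longitude": 1.0}])
        out = filter_quality(recs, region=BOX)
        assert len(out.records) == 2

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            filter_quality(make_records([{}]), window=("2021-01-01", "2011-01-01"))


class TestGeoprivacy:
    @staticmethod
    def _species(name, n_obscured, n_open):
        return ([{"taxon_name": name, "geoprivacy": "obscured"}] * n_obscured
                + [{"taxon_name": name, "geoprivacy": "open"}] * n_open)

    def test_species_over_threshold_removed_entirely(self):
        recs = make_records(self._species("A", 7, 3))  # 70% > 60%
        out = filter_geoprivacy(recs)
        assert len(out.records) == 0
        assert out.dropped["species_over_obscured_threshold"] == 10

    def test_exactly_at_threshold_survives(self):
        # 6/10 = 60% is NOT more than 60%: species kept, obscured rows dropped
        recs = make_records(self._species("A", 6, 4))
        out = filter_geoprivacy(recs)
        assert len(out.records) == 4
        assert out.dropped == {"species_over_obscured_threshold": 0,
                               "obscured_record": 6}

    def test_unobscured_species_untouched(self):
        recs = make_records(self._species("A", 0, 5))
        out = filter_geoprivacy(recs)
        pd.testing.assert_frame_equal(out.records, recs)

    def test_share_is_computed_before_obscured_removal(self):
        """Running the stage twice shows why the order is fixed: after one
        pass no obscured records remain, so every share is 0 and a second
        pass can never remove a species."""
        recs = make_records(self._species("A", 6, 4) + self._species("B", 8, 2))
        once = filter_geoprivacy(recs)
        again = filter_geoprivacy(once.records)
        pd.testing.assert_frame_equal(again.records, once.records)
        assert again.dropped == {"species_over_obscured_threshold": 0,
                                 "obscured_record": 0}


def curation_frame(rows):
    defaults = dict(native=True, terrestrial=True, effort_proxy_ok=True,
                    include=True, parent_species="")
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestSubspecies:
    def test_subspecies_merge_with_parent(self):
        cur = CurationTable(curation_frame([
            {"taxon_name": "Genus parens"},
            {"taxon_name": "Genus parens alpha", "parent_species": "Genus parens"},
        ]))
        recs = make_records([{"taxon_name": "Genus parens alpha"}] * 3
                            + [{"taxon_name": "Genus parens"}] * 2)
        out = reclassify_subspecies(recs, cur)
        assert (out["species_id"] == "Genus parens").all()
        assert len(out) == 5

    def test_no_subspecies_is_identity(self):
        cur = CurationTable(curation_frame([{"taxon_name": "Genus unus"}]))
        recs = make_records([{"taxon_name": "Genus unus"}] * 2)
        out = reclassify_subspecies(recs, cur)
        assert (out["species_id"] == out["taxon_name"]).all()

    def test_two_subspecies_share_one_species_id(self):
        cur = CurationTable(curation_frame([
            {"taxon_name": "Genus parens"},
            {"taxon_name": "Genus parens alpha", "parent_species": "Genus parens"},
            {"taxon_name": "Genus parens beta", "parent_species": "Genus parens"},
        ]))
        recs = make_records([{"taxon_name": "Genus parens alpha"},
                             {"taxon_name": "Genus parens beta"}])
        out = reclassify_subspecies(recs, cur)
        assert out["species_id"].nunique() == 1

    def test_unmapped_subspecies_raises_with_names(self):
        cur = CurationTable(curation_frame([{"taxon_name": "Genus parens"}]))
        recs = make_records([{"taxon_name": "Genus parens gamma"}])
        with pytest.raises(CurationGapError, match="gamma"):
            reclassify_subspecies(recs, cur)


class TestCuration:
    def test_flag_conjunction(self):
        cur = CurationTable(curation_frame([
            {"taxon_name": "all good"},
            {"taxon_name": "alien", "native": False},
            {"taxon_name": "fish", "terrestrial": False},
            {"taxon_name": "oddball", "include": False},
        ]))
        recs = make_records([{"taxon_name": n}
                             for n in ["all good", "alien", "fish", "oddball"]])
        recs["species_id"] = recs["taxon_name"]
        out = filter_curation(recs, cur)
        assert list(out.records["taxon_name"]) == ["all good"]
        assert out.dropped == {"non_native": 1, "non_terrestrial": 1,
                               "not_effort_proxy": 0, "excluded_other": 1}

    def test_all_flags_true_is_identity(self):
        cur = CurationTable(curation_frame([{"taxon_name": "sp A"}]))
        recs = make_records([{}, {}])
        recs["species_id"] = recs["taxon_name"]
        out = filter_curation(recs, cur)
        pd.testing.assert_frame_equal(out.records, recs)

    def test_missing_entry_strict_raises(self):
        cur = CurationTable(curation_frame([{"taxon_name": "known"}]))
        recs = make_records([{"taxon_name": "mystery"}])
        recs["species_id"] = recs["taxon_name"]
        with pytest.raises(CurationGapError, match="mystery"):
            filter_curation(recs, cur, strict=True)


class TestFullChain:
    @pytest.fixture
    def chain_inputs(self):
        cur = CurationTable(curation_frame([
            {"taxon_name": "Genus bonus"},
            {"taxon_name": "Genus bonus prime", "parent_species": "Genus bonus"},
            {"taxon_name": "Genus alien", "native": False},
            {"taxon_name": "Genus privatus"},
        ]))
        recs = make_records(
            [{"taxon_name": "Genus bonus"}] * 4
            + [{"taxon_name": "Genus bonus prime"}] * 2
            + [{"taxon_name": "Genus alien"}] * 3
            + [{"taxon_name": "Genus privatus", "geoprivacy": "obscured"}] * 7
            + [{"taxon_name": "Genus privatus"}] * 3
            + [{"taxon_name": "Genus bonus", "quality_grade": "casual"}])
        return recs, cur

    def test_bookkeeping_is_exact(self, chain_inputs):
        recs, cur = chain_inputs
        out = apply_filters(recs, cur, region=BOX)
        assert len(recs) == len(out.records) + out.n_dropped

    def test_chain_is_idempotent(self, chain_inputs):
        recs, cur = chain_inputs
        once = apply_filters(recs, cur, region=BOX)
        twice = apply_filters(once.records, cur, region=BOX)
        pd.testing.assert_frame_equal(
            twice.records.reset_index(drop=True),
            once.records.reset_index(drop=True))
        assert twice.n_dropped == 0

    def test_expected_survivors(self, chain_inputs):
        recs, cur = chain_inputs
        out = apply_filters(recs, cur, region=BOX)
        # privatus: 7/10 obscured (70% > 60%) -> species removed; alien ->
        # curation; casual -> quality; bonus + prime merge to 6 records
        assert len(out.records) == 6
        assert set(out.records["species_id"]) == {"Genus bonus"}
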