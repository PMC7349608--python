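"""Store and access service: queries, re-aggregation, privacy."""

import json

import pytest

from hexsense import synth
from hexsense.acoustics import batch_stats, init_stats, merge_stats
from hexsense.spatial_index import CellId, cell_centroid, parent_cell
from hexsense.store_access import (
    AccessService,
    AuthError,
    AuthRegistry,
    QueryRequest,
    Store,
    UnsupportedCombinationError,
    bbox_ring,
)

HOUR = 3_600_000


class TestStore:
    def test_upsert_then_read(self):
        store = Store()
        s = init_stats(61.0, kind="LAeq")
        store.upsert_aggregate(10, 15, "00" * 8, 0, "LAeq", s)
        assert store.entries(10, 15)[("00" * 8, 0, "LAeq")] == s

    def test_last_write_wins(self):
        store = Store()
        store.upsert_aggregate(10, 15, "00" * 8, 0, "LAeq", init_stats(61.0))
        second = batch_stats([50.0, 70.0])
        store.upsert_aggregate(10, 15, "00" * 8, 0, "LAeq", second)
        assert store.entries(10, 15)[("00" * 8, 0, "LAeq")] == second

    def test_raw_store_refuses_user_bearing_records(self, city_run):
        m = next(iter(city_run.store.raw.values()))
        import dataclasses

        with pytest.raises(ValueError):
            Store().put_raw(dataclasses.replace(m, user_id="user-0001"))

    def test_snapshot_round_trip(self, city_run, tmp_path):
        city_run.store.save(tmp_path / "snap")
        again = Store.load(tmp_path / "snap")
        assert again.combos() == city_run.store.combos()
        for combo in again.combos():
            assert again.entries(*combo) == city_run.store.entries(*combo)
        assert again.mappings == city_run.store.mappings
        assert set(again.raw) == set(city_run.store.raw)


class TestQuery:
    def test_preaggregated_combo_served_verbatim(self, city_run):
        q = QueryRequest(
            resolution=10,
            window_length_min=15,
            time_range=city_run.time_range,
            boundary=bbox_ring(*city_run.model.bbox),
        )
        features = city_run.service.query_aggregates(q)
        stored = city_run.store.entries(10, 15)
        for f in features:
            for kind, s in f.stats.items():
                assert stored[(f.cell.token, f.window_start, kind)] == s

    def test_empty_region_yields_empty_collection(self, city_run):
        q = QueryRequest(
            resolution=10,
            window_length_min=15,
            time_range=city_run.time_range,
            boundary=bbox_ring(-20.0, -20.0, -19.9, -19.9),
        )
        fc = city_run.service.query(q)
        assert fc == {"type": "FeatureCollection", "features": []}

    def test_completeness_matches_brute_force_scan(self, city_run):
        """Query result set == brute-force filter of all stored entries."""
        bbox = (9.94, 48.37, 10.01, 48.43)
        window = (city_run.time_range[0] + 6 * HOUR, city_run.time_range[0] + 12 * HOUR)
        q = QueryRequest(
            resolution=10, window_length_min=15, time_range=window, boundary=bbox_ring(*bbox)
        )
        got = {
            (f.cell.token, f.window_start, kind)
            for f in city_run.service.query_aggregates(q)
            for kind in f.stats
        }
        from hexsense.spatial_index import cover_boundary

        cells = {c.token for c in cover_boundary(bbox_ring(*bbox), 10)}
        expect = {
            (cell, wstart, kind)
            for (cell, wstart, kind) in city_run.store.entries(10, 15)
            if cell in cells and wstart < window[1] and wstart + 15 * 60_000 > window[0]
        }
        assert got == expect and got  # non-empty region

    def test_time_window_filter_is_half_open(self, city_run):
        t0 = city_run.time_range[0]
        q = QueryRequest(
            resolution=10,
            window_length_min=15,
            time_range=(t0, t0 + 15 * 60_000),
            boundary=bbox_ring(*city_run.model.bbox),
        )
        for f in city_run.service.query_aggregates(q):
            assert f.window_start == t0

    def test_limit_offset_pagination(self, city_run):
        q = QueryRequest(
            resolution=10,
            window_length_min=15,
            time_range=city_run.time_range,
            boundary=bbox_ring(*city_run.model.bbox),
        )
        full = city_run.service.query_aggregates(q)
        q2 = QueryRequest(**{**q.__dict__, "limit": 5, "offset": 3})
        assert city_run.service.query_aggregates(q2) == full[3:8]

    def test_invalid_boundary_raises(self, city_run):
        q = QueryRequest(
            resolution=10,
            window_length_min=15,
            time_range=city_run.time_range,
            boundary=[(0.0, 0.0), (1.0, 1.0)],
        )
        with pytest.raises(ValueError):
            city_run.service.query(q)

    def test_degenerate_requests_rejected(self):
        with pytest.raises(ValueError):
            QueryRequest(resolution=10, window_length_min=15, time_range=(5, 5), boundary=[])
        with pytest.raises(ValueError):
            QueryRequest(resolution=16, window_length_min=15, time_range=(0, 1), boundary=[])


class TestReaggregation:
    def test_hourly_from_quarter_hours_equals_stored_hourly(self, city_run):
        """Two-path check: merge four 15-min windows vs the hourly log."""
        only15 = Store()
        for key, s in city_run.store.entries(10, 15).items():
            only15.upsert_aggregate(10, 15, key[0], key[1], key[2], s)
        derived = AccessService(only15).reaggregate(10, 60)
        stored = city_run.store.entries(10, 60)
        assert set(derived) == set(stored)
        for key in derived:
            assert derived[key].count == stored[key].count
            assert derived[key].min == stored[key].min
            assert derived[key].max == stored[key].max
            assert abs(derived[key].mean - stored[key].mean) <= 1e-9

    def test_coarse_cells_from_fine_equals_raw_batch_oracle(self, city_run):
        """(5, 15) is not pre-aggregated; on-the-fly result must match
        a from-scratch batch aggregation of the raw records."""
        derived = city_run.service.reaggregate(5, 15)
        oracle = synth.ground_truth(city_run.model, city_run.time_range, 5, 15)
        assert set(derived) == set(oracle)
        for key in oracle:
            assert derived[key].count == oracle[key].count
            assert abs(derived[key].mean - oracle[key].mean) <= 1e-9

    def test_unaligned_window_length_unsupported(self, city_run):
        with pytest.raises(UnsupportedCombinationError):
            city_run.service.reaggregate(10, 45)

    def test_finer_than_stored_resolution_unsupported(self, city_run):
        with pytest.raises(UnsupportedCombinationError):
            city_run.service.reaggregate(12, 15)

    def test_query_path_uses_reaggregation_for_missing_combo(self, city_run):
        q = QueryRequest(
            resolution=5,
            window_length_min=15,
            time_range=city_run.time_range,
            boundary=bbox_ring(*city_run.model.bbox),
        )
        features = city_run.service.query_aggregates(q)
        assert features
        derived = city_run.service.reaggregate(5, 15)
        for f in features:
            for kind, s in f.stats.items():
                assert derived[(f.cell.token, f.window_start, kind)] == s


class TestPrivacy:
    def test_query_responses_contain_no_user_token(self, city_run):
        q = QueryRequest(
            resolution=10,
            window_length_min=60,
            time_range=city_run.time_range,
            boundary=bbox_ring(*city_run.model.bbox),
        )
        text = json.dumps(city_run.service.query(q))
        assert "user" not in text.lower()
        for token in synth.user_tokens(city_run.model):
            assert token not in text

    def test_owner_gets_exactly_their_measurements(self, city_run):
        # pick two users that actually contributed
        users = [u for u, ids in city_run.store.mappings.items() if ids][:2]
        assert len(users) == 2
        tokens = {u: t for t, u in synth.user_tokens(city_run.model).items()}
        got_a = city_run.service.fetch_user_measurements(tokens[users[0]])
        got_b = city_run.service.fetch_user_measurements(tokens[users[1]])
        assert {m.id for m in got_a} == city_run.store.mappings[users[0]]
        assert {m.id for m in got_b} == city_run.store.mappings[users[1]]
        assert not ({m.id for m in got_a} & {m.id for m in got_b})
        assert all(m.user_id is None for m in got_a + got_b)

    def test_invalid_or_missing_token_refused(self, city_run):
        with pytest.raises(AuthError):
            city_run.service.fetch_user_measurements("not-a-token")
        with pytest.raises(AuthError):
            city_run.service.fetch_user_measurements(None)
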