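"""Streaming pipeline: windows, retention, anonymization, replay."""

import json

import pytest

from hexsense import geodata, synth
from hexsense.spatial_index import CellId, parent_cell
from hexsense.store_access import AuthRegistry, Store
from hexsense.stream_core import (
    LATE,
    Broker,
    Confirmation,
    Pipeline,
    Rejection,
    TopicLayout,
    WindowSpec,
    assign_window,
)

MIN = 60_000
T1600 = 1_600_000_000_000


def feature(lon=9.99, lat=48.40, created_at=T1600, value=61.0, **props):
    p = {
        "sensorType": "smartphone-mic",
        "trigger": "manual",
        "createdAt": created_at,
        "values": [{"type": "LAeq", "value": value}],
    }
    p.update(props)
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [lon, lat]},
        "properties": p,
    }


class TestAssignWindow:
    def test_floor_alignment(self):
        spec = WindowSpec(length_min=15)
        w = assign_window(7 * MIN + 30_000, spec, now=8 * MIN)
        assert (w.start, w.end) == (0, 15 * MIN)

    def test_half_open_boundary(self):
        spec = WindowSpec(length_min=15)
        w = assign_window(15 * MIN, spec, now=15 * MIN)
        assert (w.start, w.end) == (15 * MIN, 30 * MIN)

    def test_late_iff_past_retention(self):
        spec = WindowSpec(length_min=15, retention_min=1440)
        end = 15 * MIN
        assert assign_window(1, spec, now=end + 1440 * MIN) is LATE
        w = assign_window(1, spec, now=end + 1440 * MIN - 1)
        assert w.start == 0

    def test_retention_shorter_than_length_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(length_min=60, retention_min=15)


class TestIngress:
    def test_valid_anonymous_feature_confirmed(self):
        pipe = Pipeline()
        result = pipe.ingest(feature(), now=T1600)
        assert isinstance(result, Confirmation) and result.id
        assert len(pipe.broker.topic(pipe.layout.raw)) == 1
        assert len(pipe.broker.topic(pipe.layout.mapping)) == 0

    def test_invalid_rejected_atomically(self):
        pipe = Pipeline()
        result = pipe.ingest(feature(lat=95.0), now=T1600)
        assert isinstance(result, Rejection)
        assert any("lat" in str(v) for v in result.violations)
        assert all(len(pipe.broker.topic(t)) == 0 for t in pipe.layout.all_topics())

    def test_malformed_document_rejected(self):
        pipe = Pipeline()
        assert isinstance(pipe.ingest("{not json", now=T1600), Rejection)

    def test_unknown_token_rejected(self):
        pipe = Pipeline(auth=AuthRegistry())
        assert isinstance(pipe.ingest(feature(), token="nope", now=T1600), Rejection)

    def test_raw_log_keyed_by_created_at_with_monotone_offsets(self):
        pipe = Pipeline()
        for k in range(5):
            pipe.ingest(feature(created_at=T1600 + k), now=T1600 + k)
        recs = list(pipe.broker.topic(pipe.layout.raw))
        assert [r.offset for r in recs] == [0, 1, 2, 3, 4]
        assert [r.key for r in recs] == [str(T1600 + k) for k in range(5)]


class TestPreparator:
    def run_one(self, token=None):
        auth = AuthRegistry()
        auth.register("tok-1", "user-1")
        pipe = Pipeline(auth=auth)
        res = pipe.ingest(feature(), token=token, now=T1600)
        assert isinstance(res, Confirmation)
        pipe.prepare_pending()
        return pipe, res.id

    def test_authenticated_record_yields_mapping_and_two_anonymized(self):
        pipe, mid = self.run_one(token="tok-1")
        mapping = list(pipe.broker.topic(pipe.layout.mapping))
        assert len(mapping) == 1
        assert mapping[0].value == {"userId": "user-1", "measurementId": mid}
        for res in (10, 5):
            assert len(pipe.broker.topic(pipe.layout.anonymized_topic(res))) == 1

    def test_anonymous_record_yields_no_mapping(self):
        pipe, _ = self.run_one(token=None)
        assert len(pipe.broker.topic(pipe.layout.mapping)) == 0

    def test_anonymized_records_carry_no_user_id(self):
        pipe, _ = self.run_one(token="tok-1")
        for res in (10, 5):
            rec = list(pipe.broker.topic(pipe.layout.anonymized_topic(res)))[0]
            assert "user" not in json.dumps(rec.value).lower()

    def test_keys_are_hierarchy_consistent_cell_tokens(self):
        pipe, _ = self.run_one()
        k10 = list(pipe.broker.topic(pipe.layout.anonymized_topic(10)))[0].key
        k5 = list(pipe.broker.topic(pipe.layout.anonymized_topic(5)))[0].key
        assert parent_cell(CellId.from_token(k10), 5).token == k5


class TestRetentionPerLog:
    """A record's lateness is judged per aggregation log."""

    def ingest_at(self, pipe, created_at, arrival):
        res = pipe.ingest(feature(created_at=created_at), now=arrival)
        assert isinstance(res, Confirmation)
        pipe.run()

    def counts(self, store):
        return {
            combo: sum(s.count for s in store.entries(*combo).values())
            for combo in [(10, 15), (10, 60), (5, 60), (10, 1440), (5, 1440)]
        }

    def test_late_for_short_windows_still_updates_long_ones(self):
        store = Store()
        pipe = Pipeline(store=store)
        created = T1600 - (T1600 % (1440 * MIN))  # midnight: first 15-min window
        arrival = created + 15 * MIN + 1440 * MIN  # exactly at the w15 horizon
        self.ingest_at(pipe, created, arrival)
        assert self.counts(store) == {
            (10, 15): 0, (10, 60): 1, (5, 60): 1, (10, 1440): 1, (5, 1440): 1
        }
        assert pipe.counters["late_dropped"] == 1

    def test_past_every_retention_changes_nothing(self):
        store = Store()
        pipe = Pipeline(store=store)
        created = T1600 - (T1600 % (1440 * MIN))
        arrival = created + 2 * 1440 * MIN  # daily window end + full retention
        res = pipe.ingest(feature(created_at=created), now=arrival)
        assert isinstance(res, Confirmation)  # 2 days old: passes ingress age check
        pipe.run()
        assert pipe.counters["late_dropped"] == 5  # dropped by every log
        assert self.counts(store) == {c: 0 for c in self.counts(store)}

    def test_just_inside_retention_updates_exactly_its_window(self):
        store = Store()
        pipe = Pipeline(store=store)
        created = T1600 - (T1600 % (1440 * MIN))
        arrival = created + 15 * MIN + 1440 * MIN - 1
        self.ingest_at(pipe, created, arrival)
        entries = store.entries(10, 15)
        assert len(entries) == 1
        (cell, wstart, kind), s = next(iter(entries.items()))
        assert wstart == created and s.count == 1


class TestRunReplay:
    def build(self, n=40):
        model = synth.CityModel(n_users=6, rate_per_hour=3, seed=9)
        items = synth.generate_workload(model, (0, 4 * 3_600_000))
        return items

    def run_items(self, items, tmp_path, name):
        store = Store()
        pipe = Pipeline(store=store)
        for it in items:
            assert isinstance(pipe.ingest(it.feature, now=it.arrival), Confirmation)
        pipe.run()
        out = tmp_path / name
        store.save(out)
        return store, (out / "aggregates.ndjson").read_bytes()

    def test_replay_from_scratch_is_byte_identical(self, tmp_path):
        items = self.build()
        _, bytes_a = self.run_items(items, tmp_path, "a")
        _, bytes_b = self.run_items(items, tmp_path, "b")
        assert bytes_a == bytes_b

    def test_run_is_idempotent_on_repeat(self, tmp_path):
        items = self.build()
        store = Store()
        pipe = Pipeline(store=store)
        for it in items:
            pipe.ingest(it.feature, now=it.arrival)
        pipe.run()
        store.save(tmp_path / "one")
        pipe.run()  # nothing pending
        store.save(tmp_path / "two")
        assert (tmp_path / "one" / "aggregates.ndjson").read_bytes() == (
            tmp_path / "two" / "aggregates.ndjson"
        ).read_bytes()

    def test_split_stream_equals_single_run(self, tmp_path):
        items = self.build()
        store = Store()
        pipe = Pipeline(store=store)
        half = len(items) // 2
        for it in items[:half]:
            pipe.ingest(it.feature, now=it.arrival)
        pipe.run()
        for it in items[half:]:
            pipe.ingest(it.feature, now=it.arrival)
        pipe.run()
        store.save(tmp_path / "split")
        _, whole = self.run_items(items, tmp_path, "whole")
        assert (tmp_path / "split" / "aggregates.ndjson").read_bytes() == whole

    def test_count_conservation_per_combo(self, tmp_path):
        items = self.build()
        store, _ = self.run_items(items, tmp_path, "c")
        n = len(items)
        for combo in [(10, 15), (10, 60), (5, 60), (10, 1440), (5, 1440)]:
            for kind in ("LAeq", "LCpeak"):
                total = sum(
                    s.count for (c, w, k), s in store.entries(*combo).items() if k == kind
                )
                assert total == n

    def test_broker_round_trips_through_ndjson(self, tmp_path):
        items = self.build()
        pipe = Pipeline()
        for it in items:
            pipe.ingest(it.feature, now=it.arrival)
        pipe.run()
        pipe.broker.save(tmp_path / "topics")
        again = Broker.load(tmp_path / "topics")
        for name in pipe.broker.topic_names:
            a = [(r.key, r.timestamp, r.offset, r.value) for r in pipe.broker.topic(name)]
            b = [(r.key, r.timestamp, r.offset, r.value) for r in again.topic(name)]
            assert a == b


class TestLayout:
    def test_default_topology_has_nine_logs_and_no_5_15(self):
        layout = TopicLayout()
        assert len(layout.all_topics()) == 9
        assert (5, 15) not in layout.average_combos
        assert set(layout.average_combos) == {(10, 15), (10, 60), (5, 60), (10, 1440), (5, 1440)}
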