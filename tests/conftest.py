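"""Shared fixtures: one synthetic city day pushed through the pipeline."""

from types import SimpleNamespace

import pytest

from hexsense import synth
from hexsense.store_access import AccessService, AuthRegistry, Store
from hexsense.stream_core import Confirmation, Pipeline

T0 = 0  # epoch-aligned midnight, UTC
DAY_MS = 24 * 3_600_000


@pytest.fixture(scope="session")
def city_model():
    """Default study conditions: ~5,800 measurements, 2 hotspots, 24 h."""
    return synth.CityModel()


@pytest.fixture(scope="session")
def city_run(city_model):
    """The full default workload ingested and aggregated once."""
    time_range = (T0, T0 + DAY_MS)
    items = synth.generate_workload(city_model, time_range)
    auth = AuthRegistry()
    for token, user in synth.user_tokens(city_model).items():
        auth.register(token, user)
    store = Store()
    pipeline = Pipeline(auth=auth, store=store)
    for item in items:
        result = pipeline.ingest(item.feature, token=item.token, now=item.arrival)
        assert isinstance(result, Confirmation)
    pipeline.run()
    return SimpleNamespace(
        model=city_model,
        time_range=time_range,
        items=items,
        auth=auth,
        store=store,
        pipeline=pipeline,
        service=AccessService(store, auth),
    )
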