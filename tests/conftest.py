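import pytest

from marrec.datamodel import DetectorConfig
from marrec.detector import detect
from marrec.synthgen import make_scenarios
from marrec.timeline import build_timeline, recover_original_orders


@pytest.fixture(scope="session")
def scenarios():
    return make_scenarios()


@pytest.fixture
def config():
    return DetectorConfig()


def run_pipeline(bundle, config=None, recover=False, directives=()):
    """Recover (optionally), build timelines, detect; returns calls."""
    config = config or DetectorConfig()
    orders = bundle.orders
    if recover:
        orders, _ = recover_original_orders(orders, bundle.audits, config)
    timelines = build_timeline(orders, bundle.audits, list(directives), bundle.mars, config)
    return detect(timelines, config)
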