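import logging

import pytest

from iscore import worked_example


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # the unscored-gene warnings are intentional; keep test output readable
    logging.getLogger("iscore").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def example():
    """The fixed 3-TF / 6-gene worked example (net, profile)."""
    return worked_example()
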