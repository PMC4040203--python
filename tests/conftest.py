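import pytest

from sacgen.config import default_config
from sacgen.runner import run_saccade

MAGNITUDES = (4, 8, 12, 16, 20)


@pytest.fixture(scope="session")
def scenario_runs(tmp_path_factory):
    """End-to-end runs of all five configured scenarios (shared).

    The 4-degree run also exercises the trace exports.
    """
    out = tmp_path_factory.mktemp("saccade_runs")
    cfg = default_config()
    runs = {}
    for mag in MAGNITUDES:
        rep, arr = run_saccade(mag, cfg, out_dir=out if mag == 4 else None)
        runs[mag] = (rep, arr)
    return runs
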