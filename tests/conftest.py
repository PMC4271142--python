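import os

import pytest

from pipescript import EngineOptions, run_script


@pytest.fixture
def run_dir(tmp_path):
    return str(tmp_path)


def run_pipeline(source, run_dir, **options):
    """Run a script with test-friendly defaults; returns (status, engine)."""
    defaults = dict(run_dir=run_dir, write_report=False, dispatch_tick=0.003)
    defaults.update(options)
    return run_script(source, options=EngineOptions(**defaults),
                      origin=os.path.join(run_dir, "script.bds"))


@pytest.fixture
def run(run_dir):
    def _run(source, **options):
        return run_pipeline(source, run_dir, **options)

    return _run
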