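import dataclasses

import numpy as np
import pytest

from latticeplate import ConstructSpec, LoadCase, default_porosity_law


@pytest.fixture(scope="session")
def law():
    return default_porosity_law()


@pytest.fixture(scope="session")
def canonical_spec():
    return ConstructSpec()


@pytest.fixture()
def small_spec():
    """Coarse construct for fast unit tests (not the converged density)."""
    return ConstructSpec(mesh_divisions=(24, 4, 6), band_divisions=(2, 2, 2))


@pytest.fixture(scope="session")
def bite_600():
    return LoadCase(600.0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full canonical pipeline run shared by the acceptance tests.

    Runs calibrate -> mesh -> sweep -> train -> risk -> optimize ->
    report once per session at the default configuration.
    """
    from latticeplate.pipeline import RunConfig, run_all

    outdir = tmp_path_factory.mktemp("canonical_run")
    cfg = RunConfig(seed=2025, outdir=str(outdir))
    run_all(cfg)
    return cfg, outdir
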