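"""Shared fixtures.

Heavy artefacts (trained models, the end-to-end demo run) are
session-scoped so the cost is paid once; everything is seeded and
generated programmatically.
"""

from __future__ import annotations

import numpy as np
import pytest

import trajblend as tb
from trajblend.datamodel import RunConfig


@pytest.fixture(scope="session")
def bridge_spec():
    """Default study conditions: 5 types + bridge, 2000 cells, 300 genes."""
    return tb.SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def bridge_ref(bridge_spec):
    return tb.make_reference(bridge_spec)


@pytest.fixture(scope="session")
def bridge_ref_lognorm(bridge_ref):
    return tb.normalize_log1p(bridge_ref)


@pytest.fixture(scope="session")
def ref5():
    """5 discrete types, no bridge (the deconvolution fixture)."""
    return tb.make_reference(tb.SyntheticSpec(seed=0, bridge=None))


@pytest.fixture(scope="session")
def fraction_model(ref5):
    return tb.train_fraction_ae(ref5, 200, RunConfig(seed=0))


@pytest.fixture(scope="session")
def trained_vae(bridge_ref_lognorm):
    return tb.train_beta_vae(bridge_ref_lognorm, RunConfig(seed=0))


@pytest.fixture(scope="session")
def vae_factors(trained_vae, bridge_ref_lognorm):
    return tb.extract_type_factors(trained_vae, bridge_ref_lognorm)


@pytest.fixture(scope="session")
def generated_cells(trained_vae, vae_factors, bridge_ref_lognorm):
    types = bridge_ref_lognorm.cell_types
    fractions = tb.CellFractionVector(types, np.full(len(types), 1 / len(types)))
    return tb.generate_cells(trained_vae, vae_factors, fractions,
                             target_type="bridge", scale=2.0, seed=1)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full omission-rescue pipeline on the demo dataset, seed 0."""
    from trajblend.pipeline import make_demo, run_pipeline
    outdir = tmp_path_factory.mktemp("demo")
    config = make_demo(outdir, seed=0)
    manifest, outputs = run_pipeline(config)
    return config, manifest, outputs
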