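import numpy as np
import pytest

import gaitscore as gs
from gaitscore import pipeline


@pytest.fixture(scope="session")
def cfg():
    return gs.PipelineConfig()


@pytest.fixture(scope="session")
def clean_recording():
    """A noise-free synthetic walk: zero pathology, default cadence."""
    return gs.generate_recording(gs.SyntheticGaitProfile(seed=7), subject_id="clean")


@pytest.fixture(scope="session")
def healthy_reference(cfg):
    """Four healthy adults, their CGG, and the fitted grey model."""
    recs = gs.generate_cohort(4, "healthy", seed=11)
    cgg = pipeline.build_reference_cgg(recs, cfg)
    import pandas as pd
    table = pd.concat([gs.run_extract(r, cgg, cfg) for r in recs], ignore_index=True)
    model = gs.run_fit(table, cfg)
    return {"recordings": recs, "cgg": cgg, "table": table, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
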