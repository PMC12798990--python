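import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ligandfish as lf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_library():
    return lf.default_phantom_library()


@pytest.fixture(scope="session")
def phantom_screen(phantom_library):
    """Full phantom-scenario pipeline at a fixed seed (shared; read-only)."""
    config = lf.ExperimentConfig(seed=1)
    runs, manifest = lf.simulate_experiment(phantom_library, config)
    bundle = lf.run_pipeline(runs, lf.PipelineConfig(seed=1))
    return runs, manifest, bundle


@pytest.fixture()
def tiny_run():
    """One binder + one inert compound, short noise-free run."""
    compounds = [
        lf.TrueCompound("binder", lf.MolecularFormula(19, 18, 7), 2.0, 3e7, 2.0),
        lf.TrueCompound("inert", lf.MolecularFormula(15, 12, 5), 4.0, 2e7, 1.0),
    ]
    config = lf.ExperimentConfig(
        seed=5,
        run_duration=6.0,
        intensity_cv=0.0,
        rt_jitter_sd=0.0,
        mz_jitter_ppm=0.0,
        noise_peak_rate=0.0,
    )
    runs, manifest = lf.simulate_experiment(compounds, config)
    return compounds, config, runs, manifest
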