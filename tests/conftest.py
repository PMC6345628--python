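import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisefree_tip_scene():
    """One rendered tip-enriched scene without noise, shared across tests."""
    import filomap as fm

    traces = fm.generate_traces(10, (2.0, 4.5), seed=21, image_shape=(512, 512))
    cls = fm.localization_class("tip_enriched", tip_fold=4.0, detection_prob=1.0)
    return fm.render_scene(traces, cls, noise=fm.NoiseParams.off(), seed=8)
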