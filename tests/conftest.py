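import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def null_panel():
    """10,000 pure-null z-statistics (global null GWAS panel)."""
    from sumherit import ZPanel
    z = np.random.default_rng(11).standard_normal(10_000)
    return ZPanel(z=z, n=50_000)


@pytest.fixture
def small_panel():
    """2,000-SNP panel with a sprinkling of real effects."""
    from sumherit import ZPanel
    g = np.random.default_rng(7)
    z = g.standard_normal(2000)
    z[:20] += g.choice([-4.0, 4.0], 20)
    return ZPanel(z=z, n=20_000)


@pytest.fixture
def binned_config():
    """Correction settings forcing the fast binned KDE path."""
    from sumherit import CorrectionConfig
    return CorrectionConfig(mode="binned")
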