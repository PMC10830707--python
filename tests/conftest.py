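import numpy as np
import pytest
from hypothesis import settings

from isomix.records import CLAW, IsotopeRecord, SourceDistribution

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sources():
    """Default marine/terrestrial arthropod source pair."""
    return (
        SourceDistribution("marine", mu_C=-10.0, mu_N=9.0, sd_C=1.0, sd_N=1.0, n=9),
        SourceDistribution("terrestrial", mu_C=-28.0, mu_N=2.0, sd_C=1.5, sd_N=1.5, n=8),
    )


@pytest.fixture(scope="session")
def claw():
    return CLAW


def make_consumer(sample_id, d13C, d15N, site="DM"):
    return IsotopeRecord(sample_id=sample_id, site=site, habitat="beach",
                         tissue="lizard_tail", d13C=d13C, d15N=d15N, cn_ratio=3.5)


@pytest.fixture(scope="session")
def random_consumers(sources, claw):
    """20 consumers drawn on the mixing segment with process noise, plus their
    true marine fractions (frozen generator seed)."""
    rng = np.random.default_rng(42)
    mar, ter = sources
    mu = np.array([[mar.mu_C + claw.dC_mean, mar.mu_N + claw.dN_mean],
                   [ter.mu_C + claw.dC_mean, ter.mu_N + claw.dN_mean]])
    var = np.array([[mar.sd_C, mar.sd_N], [ter.sd_C, ter.sd_N]]) ** 2 \
        + np.array([claw.dC_sd, claw.dN_sd]) ** 2
    out = []
    for k in range(20):
        p = rng.uniform(0.02, 0.98)
        m = p * mu[0] + (1 - p) * mu[1]
        sd = np.sqrt(p**2 * var[0] + (1 - p) ** 2 * var[1])
        x = m + sd * rng.standard_normal(2)
        out.append((make_consumer(f"c{k:02d}", float(x[0]), float(x[1])), p))
    return out
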