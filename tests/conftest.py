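import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def std_normal_cloud():
    """4000 draws from the standard bivariate normal (KUD area oracle input)."""
    return np.random.default_rng(42).standard_normal((4000, 2))


@pytest.fixture(scope="session")
def three_sources():
    from isoniche.synthetic import SourceGroup
    return [
        SourceGroup("mesopelagic_fish", -19.5, 9.0, 0.5, 0.6),
        SourceGroup("ommastrephid_squid", -17.5, 12.0, 0.6, 0.5),
        SourceGroup("gelatinous", -18.5, 6.5, 0.7, 0.8),
    ]


@pytest.fixture(scope="session")
def isotope_csv(tmp_path_factory):
    """Small well-formed isotope table on disk."""
    path = tmp_path_factory.mktemp("io") / "samples.csv"
    df = pd.DataFrame({
        "species": ["blue_shark", "swordfish", "swordfish"],
        "region": ["w_mediterranean"] * 3,
        "lon": [3.2, 4.1, 5.0],
        "lat": [39.5, 38.7, 40.1],
        "d13c": [-17.5, -18.3, -18.1],
        "d15n": [11.2, 11.5, 11.9],
    })
    df.to_csv(path, index=False)
    return path, df
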