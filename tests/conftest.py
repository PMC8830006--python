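import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# the 5 mm arm-length warning is expected noise in synthetic fixtures
logging.getLogger("bifmorph").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_class_frame(rng):
    """Small case-control morphometry frame with a known alpha effect."""
    n = 80
    rows = []
    for aneurysm, alpha_mu in ((0, 95.0), (1, 125.0)):
        for i in range(n):
            rows.append({
                "subject_id": f"{aneurysm}{i:03d}",
                "site": "MCA_an" if aneurysm else "MCA",
                "group": "case" if aneurysm else "control",
                "aneurysm": aneurysm,
                "alpha_deg": float(np.clip(rng.normal(alpha_mu, 20.0), 1, 179)),
                "phi1_obs_deg": float(np.clip(rng.normal(45, 20), 1, 179)),
                "phi2_obs_deg": float(np.clip(rng.normal(60, 18), 1, 179)),
                "r0_mm": float(max(rng.normal(1.4, 0.2), 0.3)),
                "r1_mm": float(max(rng.normal(1.1, 0.15), 0.25)),
                "r2_mm": float(max(rng.normal(0.9, 0.12), 0.2)),
            })
    return pd.DataFrame(rows)
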