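import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xplat.core import ExpressionMatrix
from xplat.simulate import make_canonical_design

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    """Canonical benchmark design: 5 MOAs x 3 chemicals x 3 replicates + 18 controls."""
    return make_canonical_design()


@pytest.fixture(scope="session")
def treated_ids(design):
    return list(design.treated["sample_id"])


def planted_ratio_matrix(design, rng, n_noise=100, n_block=50, effect=2.0, noise_sd=0.2):
    """Log2-ratio matrix with two anti-correlated MOA-driven gene blocks plus noise."""
    treated = design.treated
    moa_sign = {"AhR": 1.0, "CAR/PXR": -1.0, "Cytotox": 1.0, "DNA_Damage": -1.0, "PPARA": 0.0}
    base = np.array([moa_sign[m] for m in treated["moa"]]) * effect
    up = base + rng.normal(0, noise_sd, (n_block, len(treated)))
    down = -base + rng.normal(0, noise_sd, (n_block, len(treated)))
    noise = rng.normal(0, noise_sd, (n_noise, len(treated)))
    genes = ([f"up{i:03d}" for i in range(n_block)]
             + [f"dn{i:03d}" for i in range(n_block)]
             + [f"nz{i:03d}" for i in range(n_noise)])
    return ExpressionMatrix(genes, list(treated["sample_id"]),
                            np.vstack([up, down, noise]), "log2ratio", "synthetic")


@pytest.fixture()
def planted_blocks(design):
    return planted_ratio_matrix(design, np.random.default_rng(7))
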