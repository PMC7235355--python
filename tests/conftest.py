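import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bridgenet import (
    CorrelationMatrix,
    ItemResponseMatrix,
    ScaleDefinition,
    SyntheticSpec,
    generate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_items(
    p: int, community: str = "ED", lo: int = 0, hi: int = 6, reverse=()
) -> list[ScaleDefinition]:
    return [
        ScaleDefinition(
            item_id=f"{community}{j + 1:02d}",
            instrument=community,
            community=community,
            likert_min=lo,
            likert_max=hi,
            reverse_coded=j in reverse,
        )
        for j in range(p)
    ]


def random_corr(p: int, rng: np.random.Generator, n: int = 200) -> np.ndarray:
    """Sample correlation matrix of random Gaussian data (valid, full rank)."""
    X = rng.standard_normal((n, p))
    return np.corrcoef(X, rowvar=False)


def corr_obj(S: np.ndarray, n: int = 200, method: str = "pearson") -> CorrelationMatrix:
    p = S.shape[0]
    return CorrelationMatrix(
        S=S,
        item_ids=[f"V{j + 1:02d}" for j in range(p)],
        n_effective=np.full((p, p), n),
        method=method,
    )


def random_weights(p: int, rng: np.random.Generator, density: float = 0.5) -> np.ndarray:
    """Random symmetric signed edge-weight matrix with zero diagonal."""
    W = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    vals = rng.uniform(-0.5, 0.5, len(iu[0]))
    vals[rng.random(len(vals)) > density] = 0.0
    W[iu] = vals
    return W + W.T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-community Likert dataset with known ground truth."""
    spec = SyntheticSpec(
        p_community_a=8,
        p_community_b=8,
        n=300,
        n_redundant_pairs=0,
        missing_rate=0.0,
        n_reverse_coded=1,
        seed=7,
    )
    m, gt = generate_dataset(spec)
    return spec, m, gt
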