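import numpy as np
import pytest

from metdecode_kit.io_formats import MixtureCounts
from metdecode_kit.simulator import make_synthetic_atlas, sample_proportions


@pytest.fixture
def small_atlas():
    """A 6-entity, 60-region block atlas with its true ratios."""
    atlas, ratios = make_synthetic_atlas(6, 60, seed=42, mean_depth=300)
    return atlas, ratios


@pytest.fixture
def noiseless_mixture():
    """Exactly representable mixtures of a noiseless atlas at high depth.

    Methylated counts are rounded at depth 1e6, so the mixture ratios
    equal the atlas-row convex combinations up to 1e-6 quantization.
    """
    atlas, _ = make_synthetic_atlas(5, 50, seed=7, mean_depth=1_000_000, noiseless=True)
    A_true = sample_proportions(20, 5, 1.0, rng=3)
    R = A_true @ (atlas.M / atlas.D)
    D = np.full((20, 50), 1_000_000, dtype=np.int64)
    M = np.rint(R * D).astype(np.int64)
    mix = MixtureCounts(
        samples=[f"s{i}" for i in range(20)], regions=atlas.regions, D=D, M=M
    )
    return atlas, mix, A_true
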