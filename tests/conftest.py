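"""Shared fixtures: small deterministic matrices and latent-factor sets."""

import numpy as np
import pytest

from omicsfill import MultiOmicsSet, OmicsMatrix


def make_matrix(values, mask=None, name="omics"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    p, n = values.shape
    return OmicsMatrix(values, np.asarray(mask, bool),
                       [f"f{i}" for i in range(p)],
                       [f"s{j}" for j in range(n)], name)


def latent_factor_pair(seed, *, n=50, p_target=100, p_sources=(300, 250),
                       rank=3, noise_sd=0.3, missing_rate=0.10):
    """Target matrix with MCAR missingness + complete correlated sources.

    Returns (masked_target, truth_target, sources, locations).
    """
    from omicsfill import MissingLocations

    rng = np.random.default_rng(seed)
    F = rng.standard_normal((rank, n))
    sample_ids = [f"s{j}" for j in range(n)]
    T = rng.standard_normal((p_target, rank)) @ F \
        + noise_sd * rng.standard_normal((p_target, n))
    sources = []
    for si, p in enumerate(p_sources):
        G = rng.standard_normal((p, rank)) @ F + noise_sd * rng.standard_normal((p, n))
        sources.append(OmicsMatrix(G, np.zeros_like(G, dtype=bool),
                                   [f"src{si}_{i}" for i in range(p)],
                                   sample_ids, f"source{si}"))
    mask = rng.random(T.shape) < missing_rate
    # keep every row estimable
    for r in np.nonzero(mask.all(axis=1))[0]:
        mask[r, 0] = False
    vals = T.copy()
    vals[mask] = np.nan
    masked = OmicsMatrix(vals, mask, [f"t{i}" for i in range(p_target)],
                         sample_ids, "target")
    truth = OmicsMatrix(T, np.zeros_like(mask), list(masked.feature_ids),
                        sample_ids, "target")
    return masked, truth, sources, MissingLocations.from_masks([masked])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_incomplete():
    """4x5 matrix with two missing entries."""
    vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0],
                     [2.0, 4.0, 6.0, 8.0, 10.0],
                     [1.5, np.nan, 4.5, 6.0, 7.5],
                     [0.0, 1.0, np.nan, 3.0, 4.0]])
    return make_matrix(vals)
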