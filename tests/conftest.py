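import numpy as np
import pytest
from hypothesis import settings

import crossprofiler as cp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def helix_chain():
    """Ideal-geometry 12-residue alpha-helical backbone."""
    n = 12
    return cp.backbone_from_dihedrals(
        np.full(n, -60.0), np.full(n, -45.0), "ADKLMNPQRSTV")


@pytest.fixture
def planted_population():
    """Three planted dihedral clusters (noise 3 deg, seed 1) + true labels."""
    spec = cp.FixtureSpec(seed=1, k_clusters=3, members_per_cluster=50,
                          angular_noise_deg=3.0)
    return cp.generate_segment_population(spec)


@pytest.fixture
def uniform_background():
    return np.full(20, 0.05)


def random_segments(rng, n, L=9):
    """Plain random segments for property tests."""
    segs = []
    for k in range(n):
        ang = rng.uniform(-179.0, 180.0, 2 * L)
        seq = "".join(rng.choice(list(cp.ALPHABET), L))
        segs.append(cp.DihedralSegment(
            source=f"r{k}", chain_id="A", start=1, sequence=seq,
            phi=ang[0::2], psi=ang[1::2], resnum_start=1, resnum_end=L))
    return segs
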