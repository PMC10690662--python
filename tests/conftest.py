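import numpy as np
import pytest

import sipcom as sp


@pytest.fixture(scope="session")
def small_spec():
    """32^3 grid at 2 mm, brain ellipsoid 24/26/24 mm."""
    return sp.PhantomSpec(
        shape=(32, 32, 32),
        voxel_size_mm=2.0,
        semi_axes_mm=(24.0, 26.0, 24.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return sp.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noiseless_spec():
    return sp.PhantomSpec(
        shape=(32, 32, 32),
        voxel_size_mm=2.0,
        semi_axes_mm=(24.0, 26.0, 24.0),
        noise_sd=0.0,
        smooth_fwhm_mm=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_spec):
    return sp.generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def cohort():
    return sp.load_cohort()


def brute_force_clusters(
    z: np.ndarray, mask: np.ndarray, threshold: float, connectivity: int
) -> list[set[tuple[int, int, int]]]:
    """Independent flood-fill connected-component oracle.

    Pure-python BFS over supra-threshold in-mask voxels; neighbourhood by
    Chebyshev/offset rule for 6/18/26 connectivity.
    """
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                manhattan = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((di, dj, dk))
    supra = {tuple(v) for v in np.argwhere((z > threshold) & mask)}
    components = []
    remaining = set(supra)
    while remaining:
        seed_vox = remaining.pop()
        comp = {seed_vox}
        frontier = [seed_vox]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(comp)
    return components
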