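"""Shared fixtures: tiny, fast problem instances.

The tiny acoustic configuration uses a 1 MHz sampling rate so that a
64-sample record covers the whole 38 mm grid diagonal (c dt = 1.5 mm);
this keeps dense-oracle comparisons affordable.
"""

import numpy as np
import pytest

import patlv as P


@pytest.fixture(scope="session")
def grid8():
    return P.make_grid(8, 38.0)


@pytest.fixture(scope="session")
def tiny_acoustics():
    # c dt = 1.5 mm per sample; 64 samples cover the 53.7 mm diagonal
    return P.AcousticConfig(c=1500.0, fs=1e6, T=64)


@pytest.fixture(scope="session")
def tiny_square(grid8):
    return P.make_square(grid8, Q=4, pitch_mm=4.0)


@pytest.fixture(scope="session")
def tiny_operator(tiny_square, grid8, tiny_acoustics):
    return P.build_projection(tiny_square, grid8, tiny_acoustics)


@pytest.fixture(scope="session")
def grid64():
    return P.make_grid(64, 38.0)


@pytest.fixture(scope="session")
def forbild64(grid64):
    return P.forbild_phantom(grid64)


def dense_oracle(geometry, grid, acoustics, profile=None):
    """Brute-force dense operator built entry-by-entry from the model formula.

    Independent of the sparse construction path: loops over elements,
    pixels and temporal samples, evaluating the interpolation weight,
    directivity and decay directly.
    """
    import math

    if profile is None:
        profile = P.DirectivityProfile()
    pos = geometry.all_positions()
    nrm = geometry.all_normals()
    Y, X = grid.pixel_centers()
    yv, xv = Y.ravel(), X.ravel()
    T = acoustics.T
    n2 = grid.n * grid.n
    cdt = acoustics.sample_distance_mm
    blocks = []
    for p, nv in zip(pos, nrm):
        A = np.zeros((T, n2))
        for k in range(n2):
            dy, dx = yv[k] - p[0], xv[k] - p[1]
            r = max(math.hypot(dy, dx), grid.pixel_size / 2.0)
            ang = math.acos(
                min(1.0, max(-1.0, (dy * nv[0] + dx * nv[1]) / r))
            )
            d = P.directivity(profile, ang)
            amp = d / (2.0 * math.pi * (r / cdt))
            tau = r / cdt
            for j in range(T):
                w = 1.0 - abs(tau - j)
                if w > 0:
                    A[j, k] = w * amp
        blocks.append(A)
    return blocks
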