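"""Shared fixtures: deterministic synthetic structures and curves."""

import logging

import numpy as np
import pytest

from hipsaxs.structure_model import CoarseStructure, apply_c2
from hipsaxs.synthetic_data import make_hexamer_half, sphere_cloud

logging.getLogger("hipsaxs").setLevel(logging.ERROR)


def bead_structure(coords, chain="A", first_res=1, b=None) -> CoarseStructure:
    n = len(coords)
    bvals = np.ones(n) if b is None else np.asarray(b, dtype=float)
    return CoarseStructure(
        np.asarray(coords, dtype=float), bvals, np.zeros(n, np.uint8),
        np.full(n, chain), np.arange(first_res, first_res + n),
        np.full(n, "ALA"), np.full(n, "CA"), "test beads",
    )


def fibonacci_sphere(m: int) -> np.ndarray:
    i = np.arange(m) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / m)
    theta = np.pi * (1.0 + 5**0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def ball_quadrature(radius: float, n_shells: int = 32,
                    pts_per_shell: int = 160) -> CoarseStructure:
    """Deterministic quadrature of a uniform ball: Fibonacci-point shells
    with volume weights carried in b.  Far more accurate than random
    sampling for closed-form comparisons."""
    coords, weights = [], []
    edges = np.linspace(0.0, radius, n_shells + 1)
    for k in range(n_shells):
        r = 0.5 * (edges[k] + edges[k + 1])
        vol = 4.0 / 3.0 * np.pi * (edges[k + 1] ** 3 - edges[k] ** 3)
        m = max(6, int(round(pts_per_shell * (r / radius) ** 2)))
        coords.append(fibonacci_sphere(m) * r)
        weights.append(np.full(m, vol / m))
    coords = np.vstack(coords)
    return bead_structure(coords, b=np.concatenate(weights))


SPHERE_RADIUS = 30.0


@pytest.fixture(scope="session")
def sphere_quadrature():
    """Uniform ball of radius 30 A as a deterministic quadrature."""
    return ball_quadrature(SPHERE_RADIUS)


@pytest.fixture(scope="session")
def sphere_points():
    """2000 random points uniform in a 30 A sphere (seeded)."""
    return bead_structure(sphere_cloud(2000, SPHERE_RADIUS, seed=11))


@pytest.fixture(scope="session")
def hexamer_half():
    return make_hexamer_half(seed=0)


@pytest.fixture(scope="session")
def hexamer_full(hexamer_half):
    return apply_c2(hexamer_half)


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form uniform-sphere form factor [3(sin x - x cos x)/x^3]^2."""
    x = np.asarray(q, dtype=float) * radius
    x = np.where(x == 0, 1e-12, x)
    amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    return amp**2


def sphere_pair_distance_density(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form pair-distance density of a uniform sphere (0 <= r <= 2R),
    normalized to unit integral."""
    r = np.asarray(r, dtype=float)
    u = r / radius
    p = 3.0 * r**2 / radius**3 * (1.0 - 0.75 * u + u**3 / 16.0)
    return np.where((r >= 0) & (r <= 2 * radius), p, 0.0)
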