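"""Small shared numerical helpers (rotations, seeding)."""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError


def as_vector3(x, name: str = "vector") -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise InvalidArgumentError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError(f"{name} must be finite")
    return v


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise InvalidArgumentError("cannot normalise the zero vector")
    return v / n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = unit(np.asarray(axis, dtype=float))
    k = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def perpendicular_unit(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit vector perpendicular to ``v``."""
    v = unit(v)
    w = rng.normal(size=3)
    w -= np.dot(w, v) * v
    # resample in the measure-zero event of near-parallel draw
    while np.linalg.norm(w) < 1e-12:
        w = rng.normal(size=3)
        w -= np.dot(w, v) * v
    return w / np.linalg.norm(w)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
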