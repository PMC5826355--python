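"""Antipodally balanced sphere tessellations for ODF sampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = ["SphereSampling", "icosphere_sampling"]


@dataclass(frozen=True)
class SphereSampling:
    """Unit directions used to sample spherical functions such as the ODF."""

    directions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or len(d) == 0:
            raise ValueError("directions must be a nonempty (n, 3) array")
        norms = np.linalg.norm(d, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("directions must have unit norm")

    @property
    def n(self) -> int:
        return len(self.directions)


def icosphere_sampling(subdivisions: int = 3) -> SphereSampling:
    """Subdivided-icosahedron tessellation (642 vertices at 3 subdivisions).

    Icosahedral subdivision preserves the antipodal symmetry of the
    icosahedron, so the vertex set is exactly closed under ``u -> -u`` —
    the property required for sampling even spherical functions.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    d = np.asarray(mesh.vertices, dtype=float)
    d /= np.linalg.norm(d, axis=1)[:, None]
    return SphereSampling(directions=d)
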