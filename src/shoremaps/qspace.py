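"""Cartesian DSI q-space sampling schemes.

Diffusion spectrum imaging (DSI) samples the reciprocal (q-) space of
diffusion encoding on an integer Cartesian grid restricted to a ball.  The
scanner acquires one hemisphere of the grid ("keyhole" acquisition) and the
magnitude signal, being antipodally symmetric, is duplicated onto the other
hemisphere before reconstruction.  A radius-5 grid yields 257 hemisphere
points plus the origin, hence 515 samples after symmetrization.

The b-value of a grid point ``g`` follows the narrow-pulse relation
``b = b_max * |g|^2 / R^2`` so that the outermost shell sits at ``b_max``.
Physical q-vectors (mm^-1) follow from ``b = 4 pi^2 q^2 tau`` with ``tau``
the effective diffusion time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionScheme",
    "build_dsi_scheme",
    "subset_by_bvalue",
    "write_scheme",
    "read_scheme",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """A q-space sampling table.

    Attributes
    ----------
    grid : (N, 3) int array
        Integer grid coordinates ``g`` of each sample.
    qvecs : (N, 3) float array
        Physical q-vectors in mm^-1.
    bvals : (N,) float array
        b-values in s/mm^2.
    is_b0 : (N,) bool array
        True for the single ``g = 0`` sample.
    radial_grid_size : int
        Grid radius R; all samples satisfy ``|g|^2 <= R^2``.
    b_max : float
        b-value assigned to the outermost shell, s/mm^2.
    tau : float
        Effective diffusion time in seconds (narrow-pulse bookkeeping).
    big_delta, small_delta : float or None
        Gradient separation and pulse duration in seconds, recorded for
        provenance only; when given, ``tau = big_delta - small_delta / 3``.
    """

    grid: np.ndarray
    qvecs: np.ndarray
    bvals: np.ndarray
    is_b0: np.ndarray
    radial_grid_size: int
    b_max: float
    tau: float
    big_delta: float | None = None
    small_delta: float | None = None

    def __post_init__(self) -> None:
        if int(np.sum(self.is_b0)) != 1:
            raise ValueError("scheme must contain exactly one b0 sample")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_samples(self) -> int:
        return len(self.bvals)

    @property
    def directions(self) -> np.ndarray:
        """Unit encoding directions; the b0 row is set to zero."""
        norm = np.linalg.norm(self.qvecs, axis=1)
        out = np.zeros_like(self.qvecs)
        nz = norm > 0
        out[nz] = self.qvecs[nz] / norm[nz, None]
        return out

    @property
    def b0_index(self) -> int:
        return int(np.flatnonzero(self.is_b0)[0])

    def hemisphere_mask(self) -> np.ndarray:
        """Keyhole half-grid: origin plus points whose first nonzero grid
        coordinate is positive (lexicographic sign rule)."""
        g = self.grid
        mask = np.zeros(len(g), dtype=bool)
        for i, (x, y, z) in enumerate(g):
            if x > 0 or (x == 0 and y > 0) or (x == 0 and y == 0 and z >= 0):
                mask[i] = True
        return mask


def _lattice_points(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    gx, gy, gz = np.meshgrid(r, r, r, indexing="ij")
    g = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.einsum("ij,ij->i", g, g) <= radius * radius
    g = g[keep]
    # deterministic order: by shell, then lexicographic
    n2 = np.einsum("ij,ij->i", g, g)
    order = np.lexsort((g[:, 2], g[:, 1], g[:, 0], n2))
    return g[order]


def build_dsi_scheme(
    radial_grid_size: int = 5,
    b_max: float = 8000.0,
    tau: float = 0.0538,
    big_delta: float | None = None,
    small_delta: float | None = None,
) -> AcquisitionScheme:
    """Enumerate the symmetrized Cartesian DSI scheme.

    All integer lattice points with ``|g|^2 <= R^2`` are kept;
    ``b = b_max |g|^2 / R^2`` and ``|q| = sqrt(b / (4 pi^2 tau))``.
    The default radius-5 grid has 515 samples, of which 32 fall in the
    low-b range (0, 1500) s/mm^2 used for tensor fitting.
    """
    if radial_grid_size < 1:
        raise ValueError(f"radial_grid_size must be >= 1, got {radial_grid_size}")
    if b_max <= 0:
        raise ValueError(f"b_max must be positive, got {b_max}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if big_delta is not None and small_delta is not None:
        tau = big_delta - small_delta / 3.0

    g = _lattice_points(radial_grid_size)
    n2 = np.einsum("ij,ij->i", g, g).astype(float)
    bvals = b_max * n2 / radial_grid_size**2
    qmag = np.sqrt(bvals / (4.0 * np.pi**2 * tau))
    gnorm = np.sqrt(n2)
    qvecs = np.zeros((len(g), 3))
    nz = gnorm > 0
    qvecs[nz] = g[nz] / gnorm[nz, None] * qmag[nz, None]
    return AcquisitionScheme(
        grid=g,
        qvecs=qvecs,
        bvals=bvals,
        is_b0=n2 == 0,
        radial_grid_size=radial_grid_size,
        b_max=float(b_max),
        tau=float(tau),
        big_delta=big_delta,
        small_delta=small_delta,
    )


def subset_by_bvalue(
    scheme: AcquisitionScheme,
    b_lo: float,
    b_hi: float,
    keep_b0: bool = True,
) -> AcquisitionScheme:
    """Samples with ``b in [b_lo, b_hi)``; the b0 sample is always carried
    alongside (needed to normalize attenuations) unless ``keep_b0=False``.

    Raises ``ValueError`` when no diffusion-weighted sample falls in the
    interval.
    """
    if b_lo >= b_hi:
        raise ValueError(f"empty interval [{b_lo}, {b_hi})")
    sel = (scheme.bvals >= b_lo) & (scheme.bvals < b_hi) & ~scheme.is_b0
    if not np.any(sel):
        raise ValueError(f"no diffusion samples with b in [{b_lo}, {b_hi}) s/mm^2")
    if keep_b0:
        sel = sel | scheme.is_b0
    return AcquisitionScheme(
        grid=scheme.grid[sel],
        qvecs=scheme.qvecs[sel],
        bvals=scheme.bvals[sel],
        is_b0=scheme.is_b0[sel],
        radial_grid_size=scheme.radial_grid_size,
        b_max=scheme.b_max,
        tau=scheme.tau,
        big_delta=scheme.big_delta,
        small_delta=scheme.small_delta,
    )


def write_scheme(scheme: AcquisitionScheme, stem: str | Path) -> None:
    """Serialize as FSL-dialect ``<stem>.bval``/``<stem>.bvec`` (bvecs one
    row per axis) plus a lossless TSV sidecar ``<stem>.tsv``."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".bval"), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(stem.with_suffix(".bvec"), scheme.directions.T, fmt="%.10g")
    df = pd.DataFrame(
        {
            "gx": scheme.grid[:, 0],
            "gy": scheme.grid[:, 1],
            "gz": scheme.grid[:, 2],
            "qx": scheme.qvecs[:, 0],
            "qy": scheme.qvecs[:, 1],
            "qz": scheme.qvecs[:, 2],
            "b": scheme.bvals,
            "is_b0": scheme.is_b0.astype(int),
        }
    )
    header = (
        f"# radial_grid_size={scheme.radial_grid_size} b_max={scheme.b_max} "
        f"tau={scheme.tau}\n"
    )
    with open(stem.with_suffix(".tsv"), "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def read_scheme(stem: str | Path) -> AcquisitionScheme:
    """Read a scheme written by :func:`write_scheme` from its TSV sidecar."""
    stem = Path(stem)
    with open(stem.with_suffix(".tsv"), encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"malformed scheme sidecar {stem}: missing header")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    return AcquisitionScheme(
        grid=df[["gx", "gy", "gz"]].to_numpy(dtype=int),
        qvecs=df[["qx", "qy", "qz"]].to_numpy(dtype=float),
        bvals=df["b"].to_numpy(dtype=float),
        is_b0=df["is_b0"].to_numpy(dtype=bool),
        radial_grid_size=int(meta["radial_grid_size"]),
        b_max=float(meta["b_max"]),
        tau=float(meta["tau"]),
    )
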