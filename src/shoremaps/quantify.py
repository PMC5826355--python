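"""Reduce index volumes to per-connection and per-region scalar measures.

Tract-based: each microstructural index is mapped onto every streamline of
a bundle (trilinear interpolation at equally spaced arc-length points) and
averaged per fiber, then the per-fiber means are averaged — unweighted —
across the bundle, giving one representative value per connection.

Region-based: gray matter is masked at a conservative probability
threshold (default 95%); the masked mean of each parcel is computed per
hemisphere and either averaged across hemispheres (controls) or restricted
to the contralateral hemisphere (patients).  Regions left empty by the
mask are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .phantom import CC_REGION, ToyGeometry

__all__ = [
    "NetworkDefinition",
    "streamline_mean",
    "connection_value",
    "gm_mask",
    "roi_means",
    "measure_records",
]

MEASURE_COLUMNS = [
    "subject",
    "group",
    "session",
    "unit_type",
    "unit_id",
    "index",
    "value",
]


@dataclass(frozen=True)
class NetworkDefinition:
    """A named motor network as a list of parcel-label pairs."""

    name: str  # CC | CORT | SUBCORT
    connections: list[tuple[str, str]]

    def __post_init__(self) -> None:
        cortical = {"M1", "SMA", "SC", "PM"}
        for a, b in self.connections:
            if self.name == "CORT" and not ({a, b} <= cortical):
                raise ValueError(f"CORT connection {a}-{b} outside cortical ROIs")
            if self.name == "SUBCORT" and "SC" in (a, b):
                raise ValueError("SUBCORT excludes the somatosensory cortex")
            if self.name == "CC" and CC_REGION not in (a, b):
                raise ValueError("CC connections must involve the corpus callosum")


def _resample_arclength(points: np.ndarray, step: float) -> np.ndarray:
    """Equally spaced points (spacing ``step``, voxel units) along a
    polyline, endpoints included."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("streamline must be an (n, 3) array")
    if len(points) == 1:
        return points
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(si, s, points[:, k])
    return out


def streamline_mean(
    volume: np.ndarray,
    streamline: np.ndarray,
    step: float = 0.5,
    interpolation: str = "trilinear",
) -> float:
    """Mean index value along one fiber.

    Streamline coordinates are voxel-space, 0-based, corner-origin (the
    value at the center of voxel ``(i, j, k)`` lives at coordinate
    ``i+0.5, j+0.5, k+0.5``).  Points outside the volume are discarded; a
    fully outside streamline is an error.
    """
    pts = _resample_arclength(streamline, step)
    shape = np.asarray(volume.shape, dtype=float)
    inside = np.all((pts >= 0) & (pts <= shape[None, :]), axis=1)
    if not inside.any():
        raise ValueError("streamline lies fully outside the volume")
    coords = (pts[inside] - 0.5).T  # corner-origin -> sample-center grid
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    vals = map_coordinates(
        np.asarray(volume, dtype=float), coords, order=order, mode="nearest"
    )
    return float(vals.mean())


def connection_value(
    bundle: list[np.ndarray],
    volume: np.ndarray,
    step: float = 0.5,
    weight_by_length: bool = False,
) -> float | None:
    """Unweighted mean of per-fiber means (the paper-default convention);
    ``weight_by_length`` switches to arc-length weighting.  An empty
    bundle is recorded as missing (None), never as zero."""
    if not bundle:
        return None
    means, weights = [], []
    for line in bundle:
        means.append(streamline_mean(volume, line, step=step))
        seg = np.linalg.norm(np.diff(np.asarray(line, float), axis=0), axis=1)
        weights.append(seg.sum())
    if weight_by_length:
        w = np.asarray(weights)
        return float(np.average(means, weights=w)) if w.sum() > 0 else float(np.mean(means))
    return float(np.mean(means))


def gm_mask(gm_probability: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Binary mask of voxels with GM probability >= threshold."""
    p = np.asarray(gm_probability)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return p >= threshold


def roi_means(
    index_map: np.ndarray,
    geometry: ToyGeometry,
    mask: np.ndarray,
    hemisphere_policy: str = "bilateral_mean",
    weight_by_voxels: bool = False,
) -> tuple[dict[str, float], list[str]]:
    """Masked per-region means under a hemisphere policy.

    ``bilateral_mean`` averages the two hemispheric means with equal
    weight (``weight_by_voxels`` switches to voxel-count weighting);
    ``contralateral_only`` uses the left-hemisphere (contralesional
    analog) mean alone.  Returns ``(values, excluded)`` where regions with
    no masked voxel in the required hemisphere(s) are dropped and listed.
    """
    if index_map.shape != geometry.parcellation.shape or mask.shape != index_map.shape:
        raise ValueError("index map, parcellation and mask shapes must match")
    if hemisphere_policy not in ("bilateral_mean", "contralateral_only"):
        raise ValueError(f"unknown hemisphere policy {hemisphere_policy!r}")
    values: dict[str, float] = {}
    excluded: list[str] = []
    parc = geometry.parcellation
    for name in geometry.region_names:
        left_label, right_label = geometry.labels_for(name)
        sides = []
        for label in ([left_label] if hemisphere_policy == "contralateral_only" else [left_label, right_label]):
            sel = (parc == label) & mask
            n = int(sel.sum())
            if n:
                sides.append((float(index_map[sel].mean()), n))
        if not sides or (
            hemisphere_policy == "bilateral_mean" and len(sides) < 2
        ):
            excluded.append(name)
            continue
        if weight_by_voxels:
            tot = sum(n for _, n in sides)
            values[name] = sum(v * n for v, n in sides) / tot
        else:
            values[name] = float(np.mean([v for v, _ in sides]))
    return values, excluded


def measure_records(
    subject: str,
    group: str,
    session: int,
    index_name: str,
    index_map: np.ndarray,
    geometry: ToyGeometry,
    mask: np.ndarray,
    step: float = 0.5,
) -> pd.DataFrame:
    """Long-format records for one (acquisition, index) pair: every
    network connection plus every GM region, using the contralateral
    hemisphere for patients and the bilateral mean for controls."""
    rows = []
    for net, conn in geometry.connections:
        val = connection_value(geometry.bundles[(net, conn)], index_map, step=step)
        if val is not None:
            rows.append(
                (subject, group, session, "connection", f"{net}:{conn}", index_name, val)
            )
    policy = "contralateral_only" if group == "patient" else "bilateral_mean"
    values, _ = roi_means(index_map, geometry, mask, hemisphere_policy=policy)
    for name, val in values.items():
        rows.append((subject, group, session, "roi", name, index_name, val))
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
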