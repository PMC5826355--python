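"""Diffusion tensor fitting and the classical scalar indices MD and FA.

The tensor is fitted to the b0-normalized attenuation on the low-b portion
of the DSI scheme (b < 1,500 s/mm^2, 32 encoding directions on the default
radius-5 grid) by weighted log-linear least squares.  Mean diffusivity is
the eigenvalue mean, and fractional anisotropy the normalized eigenvalue
dispersion

    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / sqrt(l1^2+l2^2+l3^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qspace import AcquisitionScheme

__all__ = ["TensorFit", "fit_tensor", "md", "fa", "fit_tensor_volume"]


@dataclass(frozen=True)
class TensorFit:
    """A single-voxel diffusion tensor.

    ``evals`` are sorted descending and clamped at zero; ``clamped`` flags
    voxels where negative eigenvalues were produced by noise and set to 0.
    """

    tensor: np.ndarray  # (3, 3) symmetric, mm^2/s
    evals: np.ndarray  # (3,) descending, >= 0
    evecs: np.ndarray  # (3, 3), columns matching evals
    clamped: bool

    @property
    def e1(self) -> np.ndarray:
        """Principal diffusion direction (unit eigenvector of l1)."""
        return self.evecs[:, 0]


def _design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    u = scheme.directions
    b = scheme.bvals
    return -b[:, None] * np.column_stack(
        [
            u[:, 0] ** 2,
            u[:, 1] ** 2,
            u[:, 2] ** 2,
            2 * u[:, 0] * u[:, 1],
            2 * u[:, 0] * u[:, 2],
            2 * u[:, 1] * u[:, 2],
        ]
    )


def _unpack(d6: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = d6
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def fit_tensor(signal: np.ndarray, scheme: AcquisitionScheme) -> TensorFit:
    """Weighted log-linear LS tensor fit of a b0-normalized attenuation.

    A first OLS pass on log-attenuations provides predicted signals whose
    squares serve as WLS weights (the standard first-order correction for
    the log transform heteroscedasticity).  Eigenvalues are sorted
    descending; negative values are clamped to zero and flagged.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) != scheme.n_samples:
        raise ValueError("signal length does not match scheme")
    if len(signal) < 7:
        raise ValueError("tensor fit needs at least 7 samples including b0")
    s0 = signal[scheme.b0_index]
    if s0 <= 0:
        raise ValueError("non-positive b0 signal")
    atten = np.clip(signal / s0, 1e-10, None)
    dwi = ~scheme.is_b0
    X = _design_matrix(scheme)[dwi]
    y = np.log(atten[dwi])
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient tensor design (too few distinct directions)")
    d6, *_ = np.linalg.lstsq(X, y, rcond=None)
    # WLS pass: weights = squared predicted signal
    w = np.exp(X @ d6) ** 2
    Xw = X * w[:, None]
    d6 = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    D = _unpack(d6)
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    clamped = bool(np.any(evals < 0))
    evals = np.clip(evals, 0.0, None)
    return TensorFit(tensor=D, evals=evals, evecs=evecs, clamped=clamped)


def md(fit: TensorFit) -> float:
    """Mean diffusivity, (l1 + l2 + l3) / 3, in mm^2/s."""
    return float(np.mean(fit.evals))


def fa(fit: TensorFit) -> float:
    """Fractional anisotropy in [0, 1]; defined as 0 for an all-zero tensor."""
    l1, l2, l3 = fit.evals
    denom = l1 * l1 + l2 * l2 + l3 * l3
    if denom == 0:
        return 0.0
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    return float(np.sqrt(0.5 * num / denom))


def fit_tensor_volume(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise tensor fit over a 4-D volume.

    Returns float32 maps ``md``, ``fa``, a principal-direction map ``e1``
    of shape ``(*spatial, 3)`` and the boolean ``clamped`` flag map.
    Voxels outside ``mask`` (or with non-positive b0) are left at zero.
    """
    spatial = volume.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    md_map = np.zeros(spatial, dtype=np.float32)
    fa_map = np.zeros(spatial, dtype=np.float32)
    e1_map = np.zeros(spatial + (3,), dtype=np.float32)
    clamped = np.zeros(spatial, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        sig = volume[idx]
        if sig[scheme.b0_index] <= 0:
            continue
        fit = fit_tensor(sig, scheme)
        md_map[idx] = md(fit)
        fa_map[idx] = fa(fit)
        e1_map[idx] = fit.e1
        clamped[idx] = fit.clamped
    return {"md": md_map, "fa": fa_map, "e1": e1_map, "clamped": clamped}
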