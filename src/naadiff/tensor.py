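"""Diffusion tensor estimation and VOI fiber-geometry extraction.

The diffusion tensor is estimated per voxel by log-linear least squares on
``ln S = ln S0 - b g^T T g`` (tensor in um^2/ms, b in s/mm^2, exponent scaled
by 1e-3) and diagonalized to yield the standard scalar maps: fractional
anisotropy (FA), mean diffusivity (MD = (l1+l2+l3)/3), parallel diffusivity
(l_par = l1) and perpendicular diffusivity (l_perp = (l2+l3)/2).

The fiber geometry of a spectroscopy VOI is the set of per-voxel angles
between the primary eigenvector and each diffusion-weighting gradient
direction of the DW-MRS scan; the dispersion model uses it to account for
macroscopic tract curvature inside the VOI. Angles are folded to [0, 90]
degrees because the eigenvector sign is physically meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError, FitError, GeometryError

__all__ = [
    "TensorVoxel",
    "FiberGeometry",
    "design_matrix",
    "fit_tensor_loglinear",
    "scalar_maps",
    "fit_tensor_volume",
    "voi_fiber_angles",
]


@dataclass
class TensorVoxel:
    """Fitted diffusion tensor and derived scalars for one voxel."""

    tensor: np.ndarray  # symmetric 3x3, um^2/ms
    s0: float
    eigenvalues: np.ndarray  # sorted descending, um^2/ms
    eigenvectors: np.ndarray  # columns matching eigenvalues, unit norm
    fa: float
    md: float
    lambda_par: float
    lambda_perp: float
    valid: bool = True
    clamped: bool = False  # negative eigenvalue clamped to zero

    @property
    def primary_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class FiberGeometry:
    """Per-voxel primary fiber directions of a VOI with angles to the DW-MRS
    gradient directions (degrees, folded to [0, 90]) and normalized voxel
    weights."""

    eigenvectors: np.ndarray  # (n_voxels, 3)
    angles_deg: np.ndarray  # (n_voxels, n_gradients)
    weights: np.ndarray  # (n_voxels,), sums to 1

    def __post_init__(self) -> None:
        self.eigenvectors = np.atleast_2d(np.asarray(self.eigenvectors, dtype=float))
        self.angles_deg = np.atleast_2d(np.asarray(self.angles_deg, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.eigenvectors.shape[0] != self.weights.size:
            raise GeometryError("eigenvector and weight counts differ")
        s = self.weights.sum()
        if s <= 0:
            raise GeometryError("voxel weights must have positive sum")
        self.weights = self.weights / s

    @property
    def n_voxels(self) -> int:
        return self.weights.size

    @classmethod
    def single_voxel(cls, angles_deg) -> "FiberGeometry":
        """Convenience: one voxel specified directly by its gradient angles."""
        ang = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        return cls(eigenvectors=np.array([[1.0, 0.0, 0.0]]), angles_deg=ang[None, :], weights=np.array([1.0]))

    def to_dict(self) -> dict:
        return {
            "eigenvectors": self.eigenvectors.tolist(),
            "angles_deg": self.angles_deg.tolist(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberGeometry":
        return cls(
            eigenvectors=np.asarray(d["eigenvectors"]),
            angles_deg=np.asarray(d["angles_deg"]),
            weights=np.asarray(d["weights"]),
        )


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear DTI design matrix.

    Row layout: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    scaled by 1e-3 so the fitted tensor elements come out in um^2/ms.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    X = np.column_stack([np.ones_like(b), -1e-3 * b[:, None] * cols])
    return X


def _tensor_from_coeffs(c: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = c
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def scalar_maps(eigenvalues: np.ndarray) -> tuple[float, float, float, float, bool]:
    """(fa, md, lambda_par, lambda_perp, clamped) from descending eigenvalues.

    Negative eigenvalues (noise) are clamped to zero and flagged.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    clamped = bool(np.any(lam < 0))
    lam = np.clip(lam, 0.0, None)
    md = float(lam.mean())
    denom = float(np.sum(lam**2))
    if denom == 0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom))
    return fa, md, float(lam[0]), float((lam[1] + lam[2]) / 2.0), clamped


def fit_tensor_loglinear(
    signals: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    weighted: bool = True,
) -> TensorVoxel:
    """Fit one voxel's diffusion tensor by (weighted) log-linear least squares.

    Non-positive signals are excluded. Weights are the squared signals
    (the standard first-order variance correction for log-transformed data).

    Raises
    ------
    DesignError: rank-deficient direction set.
    FitError: fewer than 7 usable measurements or no b=0-equivalent anchor.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    usable = s > 0
    if usable.sum() < 7:
        raise FitError(f"only {int(usable.sum())} positive signals; need >= 7")
    X = design_matrix(b[usable], g[usable])
    if np.linalg.matrix_rank(X) < 7:
        raise DesignError("diffusion direction set is rank deficient for tensor fitting")
    y = np.log(s[usable])
    if weighted:
        w = s[usable] ** 2
        Xw = X * w[:, None]
        coef, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    s0 = float(np.exp(coef[0]))
    T = _tensor_from_coeffs(coef[1:])

    lam, V = np.linalg.eigh(T)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    # Fix eigenvector sign: first nonzero component positive (sign is arbitrary).
    for j in range(3):
        v = V[:, j]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            V[:, j] = -v
    fa, md, lpar, lperp, clamped = scalar_maps(lam)
    return TensorVoxel(
        tensor=T, s0=s0, eigenvalues=lam, eigenvectors=V,
        fa=fa, md=md, lambda_par=lpar, lambda_perp=lperp, clamped=clamped,
    )


def fit_tensor_volume(
    data: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
) -> dict[tuple[int, int, int], TensorVoxel]:
    """Fit every (masked) voxel of a 4-D DWI volume; invalid voxels are skipped."""
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    out: dict[tuple[int, int, int], TensorVoxel] = {}
    for idx in zip(*np.nonzero(mask)):
        try:
            out[idx] = fit_tensor_loglinear(data[idx], bvals, bvecs)
        except FitError:
            continue
    return out


def voi_fiber_angles(
    eigenvectors: np.ndarray,
    gradient_directions: np.ndarray,
    voi_to_image_rotation: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> FiberGeometry:
    """Angles between VOI-voxel primary eigenvectors and DW-MRS gradients.

    Gradient directions are given in the VOI frame and rotated into the image
    frame by ``voi_to_image_rotation`` (orthonormal 3x3; identity by default).
    The angle per voxel and gradient is ``arccos |e . g|`` in degrees --
    folding to [0, 90] identifies antipodal axes.
    """
    E = np.atleast_2d(np.asarray(eigenvectors, dtype=float))
    if E.size == 0:
        raise GeometryError("empty VOI mask: no eigenvectors")
    G = np.atleast_2d(np.asarray(gradient_directions, dtype=float))
    if voi_to_image_rotation is not None:
        R = np.asarray(voi_to_image_rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("voi_to_image_rotation must be orthonormal")
        G = G @ R.T
    E = E / np.linalg.norm(E, axis=1, keepdims=True)
    G = G / np.linalg.norm(G, axis=1, keepdims=True)
    cosang = np.clip(np.abs(E @ G.T), 0.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    if weights is None:
        weights = np.full(E.shape[0], 1.0 / E.shape[0])
    return FiberGeometry(eigenvectors=E, angles_deg=angles, weights=weights)
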