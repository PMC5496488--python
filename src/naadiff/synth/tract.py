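"""Synthetic DWI volumes of a curved, quasi-coherent fiber tract.

Emulates a whole-brain DTI acquisition restricted to a small grid containing
a callosum-like tract: per-voxel diffusion tensors share the eigenvalue
spectrum of coherent white matter while the primary eigenvector sweeps a
planar arc (the macroscopic curvature of the tract). Signals follow
``S = S0 * exp(-1e-3 * b * g^T T g)`` with optional Gaussian or Rician noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import DesignError
from ..io import DWIDataset

__all__ = ["TractGroundTruth", "fibonacci_directions", "simulate_dwi_tract"]


@dataclass
class TractGroundTruth:
    """Geometry and noise parameters of the synthetic tract.

    The tract spans the grid's x axis; the fiber direction rotates in the
    x-y plane by ``arc_bend_deg`` in total from the first to the last x slab,
    giving a continuous direction field (adjacent-voxel angle well below 15
    degrees for modest grids).
    """

    grid_shape: tuple[int, int, int] = (10, 4, 4)
    eigenvalues: tuple[float, float, float] = (1.85, 0.73, 0.73)  # um^2/ms, healthy callosal WM
    arc_bend_deg: float = 30.0
    s0: float = 1000.0
    noise_model: str = "none"  # {"none", "gaussian", "rician"}
    noise_sd_fraction: float = 0.0  # SD as a fraction of s0

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def fiber_direction(self, x_index: int) -> np.ndarray:
        """Unit fiber direction at slab x (planar arc in the x-y plane)."""
        nx = self.grid_shape[0]
        frac = x_index / (nx - 1) if nx > 1 else 0.0
        ang = np.deg2rad(self.arc_bend_deg) * (frac - 0.5)
        return np.array([np.cos(ang), np.sin(ang), 0.0])

    def voxel_tensor(self, x_index: int) -> np.ndarray:
        e1 = self.fiber_direction(x_index)
        e2 = np.array([-e1[1], e1[0], 0.0])
        e3 = np.array([0.0, 0.0, 1.0])
        R = np.column_stack([e1, e2, e3])
        return R @ np.diag(self.eigenvalues) @ R.T


def fibonacci_directions(n: int = 32) -> np.ndarray:
    """Deterministic well-spread unit directions (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + np.sqrt(5)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z**2, 0, 1))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def simulate_dwi_tract(
    truth: TractGroundTruth,
    bvals: np.ndarray | None = None,
    bvecs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[DWIDataset, np.ndarray, dict]:
    """Simulate DWI of the tract.

    By default uses 1 b=0 volume plus 32 directions at b = 800 s/mm^2.
    Returns (DWI dataset, VOI mask covering the tract, truth dict with the
    per-slab tensors). Raises DesignError if the direction set cannot support
    a tensor fit.
    """
    if bvals is None or bvecs is None:
        dirs = fibonacci_directions(32)
        bvals = np.concatenate([[0.0], np.full(32, 800.0)])
        bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)

    from ..tensor import design_matrix

    X = design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7 or np.linalg.cond(X.T @ X) > 1e12:
        raise DesignError("direction set is too degenerate for tensor estimation")

    nx, ny, nz = truth.grid_shape
    data = np.zeros((nx, ny, nz, bvals.size))
    tensors = np.zeros((nx, 3, 3))
    for x in range(nx):
        T = truth.voxel_tensor(x)
        tensors[x] = T
        expo = -1e-3 * bvals * np.einsum("vi,ij,vj->v", bvecs, T, bvecs)
        data[x, :, :, :] = truth.s0 * np.exp(expo)[None, None, :]

    rng = np.random.default_rng(seed)
    sd = truth.noise_sd_fraction * truth.s0
    if truth.noise_model == "gaussian" and sd > 0:
        data = data + rng.normal(0.0, sd, size=data.shape)
    elif truth.noise_model == "rician" and sd > 0:
        data = np.abs(
            data + rng.normal(0.0, sd, size=data.shape)
            + 1j * rng.normal(0.0, sd, size=data.shape)
        )

    mask = np.ones((nx, ny, nz), dtype=bool)
    dset = DWIDataset(data=data, bvals=bvals, bvecs=bvecs, affine=np.eye(4))
    truth_dict = {
        "eigenvalues": list(truth.eigenvalues),
        "arc_bend_deg": truth.arc_bend_deg,
        "tensors_per_slab": tensors.tolist(),
        "fiber_directions": [truth.fiber_direction(x).tolist() for x in range(nx)],
        "seed": seed,
    }
    return dset, mask, truth_dict
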