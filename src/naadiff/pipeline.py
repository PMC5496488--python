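"""High-level pipeline stages chaining the library modules.

Stage order for one VOI:

1. preprocess: per-transient phase/frequency correction, eddy-current
   correction against the condition's water reference, averaging, HSVD water
   removal -> one clean FID per diffusion condition;
2. quantify: NAA singlet amplitude + CRLB% per condition, quality filter;
3. dti: tensor fit inside the VOI mask -> fiber geometry (angles to the two
   DW-MRS gradient directions);
4. fit: the two-parameter (D_cytosol, sigma_phi) dispersed-stick model plus
   the empirical per-direction ADC.
"""

from __future__ import annotations

import logging

import numpy as np

from .axonal import AxonalFit, empirical_adc, fit_dcytosol
from .errors import FitError
from .preprocess import Transient, preprocess_condition
from .protocol import AcquisitionProtocol
from .quantify import NAA_PPM, PeakPrior, QuantifiedDecay, fit_singlets, quality_filter
from .tensor import FiberGeometry, fit_tensor_volume, voi_fiber_angles

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_container",
    "quantify_conditions",
    "dti_fiber_geometry",
    "run_voi_pipeline",
]


def preprocess_container(
    protocol: AcquisitionProtocol,
    transients: list[Transient],
    water_references: list[Transient],
    **kwargs,
) -> tuple[list[Transient], list[float], dict]:
    """Preprocess every condition; returns (clean FIDs, noise SDs, QC report)."""
    waters = {w.condition_index: w for w in water_references}
    qc: dict = {}
    clean, noise = [], []
    for ci in range(len(protocol.conditions)):
        group = [t for t in transients if t.condition_index == ci]
        fid, sd = preprocess_condition(group, waters[ci], protocol, qc=qc, **kwargs)
        clean.append(fid)
        noise.append(sd)
    return clean, noise, qc


def quantify_conditions(
    clean_fids: list[Transient],
    noise_sds: list[float],
    protocol: AcquisitionProtocol,
    crlb_threshold: float = 15.0,
) -> tuple[QuantifiedDecay, list, dict]:
    """Fit the NAA singlet per condition and apply the CRLB quality filter."""
    results = []
    for fid, sd in zip(clean_fids, noise_sds):
        res = fit_singlets(
            fid.data, fid.dwell_time_s,
            priors=[PeakPrior("NAA", NAA_PPM)],
            noise_sd=sd, ppm_to_hz=protocol.ppm_to_hz,
            condition_index=fid.condition_index,
        )
        results.append(res[0])
    decay, rejected = quality_filter(results, list(protocol.conditions), crlb_threshold)
    qc = {
        "conditions": [
            {
                "condition": r.condition_index,
                "b_value": protocol.conditions[r.condition_index].b_value,
                "amplitude": r.amplitude,
                "crlb_percent": r.crlb_percent,
            }
            for r in results
        ],
        "n_rejected": len(rejected),
    }
    return decay, rejected, qc


def dti_fiber_geometry(
    dwi_data: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    voi_mask: np.ndarray,
    gradient_directions: np.ndarray,
    voi_to_image_rotation: np.ndarray | None = None,
) -> FiberGeometry:
    """Tensor-fit the VOI voxels and extract fiber angles to the DW-MRS gradients."""
    voxels = fit_tensor_volume(dwi_data, bvals, bvecs, mask=voi_mask)
    if not voxels:
        raise FitError("no valid tensor fits inside the VOI mask")
    evecs = np.array([v.primary_eigenvector for v in voxels.values()])
    return voi_fiber_angles(evecs, gradient_directions, voi_to_image_rotation)


def run_voi_pipeline(
    protocol: AcquisitionProtocol,
    transients: list[Transient],
    water_references: list[Transient],
    geometry: FiberGeometry,
    crlb_threshold: float = 15.0,
    weighting: str = "crlb",
) -> dict:
    """Full chain for one VOI; returns a result dict with fit + diagnostics."""
    clean, noise, pre_qc = preprocess_container(protocol, transients, water_references)
    decay, _rejected, quant_qc = quantify_conditions(clean, noise, protocol, crlb_threshold)
    fit = fit_dcytosol(decay, geometry, weighting=weighting)
    adc = empirical_adc(decay, weighting=weighting)
    return {
        "d_cytosol": fit.d_cytosol,
        "sigma_phi_deg": fit.sigma_phi_deg,
        "fit": fit.to_dict(),
        "adc": {"adc": adc.adc, "intercept": adc.intercept, "r2": adc.r2},
        "decay": decay.to_dict(),
        "preprocess_qc": pre_qc,
        "quantify_qc": quant_qc,
    }
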