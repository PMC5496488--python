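"""Monte-Carlo forward model for dispersed-stick diffusion attenuation.

Independent of the quadrature implementation in :mod:`naadiff.axonal`, this
samples stick axes directly and serves as the oracle the quadrature is
checked against.
"""

from __future__ import annotations

import numpy as np

__all__ = ["attenuation_monte_carlo"]


def attenuation_monte_carlo(
    d: float,
    sigma_phi_deg: float,
    theta_deg: float,
    b: float,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the dispersed-stick attenuation.

    Stick axes deviate from the mean axis (at angle ``theta_deg`` to the
    gradient) by a Gaussian polar angle of SD ``sigma_phi_deg`` with uniform
    azimuth; antipodal axes are identified (the attenuation depends on
    ``(u.g)^2`` only, so no folding is needed). Returns the sample mean of
    ``exp(-b * d * 1e-3 * (u.g)^2)`` and its standard error.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = np.deg2rad(theta_deg)
    sigma = np.deg2rad(sigma_phi_deg)
    alpha = rng.normal(0.0, sigma, size=n_samples) if sigma > 0 else np.zeros(n_samples)
    beta = rng.uniform(0.0, 2 * np.pi, size=n_samples)
    ug = np.cos(alpha) * np.cos(theta) + np.sin(alpha) * np.sin(theta) * np.cos(beta)
    vals = np.exp(-b * d * 1e-3 * ug**2)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else 0.0
    return mean, se
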