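"""Transient-level corrections and water removal for DW-MRS.

Raw single-shot FIDs of a diffusion-weighted spectroscopy scan carry several
instrumental distortions that must be removed before averaging and
quantification:

* zero-order phase fluctuations and frequency drift (cardiac pulsation,
  scanner drift), estimated per transient from the de-optimized residual
  water peak;
* eddy-current-induced time-dependent phase, shared between the metabolite
  acquisition and the unsuppressed water reference, removed by dividing out
  the water phase (Klose-style correction);
* the residual water resonance itself, removed after averaging by modeling
  the averaged FID as a sum of damped complex exponentials via Hankel
  singular value decomposition (HSVD) and subtracting the components that
  fall in the water band.

The processing order is fixed: phase/frequency correction -> eddy-current
correction -> averaging within condition -> HSVD water removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConsistencyError, CorrectionError, FitError
from .protocol import AcquisitionProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "Transient",
    "HSVDComponent",
    "estimate_phase_freq",
    "apply_phase_freq_correction",
    "eddy_correct",
    "average_transients",
    "hsvd_decompose",
    "reconstruct_components",
    "remove_water",
    "preprocess_condition",
    "WATER_PPM",
    "DEFAULT_WATER_SEARCH_HZ",
    "DEFAULT_WATER_BAND_PPM",
]

#: Chemical shift of water (ppm); +345 Hz from the 2.0 ppm carrier at 127.74 MHz.
WATER_PPM = 4.7
#: Half-width (Hz) of the search window around the nominal water frequency.
DEFAULT_WATER_SEARCH_HZ = 60.0
#: Half-width (ppm) of the HSVD water-removal band.
DEFAULT_WATER_BAND_PPM = 0.35


@dataclass
class Transient:
    """One complex FID with its acquisition labels."""

    data: np.ndarray  # complex128, length n_points
    dwell_time_s: float
    condition_index: int
    transient_index: int
    is_water_reference: bool = False
    flagged: bool = False  # set when a correction failed; excluded from averages

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 1:
            raise ValueError("FID data must be one-dimensional")

    @property
    def n_points(self) -> int:
        return self.data.size

    @property
    def time_axis_s(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_time_s

    def with_data(self, data: np.ndarray) -> "Transient":
        return replace(self, data=np.asarray(data, dtype=np.complex128))


@dataclass(frozen=True)
class HSVDComponent:
    """One damped complex exponential: a*exp(i*phi)*exp((-damping + 2i*pi*f) t)."""

    frequency_hz: float
    damping_per_s: float
    amplitude: float
    phase_rad: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amplitude
            * np.exp(1j * self.phase_rad)
            * np.exp((-self.damping_per_s + 2j * np.pi * self.frequency_hz) * t)
        )


def _spectrum(fid: np.ndarray, dwell: float, zero_fill: int = 4):
    """FFT spectrum with zero filling; returns (freq axis Hz, complex spectrum)."""
    n = fid.size * zero_fill
    spec = np.fft.fftshift(np.fft.fft(fid, n=n))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=dwell))
    return freqs, spec


def _tail_noise_sd(fid: np.ndarray, fraction: float = 0.1) -> float:
    """Noise SD per real/imag component from the FID tail (signal decayed away)."""
    tail = fid[int((1 - fraction) * fid.size):]
    return float(np.std(np.concatenate([tail.real, tail.imag])))


def estimate_phase_freq(
    transient: Transient,
    water_freq_hz: float,
    search_halfwidth_hz: float = DEFAULT_WATER_SEARCH_HZ,
    snr_floor: float = 5.0,
    matched_width_hz: float = 9.0,
) -> tuple[float, float]:
    """Estimate zero-order phase and frequency drift from the residual water peak.

    Parameters
    ----------
    transient:
        Raw FID; the residual water peak must exceed ``snr_floor`` times the
        spectral noise level inside the search window.
    water_freq_hz:
        Nominal carrier-relative water frequency (e.g. +345 Hz at 3 T with the
        carrier on NAA).

    Returns
    -------
    (phi0_rad, delta_f_hz):
        Zero-order phase at the water peak and the offset of the peak from its
        nominal frequency. Sub-bin frequency resolution is obtained by 4x zero
        filling plus parabolic interpolation of the peak magnitude.

    Raises
    ------
    CorrectionError
        If no peak in the window exceeds the SNR floor.
    """
    raw = transient.data
    sigma = _tail_noise_sd(raw)
    t_all = transient.time_axis_s
    # Matched apodization (prior water linewidth): suppresses late-time noise
    # before the peak search. Real weights leave the line center and the
    # zero-order phase at the center unchanged.
    apod = np.exp(-np.pi * matched_width_hz * t_all)
    fid = raw * apod
    freqs, spec = _spectrum(fid, transient.dwell_time_s, zero_fill=4)
    mag = np.abs(spec)

    in_window = np.abs(freqs - water_freq_hz) <= search_halfwidth_hz
    if not np.any(in_window):
        raise CorrectionError("water search window outside spectral range")

    # Spectral noise level of the apodized FID: noise SD sigma per component
    # gives a magnitude-spectrum level sigma*sqrt(sum(apod^2)) (zero filling
    # adds no noise power).
    noise_level = sigma * np.sqrt(np.sum(apod**2))

    idx_window = np.flatnonzero(in_window)
    k = idx_window[np.argmax(mag[idx_window])]
    peak_snr = mag[k] / noise_level if noise_level > 0 else np.inf
    if peak_snr < snr_floor:
        raise CorrectionError(
            f"residual water peak SNR {peak_snr:.2f} below floor {snr_floor}"
        )

    # Parabolic sub-bin interpolation on the magnitude spectrum, then a
    # direct DTFT refinement of the peak maximum (the parabola is only
    # approximate for a Lorentzian line; the DTFT argmax is exact for a
    # noiseless on-peak line, which makes the correction self-consistent).
    if 0 < k < mag.size - 1:
        y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df_bin = freqs[1] - freqs[0]
    f_par = freqs[k] + delta * df_bin

    t = transient.time_axis_s
    w2pt = -2j * np.pi * t

    def dtft(f: float) -> tuple[complex, complex, complex]:
        e = fid * np.exp(w2pt * f)
        s = np.sum(e)
        s1 = np.sum(w2pt * e)
        s2 = np.sum(w2pt**2 * e)
        return s, s1, s2

    # Newton iterations on d|S(f)|^2/df = 0: converges to the exact DTFT
    # magnitude maximum (the true line center for a noiseless on-peak line).
    f_peak = float(f_par)
    for _ in range(8):
        s, s1, s2 = dtft(f_peak)
        g = np.real(s1 * np.conj(s))
        gp = np.real(s2 * np.conj(s)) + abs(s1) ** 2
        if gp >= 0:  # not near a maximum; keep the parabolic estimate
            break
        step = g / gp
        if abs(step) > df_bin:
            break
        f_peak -= step
        if abs(step) < 1e-13:
            break
    phi0 = float(np.angle(dtft(f_peak)[0]))
    delta_f = float(f_peak - water_freq_hz)
    return phi0, delta_f


def apply_phase_freq_correction(
    transient: Transient, phi0_rad: float, delta_f_hz: float
) -> Transient:
    """Remove a zero-order phase and frequency offset.

    Multiplies the FID by ``exp(-i*phi0) * exp(-2i*pi*delta_f*t)`` -- the exact
    inverse of injecting the pair (phi0, delta_f).
    """
    if not (np.isfinite(phi0_rad) and np.isfinite(delta_f_hz)):
        raise ValueError("phase/frequency estimates must be finite")
    t = transient.time_axis_s
    corrected = transient.data * np.exp(-1j * phi0_rad) * np.exp(-2j * np.pi * delta_f_hz * t)
    return transient.with_data(corrected)


def eddy_correct(
    fid: Transient, water_fid: Transient, snr_floor: float = 5.0
) -> Transient:
    """Eddy-current correction using the unsuppressed water acquisition.

    The time-dependent eddy phase is common to the metabolite FID and the water
    reference, so multiplying the metabolite FID by ``exp(-i*arg(water(t)))``
    cancels it exactly. The water phase is only trusted where the water
    magnitude exceeds ``snr_floor`` times its tail noise SD; beyond the last
    reliable sample the unwrapped phase is held constant.
    """
    if water_fid.n_points != fid.n_points or water_fid.dwell_time_s != fid.dwell_time_s:
        raise ConsistencyError("water reference must match FID length and dwell time")

    mag = np.abs(water_fid.data)
    sigma = _tail_noise_sd(water_fid.data)
    floor = snr_floor * sigma
    reliable = mag > floor
    if not reliable[0]:
        raise CorrectionError("water reference below SNR floor from the first sample")

    # Last index of the initial contiguous reliable run.
    unreliable = np.flatnonzero(~reliable)
    last = int(unreliable[0]) - 1 if unreliable.size else fid.n_points - 1

    phase = np.unwrap(np.angle(water_fid.data))
    phase_held = phase.copy()
    phase_held[last + 1:] = phase[last]
    return fid.with_data(fid.data * np.exp(-1j * phase_held))


def average_transients(
    transients: list[Transient], weighting: str = "uniform"
) -> tuple[Transient, float]:
    """Average corrected transients of one condition.

    The extra block acquired at the highest b-value is pooled with its
    condition under uniform weights. Returns the averaged FID and the noise SD
    per real/imag component estimated from the last 10% of its samples.

    Raises
    ------
    ConsistencyError
        If the group mixes condition indices.
    CorrectionError
        If every transient is flagged.
    """
    if weighting != "uniform":
        raise ValueError(f"unsupported weighting {weighting!r}")
    usable = [t for t in transients if not t.flagged]
    if not usable:
        raise CorrectionError("all transients flagged; condition dropped")
    cond = {t.condition_index for t in transients}
    if len(cond) != 1:
        raise ConsistencyError(f"mixed condition indices in one average group: {sorted(cond)}")
    dwell = {t.dwell_time_s for t in usable}
    if len(dwell) != 1:
        raise ConsistencyError("mixed dwell times in one average group")

    n_flagged = len(transients) - len(usable)
    if n_flagged:
        logger.warning(
            "condition %d: excluded %d flagged transient(s) from average",
            transients[0].condition_index, n_flagged,
        )
    mean = np.mean([t.data for t in usable], axis=0)
    avg = usable[0].with_data(mean)
    avg = replace(avg, transient_index=-1)
    return avg, _tail_noise_sd(mean)


def hsvd_decompose(
    fid: np.ndarray,
    dwell_time_s: float,
    model_order: int = 25,
    hankel_rows: int | None = None,
) -> list[HSVDComponent]:
    """Decompose an FID into damped complex exponentials (HSVD).

    State-space method: build the L x (N-L+1) Hankel matrix of the FID,
    truncate its SVD at rank K (`model_order`), solve the shift-invariance
    equation of the left singular subspace by least squares to obtain the
    signal poles, then solve a linear least-squares problem for the complex
    amplitudes.

    Returns components sorted by decreasing amplitude. Growing poles
    (|z| > 1, non-physical for an FID) are kept in the returned list with
    negative damping; `reconstruct_components` discards them.
    """
    fid = np.asarray(fid, dtype=np.complex128)
    n = fid.size
    L = n // 2 if hankel_rows is None else int(hankel_rows)
    K = int(model_order)
    if not (K < L < n - K):
        raise ValueError(f"need model_order < hankel_rows < n - model_order, got K={K}, L={L}, n={n}")

    if np.max(np.abs(fid)) == 0.0:
        return []

    from scipy.linalg import hankel, lstsq, svd

    H = hankel(fid[:L], fid[L - 1:])
    U, s, _ = svd(H, full_matrices=False)
    rank = min(K, int(np.sum(s > s[0] * 1e-13)))
    if rank == 0:
        return []
    Uk = U[:, :rank]

    # Shift invariance: Uk_bottom ~= Uk_top @ Z ; eigenvalues of Z are the poles.
    Z, *_ = lstsq(Uk[:-1, :], Uk[1:, :], lapack_driver="gelsd")
    poles = np.linalg.eigvals(Z)
    poles = poles[np.abs(poles) > 1e-12]
    if poles.size == 0:
        return []

    # Complex amplitudes by linear least squares on the Vandermonde basis.
    t_idx = np.arange(n)
    basis = poles[None, :] ** t_idx[:, None]
    try:
        coeffs, *_ = lstsq(basis, fid, lapack_driver="gelsd")
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise FitError(f"rank-deficient HSVD amplitude solve: {exc}") from exc

    comps = []
    for z, c in zip(poles, coeffs):
        freq = float(np.angle(z) / (2 * np.pi * dwell_time_s))
        damping = float(-np.log(np.abs(z)) / dwell_time_s)
        comps.append(
            HSVDComponent(
                frequency_hz=freq,
                damping_per_s=damping,
                amplitude=float(np.abs(c)),
                phase_rad=float(np.angle(c)),
            )
        )
    comps.sort(key=lambda c: -c.amplitude)
    return comps


def reconstruct_components(
    components: list[HSVDComponent], t: np.ndarray
) -> np.ndarray:
    """Sum of decaying components on the time axis; growing poles are discarded."""
    out = np.zeros(t.size, dtype=np.complex128)
    for c in components:
        if c.damping_per_s < 0:
            continue
        out += c.evaluate(t)
    return out


def remove_water(
    fid: Transient,
    components: list[HSVDComponent],
    water_band_hz: tuple[float, float],
) -> Transient:
    """Subtract HSVD components whose frequency falls inside the water band."""
    lo, hi = water_band_hz
    in_band = [c for c in components if lo <= c.frequency_hz <= hi]
    if not in_band:
        return fid
    model = reconstruct_components(in_band, fid.time_axis_s)
    return fid.with_data(fid.data - model)


def preprocess_condition(
    transients: list[Transient],
    water_reference: Transient,
    protocol: AcquisitionProtocol,
    snr_floor: float = 5.0,
    eddy_snr_floor: float = 5.0,
    hsvd_order: int = 25,
    water_band_ppm: float = DEFAULT_WATER_BAND_PPM,
    qc: dict | None = None,
) -> tuple[Transient, float]:
    """Run the full fixed-order chain on one condition's transients.

    phase/frequency correction (per transient, from the residual water peak)
    -> eddy-current correction (shared water reference) -> uniform average
    -> HSVD water removal. Transients whose water peak is below the SNR floor
    are flagged and excluded, never interpolated.

    Returns the cleaned averaged FID and the tail noise SD estimate.
    `qc`, if given, collects per-transient phase/frequency estimates and flags.
    """
    water_hz = protocol.ppm_to_hz(WATER_PPM)
    corrected = []
    for tr in transients:
        rec = {"condition": tr.condition_index, "transient": tr.transient_index}
        try:
            phi0, df = estimate_phase_freq(tr, water_hz, snr_floor=snr_floor)
            fixed = apply_phase_freq_correction(tr, phi0, df)
            fixed = eddy_correct(fixed, water_reference, snr_floor=eddy_snr_floor)
            # Second pass: the eddy phase perturbs the water line and biases
            # the first-pass estimates; re-estimating on the eddy-corrected
            # FID removes that residual.
            phi1, df1 = estimate_phase_freq(fixed, water_hz, snr_floor=snr_floor)
            fixed = apply_phase_freq_correction(fixed, phi1, df1)
            rec.update(phi0_rad=phi0 + phi1, delta_f_hz=df + df1, flagged=False)
        except CorrectionError as exc:
            logger.warning(
                "condition %d transient %d flagged: %s",
                tr.condition_index, tr.transient_index, exc,
            )
            fixed = replace(tr, flagged=True)
            rec.update(flagged=True, reason=str(exc))
        corrected.append(fixed)
        if qc is not None:
            qc.setdefault("transients", []).append(rec)

    avg, noise_sd = average_transients(corrected)
    comps = hsvd_decompose(avg.data, avg.dwell_time_s, model_order=hsvd_order)
    band = (
        protocol.ppm_to_hz(WATER_PPM - water_band_ppm),
        protocol.ppm_to_hz(WATER_PPM + water_band_ppm),
    )
    clean = remove_water(avg, comps, band)
    if qc is not None:
        qc.setdefault("conditions", []).append(
            {
                "condition": avg.condition_index,
                "noise_sd": noise_sd,
                "n_water_components": sum(1 for c in comps if band[0] <= c.frequency_hz <= band[1]),
            }
        )
    return clean, noise_sd
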