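"""Phase congruency maps, moment images and the 4-element descriptor.

Phase congruency (PC) measures how much the local Fourier components agree
in phase: edges, corners and texture lines score highly regardless of their
contrast, because only phase — not amplitude — enters the measure.  Per
orientation theta,

    PC_theta(x) = w_theta(x) * max(sum_n A_n dPhi_n(x) - T_theta, 0)
                  / (sum_n A_n(x) + eps)

where A_n and phi_n are the amplitude and phase of the n-th log-Gabor scale,
dPhi_n = cos(phi_n - phibar) - |sin(phi_n - phibar)| is the phase-deviation
measure, T_theta an estimated noise floor and w_theta a sigmoid weighting of
the filter-response spread.  The combined map divides the summed oriented
energy by the total amplitude over all orientations.

Treating PC_theta(x)(cos theta, sin theta) as an oriented vector field, the
pointwise second-moment matrix has extreme values

    M = (c + a + sqrt(b^2 + (a - c)^2)) / 2     (edge strength)
    m = (c + a - sqrt(b^2 + (a - c)^2)) / 2     (corner strength)

with a = sum (PC cos)^2, b = 2 sum (PC cos)(PC sin), c = sum (PC sin)^2.
The texture descriptor is (mean M, std M, mean m, std m), computed over the
full frame by default (optionally inside the valve mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gabor import LogGaborBank, cached_loggabor_bank, filter_responses

__all__ = [
    "PCParams",
    "PCMaps",
    "MomentMaps",
    "pc_descriptor_names",
    "oriented_pc_maps",
    "pc_moments",
    "pc_descriptor",
]

pc_descriptor_names = ("pc_mean_M", "pc_std_M", "pc_mean_m", "pc_std_m")


@dataclass(frozen=True)
class PCParams:
    """Parameters of the phase-congruency computation."""

    n_scales: int = 4
    n_orientations: int = 6
    min_wavelength: float = 4.0
    scale_mult: float = 2.0
    sigma_rho: float = 0.65
    sigma_theta: float = np.pi / 7.2
    epsilon: float = 1e-4
    noise_k: float = 2.0       # noise floor = k * median(A_smallest)/0.6745; 0 disables
    weight_cutoff: float = 0.5  # sigmoid cutoff on the spread measure
    weight_gain: float = 10.0

    def __post_init__(self) -> None:
        if self.n_scales < 2 or self.n_orientations < 2:
            raise ValueError("need at least 2 scales and 2 orientations")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.noise_k < 0:
            raise ValueError("noise_k must be >= 0")


@dataclass(frozen=True)
class PCMaps:
    per_orientation: np.ndarray  # (O, rows, cols), values in [0, 1]
    combined: np.ndarray         # (rows, cols)
    orientations: np.ndarray     # radians


@dataclass(frozen=True)
class MomentMaps:
    M: np.ndarray
    m: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def oriented_pc_maps(image: np.ndarray, params: PCParams = PCParams()) -> PCMaps:
    """Per-orientation and combined phase-congruency maps of an image."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    max_wavelength = params.min_wavelength * params.scale_mult ** (params.n_scales - 1)
    if min(img.shape) < max_wavelength:
        raise ValueError("image smaller than the largest filter wavelength")

    bank = cached_loggabor_bank(
        img.shape,
        S=params.n_scales,
        O=params.n_orientations,
        min_wavelength=params.min_wavelength,
        scale_mult=params.scale_mult,
        sigma_rho=params.sigma_rho,
        sigma_theta=params.sigma_theta,
    )
    responses = filter_responses(img, bank)
    eps = params.epsilon

    per_orient = np.empty((bank.O,) + img.shape)
    energy_all = np.empty((bank.O,) + img.shape)
    sum_amp_all = np.zeros(img.shape)
    for t in range(bank.O):
        e = responses[:, t].real   # (S, rows, cols) even responses
        o = responses[:, t].imag   # odd responses
        amps = np.hypot(e, o)
        sum_e = e.sum(axis=0)
        sum_o = o.sum(axis=0)
        sum_amp = amps.sum(axis=0)
        xenergy = np.hypot(sum_e, sum_o) + eps
        cos_mean = sum_e / xenergy
        sin_mean = sum_o / xenergy
        # sum_n A_n * dPhi_n without forming explicit phases
        energy = np.sum(e * cos_mean + o * sin_mean
                        - np.abs(e * sin_mean - o * cos_mean), axis=0)
        if params.noise_k > 0:
            tau = np.median(amps[0]) / 0.6745
            T = params.noise_k * tau
        else:
            T = 0.0
        energy = np.maximum(energy - T, 0.0)
        spread = (sum_amp / (amps.max(axis=0) + eps)) / bank.S
        weight = 1.0 / (1.0 + np.exp(params.weight_gain * (params.weight_cutoff - spread)))
        energy_all[t] = weight * energy
        sum_amp_all += sum_amp
        per_orient[t] = np.clip(weight * energy / (sum_amp + eps), 0.0, 1.0)

    combined = np.clip(energy_all.sum(axis=0) / (sum_amp_all + eps), 0.0, 1.0)
    return PCMaps(per_orientation=per_orient, combined=combined,
                  orientations=bank.orientations)


def pc_moments(maps: PCMaps) -> MomentMaps:
    """Maximum/minimum moment images of the oriented PC stack."""
    pc = maps.per_orientation
    if pc.shape[0] < 2:
        raise ValueError("need at least 2 orientations")
    cos_t = np.cos(maps.orientations)[:, None, None]
    sin_t = np.sin(maps.orientations)[:, None, None]
    a = np.sum((pc * cos_t) ** 2, axis=0)
    b = 2.0 * np.sum((pc * cos_t) * (pc * sin_t), axis=0)
    c = np.sum((pc * sin_t) ** 2, axis=0)
    root = np.sqrt(b ** 2 + (a - c) ** 2)
    M = 0.5 * (c + a + root)
    m = 0.5 * (c + a - root)
    return MomentMaps(M=M, m=np.maximum(m, 0.0), a=a, b=b, c=c)


def pc_descriptor(
    image: np.ndarray,
    params: PCParams = PCParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """4-vector (mean M, std M, mean m, std m) of the moment images.

    Statistics run over the whole frame unless ``mask`` restricts them to
    the valve interior.
    """
    maps = oriented_pc_maps(image, params)
    mom = pc_moments(maps)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mom.M.shape:
            raise ValueError("mask shape mismatch")
        M, m = mom.M[mask], mom.m[mask]
    else:
        M, m = mom.M.ravel(), mom.m.ravel()
    return np.array([M.mean(), M.std(), m.mean(), m.std()])
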