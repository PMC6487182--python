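"""Elliptical Fourier Descriptors of closed contours via the Freeman chain code.

A digital contour is encoded as a Freeman 8-direction chain; the x/y
projections of the chain define a piecewise-linear closed curve parametrized
by arc length t in [0, T].  The Fourier series coefficients (a_n, b_n) of the
x projection and (c_n, d_n) of the y projection are computed in closed form
from the per-link increments, and the per-harmonic amplitudes

    amp_n = (1/2) * sqrt(a_n^2 + b_n^2 + c_n^2 + d_n^2)

form a shape descriptor that is invariant to translation (the DC terms never
enter), to rotation and to the choice of starting pixel (both act as
orthogonal mixings within each harmonic), and — after dividing by amp_1 —
to scale.

Conventions: image row/col coordinates are mapped to the display frame
x = +col, y = -row, so Freeman code 0 points East, 2 North, 4 West, 6 South.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Contour

__all__ = [
    "ChainCode",
    "ChainIncrements",
    "EFDCoefficients",
    "EFDDescriptor",
    "freeman_encode",
    "freeman_decode",
    "chain_increments",
    "efd_coefficients",
    "harmonic_amplitudes",
    "reconstruct_contour",
]

# Freeman code -> (drow, dcol); code 0 = East, counter-clockwise on screen
# (clockwise in row/col coordinates).
FREEMAN_STEPS: dict[int, tuple[int, int]] = {
    0: (0, 1),    # E
    1: (-1, 1),   # NE
    2: (-1, 0),   # N
    3: (-1, -1),  # NW
    4: (0, -1),   # W
    5: (1, -1),   # SW
    6: (1, 0),    # S
    7: (1, 1),    # SE
}

_STEP_TO_CODE = {v: k for k, v in FREEMAN_STEPS.items()}


class InvalidContourError(ValueError):
    """Consecutive contour points are not 8-adjacent."""


@dataclass(frozen=True)
class ChainCode:
    """Freeman 8-direction chain code of a contour."""

    codes: np.ndarray
    start_point: tuple[int, int]
    closed: bool = True

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.size and (codes.min() < 0 or codes.max() > 7):
            raise ValueError("Freeman codes must lie in 0..7")

    @property
    def K(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class ChainIncrements:
    """Per-link increments (dx_i, dy_i, dt_i) and cumulative arc length."""

    dx: np.ndarray
    dy: np.ndarray
    dt: np.ndarray
    t: np.ndarray  # cumulative arc length t_p, p = 1..K
    T: float       # total perimeter


@dataclass(frozen=True)
class EFDCoefficients:
    """Per-harmonic quadruples (a_n, b_n, c_n, d_n), n = 1..N."""

    harmonics: np.ndarray  # (N, 4)
    T: float
    K: int
    # DC offsets of the x/y projections relative to the start point; needed
    # only for reconstruction, not for the descriptor.
    A0: float = 0.0
    C0: float = 0.0
    start_point: tuple[int, int] = (0, 0)

    @property
    def n_harmonics(self) -> int:
        return int(self.harmonics.shape[0])


@dataclass(frozen=True)
class EFDDescriptor:
    """Harmonic amplitude spectrum amp_1..amp_N."""

    amplitudes: np.ndarray
    normalized: bool = False

    def __len__(self) -> int:
        return int(self.amplitudes.size)


def freeman_encode(contour: Contour) -> ChainCode:
    """Encode an ordered contour as a Freeman chain code.

    Code i gives the direction from point i to point i+1; for a closed
    contour the chain wraps from the last point back to the first.
    """
    pts = np.asarray(contour.points, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidContourError("contour points must be an (N, 2) array")
    if contour.closed and pts.shape[0] < 4:
        raise InvalidContourError("closed contour needs at least 4 points")
    if contour.closed:
        steps = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    else:
        steps = np.diff(pts, axis=0)
    codes = np.empty(steps.shape[0], dtype=np.int64)
    for i, (dr, dc) in enumerate(steps):
        code = _STEP_TO_CODE.get((int(dr), int(dc)))
        if code is None:
            raise InvalidContourError(
                f"points {i} and {i + 1} are not 8-adjacent (step {dr},{dc})"
            )
        codes[i] = code
    return ChainCode(codes=codes, start_point=tuple(pts[0]), closed=contour.closed)


def freeman_decode(chain: ChainCode) -> np.ndarray:
    """Rebuild the (row, col) point sequence from a chain code."""
    steps = np.array([FREEMAN_STEPS[int(a)] for a in chain.codes], dtype=np.int64)
    pts = np.empty((chain.K + 1, 2), dtype=np.int64)
    pts[0] = chain.start_point
    if chain.K:
        pts[1:] = np.asarray(chain.start_point) + np.cumsum(steps, axis=0)
    if chain.closed:
        pts = pts[:-1]  # the wrap step returns to the start
    return pts


def chain_increments(chain: ChainCode) -> ChainIncrements:
    """Per-link projection increments of the chain.

    dx_i = sgn(6 - a_i) sgn(2 - a_i)
    dy_i = sgn(4 - a_i) sgn(a_i)
    dt_i = 1 + ((sqrt(2) - 1)/2) (1 - (-1)^a_i)   (1 for even, sqrt2 for odd)
    """
    a = chain.codes.astype(np.float64)
    dx = np.sign(6.0 - a) * np.sign(2.0 - a)
    dy = np.sign(4.0 - a) * np.sign(a)
    dt = 1.0 + ((np.sqrt(2.0) - 1.0) / 2.0) * (1.0 - (-1.0) ** chain.codes)
    t = np.cumsum(dt)
    return ChainIncrements(dx=dx, dy=dy, dt=dt, t=t, T=float(t[-1]) if t.size else 0.0)


def efd_coefficients(chain: ChainCode, n_harmonics: int = 30) -> EFDCoefficients:
    """Elliptical Fourier coefficients of a closed chain.

    a_n = T/(2 n^2 pi^2) * sum_p (dx_p/dt_p) [cos(2 pi n t_p / T) - cos(2 pi n t_{p-1} / T)]

    and analogously b_n (sin, dx), c_n (cos, dy), d_n (sin, dy), with t_0 = 0.
    """
    if not chain.closed:
        raise ValueError("EFD requires a closed chain")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    inc = chain_increments(chain)
    if inc.T <= 0:
        raise ValueError("degenerate chain with zero perimeter")
    T = inc.T
    t_p = inc.t
    t_prev = np.concatenate([[0.0], t_p[:-1]])
    n = np.arange(1, n_harmonics + 1, dtype=np.float64)[:, None]
    omega = 2.0 * np.pi / T
    cos_diff = np.cos(omega * n * t_p) - np.cos(omega * n * t_prev)   # (N, K)
    sin_diff = np.sin(omega * n * t_p) - np.sin(omega * n * t_prev)
    scale = T / (2.0 * (n[:, 0] ** 2) * np.pi ** 2)
    vx = inc.dx / inc.dt
    vy = inc.dy / inc.dt
    a_n = scale * (cos_diff @ vx)
    b_n = scale * (sin_diff @ vx)
    c_n = scale * (cos_diff @ vy)
    d_n = scale * (sin_diff @ vy)

    # DC components of the projections (displacement from the start point),
    # used only to place reconstructions.
    xi = np.concatenate([[0.0], np.cumsum(inc.dx)[:-1]]) - vx * t_prev
    delta = np.concatenate([[0.0], np.cumsum(inc.dy)[:-1]]) - vy * t_prev
    A0 = float(np.sum(vx / 2.0 * (t_p ** 2 - t_prev ** 2) + xi * (t_p - t_prev)) / T)
    C0 = float(np.sum(vy / 2.0 * (t_p ** 2 - t_prev ** 2) + delta * (t_p - t_prev)) / T)

    return EFDCoefficients(
        harmonics=np.column_stack([a_n, b_n, c_n, d_n]),
        T=T,
        K=chain.K,
        A0=A0,
        C0=C0,
        start_point=chain.start_point,
    )


def harmonic_amplitudes(coeffs: EFDCoefficients, normalize: bool = True) -> EFDDescriptor:
    """Amplitude spectrum amp_n = 0.5 sqrt(a_n^2 + b_n^2 + c_n^2 + d_n^2).

    With ``normalize`` the spectrum is divided by amp_1, making it scale
    invariant; a vanishing first harmonic signals a degenerate contour.
    """
    if coeffs.n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    amp = 0.5 * np.sqrt(np.sum(coeffs.harmonics ** 2, axis=1))
    if normalize:
        if amp[0] <= 0.0:
            raise ValueError("degenerate contour: first-harmonic amplitude is zero")
        amp = amp / amp[0]
    return EFDDescriptor(amplitudes=amp, normalized=normalize)


def reconstruct_contour(
    coeffs: EFDCoefficients,
    n_harmonics: int | None = None,
    n_points: int = 256,
) -> np.ndarray:
    """Truncated Fourier synthesis of the contour.

    Returns an (n_points, 2) float array of (row, col) positions sampled at
    uniform arc-length parameter values.  With ``n_harmonics=1`` the curve is
    an ellipse.
    """
    N = coeffs.n_harmonics if n_harmonics is None else int(n_harmonics)
    if not 1 <= N <= coeffs.n_harmonics:
        raise ValueError("n_harmonics out of range")
    T = coeffs.T
    t = np.linspace(0.0, T, n_points, endpoint=False)
    n = np.arange(1, N + 1, dtype=np.float64)[:, None]
    arg = 2.0 * np.pi * n * t / T  # (N, n_points)
    h = coeffs.harmonics[:N]
    x = coeffs.A0 + h[:, 0] @ np.cos(arg) + h[:, 1] @ np.sin(arg)
    y = coeffs.C0 + h[:, 2] @ np.cos(arg) + h[:, 3] @ np.sin(arg)
    r0, c0 = coeffs.start_point
    return np.column_stack([r0 - y, c0 + x])
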