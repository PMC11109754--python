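"""EMG-driven muscle activation.

Raw surface EMG is band-pass filtered (10–400 Hz Butterworth, zero phase),
full-wave rectified, and smoothed with a 6 Hz low-pass to give an envelope
that is normalised by the peak of the maximal-voluntary-contraction (MVC)
envelope, yielding the excitation e(t) ∈ [0, 1].  Neural activation follows
the second-order recursion

    u(t) = α e(t − d) − β₁ u(t − 1) − β₂ u(t − 2)

with β₁ = C₁ + C₂, β₂ = C₁·C₂, |C₁|, |C₂| < 1 and the stability/unit-gain
constraint α = 1 + β₁ + β₂ (so constant e = 1 drives u → 1).  The
electromechanical delay d (10 ms) is rounded to whole samples.  Muscle
activation applies the nonlinear shaping

    a(t) = (exp(A·u(t)) − 1) / (exp(A) − 1),   A = 1.5 by default,

which maps [0, 1] onto [0, 1] monotonically and tends to the identity as
A → 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal, stats

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ShapeError,
)

__all__ = [
    "ActivationParams",
    "EmgTrace",
    "NormalizedExcitation",
    "AgreementReport",
    "preprocess_emg",
    "normalize_to_mvc",
    "neural_activation",
    "muscle_activation",
    "compare_activation",
]


@dataclass(frozen=True)
class ActivationParams:
    """Parameters of the excitation→activation dynamics.

    ``c1``/``c2`` are the recursion roots (defaults −0.5, −0.5: a stable
    mid-range choice; the coefficients themselves are rarely reported).
    β₁, β₂ and the gain α are derived, never free, so the unit-gain
    constraint α = 1 + β₁ + β₂ holds identically.
    """

    electromechanical_delay_ms: float = 10.0
    c1: float = -0.5
    c2: float = -0.5
    shape: float = 1.5  # nonlinearity A of the activation curve

    def __post_init__(self):
        if abs(self.c1) >= 1 or abs(self.c2) >= 1:
            raise InvalidParameterError("recursion roots must satisfy |C| < 1")
        if self.electromechanical_delay_ms < 0:
            raise InvalidParameterError("delay must be non-negative")

    @property
    def beta1(self) -> float:
        return self.c1 + self.c2

    @property
    def beta2(self) -> float:
        return self.c1 * self.c2

    @property
    def gain(self) -> float:
        return 1.0 + self.beta1 + self.beta2


@dataclass(frozen=True)
class EmgTrace:
    """A raw EMG channel in mV at a fixed sampling rate (1000 Hz in-study)."""

    samples: NDArray[np.float64]
    sampling_rate: float = 1000.0
    muscle: str = ""
    is_mvc: bool = False


class NormalizedExcitation(NamedTuple):
    excitation: NDArray[np.float64]
    exceeds_mvc: bool


@dataclass(frozen=True)
class AgreementReport:
    """Symmetric agreement metrics between two activation traces."""

    rms_difference: float
    pearson_r: float
    peak_difference: float


def _zero_phase_sos(order: int, Wn, fs: float, btype: str) -> NDArray:
    # Forward–backward pass of a half-order design gives the stated effective
    # order with zero phase lag (the common "fourth-order zero-phase" reading).
    return signal.butter(order // 2, Wn, btype=btype, fs=fs, output="sos")


def preprocess_emg(
    raw: EmgTrace,
    band: tuple[float, float] = (10.0, 400.0),
    envelope_cutoff: float = 6.0,
    order: int = 4,
    effective_order: bool = True,
) -> NDArray:
    """Band-pass, full-wave rectify, and low-pass a raw EMG trace.

    Returns the non-negative linear envelope at the input length.  The
    sampling rate must exceed twice the band-pass upper edge (> 800 Hz for
    the default 400 Hz edge).  ``effective_order=True`` interprets the filter
    order as the effective (forward–backward) order.
    """
    x = np.asarray(raw.samples, dtype=float)
    fs = raw.sampling_rate
    if fs <= 2 * band[1]:
        raise InvalidParameterError(
            f"sampling rate {fs} Hz cannot support a {band[1]} Hz band edge"
        )
    if x.size < int(0.5 * fs):
        raise InsufficientDataError("EMG trace shorter than ~0.5 s; filter edges unreliable")
    n = order if effective_order else 2 * order
    bp = _zero_phase_sos(n, band, fs, "bandpass")
    rectified = np.abs(signal.sosfiltfilt(bp, x))
    lp = _zero_phase_sos(n, envelope_cutoff, fs, "lowpass")
    envelope = signal.sosfiltfilt(lp, rectified)
    return np.clip(envelope, 0.0, None)


def normalize_to_mvc(
    envelope: ArrayLike,
    mvc_envelope: ArrayLike,
    rms_window_s: float | None = None,
    sampling_rate: float = 1000.0,
) -> NormalizedExcitation:
    """Scale a task envelope by the MVC envelope peak to get e(t).

    Values above 1 are preserved and flagged (``exceeds_mvc``), never
    silently clipped.  ``rms_window_s`` switches the reference from the MVC
    envelope peak to the peak moving-RMS amplitude of the MVC envelope.
    """
    env = np.asarray(envelope, dtype=float)
    mvc = np.asarray(mvc_envelope, dtype=float)
    if rms_window_s is not None:
        win = max(int(rms_window_s * sampling_rate), 1)
        kernel = np.ones(win) / win
        reference = float(np.sqrt(np.convolve(mvc**2, kernel, mode="valid")).max())
    else:
        reference = float(mvc.max())
    if reference <= 0:
        raise InvalidParameterError("MVC reference peak must be positive")
    e = env / reference
    return NormalizedExcitation(excitation=e, exceeds_mvc=bool(np.any(e > 1.0)))


def neural_activation(
    excitation: ArrayLike, params: ActivationParams, dt: float
) -> NDArray:
    """Run the second-order neural-activation recursion with zero history.

    The delay is converted to ``round(d/dt)`` samples.  Excitation outside
    [0, 1] is clipped with a warning (the upstream MVC flag reports it).
    """
    e = np.asarray(excitation, dtype=float)
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if np.any(e < 0) or np.any(e > 1):
        warnings.warn("excitation outside [0, 1]; clipping", stacklevel=2)
        e = np.clip(e, 0.0, 1.0)
    d = int(round(params.electromechanical_delay_ms / 1000.0 / dt))
    alpha, b1, b2 = params.gain, params.beta1, params.beta2
    u = np.zeros_like(e)
    for t in range(e.size):
        drive = e[t - d] if t - d >= 0 else 0.0
        u_1 = u[t - 1] if t >= 1 else 0.0
        u_2 = u[t - 2] if t >= 2 else 0.0
        u[t] = alpha * drive - b1 * u_1 - b2 * u_2
    return u


def muscle_activation(u: ArrayLike, shape: float = 1.5) -> NDArray | float:
    """Nonlinear neural→muscle activation a = (e^{A·u} − 1)/(e^A − 1).

    At A = 0 the analytic limit a = u is used.  Monotone, maps 0 → 0, 1 → 1.
    """
    uu = np.asarray(u, dtype=float)
    if shape == 0.0:
        a = uu.copy()
    else:
        a = np.expm1(shape * uu) / np.expm1(shape)
    return a if a.ndim else float(a)


def compare_activation(a_emg: ArrayLike, a_model: ArrayLike) -> AgreementReport:
    """RMS difference, Pearson r, and peak difference between two traces,
    both already resampled onto the common 101-point landing phase."""
    x = np.asarray(a_emg, dtype=float)
    y = np.asarray(a_model, dtype=float)
    if x.shape != y.shape:
        raise ShapeError("activation traces must have equal length")
    r = float(stats.pearsonr(x, y).statistic)
    return AgreementReport(
        rms_difference=float(np.sqrt(np.mean((x - y) ** 2))),
        pearson_r=r,
        peak_difference=float(x.max() - y.max()),
    )
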