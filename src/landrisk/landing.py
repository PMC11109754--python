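"""Landing-phase biomechanics of a single-leg drop landing trial.

The landing phase runs from initial contact (first sample with vertical
ground reaction force above 10 N, thresholded on the raw force in absolute
newtons) to maximum knee flexion.  Kinematics are low-passed at 10 Hz and
kinetics at 20 Hz with fourth-order zero-phase Butterworth filters, curves
are time-normalised to 101 points (0–100 % of the phase), joint power is the
product of joint moment and joint angular velocity, per-joint energy
dissipation is the time integral of negative (eccentric) power reported as a
positive magnitude, and total energy dissipation (TED) sums the sagittal
ankle, knee, and hip dissipations.

Sign conventions: ankle plantarflexion positive / dorsiflexion negative, so
the ankle initial contact angle (AICA) is the angle at the contact sample
and the ankle range of motion (AROM) is the excursion from AICA to the peak
dorsiflexion angle.  Inversion is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal

from . import ligament
from .exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    PhaseDetectionError,
    ShapeError,
)
from .ligament import LigamentBundleSpec, compute_strain, compute_strain_rate

__all__ = [
    "TrialTimeSeries",
    "TrialSummary",
    "SUMMARY_FIELDS",
    "detect_landing_phase",
    "filter_signal",
    "time_normalize",
    "angular_velocity",
    "joint_power",
    "energy_dissipation",
    "total_energy_dissipation",
    "peak_acl_force",
    "extract_summary",
]

#: Order of the scalar summary variables throughout tables and reports.
SUMMARY_FIELDS = (
    "AICA", "AROM", "PVGRF", "TED", "PADM", "PKFM", "PHFM", "PAIA", "PAIM", "PAF",
)


@dataclass
class TrialTimeSeries:
    """Synchronised per-trial signals on a common time grid.

    Angles in degrees, moments in Nm/kg (the inversion moment unit is carried
    as configured metadata — see ``inversion_moment_unit``), VGRF in absolute
    newtons, optional ACL (anteromedial-bundle) elongation in mm.
    """

    time: NDArray[np.float64]  # s, monotone
    vgrf: NDArray[np.float64]  # N
    ankle_sagittal: NDArray[np.float64]  # deg, plantarflexion +
    knee_flexion: NDArray[np.float64]  # deg
    hip_flexion: NDArray[np.float64]  # deg
    ankle_inversion: NDArray[np.float64]  # deg, inversion +
    ankle_moment: NDArray[np.float64]  # Nm/kg, dorsiflexion moment +
    knee_moment: NDArray[np.float64]  # Nm/kg, flexion moment +
    hip_moment: NDArray[np.float64]  # Nm/kg, flexion moment +
    ankle_inversion_moment: NDArray[np.float64]
    body_mass: float  # kg
    acl_elongation: NDArray[np.float64] | None = None  # mm
    inversion_moment_unit: str = "N/kg"  # as printed in the source table

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("time must be strictly increasing")
        n = self.time.size
        for name in (
            "vgrf", "ankle_sagittal", "knee_flexion", "hip_flexion",
            "ankle_inversion", "ankle_moment", "knee_moment", "hip_moment",
            "ankle_inversion_moment",
        ):
            if getattr(self, name).size != n:
                raise ShapeError(f"channel {name!r} length differs from time grid")
        if self.acl_elongation is not None and self.acl_elongation.size != n:
            raise ShapeError("acl_elongation length differs from time grid")
        if self.body_mass <= 0:
            raise InvalidParameterError("body mass must be positive")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class TrialSummary:
    """Scalar summary variables of one landing trial.

    AICA/AROM/PAIA in degrees, PVGRF and PAF in N/kg (body-mass normalised),
    TED in J/kg, sagittal peak moments in Nm/kg.
    """

    AICA: float
    AROM: float
    PVGRF: float
    TED: float
    PADM: float
    PKFM: float
    PHFM: float
    PAIA: float
    PAIM: float
    PAF: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in SUMMARY_FIELDS}


def detect_landing_phase(
    vgrf_n: ArrayLike, knee_flexion: ArrayLike, threshold_n: float = 10.0
) -> tuple[int, int]:
    """Locate (contact index, max-knee-flexion index) on the raw signals.

    Contact is the first sample with VGRF above the absolute-newton
    threshold (the first crossing on bouncy force traces); the phase ends at
    the knee-flexion argmax at or after contact.
    """
    f = np.asarray(vgrf_n, dtype=float)
    k = np.asarray(knee_flexion, dtype=float)
    if f.shape != k.shape:
        raise ShapeError("VGRF and knee flexion must share the time grid")
    above = np.flatnonzero(f > threshold_n)
    if above.size == 0:
        raise PhaseDetectionError(f"VGRF never exceeds {threshold_n} N")
    start = int(above[0])
    end = start + int(np.argmax(k[start:]))
    if end <= start:
        raise PhaseDetectionError("knee flexion peaks at (or before) initial contact")
    return start, end


def filter_signal(
    series: ArrayLike, fs: float, cutoff: float, order: int = 4
) -> NDArray:
    """Zero-phase Butterworth low-pass (effective ``order`` via filtfilt).

    Kinematic channels use 10 Hz, kinetic channels 20 Hz.
    """
    x = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff:
        raise InvalidParameterError("sampling rate must exceed twice the cutoff")
    sos = signal.butter(order // 2, cutoff, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * (order // 2) + 1)
    if x.size <= padlen:
        raise InvalidParameterError("series shorter than the filter pad length")
    return signal.sosfiltfilt(sos, x)


def time_normalize(series: ArrayLike, n_points: int = 101) -> NDArray:
    """Resample a phase window onto 0–100 % in 1 % steps (101 points).

    Linear interpolation; the window endpoints are preserved exactly.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("time normalization needs at least 2 samples")
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, x)


def angular_velocity(angle_deg: ArrayLike, dt: float) -> NDArray:
    """Angular velocity in rad/s from an angle series in degrees
    (central differences, one-sided endpoints)."""
    return np.gradient(np.deg2rad(np.asarray(angle_deg, dtype=float)), dt)


def joint_power(moment: ArrayLike, angular_velocity: ArrayLike) -> NDArray:
    """Joint power (W/kg) as the element-wise moment × angular velocity."""
    m = np.asarray(moment, dtype=float)
    w = np.asarray(angular_velocity, dtype=float)
    if m.shape != w.shape:
        raise ShapeError("moment and angular velocity must have equal length")
    return m * w


def energy_dissipation(power: ArrayLike, time: ArrayLike) -> float:
    """Energy dissipated (J/kg): trapezoidal integral of negative power,
    returned as a positive magnitude."""
    p = np.asarray(power, dtype=float)
    t = np.asarray(time, dtype=float)
    if p.shape != t.shape:
        raise ShapeError("power and time must have equal length")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("time must be strictly increasing")
    return float(-np.trapezoid(np.minimum(p, 0.0), t))


def total_energy_dissipation(ankle: float, knee: float, hip: float) -> float:
    """TED (J/kg): sum of the sagittal ankle, knee, and hip dissipations."""
    for v in (ankle, knee, hip):
        if v is None or np.isnan(v):
            raise InvalidParameterError("all three joint dissipations are required")
    return float(ankle + knee + hip)


def peak_acl_force(
    elongation_mm: ArrayLike,
    dt: float,
    body_mass: float,
    bundles: tuple[LigamentBundleSpec, ...] = (ligament.A_ACL, ligament.P_ACL),
) -> float:
    """Peak total ACL force in N/kg from an anteromedial-bundle elongation
    trace (already low-passed by the caller): strain and strain rate
    (central differences) feed the viscoelastic bundle model; both bundles
    share the strain history and their forces sum."""
    le = np.asarray(elongation_mm, dtype=float)
    strain = compute_strain(le, bundles[0].resting_length)
    rate = compute_strain_rate(strain, dt)
    force = ligament.total_force_from_strain(strain, rate, bundles)
    return float(force.max() / body_mass)


def extract_summary(
    trial: TrialTimeSeries,
    bundles: tuple[LigamentBundleSpec, ...] = (ligament.A_ACL, ligament.P_ACL),
    kinematic_cutoff: float = 10.0,
    kinetic_cutoff: float = 20.0,
) -> TrialSummary:
    """Full per-trial pipeline: phase detection on the raw VGRF, channel
    filtering, and extraction of every scalar summary variable strictly
    within the landing phase.

    PAF requires the trial to carry an ACL elongation channel; it is NaN
    otherwise.
    """
    fs = trial.sampling_rate
    start, end = detect_landing_phase(trial.vgrf, trial.knee_flexion)
    sl = slice(start, end + 1)
    t = trial.time[sl]
    dt = trial.dt

    kin = {
        name: filter_signal(getattr(trial, name), fs, kinematic_cutoff)
        for name in ("ankle_sagittal", "knee_flexion", "hip_flexion", "ankle_inversion")
    }
    kinet = {
        name: filter_signal(getattr(trial, name), fs, kinetic_cutoff)
        for name in ("vgrf", "ankle_moment", "knee_moment", "hip_moment",
                     "ankle_inversion_moment")
    }

    aica = float(kin["ankle_sagittal"][start])
    arom = aica - float(kin["ankle_sagittal"][sl].min())
    pvgrf = float(kinet["vgrf"][sl].max()) / trial.body_mass

    dissipations = {}
    for joint, angle_name, moment_name in (
        ("ankle", "ankle_sagittal", "ankle_moment"),
        ("knee", "knee_flexion", "knee_moment"),
        ("hip", "hip_flexion", "hip_moment"),
    ):
        omega = angular_velocity(kin[angle_name], dt)[sl]
        power = joint_power(kinet[moment_name][sl], omega)
        dissipations[joint] = energy_dissipation(power, t)
    ted = total_energy_dissipation(**dissipations)

    if trial.acl_elongation is not None:
        le = filter_signal(trial.acl_elongation, fs, kinematic_cutoff)
        paf = peak_acl_force(le[sl], dt, trial.body_mass, bundles)
    else:
        paf = float("nan")

    return TrialSummary(
        AICA=aica,
        AROM=arom,
        PVGRF=pvgrf,
        TED=ted,
        PADM=float(kinet["ankle_moment"][sl].max()),
        PKFM=float(kinet["knee_moment"][sl].max()),
        PHFM=float(kinet["hip_moment"][sl].max()),
        PAIA=float(kin["ankle_inversion"][sl].max()),
        PAIM=float(kinet["ankle_inversion_moment"][sl].max()),
        PAF=paf,
    )
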