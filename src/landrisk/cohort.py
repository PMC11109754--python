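"""Synthetic single-leg-landing cohorts.

Two layers make the whole pipeline testable without any recorded data:

* **Summary level** — subject vectors of the ten scalar landing variables
  are drawn from a multivariate normal whose means/SDs and anchor-row
  correlations default to the published cohort calibration (60 male
  subjects, 5 trials each).  Only the correlations of the two ankle-motion
  anchors (initial contact angle, range of motion) with the other eight
  variables — plus the ACL-force/inversion-angle pair — are reported
  anywhere; the remaining pairs are filled with a product-of-paths
  heuristic through the anchors and the matrix is projected to the nearest
  valid correlation matrix *holding the reported entries fixed* (alternating
  projections).  Within-subject trial scatter is added as independent
  Gaussian noise at a configurable fraction of the between-subject SD.

* **Trial level** — given one summary row, smooth waveform templates
  (raised-cosine impact bump, smoothstep angle transitions) are assembled so
  that the landing-metrics extraction pipeline recovers the row's embedded
  AICA, AROM, PVGRF, peak moments, and PAIA to within 1 % on noiseless
  trials, and the ACL-elongation bump amplitude is solved numerically
  against the extraction pipeline itself so the embedded peak ACL force is
  recovered through the viscoelastic ligament model.

A band-limited, burst-modulated EMG generator emulates raw surface EMG for
the activation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import signal as _signal
from scipy.optimize import brentq

from . import landing
from .activation import EmgTrace
from .exceptions import GenerationError, InvalidParameterError
from .landing import SUMMARY_FIELDS, TrialTimeSeries

__all__ = [
    "SUMMARY_MEANS",
    "SUMMARY_SDS",
    "AICA_CORRELATIONS",
    "AROM_CORRELATIONS",
    "EXTRA_CORRELATIONS",
    "CohortConfig",
    "CohortTables",
    "WaveformTemplateParams",
    "EmgBurstParams",
    "build_correlation_matrix",
    "nearest_correlation_fixed",
    "generate_summary_cohort",
    "generate_trial_waveforms",
    "is_waveform_feasible",
    "generate_emg",
]

GRAVITY = 9.81  # m/s²

#: Cohort means of the summary variables (deg, N/kg, J/kg, Nm/kg).
SUMMARY_MEANS: dict[str, float] = {
    "AICA": 33.47, "AROM": 59.99, "PVGRF": 36.61, "TED": 6.01,
    "PADM": 1.61, "PKFM": 3.13, "PHFM": 1.58, "PAIA": 14.19,
    "PAIM": 0.75, "PAF": 14.72,
}

#: Between-subject SDs matching :data:`SUMMARY_MEANS`.
SUMMARY_SDS: dict[str, float] = {
    "AICA": 5.16, "AROM": 8.35, "PVGRF": 5.10, "TED": 0.77,
    "PADM": 0.32, "PKFM": 0.56, "PHFM": 0.40, "PAIA": 2.74,
    "PAIM": 0.23, "PAF": 1.68,
}

#: Reported correlations of each variable with the ankle initial contact angle.
AICA_CORRELATIONS: dict[str, float] = {
    "PVGRF": -0.591, "TED": 0.490, "PADM": -0.542, "PKFM": -0.441,
    "PHFM": -0.253, "PAIA": 0.502, "PAIM": -0.268, "PAF": -0.554,
}

#: Reported correlations of each variable with the ankle range of motion.
AROM_CORRELATIONS: dict[str, float] = {
    "PVGRF": -0.451, "TED": 0.687, "PADM": -0.357, "PKFM": -0.284,
    "PHFM": -0.357, "PAIA": 0.600, "PAIM": -0.138, "PAF": -0.332,
}

#: Reported non-anchor pair: ACL-force vs inversion-angle risk markers.
EXTRA_CORRELATIONS: dict[tuple[str, str], float] = {("PAIA", "PAF"): -0.330}


def nearest_correlation_fixed(
    matrix: NDArray,
    fixed: NDArray,
    max_iter: int = 500,
    eig_floor: float = 0.0,
) -> NDArray:
    """Project a symmetric matrix to the nearest positive-semidefinite
    correlation matrix while holding ``fixed`` (boolean mask) entries and the
    unit diagonal exactly.

    Alternating projections with Dykstra correction between the PSD cone and
    the affine set of matrices with the prescribed entries.
    """
    R = np.asarray(matrix, dtype=float)
    X = R.copy()
    ds = np.zeros_like(X)
    for _ in range(max_iter):
        rk = X - ds
        w, v = np.linalg.eigh(rk)
        xp = (v * np.clip(w, eig_floor, None)) @ v.T
        ds = xp - rk
        X = xp.copy()
        X[fixed] = R[fixed]
        np.fill_diagonal(X, 1.0)
    X = 0.5 * (X + X.T)
    if np.linalg.eigvalsh(X).min() < -1e-8:
        raise InvalidParameterError(
            "correlation targets are infeasible: projection did not reach PSD"
        )
    return X


def build_correlation_matrix(
    aica_r: Mapping[str, float] | None = None,
    arom_r: Mapping[str, float] | None = None,
    extra: Mapping[tuple[str, str], float] | None = None,
    variables: tuple[str, ...] = SUMMARY_FIELDS,
) -> NDArray:
    """Assemble the full 10×10 correlation matrix from the anchor rows.

    Unreported pairs are filled by averaging the product-of-paths estimates
    through the two anchors, r(i,j) ≈ ½[r(i,A)r(j,A) + r(i,B)r(j,B)], the
    anchor–anchor entry by the mean product across the shared variables,
    and the result is projected to the nearest valid correlation matrix
    with the reported entries held fixed.
    """
    aica_r = dict(AICA_CORRELATIONS if aica_r is None else aica_r)
    arom_r = dict(AROM_CORRELATIONS if arom_r is None else arom_r)
    extra = dict(EXTRA_CORRELATIONS if extra is None else extra)
    idx = {v: i for i, v in enumerate(variables)}
    n = len(variables)
    R = np.eye(n)
    fixed = np.zeros((n, n), dtype=bool)

    def put(a: str, b: str, value: float, fix: bool) -> None:
        i, j = idx[a], idx[b]
        R[i, j] = R[j, i] = value
        if fix:
            fixed[i, j] = fixed[j, i] = True

    for var, r in aica_r.items():
        put("AICA", var, r, fix=True)
    for var, r in arom_r.items():
        put("AROM", var, r, fix=True)
    others = [v for v in variables if v not in ("AICA", "AROM")]
    put("AICA", "AROM", float(np.mean([aica_r[v] * arom_r[v] for v in others])), fix=False)
    for i, a in enumerate(others):
        for b in others[i + 1:]:
            put(a, b, 0.5 * (aica_r[a] * aica_r[b] + arom_r[a] * arom_r[b]), fix=False)
    for (a, b), r in extra.items():
        put(a, b, r, fix=True)
    return nearest_correlation_fixed(R, fixed)


@dataclass
class CohortConfig:
    """Configuration of the summary-level cohort generator.

    Defaults reproduce the study conditions: 60 subjects × 5 trials, the
    published means/SDs, and the anchor-row correlation calibration.  The
    within-subject trial scatter is never reported; the default fraction
    (0.2 of the between-subject SD) is a documented free parameter.
    """

    n_subjects: int = 60
    trials_per_subject: int = 5
    means: dict[str, float] = field(default_factory=lambda: dict(SUMMARY_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(SUMMARY_SDS))
    correlation: NDArray | None = None  # None → default calibration
    trial_noise_frac: float = 0.2
    body_mass_mean: float = 81.93
    body_mass_sd: float = 12.81

    def __post_init__(self):
        if self.n_subjects < 2 or self.trials_per_subject < 1:
            raise InvalidParameterError("need ≥ 2 subjects and ≥ 1 trial each")
        if set(self.means) != set(SUMMARY_FIELDS) or set(self.sds) != set(SUMMARY_FIELDS):
            raise InvalidParameterError("means/sds must cover exactly the summary variables")
        if any(s <= 0 for s in self.sds.values()):
            raise InvalidParameterError("all SDs must be positive")
        if self.trial_noise_frac < 0:
            raise InvalidParameterError("trial noise fraction must be non-negative")
        if self.correlation is None:
            self.correlation = build_correlation_matrix()
        else:
            C = np.asarray(self.correlation, dtype=float)
            if C.shape != (len(SUMMARY_FIELDS),) * 2 or not np.allclose(C, C.T):
                raise InvalidParameterError("correlation must be a symmetric 10×10 matrix")
            if not np.allclose(np.diag(C), 1.0):
                raise InvalidParameterError("correlation diagonal must be 1")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise InvalidParameterError("correlation matrix is not positive semidefinite")
            self.correlation = C


@dataclass(frozen=True)
class CohortTables:
    """Trial-level and subject-level views of one generated cohort."""

    trials: pd.DataFrame  # columns: subject, trial, body_mass, <variables>
    subjects_true: pd.DataFrame  # latent subject values (no trial noise)

    @property
    def subject_means(self) -> pd.DataFrame:
        """Within-subject trial means — the default unit of analysis."""
        return (
            self.trials.drop(columns="trial")
            .groupby("subject", sort=True)
            .mean(numeric_only=True)
        )


def generate_summary_cohort(config: CohortConfig, seed: int | None = None) -> CohortTables:
    """Draw a cohort of summary-variable tables.

    Subject vectors come from the configured multivariate normal; each trial
    adds independent Gaussian noise with SD ``trial_noise_frac`` × the
    between-subject SD.  Body mass is drawn independently per subject.
    Fully reproducible for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    variables = list(SUMMARY_FIELDS)
    mu = np.array([config.means[v] for v in variables])
    sd = np.array([config.sds[v] for v in variables])
    C = config.correlation + 1e-12 * np.eye(len(variables))
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((config.n_subjects, len(variables)))
    subjects = mu + (z @ L.T) * sd
    mass = np.clip(
        rng.normal(config.body_mass_mean, config.body_mass_sd, config.n_subjects),
        45.0, None,
    )

    subj_df = pd.DataFrame(subjects, columns=variables)
    subj_df.insert(0, "subject", np.arange(config.n_subjects))
    subj_df.insert(1, "body_mass", mass)

    noise_sd = config.trial_noise_frac * sd
    rows = []
    for s in range(config.n_subjects):
        for t in range(config.trials_per_subject):
            values = subjects[s] + rng.standard_normal(len(variables)) * noise_sd
            rows.append([s, t, mass[s], *values])
    trials = pd.DataFrame(rows, columns=["subject", "trial", "body_mass", *variables])
    trials["subject"] = trials["subject"].astype(int)
    trials["trial"] = trials["trial"].astype(int)
    return CohortTables(trials=trials, subjects_true=subj_df.set_index("subject"))


# ---------------------------------------------------------------------------
# trial-level waveforms


@dataclass(frozen=True)
class WaveformTemplateParams:
    """Timing/shape parameters of the smooth trial templates.

    All times in seconds relative to initial contact; the template shapes
    (raised-cosine bumps, smoothstep transitions) are chosen for closed-form
    peaks that survive the 10/20 Hz zero-phase filters with < 1 % peak loss.
    """

    sampling_rate: float = 1000.0
    pre_contact_s: float = 0.10
    phase_duration_s: float = 0.50
    post_phase_s: float = 0.15
    vgrf_rise_s: float = 0.03
    vgrf_peak_time_s: float = 0.08
    vgrf_peak_halfwidth_s: float = 0.08
    ankle_transition_delay_s: float = 0.08
    ankle_transition_s: float = 0.30
    knee_start_deg: float = 15.0
    knee_peak_deg: float = 70.0
    hip_start_deg: float = 20.0
    hip_end_deg: float = 50.0
    inversion_peak_time_s: float = 0.25
    inversion_halfwidth_s: float = 0.15
    ankle_moment_peak_time_s: float = 0.12
    knee_moment_peak_time_s: float = 0.15
    hip_moment_peak_time_s: float = 0.18
    moment_halfwidth_s: float = 0.10
    inversion_moment_peak_time_s: float = 0.20
    inversion_moment_halfwidth_s: float = 0.12
    elongation_peak_time_s: float = 0.08
    elongation_halfwidth_s: float = 0.08


def _smoothstep(x: NDArray) -> NDArray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _hann_bump(t: NDArray, center: float, halfwidth: float) -> NDArray:
    x = (t - center) / halfwidth
    return np.where(np.abs(x) < 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)


def is_waveform_feasible(row: Mapping[str, float], body_mass: float | None = None) -> bool:
    """True when the bump/ramp templates can embed the row's targets
    (positive excursions and an impact peak above body weight)."""
    mass = body_mass if body_mass is not None else row.get("body_mass", 81.93)
    return (
        row["AROM"] >= 0
        and row["PVGRF"] * mass > mass * GRAVITY
        and row["PAIA"] > 0
        and row["PADM"] > 0
        and row["PKFM"] > 0
        and row["PHFM"] > 0
        and row["PAIM"] > 0
        and row["PAF"] > 0
    )


def generate_trial_waveforms(
    summary_row: Mapping[str, float],
    template: WaveformTemplateParams | None = None,
    body_mass: float | None = None,
    seed: int | None = None,
    noise_scale: float = 0.0,
) -> TrialTimeSeries:
    """Build a full trial whose extracted summary reproduces ``summary_row``.

    The ankle starts plantarflexed at AICA, holds briefly, and transitions
    smoothly to the dorsiflexion plateau AICA − AROM; VGRF is a body-weight
    shoulder plus a raised-cosine impact bump peaking at PVGRF; moments and
    the inversion angle are raised-cosine bumps peaking at their targets;
    the ACL-elongation bump amplitude is solved with Brent's method against
    the extraction pipeline so the trial's peak ACL force equals PAF.
    ``noise_scale`` (fraction of each channel's range) adds white
    measurement noise after the templates are solved.
    """
    tp = template or WaveformTemplateParams()
    mass = float(body_mass if body_mass is not None else summary_row.get("body_mass", 81.93))
    if not is_waveform_feasible(summary_row, mass):
        raise GenerationError("summary row infeasible for the waveform templates")

    fs = tp.sampling_rate
    dt = 1.0 / fs
    total = tp.pre_contact_s + tp.phase_duration_s + tp.post_phase_s
    time = np.arange(0.0, total, dt)
    t0 = tp.pre_contact_s
    tau = time - t0  # time since contact

    bw = mass * GRAVITY
    pvgrf_n = summary_row["PVGRF"] * mass
    vgrf = bw * _smoothstep(tau / tp.vgrf_rise_s) + (pvgrf_n - bw) * _hann_bump(
        tau, tp.vgrf_peak_time_s, tp.vgrf_peak_halfwidth_s
    )
    vgrf[tau < 0] = 0.0

    aica, arom = summary_row["AICA"], summary_row["AROM"]
    ankle = aica - arom * _smoothstep((tau - tp.ankle_transition_delay_s) / tp.ankle_transition_s)

    knee = tp.knee_start_deg + (tp.knee_peak_deg - tp.knee_start_deg) * _smoothstep(
        tau / tp.phase_duration_s
    )
    # decline after the phase so the knee-flexion argmax marks the phase end
    knee -= 10.0 * _smoothstep((tau - tp.phase_duration_s) / tp.post_phase_s)
    hip = tp.hip_start_deg + (tp.hip_end_deg - tp.hip_start_deg) * _smoothstep(
        tau / (0.9 * tp.phase_duration_s)
    )

    inversion = summary_row["PAIA"] * _hann_bump(
        tau, tp.inversion_peak_time_s, tp.inversion_halfwidth_s
    )
    ankle_moment = summary_row["PADM"] * _hann_bump(
        tau, tp.ankle_moment_peak_time_s, tp.moment_halfwidth_s
    )
    knee_moment = summary_row["PKFM"] * _hann_bump(
        tau, tp.knee_moment_peak_time_s, tp.moment_halfwidth_s
    )
    hip_moment = summary_row["PHFM"] * _hann_bump(
        tau, tp.hip_moment_peak_time_s, tp.moment_halfwidth_s
    )
    inv_moment = summary_row["PAIM"] * _hann_bump(
        tau, tp.inversion_moment_peak_time_s, tp.inversion_moment_halfwidth_s
    )

    elongation = _solve_elongation(
        summary_row["PAF"], mass, time, tau, vgrf, knee, tp
    )

    if noise_scale > 0.0:
        rng = np.random.default_rng(seed)
        for arr in (vgrf, ankle, knee, hip, inversion, ankle_moment,
                    knee_moment, hip_moment, inv_moment, elongation):
            span = np.ptp(arr)
            arr += rng.standard_normal(arr.size) * noise_scale * span

    return TrialTimeSeries(
        time=time,
        vgrf=vgrf,
        ankle_sagittal=ankle,
        knee_flexion=knee,
        hip_flexion=hip,
        ankle_inversion=inversion,
        ankle_moment=ankle_moment,
        knee_moment=knee_moment,
        hip_moment=hip_moment,
        ankle_inversion_moment=inv_moment,
        body_mass=mass,
        acl_elongation=elongation,
    )


def _solve_elongation(
    paf_target: float,
    mass: float,
    time: NDArray,
    tau: NDArray,
    vgrf: NDArray,
    knee: NDArray,
    tp: WaveformTemplateParams,
) -> NDArray:
    """Invert the constitutive model: find the strain-bump amplitude whose
    extracted peak ACL force equals the target (N/kg), running the same
    filter → strain → stress pipeline the extractor uses."""
    from .ligament import A_ACL

    fs = tp.sampling_rate
    dt = 1.0 / fs
    start, end = landing.detect_landing_phase(vgrf, knee)
    bump = _hann_bump(tau, tp.elongation_peak_time_s, tp.elongation_halfwidth_s)

    def extracted_paf(amplitude: float) -> float:
        le = A_ACL.resting_length * (1.0 + amplitude * bump)
        le_f = landing.filter_signal(le, fs, 10.0)
        return landing.peak_acl_force(le_f[start : end + 1], dt, mass)

    lo, hi = 1e-6, 0.05
    while extracted_paf(hi) < paf_target:
        hi *= 2.0
        if hi > 3.0:
            raise GenerationError(
                f"target peak ACL force {paf_target:.2f} N/kg unreachable "
                "within the strain-amplitude search bracket"
            )
    amp = brentq(lambda a: extracted_paf(a) - paf_target, lo, hi, xtol=1e-12)
    return A_ACL.resting_length * (1.0 + amp * bump)


# ---------------------------------------------------------------------------
# synthetic EMG


@dataclass(frozen=True)
class EmgBurstParams:
    """Burst-envelope parametrisation of a synthetic raw EMG channel.

    ``bursts`` lists (center_s, halfwidth_s, amplitude_mv) raised-cosine
    envelope bumps; the carrier is band-limited white noise.
    """

    duration_s: float = 1.0
    sampling_rate: float = 1000.0
    bursts: tuple[tuple[float, float, float], ...] = ((0.5, 0.15, 1.0),)
    carrier_band: tuple[float, float] = (20.0, 150.0)
    muscle: str = "synthetic"


def generate_emg(params: EmgBurstParams, seed: int | None = None) -> EmgTrace:
    """Raw-like EMG: unit-RMS band-limited noise modulated by the burst
    envelope; the preprocessing→activation chain peaks within the bursts."""
    rng = np.random.default_rng(seed)
    n = int(params.duration_s * params.sampling_rate)
    t = np.arange(n) / params.sampling_rate
    carrier = rng.standard_normal(n)
    sos = _signal.butter(2, params.carrier_band, btype="bandpass",
                         fs=params.sampling_rate, output="sos")
    carrier = _signal.sosfiltfilt(sos, carrier)
    rms = np.sqrt(np.mean(carrier**2))
    if rms > 0:
        carrier /= rms
    envelope = np.zeros(n)
    for center, halfwidth, amplitude in params.bursts:
        envelope += amplitude * _hann_bump(t, center, halfwidth)
    return EmgTrace(
        samples=carrier * envelope,
        sampling_rate=params.sampling_rate,
        muscle=params.muscle,
    )


def burst_envelope(params: EmgBurstParams) -> NDArray:
    """The noiseless envelope a generated channel was modulated with."""
    n = int(params.duration_s * params.sampling_rate)
    t = np.arange(n) / params.sampling_rate
    envelope = np.zeros(n)
    for center, halfwidth, amplitude in params.bursts:
        envelope += amplitude * _hann_bump(t, center, halfwidth)
    return envelope
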