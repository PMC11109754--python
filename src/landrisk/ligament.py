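"""Strain-rate-dependent viscoelastic ACL bundle model.

The anterior cruciate ligament is modelled as dense connective tissue whose
collagen fibers straighten ("unwind") sequentially under increasing strain.
Fiber recruitment follows a two-parameter Weibull density w(ε_s) with shape
``α`` and scale ``β`` (location fixed at zero).  A fiber recruited at strain
ε_s carries an elastic stress K·(ε − ε_s) plus a viscous stress η·ε̇, so the
nominal axial stress of the bundle at strain ε and strain rate ε̇ is

    σ_af(ε, ε̇) = ∫₀^ε w(ε_s) [ K (ε − ε_s) + η ε̇ ] dε_s        (ε > 0)

and identically zero when the ligament is slack (ε ≤ 0).  Bundle force is
σ_af × cross-sectional area; with stress in MPa and area in mm² the product
is directly in newtons.  Total ACL force is the sum of the anteromedial
(A-ACL) and posterolateral (P-ACL) bundle forces.

Exchanging the order of integration gives closed forms used by the fast
vectorised path (and as analytic cross-checks of the quadrature route):

    elastic  σ_e(ε) = K [ ε − (β/α) γ(1/α, (ε/β)^α) ]   (γ = lower incomplete gamma)
    viscous  σ_v(ε, ε̇) = η ε̇ F(ε)                       (F = Weibull CDF)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from numpy.typing import ArrayLike, NDArray
from scipy import integrate
from scipy.special import gamma as gamma_fn
from scipy.special import gammainc

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    NumericalFailureError,
    ShapeError,
)

__all__ = [
    "LigamentBundleSpec",
    "StressDecomposition",
    "MaterialFitResult",
    "StrainLimitReport",
    "ElongationMapping",
    "A_ACL",
    "P_ACL",
    "BUNDLES",
    "load_bundle_registry",
    "compute_strain",
    "compute_strain_rate",
    "weibull_recruitment_density",
    "weibull_recruitment_cdf",
    "nominal_axial_stress",
    "stress_decomposition",
    "stress_series",
    "ligament_force",
    "total_acl_force",
    "total_force_from_strain",
    "acl_elongation_from_knee_flexion",
    "fit_material_polynomial",
    "strain_limit_check",
]


@dataclass(frozen=True)
class LigamentBundleSpec:
    """Material and geometric parameters of one dense-connective-tissue bundle.

    Units: lengths mm, areas mm², forces N, moduli MPa, viscosity MPa·s.
    The Weibull shape/scale describe the collagen-fiber recruitment density
    over strain; the location parameter is fixed at zero.  ``passive_strain_cap``
    (15 %) is the passive-strain ceiling used by the validation report and
    ``junction_strain_cap`` the cap at the ligament–bone junction.
    """

    name: str
    resting_length: float
    cross_sectional_area: float
    max_isometric_force: float
    elastic_modulus: float = 70.0
    viscosity: float = 20.0
    weibull_shape: float = 4.5
    weibull_scale: float = 0.3
    weibull_location: float = 0.0
    passive_strain_cap: float = 0.15
    junction_strain_cap: float = 0.030

    def __post_init__(self):
        if self.resting_length <= 0 or self.cross_sectional_area <= 0:
            raise InvalidParameterError("resting length and area must be positive")
        if self.elastic_modulus <= 0 or self.viscosity < 0:
            raise InvalidParameterError("require K > 0 and η ≥ 0")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise InvalidParameterError("Weibull shape and scale must be positive")
        if self.weibull_location != 0.0:
            raise InvalidParameterError("Weibull location is fixed at 0")
        for cap in (self.passive_strain_cap, self.junction_strain_cap):
            if not 0.0 < cap < 1.0:
                raise InvalidParameterError("strain caps must lie in (0, 1)")


#: Anteromedial bundle (resting length 30 mm, area 20.7 mm², Fmax 1500 N).
A_ACL = LigamentBundleSpec("A-ACL", 30.0, 20.7, 1500.0)
#: Posterolateral bundle (resting length 23.36 mm, area 19.3 mm², Fmax 1600 N).
P_ACL = LigamentBundleSpec("P-ACL", 23.36, 19.3, 1600.0)

BUNDLES: dict[str, LigamentBundleSpec] = {"A-ACL": A_ACL, "P-ACL": P_ACL}


def load_bundle_registry(path: str | Path) -> dict[str, LigamentBundleSpec]:
    """Load a YAML/JSON bundle registry mapping name -> parameter overrides."""
    raw = yaml.safe_load(Path(path).read_text())
    registry = {}
    for name, params in raw.items():
        base = BUNDLES.get(name)
        if base is not None:
            registry[name] = replace(base, **params)
        else:
            registry[name] = LigamentBundleSpec(name=name, **params)
    return registry


@dataclass(frozen=True)
class StressDecomposition:
    """Elastic/viscous split of the nominal axial stress (MPa); pressure is 0."""

    elastic: float
    viscous: float
    total: float
    pressure: float = 0.0


@dataclass(frozen=True)
class MaterialFitResult:
    """Mean sixth-order polynomial coefficients across sample curves."""

    coefficients: NDArray[np.float64]  # 7 entries, highest degree first
    sample_count: int
    fit_residual: float

    def __post_init__(self):
        if len(self.coefficients) != 7:
            raise InvalidParameterError("sixth-order fit requires exactly 7 coefficients")


@dataclass(frozen=True)
class StrainLimitReport:
    """Non-mutating record of strain-cap and force-cap exceedances."""

    passive_cap: float
    passive_violation_indices: NDArray[np.intp]
    junction_cap: float
    junction_violation_indices: NDArray[np.intp]
    peak_strain: float

    @property
    def any_violation(self) -> bool:
        return (
            len(self.passive_violation_indices) > 0
            or len(self.junction_violation_indices) > 0
        )


# ---------------------------------------------------------------------------
# strain kinematics


def compute_strain(elongated_length: ArrayLike, resting_length: float) -> NDArray | float:
    """Engineering strain (L_e − L_r)/L_r; negative values mean slack."""
    if resting_length <= 0:
        raise InvalidParameterError("resting length must be positive")
    le = np.asarray(elongated_length, dtype=float)
    strain = (le - resting_length) / resting_length
    return strain if strain.ndim else float(strain)


def compute_strain_rate(strain_series: ArrayLike, dt: float) -> NDArray:
    """Instantaneous strain rate (1/s) by central differences.

    Endpoints use one-sided differences (``numpy.gradient`` convention);
    exact for linear strain histories.
    """
    strain = np.asarray(strain_series, dtype=float)
    if strain.size < 2:
        raise InsufficientDataError("strain rate needs at least 2 samples")
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    return np.gradient(strain, dt)


# ---------------------------------------------------------------------------
# fiber recruitment


def weibull_recruitment_density(
    strain: ArrayLike, shape: float = 4.5, scale: float = 0.3
) -> NDArray | float:
    """Weibull pdf of fiber-unwinding strain; zero below zero strain."""
    if shape <= 0 or scale <= 0:
        raise InvalidParameterError("shape and scale must be positive")
    eps = np.asarray(strain, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(eps > 0, eps / scale, 0.0)
        pdf = (shape / scale) * x ** (shape - 1.0) * np.exp(-(x**shape))
    pdf = np.where(eps > 0, pdf, 0.0)
    return pdf if pdf.ndim else float(pdf)


def weibull_recruitment_cdf(
    strain: ArrayLike, shape: float = 4.5, scale: float = 0.3
) -> NDArray | float:
    """Fraction of fibers recruited at or below the given strain."""
    eps = np.asarray(strain, dtype=float)
    cdf = np.where(eps > 0, -np.expm1(-((np.clip(eps, 0, None) / scale) ** shape)), 0.0)
    return cdf if cdf.ndim else float(cdf)


# ---------------------------------------------------------------------------
# constitutive stress


def _elastic_stress_closed_form(eps: NDArray, spec: LigamentBundleSpec) -> NDArray:
    # σ_e(ε) = K ∫₀^ε F(s) ds = K [ε − (β/α) γ(1/α, (ε/β)^α)]
    a, b, K = spec.weibull_shape, spec.weibull_scale, spec.elastic_modulus
    epsp = np.clip(eps, 0.0, None)
    inc = gamma_fn(1.0 / a) * gammainc(1.0 / a, (epsp / b) ** a)
    return K * (epsp - (b / a) * inc)


def nominal_axial_stress(
    strain: float,
    strain_rate: float,
    spec: LigamentBundleSpec,
    *,
    tol: float = 1e-9,
) -> float:
    """Nominal axial stress σ_af (MPa) by adaptive quadrature of the
    recruitment integral; slack (ε ≤ 0) returns exactly zero and negative
    totals during unloading are clamped at zero (tension-only model).

    Falls back to a 10⁴-interval composite Simpson rule if the adaptive
    scheme cannot reach ``tol``; raises :class:`NumericalFailureError` with
    the achieved error estimate if both fail.
    """
    if strain <= 0.0:
        return 0.0
    a, b = spec.weibull_shape, spec.weibull_scale
    K, eta = spec.elastic_modulus, spec.viscosity

    def integrand(s: float) -> float:
        w = (a / b) * (s / b) ** (a - 1.0) * np.exp(-((s / b) ** a))
        return w * (K * (strain - s) + eta * strain_rate)

    value, err = integrate.quad(integrand, 0.0, strain, epsabs=tol, epsrel=1e-12, limit=200)
    if err > max(tol, 1e-12 * abs(value)):
        s = np.linspace(0.0, strain, 10_001)
        simpson = integrate.simpson(integrand(s[1:]), x=s[1:])
        # Simpson error estimate by Richardson against half resolution
        half = integrate.simpson(integrand(s[1::2]), x=s[1::2])
        est = abs(simpson - half)
        if est > 100 * tol:
            raise NumericalFailureError(
                f"stress quadrature did not converge (error ≈ {est:.3e} MPa)",
                error_estimate=est,
            )
        value = simpson
    return max(value, 0.0)


def stress_decomposition(
    strain: float, strain_rate: float, spec: LigamentBundleSpec
) -> StressDecomposition:
    """Elastic/viscous decomposition of σ_af via the closed forms.

    The viscous integral is η ε̇ × (Weibull CDF at ε) exactly; the elastic
    integral reduces to an incomplete-gamma expression.  The total matches
    :func:`nominal_axial_stress` to quadrature tolerance (tested invariant).
    """
    if strain <= 0.0:
        return StressDecomposition(0.0, 0.0, 0.0)
    elastic = float(_elastic_stress_closed_form(np.asarray(strain), spec))
    viscous = spec.viscosity * strain_rate * float(
        weibull_recruitment_cdf(strain, spec.weibull_shape, spec.weibull_scale)
    )
    total = max(elastic + viscous, 0.0)
    return StressDecomposition(elastic=elastic, viscous=viscous, total=total)


def stress_series(
    strain: ArrayLike, strain_rate: ArrayLike, spec: LigamentBundleSpec
) -> NDArray:
    """Vectorised σ_af over paired strain / strain-rate series (MPa).

    Uses the closed-form elastic + viscous expressions; agrees with the
    adaptive-quadrature scalar route to tolerance.
    """
    eps = np.asarray(strain, dtype=float)
    rate = np.asarray(strain_rate, dtype=float)
    if eps.shape != rate.shape:
        raise ShapeError("strain and strain-rate series must have equal shape")
    sigma = _elastic_stress_closed_form(eps, spec) + spec.viscosity * rate * np.asarray(
        weibull_recruitment_cdf(eps, spec.weibull_shape, spec.weibull_scale)
    )
    return np.where(eps > 0, np.clip(sigma, 0.0, None), 0.0)


# ---------------------------------------------------------------------------
# forces


def ligament_force(stress: ArrayLike, spec: LigamentBundleSpec) -> NDArray | float:
    """Bundle force F = σ_af × A (MPa × mm² → N); negative stress is an error.

    Values above the bundle's max isometric force are *not* clamped; use
    :func:`strain_limit_check` / downstream validation to flag them.
    """
    sigma = np.asarray(stress, dtype=float)
    if np.any(sigma < 0):
        raise InvalidParameterError("stress must be non-negative")
    force = sigma * spec.cross_sectional_area
    return force if force.ndim else float(force)


def total_acl_force(force_a: ArrayLike, force_p: ArrayLike) -> NDArray:
    """Total ACL force as the element-wise sum of the two bundle forces."""
    fa = np.asarray(force_a, dtype=float)
    fp = np.asarray(force_p, dtype=float)
    if fa.shape != fp.shape:
        raise ShapeError("bundle force series must have equal length")
    return fa + fp


def total_force_from_strain(
    strain: ArrayLike,
    strain_rate: ArrayLike,
    bundles: tuple[LigamentBundleSpec, ...] = (A_ACL, P_ACL),
) -> NDArray:
    """Total ACL force (N) assuming both bundles share one strain history.

    A single measured elongation channel fixes the strain of the anteromedial
    bundle; the posterolateral bundle is taken to be strained equally (its
    elongation scales with its own resting length).
    """
    forces = [
        np.asarray(ligament_force(stress_series(strain, strain_rate, b), b))
        for b in bundles
    ]
    out = forces[0]
    for f in forces[1:]:
        out = total_acl_force(out, f)
    return out


# ---------------------------------------------------------------------------
# elongation mapping and material fit


@dataclass(frozen=True)
class ElongationMapping:
    """Polynomial map from knee flexion (deg) to A-ACL length (mm).

    Stands in for the musculoskeletal-simulation elongation output; the
    coefficients are configuration (highest degree first, ``numpy.polyval``
    convention) valid only on ``flexion_range``.
    """

    coefficients: tuple[float, ...]
    flexion_range: tuple[float, float] = (0.0, 120.0)


def acl_elongation_from_knee_flexion(
    knee_flexion_deg: ArrayLike, mapping: ElongationMapping
) -> NDArray:
    """Evaluate the configured flexion→elongation polynomial per sample."""
    theta = np.asarray(knee_flexion_deg, dtype=float)
    lo, hi = mapping.flexion_range
    if np.any(theta < lo) or np.any(theta > hi):
        raise InvalidParameterError(
            f"knee flexion outside mapping range [{lo}, {hi}] deg"
        )
    return np.polyval(mapping.coefficients, theta)


def fit_material_polynomial(
    curves: list[tuple[ArrayLike, ArrayLike]]
) -> MaterialFitResult:
    """Fit a sixth-order polynomial to each (strain, response) curve and
    average the coefficients across curves.

    Each curve needs ≥ 7 points; a rank-deficient design raises an error.
    """
    if not curves:
        raise InsufficientDataError("at least one sample curve is required")
    coeffs = []
    residuals = []
    for x, y in curves:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 7:
            raise InsufficientDataError("each curve needs at least 7 points")
        vander = np.vander(x, 7)
        if np.linalg.matrix_rank(vander) < 7:
            raise NumericalFailureError("rank-deficient design: strains not distinct enough")
        c, res, *_ = np.linalg.lstsq(vander, y, rcond=None)
        coeffs.append(c)
        residuals.append(np.sqrt(np.mean((vander @ c - y) ** 2)))
    return MaterialFitResult(
        coefficients=np.mean(coeffs, axis=0),
        sample_count=len(curves),
        fit_residual=float(np.mean(residuals)),
    )


def strain_limit_check(
    strain_series: ArrayLike,
    spec: LigamentBundleSpec,
    junction_window: tuple[int, int] | None = None,
) -> StrainLimitReport:
    """Report samples exceeding the passive (15 %) and junction strain caps.

    ``junction_window`` is the (start, stop) index sub-interval treated as the
    ligament–bone junction region; by default no junction region is checked.
    Data are never mutated or clamped.
    """
    eps = np.asarray(strain_series, dtype=float)
    passive_idx = np.flatnonzero(eps > spec.passive_strain_cap)
    if junction_window is not None:
        lo, hi = junction_window
        local = np.flatnonzero(eps[lo:hi] > spec.junction_strain_cap) + lo
    else:
        local = np.array([], dtype=np.intp)
    return StrainLimitReport(
        passive_cap=spec.passive_strain_cap,
        passive_violation_indices=passive_idx,
        junction_cap=spec.junction_strain_cap,
        junction_violation_indices=local,
        peak_strain=float(eps.max()) if eps.size else 0.0,
    )
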