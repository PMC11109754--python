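"""Replicate-averaged reproduction of the cohort-level statistics.

The study cohort itself is not redistributable, so its headline statistics
are reproduced by parameter recovery: many independent synthetic cohorts
are generated at the default calibration (60 subjects × 5 trials), the full
statistical surface is computed on each — subject-mean Pearson correlations,
min–max standardized ACL/LAS risks, fitted-line risk crossings and balanced
ranges — and the estimates are averaged over replicates.  Everything is
driven by one integer seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortConfig, generate_summary_cohort
from .riskstats import (
    balanced_range,
    pearson_with_regression,
    risk_intersection,
    standardize_risk,
)

__all__ = ["ReplicateStatistics", "replicate_cohort_statistics"]

#: The correlation pairs reported by the replicate study, as (x, y) columns.
CORRELATION_PAIRS = (
    ("AICA", "PVGRF"),
    ("AROM", "TED"),
    ("AICA", "PAF"),
    ("AROM", "PAIA"),
)


@dataclass(frozen=True)
class ReplicateStatistics:
    """Replicate-averaged estimates (plus per-replicate spreads)."""

    n_replicates: int
    n_subjects: int
    mean_r: dict[str, float]  # keyed "AICA_PVGRF" etc. + "riskACL_riskLAS"
    sd_r: dict[str, float]
    crossing_aica: float
    crossing_aica_sd: float
    crossing_arom: float
    crossing_arom_sd: float
    band_aica: tuple[float, float]
    band_arom: tuple[float, float]


def replicate_cohort_statistics(
    n_replicates: int = 200,
    seed: int = 0,
    config: CohortConfig | None = None,
    band_tolerance: float = 0.25,
) -> ReplicateStatistics:
    """Generate ``n_replicates`` cohorts and average the statistical surface.

    Per replicate: trials are averaged within subject; Pearson r is computed
    for each pair in :data:`CORRELATION_PAIRS`; PAF and PAIA are min–max
    standardized and correlated with each other; both standardized risks are
    fitted linearly on AICA and on AROM and the line crossings and balanced
    bands (±``band_tolerance`` risk difference) solved.
    """
    config = config or CohortConfig()
    keys = [f"{a}_{b}" for a, b in CORRELATION_PAIRS] + ["riskACL_riskLAS"]
    rs: dict[str, list[float]] = {k: [] for k in keys}
    cross_a, cross_r = [], []
    bands_a, bands_r = [], []

    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        subject_means = generate_summary_cohort(config, seed=rep_seed).subject_means
        for a, b in CORRELATION_PAIRS:
            rs[f"{a}_{b}"].append(
                pearson_with_regression(subject_means[a], subject_means[b]).r
            )
        risk_acl = standardize_risk(subject_means["PAF"])
        risk_las = standardize_risk(subject_means["PAIA"])
        rs["riskACL_riskLAS"].append(
            pearson_with_regression(risk_acl, risk_las).r
        )
        for predictor, crossings, bands in (
            ("AICA", cross_a, bands_a),
            ("AROM", cross_r, bands_r),
        ):
            x = subject_means[predictor]
            crossings.append(risk_intersection(x, risk_acl, risk_las).crossing)
            bands.append(balanced_range(x, risk_acl, risk_las, band_tolerance))

    return ReplicateStatistics(
        n_replicates=n_replicates,
        n_subjects=config.n_subjects,
        mean_r={k: float(np.mean(v)) for k, v in rs.items()},
        sd_r={k: float(np.std(v, ddof=1)) for k, v in rs.items()},
        crossing_aica=float(np.mean(cross_a)),
        crossing_aica_sd=float(np.std(cross_a, ddof=1)),
        crossing_arom=float(np.mean(cross_r)),
        crossing_arom_sd=float(np.std(cross_r, ddof=1)),
        band_aica=tuple(np.mean(bands_a, axis=0)),
        band_arom=tuple(np.mean(bands_r, axis=0)),
    )
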