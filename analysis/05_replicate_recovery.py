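"""Replicate-averaged recovery of the calibrated cohort statistics.

A single 60-subject cohort is one noisy draw; this driver averages the
correlation estimates, risk crossings, and balanced bands over 200
independent replicates, showing that the pipeline recovers the calibration
targets it was built around.  Writes results/replicate_recovery.json.
"""

import json
from pathlib import Path

from landrisk.replication import replicate_cohort_statistics

ROOT = Path(__file__).resolve().parent.parent / "results"
TARGETS = {
    "AICA_PVGRF": -0.591,
    "AROM_TED": 0.687,
    "AICA_PAF": -0.554,
    "AROM_PAIA": 0.600,
    "riskACL_riskLAS": -0.330,
}


def main() -> None:
    stats = replicate_cohort_statistics(n_replicates=200, seed=17)
    print(f"{stats.n_replicates} replicates × {stats.n_subjects} subjects")
    print(f"{'pair':18s} {'target':>8s} {'mean r':>8s} {'sd':>6s}")
    for pair, target in TARGETS.items():
        print(f"{pair:18s} {target:8.3f} {stats.mean_r[pair]:8.3f} "
              f"{stats.sd_r[pair]:6.3f}")
    print(f"AICA risk crossing: {stats.crossing_aica:.2f}° "
          f"(± {stats.crossing_aica_sd:.2f}), balanced band "
          f"{stats.band_aica[0]:.1f}–{stats.band_aica[1]:.1f}°")
    print(f"AROM risk crossing: {stats.crossing_arom:.2f}° "
          f"(± {stats.crossing_arom_sd:.2f}), balanced band "
          f"{stats.band_arom[0]:.1f}–{stats.band_arom[1]:.1f}°")

    payload = {
        "mean_r": stats.mean_r,
        "sd_r": stats.sd_r,
        "crossing_aica_deg": stats.crossing_aica,
        "crossing_arom_deg": stats.crossing_arom,
        "band_aica_deg": list(stats.band_aica),
        "band_arom_deg": list(stats.band_arom),
    }
    ROOT.mkdir(exist_ok=True)
    (ROOT / "replicate_recovery.json").write_text(json.dumps(payload, indent=2) + "\n")


if __name__ == "__main__":
    main()
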