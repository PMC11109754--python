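"""ACL-rupture vs lateral-ankle-sprain risk trade-off.

Standardizes peak ACL force and peak ankle inversion angle to [0, 1] over
the simulated cohort, fits each standardized risk linearly on AICA and on
AROM, solves the crossing where the two risks balance, and reports the
balanced range (risk difference ≤ 0.25).  Writes results/risk_balance.json
and a two-panel figure.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from landrisk import io, riskstats

ROOT = Path(__file__).resolve().parent.parent / "results"
TOL = 0.25


def main() -> None:
    trials = io.read_summaries(ROOT / "cohort" / "trial_summaries.tsv")
    sm = trials.drop(columns="trial").groupby("subject").mean(numeric_only=True)
    risk_acl = riskstats.standardize_risk(sm["PAF"])
    risk_las = riskstats.standardize_risk(sm["PAIA"])

    report = {}
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, predictor in zip(axes, ("AICA", "AROM")):
        x = sm[predictor].to_numpy()
        inter = riskstats.risk_intersection(x, risk_acl, risk_las)
        band = riskstats.balanced_range(x, risk_acl, risk_las, tolerance=TOL)
        report[predictor] = {
            "crossing_deg": inter.crossing,
            "balanced_range_deg": list(band),
            "tolerance": TOL,
        }
        grid = np.linspace(x.min(), x.max(), 100)
        ax.scatter(x, risk_acl, s=14, label="ACL risk (PAF)", color="tab:red")
        ax.scatter(x, risk_las, s=14, label="LAS risk (PAIA)", color="tab:blue")
        ax.plot(grid, inter.line_acl(grid), color="tab:red")
        ax.plot(grid, inter.line_las(grid), color="tab:blue")
        ax.axvline(inter.crossing, ls="--", color="k", lw=1)
        ax.axvspan(*band, alpha=0.15, color="gray")
        ax.set_xlabel(f"{predictor} (deg)")
        ax.set_title(f"crossing at {inter.crossing:.2f}°")
    axes[0].set_ylabel("standardized injury risk")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(ROOT / "risk_tradeoff.png", dpi=150)

    (ROOT / "risk_balance.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
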