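"""Plain-text trial and summary I/O.

Trial schema — one CSV per trial with a single metadata comment line
(``# body_mass_kg=<float>``) followed by a header of unit-suffixed columns:

    time_s, vgrf_n, ankle_sagittal_deg, knee_flexion_deg, hip_flexion_deg,
    ankle_inversion_deg, ankle_moment_nmkg, knee_moment_nmkg,
    hip_moment_nmkg, ankle_inversion_moment_nmkg[, acl_elongation_mm]

Batch layout: ``<root>/subject_<s>/trial_<t>.csv``.  Summary tables are
tab-separated with a ``subject`` (and optionally ``trial``) column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .landing import TrialTimeSeries

__all__ = [
    "TRIAL_COLUMNS",
    "read_trial_csv",
    "write_trial_csv",
    "iter_trial_files",
    "read_summaries",
    "write_summaries",
]

TRIAL_COLUMNS = {
    "time_s": "time",
    "vgrf_n": "vgrf",
    "ankle_sagittal_deg": "ankle_sagittal",
    "knee_flexion_deg": "knee_flexion",
    "hip_flexion_deg": "hip_flexion",
    "ankle_inversion_deg": "ankle_inversion",
    "ankle_moment_nmkg": "ankle_moment",
    "knee_moment_nmkg": "knee_moment",
    "hip_moment_nmkg": "hip_moment",
    "ankle_inversion_moment_nmkg": "ankle_inversion_moment",
}
_OPTIONAL = {"acl_elongation_mm": "acl_elongation"}


def write_trial_csv(trial: TrialTimeSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {col: getattr(trial, attr) for col, attr in TRIAL_COLUMNS.items()}
    if trial.acl_elongation is not None:
        data["acl_elongation_mm"] = trial.acl_elongation
    frame = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# body_mass_kg={trial.body_mass}\n")
        frame.to_csv(fh, index=False, float_format="%.6g")


def read_trial_csv(path: str | Path) -> TrialTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# body_mass_kg="):
        raise InvalidParameterError(
            f"{path}: missing '# body_mass_kg=' metadata line"
        )
    body_mass = float(first.split("=", 1)[1])
    frame = pd.read_csv(path, comment="#")
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    kwargs = {attr: frame[col].to_numpy(float) for col, attr in TRIAL_COLUMNS.items()}
    for col, attr in _OPTIONAL.items():
        if col in frame.columns:
            kwargs[attr] = frame[col].to_numpy(float)
    return TrialTimeSeries(body_mass=body_mass, **kwargs)


def iter_trial_files(root: str | Path):
    """Yield (subject, trial, path) for a subject_*/trial_*.csv batch tree."""
    root = Path(root)
    for subj_dir in sorted(root.glob("subject_*")):
        suffix = subj_dir.name.split("_", 1)[1]
        if not (subj_dir.is_dir() and suffix.isdigit()):
            continue
        subject = int(suffix)
        for trial_file in sorted(subj_dir.glob("trial_*.csv")):
            trial = int(trial_file.stem.split("_")[1])
            yield subject, trial, trial_file


def write_summaries(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(
        path, sep="\t", float_format="%.6g",
        index=not isinstance(frame.index, pd.RangeIndex),
    )


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
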