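"""Delimited-table readers/writers and the study dataset container.

Everything is plain CSV: comma separated, '.' decimal, UTF-8, one header
row.  Schemas:

* trials:  athlete_id, trial_id, power_W, tlim_s  (+ optional kind,
  vo2peak_l_min, attained)
* breath:  athlete_id, trial_id, time_s, vo2_l_min
* roster:  athlete_id (+ any extra columns)

Malformed numeric cells are reported with their file line numbers
(header is line 1).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

__all__ = [
    "StudyDataset",
    "load_study",
    "write_study",
    "read_table",
    "TRIALS_SCHEMA",
    "BREATH_SCHEMA",
    "ROSTER_SCHEMA",
]

TRIALS_SCHEMA = {
    "required": ["athlete_id", "trial_id", "power_W", "tlim_s"],
    "numeric": ["power_W", "tlim_s"],
}
BREATH_SCHEMA = {
    "required": ["athlete_id", "trial_id", "time_s", "vo2_l_min"],
    "numeric": ["time_s", "vo2_l_min"],
}
ROSTER_SCHEMA = {"required": ["athlete_id"], "numeric": []}


@dataclass
class StudyDataset:
    """Validated study tables plus a provenance manifest."""

    trials: pd.DataFrame
    breath: pd.DataFrame | None = None
    roster: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read and validate one delimited table against a schema."""
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    for col in schema["numeric"]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ParseError(
                f"{path.name}: non-numeric value(s) in column '{col}' at line(s) {lines}"
            )
        df[col] = converted
    return df


def load_study(trials_path, breath_path=None, roster_path=None) -> StudyDataset:
    """Load and cross-validate the study tables.

    Checks trial-id uniqueness per athlete and, when a roster or breath
    table is given, referential integrity of athlete ids.
    """
    trials = read_table(trials_path, TRIALS_SCHEMA)
    dup = trials.duplicated(subset=["athlete_id", "trial_id"])
    if dup.any():
        pairs = trials.loc[dup, ["athlete_id", "trial_id"]].astype(str).agg("/".join, axis=1)
        raise IntegrityError(f"duplicate trial ids: {', '.join(pairs.unique()[:10])}")
    breath = read_table(breath_path, BREATH_SCHEMA) if breath_path else None
    roster = read_table(roster_path, ROSTER_SCHEMA) if roster_path else None
    if roster is not None:
        known = set(roster["athlete_id"])
        unknown = sorted(set(trials["athlete_id"]) - known)
        if unknown:
            raise IntegrityError(
                f"trials reference unknown athlete id(s): {', '.join(map(str, unknown[:10]))}"
            )
        if breath is not None:
            unknown = sorted(set(breath["athlete_id"]) - known)
            if unknown:
                raise IntegrityError(
                    f"breath table references unknown athlete id(s): "
                    f"{', '.join(map(str, unknown[:10]))}"
                )
    manifest = {
        "trials_path": str(trials_path),
        "breath_path": str(breath_path) if breath_path else None,
        "roster_path": str(roster_path) if roster_path else None,
    }
    return StudyDataset(trials=trials, breath=breath, roster=roster, manifest=manifest)


def write_study(dataset: StudyDataset, out_dir) -> dict[str, str]:
    """Write a dataset back to a directory; returns the written paths."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    dataset.trials.to_csv(out / "trials.csv", index=False)
    written["trials"] = str(out / "trials.csv")
    if dataset.breath is not None:
        dataset.breath.to_csv(out / "breath.csv", index=False)
        written["breath"] = str(out / "breath.csv")
    if dataset.roster is not None:
        dataset.roster.to_csv(out / "roster.csv", index=False)
        written["roster"] = str(out / "roster.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, indent=1, default=str)
    written["manifest"] = str(out / "manifest.json")
    return written
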