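"""CSV readers and writers for exposure profiles and survival tables.

Exposure series arrive as two-column tables (time, concentration), the
generic stand-in for fate-model output; time may be recorded in hours and
is converted to days on read.  Survival data use a long-form table with
columns ``treatment_id, concentration_ugL, time_d, survivors``; rows whose
``treatment_id`` starts with ``control`` or ``solvent`` (case-insensitive)
are pooled as unexposed control groups.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exposure import ExposureProfile
from .likelihood import ControlGroup, SurvivalDataset, Treatment

__all__ = ["read_exposure_csv", "write_exposure_csv",
           "read_survival_csv", "write_survival_csv",
           "write_pulse_metadata", "read_pulse_metadata"]

_CONTROL_PREFIXES = ("control", "solvent")


def read_exposure_csv(path, time_unit: str = "d", interpolation: str = "step",
                      factor: float = 1.0, time_col: str | None = None,
                      conc_col: str | None = None) -> ExposureProfile:
    """Read an exposure profile from a two-column CSV.

    ``time_unit`` is ``"d"`` (days) or ``"h"`` (hours, divided by 24 on
    read — all model time is in days).  Column names default to the first
    two columns.
    """
    table = pd.read_csv(path)
    if table.shape[1] < 2:
        raise ValueError("exposure CSV needs at least two columns")
    time_col = time_col or table.columns[0]
    conc_col = conc_col or table.columns[1]
    times = table[time_col].to_numpy(dtype=float)
    if time_unit == "h":
        times = times / 24.0
    elif time_unit != "d":
        raise ValueError(f"time_unit must be 'd' or 'h', got {time_unit!r}")
    conc = table[conc_col].to_numpy(dtype=float)
    return ExposureProfile(times, conc, interpolation=interpolation,
                           factor=factor)


def write_exposure_csv(profile: ExposureProfile, path) -> None:
    """Write the profile record (times in days, unscaled concentrations)."""
    pd.DataFrame({"time_d": profile.times,
                  "concentration_ugL": profile.concentrations}
                 ).to_csv(path, index=False)


def is_control_id(treatment_id: str) -> bool:
    return str(treatment_id).strip().lower().startswith(_CONTROL_PREFIXES)


def read_survival_csv(path) -> SurvivalDataset:
    """Read a long-form survival table into a :class:`SurvivalDataset`."""
    table = pd.read_csv(path)
    required = {"treatment_id", "concentration_ugL", "time_d", "survivors"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival CSV is missing columns {sorted(missing)}")
    treatments = []
    controls = []
    for tid, group in table.groupby("treatment_id", sort=False):
        group = group.sort_values("time_d")
        times = group["time_d"].to_numpy(dtype=float)
        survivors = group["survivors"].to_numpy(dtype=float)
        if is_control_id(tid):
            controls.append(ControlGroup(times, survivors))
        else:
            conc = float(group["concentration_ugL"].iloc[0])
            treatments.append(Treatment(conc, times, survivors))
    return SurvivalDataset(tuple(treatments), tuple(controls))


def write_survival_csv(dataset: SurvivalDataset, path) -> None:
    rows = []
    for k, tr in enumerate(dataset.treatments):
        for t, y in zip(tr.times, tr.survivors):
            rows.append({"treatment_id": f"t{k + 1}",
                         "concentration_ugL": tr.concentration,
                         "time_d": t, "survivors": int(y)})
    for k, grp in enumerate(dataset.controls):
        tid = "control" if k == 0 else f"control_{k + 1}"
        for t, y in zip(grp.times, grp.survivors):
            rows.append({"treatment_id": tid, "concentration_ugL": 0.0,
                         "time_d": t, "survivors": int(y)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pulse_metadata(pulses, path) -> None:
    """JSON sidecar with the ground-truth pulse boundaries of a generated train."""
    payload = [{"start_d": p.start, "end_d": p.end, "height_ugL": p.height,
                "merged_with_previous": p.merged_with_previous}
               for p in pulses]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_pulse_metadata(path):
    from .synthetic import PulseMeta

    payload = json.loads(Path(path).read_text())
    return tuple(PulseMeta(p["start_d"], p["end_d"], p["height_ugL"],
                           p.get("merged_with_previous", False))
                 for p in payload)
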