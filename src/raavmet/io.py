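"""CSV readers and writers for trajectories and observed metabolite profiles.

Profile CSVs carry a unit tag per concentration column (``Gln_mM``,
``Glc_g/L``); glucose and lactate measurements reported in g/L (as
bioanalyzers commonly do) are converted to mM at load time using their
molar masses, so everything downstream works in mM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ObservedProfiles, Trajectory

__all__ = [
    "MOLAR_MASS_G_PER_MOL",
    "read_profiles",
    "write_profiles",
    "read_trajectory",
    "write_trajectory",
]

MOLAR_MASS_G_PER_MOL = {"Glc": 180.16, "Lac": 90.08}

_TIME_COL = "time_h"


def write_profiles(
    profiles: ObservedProfiles, path, units: dict[str, str] | None = None
) -> None:
    """Write observed profiles with unit-tagged headers.

    ``units`` maps species id to ``"mM"`` (default) or ``"g/L"``; values are
    converted on the way out so the file is in the declared unit.
    """
    units = units or {}
    data = {_TIME_COL: profiles.times}
    for k, sp in enumerate(profiles.species):
        unit = units.get(sp, "mM")
        col = profiles.values[:, k]
        if unit == "g/L":
            col = col * MOLAR_MASS_G_PER_MOL[sp] / 1000.0
        elif unit != "mM":
            raise ValueError(f"unsupported unit {unit!r} for {sp}")
        data[f"{sp}_{unit}"] = col
    pd.DataFrame(data).to_csv(path, index=False)


def read_profiles(path) -> ObservedProfiles:
    """Read a profile CSV, converting any g/L columns to mM."""
    df = pd.read_csv(path)
    if _TIME_COL not in df.columns:
        raise ValueError(f"profile CSV must have a {_TIME_COL!r} column")
    species, values = [], []
    for col in df.columns:
        if col == _TIME_COL:
            continue
        sp, _, unit = col.rpartition("_")
        vals = df[col].to_numpy(dtype=float)
        if unit == "g/L":
            if sp not in MOLAR_MASS_G_PER_MOL:
                raise ValueError(f"no molar mass registered for {sp!r} (g/L column)")
            vals = vals * 1000.0 / MOLAR_MASS_G_PER_MOL[sp]
        elif unit != "mM":
            raise ValueError(f"column {col!r}: unit tag must be mM or g/L")
        species.append(sp)
        values.append(vals)
    return ObservedProfiles(
        df[_TIME_COL].to_numpy(dtype=float), np.column_stack(values), species
    )


def write_trajectory(traj: Trajectory, path) -> None:
    """Full state trajectory as CSV (time_h + one mM column per state)."""
    df = pd.DataFrame(traj.states, columns=traj.state_ids)
    df.insert(0, _TIME_COL, traj.times)
    df.to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    ids = [c for c in df.columns if c != _TIME_COL]
    return Trajectory(
        df[_TIME_COL].to_numpy(dtype=float), df[ids].to_numpy(dtype=float), ids
    )
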