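"""Delimited-text I/O for calibration plates and burden tables.

Formats (UTF-8, header row, decimal point):

* calibration CSV: ``modality,cell_count,signal,replicate``
* colonies CSV:    ``mouse_id,clone_id,colony_id,diameter_mm,fluor_signal``
  (an optional ``cell_count`` column is honored if present)
* mice CSV:        ``mouse_id,clone_id,n_injected,harvest_hours``
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pandas as pd

from .burden import Colony, LiverBurden
from .calibration import CalibrationPoint, Modality


def read_calibration_points(path: str | Path) -> list[CalibrationPoint]:
    df = pd.read_csv(path)
    required = {"modality", "cell_count", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    reps = df["replicate"] if "replicate" in df.columns else [0] * len(df)
    return [
        CalibrationPoint(
            cell_count=float(c), signal=float(s), modality=Modality(m),
            replicate=int(r),
        )
        for m, c, s, r in zip(df["modality"], df["cell_count"], df["signal"], reps)
    ]


def write_calibration_points(points, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"modality": p.modality.value, "cell_count": p.cell_count,
             "signal": p.signal, "replicate": p.replicate}
            for p in points
        ]
    ).to_csv(path, index=False)


def read_burdens(
    colonies_csv: str | Path, mice_csv: str | Path
) -> dict[str, list[LiverBurden]]:
    """Read colony and mouse tables into burdens grouped by clone."""
    mice = pd.read_csv(mice_csv, float_precision="round_trip")
    colonies = pd.read_csv(colonies_csv, float_precision="round_trip")
    has_cells = "cell_count" in colonies.columns
    by_clone: dict[str, list[LiverBurden]] = defaultdict(list)
    for row in mice.itertuples(index=False):
        sub = colonies[colonies["mouse_id"] == row.mouse_id]
        if "colony_id" in sub.columns:
            sub = sub.sort_values("colony_id")
        cols = tuple(
            Colony(
                fluor_signal=float(c.fluor_signal),
                diameter_mm=None if pd.isna(c.diameter_mm) else float(c.diameter_mm),
                cell_count=(
                    None
                    if not has_cells or pd.isna(c.cell_count)
                    else float(c.cell_count)
                ),
            )
            for c in sub.itertuples(index=False)
        )
        by_clone[str(row.clone_id)].append(
            LiverBurden(
                mouse_id=str(row.mouse_id),
                clone_id=str(row.clone_id),
                n_injected=int(row.n_injected),
                harvest_time=float(row.harvest_hours),
                colonies=cols,
            )
        )
    return dict(by_clone)
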