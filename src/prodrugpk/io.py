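"""Delimited-text readers and writers for the pipeline's tables.

One flat CSV dialect throughout: comma-separated, ``.`` decimal, header
required.  Concentration-time tables use the columns

    subject_id, arm, matrix, analyte, time_h, value, units, blq_flag

with plasma values in ng/mL and tumor values in ng/g (validated on read).
Tumor-burden tables use ``time_day, burden_mean, burden_sd, n``.  Writers
prepend ``#``-prefixed provenance comment lines (seed, config hash); the
readers skip them.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    ConcentrationProfile,
    TumorGrowthSeries,
    PLASMA_UNITS,
    TUMOR_UNITS,
)

__all__ = [
    "CONCENTRATION_COLUMNS",
    "read_concentration_table",
    "write_concentration_table",
    "read_growth_table",
    "write_growth_table",
    "TableFormatError",
]

logger = logging.getLogger("prodrugpk")

CONCENTRATION_COLUMNS = (
    "subject_id",
    "arm",
    "matrix",
    "analyte",
    "time_h",
    "value",
    "units",
    "blq_flag",
)
GROWTH_COLUMNS = ("time_day", "burden_mean", "burden_sd", "n")

_EXPECTED_UNITS = {"plasma": PLASMA_UNITS, "tumor": TUMOR_UNITS}


class TableFormatError(ValueError):
    """Raised when a delimited table violates the expected schema."""


def _provenance_header(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_concentration_table(
    profiles: Iterable[ConcentrationProfile],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write profiles to one flat CSV (schema above), with provenance comments."""
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times_h, p.conc, p.blq_flags):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "arm": p.arm,
                    "matrix": p.matrix,
                    "analyte": p.analyte,
                    "time_h": t,
                    "value": c,
                    "units": p.units,
                    "blq_flag": bool(b),
                }
            )
    frame = pd.DataFrame(rows, columns=list(CONCENTRATION_COLUMNS))
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        frame.to_csv(fh, index=False)


def read_concentration_table(
    path: str | Path, lloq: float = 0.0
) -> list[ConcentrationProfile]:
    """Read a concentration-time CSV into per-subject profiles.

    Validates the schema: missing columns are reported by name, duplicate
    (subject, matrix, analyte, time) rows and mixed units within one profile
    are rejected, units must match the matrix, and out-of-order times are
    sorted with a logged warning.
    """
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in CONCENTRATION_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    dup = frame.duplicated(subset=["subject_id", "matrix", "analyte", "time_h"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise TableFormatError(
            f"{path}: duplicate row for subject_id={first['subject_id']!r} "
            f"matrix={first['matrix']!r} analyte={first['analyte']!r} "
            f"time_h={first['time_h']}"
        )
    profiles = []
    for (subject, matrix, analyte), grp in frame.groupby(
        ["subject_id", "matrix", "analyte"], sort=True
    ):
        units = grp["units"].unique()
        if units.size > 1:
            raise TableFormatError(
                f"{path}: mixed units {sorted(units)} within profile "
                f"({subject}, {matrix}, {analyte})"
            )
        expected = _EXPECTED_UNITS.get(str(matrix))
        if expected is not None and units[0] != expected:
            raise TableFormatError(
                f"{path}: units {units[0]!r} invalid for matrix {matrix!r} "
                f"(expected {expected!r})"
            )
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) < 0):
            logger.warning(
                "%s: times out of order for (%s, %s, %s); sorting",
                path,
                subject,
                matrix,
                analyte,
            )
            grp = grp.sort_values("time_h")
            times = grp["time_h"].to_numpy(dtype=float)
        arms = grp["arm"].astype(str).unique()
        profiles.append(
            ConcentrationProfile(
                subject_id=str(subject),
                matrix=str(matrix),
                analyte=str(analyte),
                times_h=times,
                conc=grp["value"].to_numpy(dtype=float),
                blq_flags=grp["blq_flag"].astype(bool).to_numpy(),
                lloq=lloq,
                units=str(units[0]),
                arm=str(arms[0]) if arms.size and arms[0] != "nan" else "",
            )
        )
    return profiles


def write_growth_table(
    series: TumorGrowthSeries | Sequence[TumorGrowthSeries],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write tumor-burden series (time_day, burden_mean, burden_sd, n [, label])."""
    if isinstance(series, TumorGrowthSeries):
        series = [series]
    rows = []
    for s in series:
        for t, m, sd in zip(s.times_day, s.burden_mean, s.burden_sd):
            rows.append(
                {
                    "time_day": t,
                    "burden_mean": m,
                    "burden_sd": sd,
                    "n": s.n,
                    "label": s.label,
                }
            )
    frame = pd.DataFrame(rows, columns=list(GROWTH_COLUMNS) + ["label"])
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        frame.to_csv(fh, index=False)


def read_growth_table(path: str | Path) -> list[TumorGrowthSeries]:
    """Read tumor-burden series grouped by label."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in GROWTH_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if "label" not in frame.columns:
        frame["label"] = ""
    frame["label"] = frame["label"].fillna("")
    out = []
    for label, grp in frame.groupby("label", sort=True):
        grp = grp.sort_values("time_day")
        out.append(
            TumorGrowthSeries(
                times_day=grp["time_day"].to_numpy(dtype=float),
                burden_mean=grp["burden_mean"].to_numpy(dtype=float),
                burden_sd=grp["burden_sd"].to_numpy(dtype=float),
                n=int(grp["n"].iloc[0]),
                label=str(label),
            )
        )
    return out
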