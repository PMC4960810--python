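"""Core data containers shared across the package.

A :class:`ConcentrationProfile` is the common currency of the toolkit: one
subject's concentration-time series in one matrix (plasma or tumor) for one
analyte (prodrug CNOB or its fluorescent product MCHB).  Non-compartmental
analysis consumes it, the two-compartment simulator produces it, and the
calibration module converts imaging photon counts into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConcentrationProfile",
    "ImagingSeries",
    "TumorGrowthSeries",
    "PLASMA_UNITS",
    "TUMOR_UNITS",
]

PLASMA_UNITS = "ng/mL"
TUMOR_UNITS = "ng/g"

_VALID_MATRICES = {"plasma", "tumor"}


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject/matrix/analyte concentration-time series.

    Parameters
    ----------
    subject_id : str
        Subject label.
    matrix : {"plasma", "tumor"}
        Sampled matrix; plasma concentrations are ng/mL, tumor ng/g tissue.
        No density conversion between the two is attempted.
    analyte : str
        Measured species, e.g. ``"CNOB"`` or ``"MCHB"``.
    times_h : array-like
        Sampling times in hours, strictly increasing, all >= 0.
    conc : array-like
        Concentrations, same length as ``times_h``, all >= 0.
    blq_flags : array-like of bool, optional
        Per-point below-limit-of-quantification flags.  If omitted, points
        with ``conc < lloq`` are flagged (none when ``lloq == 0``).
    lloq : float
        Lower limit of quantification in concentration units.
    units : str
        Concentration unit label, validated against the matrix.
    """

    subject_id: str
    matrix: str
    analyte: str
    times_h: np.ndarray
    conc: np.ndarray
    blq_flags: np.ndarray | None = None
    lloq: float = 0.0
    units: str = ""
    arm: str = ""

    def __post_init__(self) -> None:
        if self.matrix not in _VALID_MATRICES:
            raise ValueError(
                f"matrix must be one of {sorted(_VALID_MATRICES)}, got {self.matrix!r}"
            )
        times = _as_float_array(self.times_h, "times_h")
        conc = _as_float_array(self.conc, "conc")
        if times.size != conc.size:
            raise ValueError(
                f"times_h (n={times.size}) and conc (n={conc.size}) differ in length"
            )
        if times.size and times[0] < 0:
            raise ValueError("times_h must be non-negative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.lloq < 0:
            raise ValueError("lloq must be non-negative")
        units = self.units or (PLASMA_UNITS if self.matrix == "plasma" else TUMOR_UNITS)
        if self.blq_flags is None:
            flags = conc < self.lloq
        else:
            flags = np.asarray(self.blq_flags, dtype=bool)
            if flags.size != conc.size:
                raise ValueError("blq_flags length differs from conc")
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "blq_flags", flags)
        object.__setattr__(self, "units", units)

    def __len__(self) -> int:
        return self.times_h.size

    @property
    def quantifiable(self) -> np.ndarray:
        """Boolean mask of points at or above the LLOQ."""
        return ~self.blq_flags

    def with_values(self, **kwargs) -> "ConcentrationProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def plot(self, ax=None, **kwargs):
        """Plot concentration vs time (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times_h, self.conc, marker="o", **kwargs)
        ax.set_xlabel("time (h)")
        ax.set_ylabel(f"{self.analyte} ({self.units})")
        ax.set_title(f"{self.subject_id} {self.matrix}")
        return ax


@dataclass(frozen=True)
class ImagingSeries:
    """ROI photon-flux time series from live-animal fluorescence imaging."""

    times_h: np.ndarray
    counts_per_s: np.ndarray
    background_counts_per_s: float = 0.0
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        times = _as_float_array(self.times_h, "times_h")
        counts = _as_float_array(self.counts_per_s, "counts_per_s")
        if times.size != counts.size:
            raise ValueError("times_h and counts_per_s differ in length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times_h must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.background_counts_per_s < 0:
            raise ValueError("background must be non-negative")
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "counts_per_s", counts)

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class TumorGrowthSeries:
    """Tumor-burden time course with per-time-point dispersion.

    ``burden_mean``/``burden_sd`` are mm^3 caliper volumes summarised over
    ``n`` subjects per point (sd = 0 and n = 1 for a deterministic curve).
    """

    times_day: np.ndarray
    burden_mean: np.ndarray
    burden_sd: np.ndarray = field(default=None)  # type: ignore[assignment]
    n: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        times = _as_float_array(self.times_day, "times_day")
        mean = _as_float_array(self.burden_mean, "burden_mean")
        sd = (
            np.zeros_like(mean)
            if self.burden_sd is None
            else _as_float_array(self.burden_sd, "burden_sd")
        )
        if not (times.size == mean.size == sd.size):
            raise ValueError("times_day, burden_mean, burden_sd differ in length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times_day must be strictly increasing")
        if np.any(mean < 0) or np.any(sd < 0):
            raise ValueError("burden mean and sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        object.__setattr__(self, "times_day", times)
        object.__setattr__(self, "burden_mean", mean)
        object.__setattr__(self, "burden_sd", sd)

    def __len__(self) -> int:
        return self.times_day.size

    def plot(self, ax=None, **kwargs):
        """Plot mean burden with SD error bars (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            self.times_day, self.burden_mean, yerr=self.burden_sd, marker="o", **kwargs
        )
        ax.set_xlabel("time (day)")
        ax.set_ylabel("tumor burden (mm$^3$)")
        if self.label:
            ax.set_title(self.label)
        return ax
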