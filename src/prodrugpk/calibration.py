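"""Fluorescence standard-curve calibration.

The imaged drug product is natively fluorescent and its ROI photon flux is
linear in concentration over the calibrated range, so quantification reduces
to an ordinary least-squares line through in-vitro standards,

    counts_per_s = slope * concentration + intercept,

and inversion of that line (after background subtraction) for in-vivo series.
A weighted fit is available but the unweighted linear-scale fit is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .profiles import ConcentrationProfile, ImagingSeries

__all__ = [
    "StandardCurve",
    "StandardCurveModel",
    "fit_standard_curve",
    "counts_to_concentration",
    "molar_to_mass_concentration",
    "mass_to_molar_concentration",
    "PAPER_STANDARD_CONCENTRATIONS_UM",
]

# in-vitro standard concentrations used by the study design this emulates (uM)
PAPER_STANDARD_CONCENTRATIONS_UM = (0.0, 1.5, 15.0, 150.0, 1500.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear photon-flux-vs-concentration standard curve.

    Retains the standards used for the fit for audit.  ``slope`` is
    counts/s per concentration unit, ``intercept`` counts/s.
    """

    slope: float
    intercept: float
    r_squared: float
    conc_unit: str = "uM"
    standards: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("a valid standard curve has positive slope")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def predict_counts(self, conc) -> np.ndarray:
        """Expected counts/s at the given concentrations."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def invert(self, counts, background: float = 0.0) -> np.ndarray:
        """Concentration from counts/s; negative solutions clamp to zero."""
        counts = np.asarray(counts, dtype=float)
        return np.clip((counts - background - self.intercept) / self.slope, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "conc_unit": self.conc_unit,
            "standards": [list(p) for p in self.standards],
        }

    def summary(self) -> str:
        return (
            "Standard curve: counts/s = "
            f"{self.slope:.6g} * conc[{self.conc_unit}] + {self.intercept:.6g}"
            f"  (R^2 = {self.r_squared:.6f}, n = {len(self.standards)})"
        )


class StandardCurveModel:
    """OLS/WLS model for a photon-flux standard curve.

    Parameters
    ----------
    concentrations, counts : array-like
        Paired standards; at least two distinct concentrations required.
    weights : array-like, optional
        Per-standard weights for a weighted fit (default unweighted).
    conc_unit : str
        Label for the concentration axis (default micromolar).
    """

    def __init__(self, concentrations, counts, weights=None, conc_unit: str = "uM"):
        conc = np.asarray(concentrations, dtype=float)
        cnt = np.asarray(counts, dtype=float)
        if conc.size != cnt.size:
            raise ValueError("concentrations and counts differ in length")
        if conc.size < 2:
            raise ValueError("need at least 2 standards")
        if not np.all(np.isfinite(conc)) or not np.all(np.isfinite(cnt)):
            raise ValueError("standards must be finite")
        if np.unique(conc).size < 2:
            raise ValueError(
                "degenerate design: all standard concentrations identical"
            )
        self.conc = conc
        self.counts = cnt
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.conc_unit = conc_unit

    def fit(self) -> StandardCurve:
        X = sm.add_constant(self.conc)
        if self.weights is None:
            res = sm.OLS(self.counts, X).fit()
        else:
            res = sm.WLS(self.counts, X, weights=self.weights).fit()
        intercept, slope = res.params
        # rsquared can dip infinitesimally outside [0,1] on exact data
        r2 = float(min(max(res.rsquared, 0.0), 1.0))
        return StandardCurve(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
            conc_unit=self.conc_unit,
            standards=tuple(zip(self.conc.tolist(), self.counts.tolist())),
        )


def fit_standard_curve(concentrations, counts, **kwargs) -> StandardCurve:
    """Functional shortcut for ``StandardCurveModel(...).fit()``."""
    return StandardCurveModel(concentrations, counts, **kwargs).fit()


def counts_to_concentration(
    series: ImagingSeries,
    curve: StandardCurve,
    subject_id: str = "imaging",
    matrix: str = "tumor",
    analyte: str = "MCHB",
) -> ConcentrationProfile:
    """Convert an ROI photon-flux series to a concentration profile.

    conc = max(0, (counts - background - intercept) / slope); the per-series
    scalar background is subtracted before inversion (baseline flux is
    treated as constant over time).  Points clamped at zero are flagged BLQ.
    """
    conc = curve.invert(series.counts_per_s, background=series.background_counts_per_s)
    raw = (
        series.counts_per_s - series.background_counts_per_s - curve.intercept
    ) / curve.slope
    clamped = raw < 0
    return ConcentrationProfile(
        subject_id=subject_id,
        matrix=matrix,
        analyte=analyte,
        times_h=series.times_h,
        conc=conc,
        blq_flags=clamped,
        units=curve.conc_unit,
    )


def molar_to_mass_concentration(conc_um: float, molar_mass_g_mol: float) -> float:
    """Convert micromolar to ng/mL: 1 uM = M ng/mL for molar mass M g/mol.

    (1 umol/L = M ug/L = M ng/mL.)  Molar mass must be supplied explicitly;
    there is no built-in constant for any particular compound.
    """
    if molar_mass_g_mol is None:
        raise ValueError("molar mass required for molar-to-mass conversion")
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    return np.asarray(conc_um, dtype=float) * molar_mass_g_mol


def mass_to_molar_concentration(conc_ng_ml: float, molar_mass_g_mol: float) -> float:
    """Inverse of :func:`molar_to_mass_concentration`."""
    if molar_mass_g_mol is None or molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    return np.asarray(conc_ng_ml, dtype=float) / molar_mass_g_mol
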