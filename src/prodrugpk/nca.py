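"""Non-compartmental pharmacokinetic analysis (NCA).

Model-free estimation of exposure and disposition parameters from a single
concentration-time profile after an IV bolus: Cmax/Tmax, trapezoidal AUC,
terminal-slope (lambda_z) regression with automatic point selection, AUC and
AUMC extrapolation to infinity, clearance, volumes of distribution (Vz and
Vss), mean residence time and terminal half-life.

Usage follows the Model/Results idiom::

    model = NCA(profile, dose_mg_per_kg=3.3)
    res = model.fit()
    print(res.summary())

Conventions
-----------
* Default AUC method is the linear trapezoid; ``linuplogdown`` (linear up,
  logarithmic down) is available and the method used is recorded.
* lambda_z auto-selection maximises adjusted R^2 over candidate sets formed
  by the last k quantifiable points (k = 3 ... all post-Tmax points,
  excluding Tmax itself); ties break toward more points.
* AUC_0-inf extrapolates from the observed (not regression-predicted) last
  quantifiable concentration.
* AUC_0-t integrates from the first sample; no back-extrapolation to t = 0.
* Unit bookkeeping: dose in mg/kg over AUC in h*ng/mL yields CL in L/h/kg via
  the exact factor 1e6 ng/mg / 1e6 mL/L = 1 -> CL [L/h/kg] = 1000 * dose /
  AUC (the residual 1e3 arises from mL vs L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .profiles import ConcentrationProfile

__all__ = [
    "NCA",
    "NCAResults",
    "LambdaZFit",
    "auc_trapezoid",
    "aumc_trapezoid",
    "fit_lambda_z",
    "handle_blq",
    "run_nca",
    "clearance_from_auc",
    "NoValidTerminalFit",
    "InsufficientDataError",
]

LN2 = math.log(2.0)

# mg/kg divided by h*ng/mL: 1e6 ng/mg over 1e6 mL/L cancels; the factor 1e3
# converts the mL in the denominator unit to L.
DOSE_OVER_AUC_TO_L_PER_H_KG = 1.0e3


class InsufficientDataError(ValueError):
    """Raised when a profile has too few points for the requested operation."""


class NoValidTerminalFit(ValueError):
    """Raised when no candidate terminal point set yields a declining phase."""


def clearance_from_auc(dose_mg_per_kg: float, auc_h_ng_ml: float) -> float:
    """CL (L/h/kg) from an IV dose (mg/kg) and an AUC (h*ng/mL), exact units."""
    if dose_mg_per_kg <= 0:
        raise ValueError("dose must be positive")
    if auc_h_ng_ml <= 0:
        raise ValueError("AUC must be positive")
    return DOSE_OVER_AUC_TO_L_PER_H_KG * dose_mg_per_kg / auc_h_ng_ml


def _interp_conc(t: np.ndarray, c: np.ndarray, x: float) -> float:
    return float(np.interp(x, t, c))


def _segment_auc(t1, c1, t2, c2, method: str) -> float:
    dt = t2 - t1
    if method == "linuplogdown" and c2 < c1 and c1 > 0 and c2 > 0:
        return dt * (c1 - c2) / math.log(c1 / c2)
    return 0.5 * dt * (c1 + c2)


def auc_trapezoid(
    profile: ConcentrationProfile,
    t_start: float | None = None,
    t_end: float | None = None,
    method: str = "linear",
) -> float:
    """Trapezoidal AUC of a profile over [t_start, t_end].

    ``method="linear"`` (default) uses the linear trapezoid on every segment;
    ``"linuplogdown"`` uses the logarithmic trapezoid on strictly declining
    positive segments.  Endpoints inside a sampling interval are obtained by
    linear interpolation.  The result is additive over adjacent windows split
    at any interior sample point.
    """
    if method not in ("linear", "linuplogdown"):
        raise ValueError(f"unknown AUC method {method!r}")
    t, c = profile.times_h, profile.conc
    if t.size < 2:
        raise InsufficientDataError("AUC needs at least 2 points")
    t_start = float(t[0]) if t_start is None else float(t_start)
    t_end = float(t[-1]) if t_end is None else float(t_end)
    if t_end <= t_start:
        raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError(
            f"[{t_start}, {t_end}] outside observed range [{t[0]}, {t[-1]}]"
        )
    # knots: window endpoints plus interior sample times
    inner = t[(t > t_start) & (t < t_end)]
    knots = np.concatenate(([t_start], inner, [t_end]))
    vals = np.array([_interp_conc(t, c, x) for x in knots])
    total = 0.0
    for i in range(knots.size - 1):
        total += _segment_auc(knots[i], vals[i], knots[i + 1], vals[i + 1], method)
    return total


def aumc_trapezoid(
    profile: ConcentrationProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Linear-trapezoid area under the first-moment curve t*C(t)."""
    moment = profile.with_values(conc=profile.times_h * profile.conc)
    return auc_trapezoid(moment, t_start, t_end, method="linear")


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result.

    ``lambda_z`` is the terminal elimination rate constant (1/h) from OLS of
    ln C on t over the selected points; ``intercept_log`` the fitted ln C at
    t = 0; ``r2_adjusted`` the adjusted coefficient of determination.
    """

    lambda_z: float
    n_points: int
    t_first_used: float
    r2_adjusted: float
    intercept_log: float

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z


def _loglinear_fit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """OLS slope/intercept of logc on t plus adjusted R^2."""
    n = t.size
    tbar, ybar = t.mean(), logc.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (logc - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    ss_res = float(np.sum((logc - intercept - slope * t) ** 2))
    ss_tot = float(np.sum((logc - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2_adj


def fit_lambda_z(
    profile: ConcentrationProfile,
    selection: str | Iterable[int] = "auto",
) -> LambdaZFit:
    """Estimate the terminal elimination rate constant lambda_z.

    ``selection="auto"`` evaluates every candidate set formed by the last k
    quantifiable points with positive concentration (k = 3 up to all points
    strictly after Tmax, Tmax itself excluded) and keeps the set with maximal
    adjusted R^2, breaking ties toward more points.  An explicit iterable of
    point indices (into the profile) bypasses the search.

    Raises :class:`NoValidTerminalFit` if every candidate has a non-negative
    slope (rising terminal phase) and :class:`InsufficientDataError` with
    fewer than 3 usable points.
    """
    t, c = profile.times_h, profile.conc
    usable = profile.quantifiable & (c > 0)

    if selection != "auto":
        idx = np.asarray(list(selection), dtype=int)
        if idx.size < 3:
            raise InsufficientDataError("lambda_z needs >= 3 points")
        slope, intercept, r2_adj = _loglinear_fit(t[idx], np.log(c[idx]))
        if slope >= 0:
            raise NoValidTerminalFit("terminal phase is not declining")
        return LambdaZFit(
            lambda_z=-slope,
            n_points=idx.size,
            t_first_used=float(t[idx].min()),
            r2_adjusted=r2_adj,
            intercept_log=intercept,
        )

    i_max = int(np.argmax(np.where(usable, c, -np.inf)))
    post = np.flatnonzero(usable & (np.arange(t.size) > i_max))
    if post.size < 3:
        raise InsufficientDataError(
            f"lambda_z needs >= 3 quantifiable post-Tmax points, have {post.size}"
        )
    best: LambdaZFit | None = None
    # iterate k from 3 upward so that on a tie the larger set (later) wins
    for k in range(3, post.size + 1):
        idx = post[-k:]
        slope, intercept, r2_adj = _loglinear_fit(t[idx], np.log(c[idx]))
        if slope >= 0:
            continue
        cand = LambdaZFit(
            lambda_z=-slope,
            n_points=k,
            t_first_used=float(t[idx[0]]),
            r2_adjusted=r2_adj,
            intercept_log=intercept,
        )
        if best is None or cand.r2_adjusted >= best.r2_adjusted - 1e-12:
            best = cand
    if best is None:
        raise NoValidTerminalFit("no candidate terminal set has a declining slope")
    return best


def handle_blq(
    profile: ConcentrationProfile,
    policy: str = "drop_after_first_terminal_blq",
) -> ConcentrationProfile:
    """Apply a below-limit-of-quantification policy to a profile.

    Both policies set pre-Tmax BLQ values to zero (absorption/formation has
    not yet raised the signal above the limit) and exclude BLQ points at or
    after Tmax, so the last quantifiable point defines t_last for AUC and the
    terminal fit.  ``policy`` is recorded for audit on the returned profile's
    ``blq_policy`` attribute.
    """
    if policy not in ("drop_after_first_terminal_blq", "zero_before_tmax"):
        raise ValueError(f"unknown BLQ policy {policy!r}")
    flags = profile.blq_flags
    if not flags.any():
        out = profile
    else:
        quant = ~flags
        if not quant.any():
            raise InsufficientDataError("all points are below the quantification limit")
        c = profile.conc.copy()
        i_max = int(np.argmax(np.where(quant, c, -np.inf)))
        keep = np.ones(c.size, dtype=bool)
        for i in range(c.size):
            if flags[i]:
                if i < i_max:
                    c[i] = 0.0
                else:
                    keep[i] = False
        out = ConcentrationProfile(
            subject_id=profile.subject_id,
            matrix=profile.matrix,
            analyte=profile.analyte,
            times_h=profile.times_h[keep],
            conc=c[keep],
            blq_flags=np.zeros(int(keep.sum()), dtype=bool),
            lloq=profile.lloq,
            units=profile.units,
            arm=profile.arm,
        )
    object.__setattr__(out, "blq_policy", policy)
    return out


@dataclass(frozen=True)
class NCAResults:
    """Full non-compartmental parameter set for one profile.

    Extrapolation-dependent fields (``auc_0_inf`` onward) are ``nan`` when no
    valid terminal fit exists; ``lambda_fit`` is then ``None``.
    Clearance/volume fields are ``nan`` when no dose was supplied (e.g. tumor
    exposure profiles, where only AUC is meaningful).
    """

    subject_id: str
    matrix: str
    analyte: str
    dose_mg_per_kg: float | None
    c_max: float
    t_max: float
    auc_0_t: float
    t_last: float
    auc_method: str
    auc_0_inf: float = math.nan
    aumc_0_inf: float = math.nan
    cl: float = math.nan
    v_z: float = math.nan
    v_ss: float = math.nan
    mrt: float = math.nan
    t_half: float = math.nan
    pct_extrapolated: float = math.nan
    lambda_fit: LambdaZFit | None = None
    blq_policy: str | None = None

    @property
    def lambda_z(self) -> float:
        return self.lambda_fit.lambda_z if self.lambda_fit else math.nan

    def to_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "matrix": self.matrix,
            "analyte": self.analyte,
            "dose_mg_per_kg": self.dose_mg_per_kg,
            "c_max": self.c_max,
            "t_max": self.t_max,
            "t_last": self.t_last,
            "auc_0_t": self.auc_0_t,
            "auc_0_inf": self.auc_0_inf,
            "aumc_0_inf": self.aumc_0_inf,
            "lambda_z": self.lambda_z,
            "t_half": self.t_half,
            "cl": self.cl,
            "v_z": self.v_z,
            "v_ss": self.v_ss,
            "mrt": self.mrt,
            "pct_extrapolated": self.pct_extrapolated,
            "auc_method": self.auc_method,
        }
        if self.lambda_fit is not None:
            d["lambda_n_points"] = self.lambda_fit.n_points
            d["lambda_r2_adjusted"] = self.lambda_fit.r2_adjusted
        return d

    def summary(self) -> str:
        rows = [
            ("Cmax", self.c_max, ""),
            ("Tmax", self.t_max, "h"),
            ("AUC_0-t", self.auc_0_t, "h*conc"),
            ("AUC_0-inf", self.auc_0_inf, "h*conc"),
            ("lambda_z", self.lambda_z, "1/h"),
            ("t_1/2", self.t_half, "h"),
            ("CL", self.cl, "L/h/kg"),
            ("Vz", self.v_z, "L/kg"),
            ("Vss", self.v_ss, "L/kg"),
            ("MRT", self.mrt, "h"),
            ("%AUC extrapolated", self.pct_extrapolated, "%"),
        ]
        head = (
            f"Non-compartmental analysis: subject={self.subject_id} "
            f"matrix={self.matrix} analyte={self.analyte}\n"
            f"dose={self.dose_mg_per_kg} mg/kg, AUC method={self.auc_method}\n"
        )
        body = "\n".join(f"{name:>20s}  {val:12.5g} {unit}" for name, val, unit in rows)
        return head + body


class NCA:
    """Non-compartmental analysis model for a single IV-bolus profile.

    Parameters
    ----------
    profile : ConcentrationProfile
        Observed concentrations.  BLQ flags, if any, are resolved with
        ``blq_policy`` before analysis.
    dose_mg_per_kg : float, optional
        IV bolus dose; omit for exposure-only (AUC/Cmax) analysis.
    auc_method : {"linear", "linuplogdown"}
    lambda_selection : "auto" or iterable of point indices
    """

    def __init__(
        self,
        profile: ConcentrationProfile,
        dose_mg_per_kg: float | None = None,
        auc_method: str = "linear",
        lambda_selection: str | Sequence[int] = "auto",
        blq_policy: str = "drop_after_first_terminal_blq",
    ) -> None:
        if dose_mg_per_kg is not None and dose_mg_per_kg <= 0:
            raise ValueError("dose must be positive")
        self.raw_profile = profile
        self.dose_mg_per_kg = dose_mg_per_kg
        self.auc_method = auc_method
        self.lambda_selection = lambda_selection
        self.blq_policy = blq_policy
        self.profile = handle_blq(profile, blq_policy)

    def fit(self) -> NCAResults:
        prof = self.profile
        t, c = prof.times_h, prof.conc
        if t.size < 2:
            raise InsufficientDataError("NCA needs at least 2 quantifiable points")
        i_max = int(np.argmax(c))
        c_max = float(c[i_max])
        t_max = float(t[i_max])
        if c_max <= 0:
            raise InsufficientDataError("profile has no quantifiable Cmax")
        t_last = float(t[-1])
        auc_0_t = auc_trapezoid(prof, method=self.auc_method)
        base = dict(
            subject_id=prof.subject_id,
            matrix=prof.matrix,
            analyte=prof.analyte,
            dose_mg_per_kg=self.dose_mg_per_kg,
            c_max=c_max,
            t_max=t_max,
            auc_0_t=auc_0_t,
            t_last=t_last,
            auc_method=self.auc_method,
            blq_policy=self.blq_policy,
        )
        try:
            lam = fit_lambda_z(prof, self.lambda_selection)
        except (NoValidTerminalFit, InsufficientDataError):
            return NCAResults(**base)

        c_last = float(c[-1])
        auc_extra = c_last / lam.lambda_z
        auc_inf = auc_0_t + auc_extra
        aumc_0_t = aumc_trapezoid(prof)
        aumc_inf = aumc_0_t + c_last * t_last / lam.lambda_z + c_last / lam.lambda_z**2
        mrt = aumc_inf / auc_inf
        t_half = LN2 / lam.lambda_z
        pct_extrap = 100.0 * auc_extra / auc_inf
        cl = v_z = v_ss = math.nan
        if self.dose_mg_per_kg is not None and prof.matrix == "plasma":
            cl = clearance_from_auc(self.dose_mg_per_kg, auc_inf)
            v_z = cl / lam.lambda_z
            v_ss = cl * mrt
        return NCAResults(
            **base,
            auc_0_inf=auc_inf,
            aumc_0_inf=aumc_inf,
            cl=cl,
            v_z=v_z,
            v_ss=v_ss,
            mrt=mrt,
            t_half=t_half,
            pct_extrapolated=pct_extrap,
            lambda_fit=lam,
        )


def run_nca(
    profile: ConcentrationProfile,
    dose_mg_per_kg: float | None = None,
    **kwargs,
) -> NCAResults:
    """Functional shortcut for ``NCA(profile, dose).fit()``."""
    return NCA(profile, dose_mg_per_kg, **kwargs).fit()
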