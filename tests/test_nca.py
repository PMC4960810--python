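import numpy as np
import pytest
from hypothesis import given, strategies as st

import prodrugpk as pp
from prodrugpk.nca import (
    InsufficientDataError,
    NoValidTerminalFit,
    aumc_trapezoid,
)
from prodrugpk.synthetic import PAPER_SAMPLING_TIMES_H


def make_profile(times, conc, **kw):
    return pp.ConcentrationProfile(
        subject_id="s1", matrix="plasma", analyte="CNOB",
        times_h=np.asarray(times, float), conc=np.asarray(conc, float), **kw
    )


# ---------------------------------------------------------------- AUC ------

def test_auc_rectangle():
    prof = make_profile([0, 12, 24], [10, 10, 10])
    assert pp.auc_trapezoid(prof, 0, 24) == pytest.approx(240.0, rel=1e-14)


def test_auc_triangle():
    prof = make_profile([0, 1], [0, 100])
    assert pp.auc_trapezoid(prof) == pytest.approx(50.0, rel=1e-14)


def test_auc_against_dense_piecewise_oracle():
    """Linear trapezoid over the nine-point design must equal a brute-force
    high-resolution integral of the piecewise-linear interpolant."""
    t = np.array(PAPER_SAMPLING_TIMES_H)
    c = 100.0 * np.exp(-0.15 * t)
    prof = make_profile(t, c)
    value = pp.auc_trapezoid(prof, t[0], 24.0)
    fine = np.linspace(t[0], 24.0, 400_001)
    oracle = np.trapezoid(np.interp(fine, t, c), fine)
    assert value == pytest.approx(oracle, rel=1e-8)


def test_auc_linuplogdown_exact_for_exponential_segment():
    """The log trapezoid integrates a mono-exponential decline exactly."""
    lam = 0.3
    t = np.array([2.0, 5.0])
    c = 80.0 * np.exp(-lam * t)
    prof = make_profile(t, c)
    exact = (c[0] - c[1]) / lam
    assert pp.auc_trapezoid(prof, method="linuplogdown") == pytest.approx(exact, rel=1e-12)
    # and the linear rule overestimates a convex decline
    assert pp.auc_trapezoid(prof, method="linear") > exact


@given(
    data=st.lists(
        st.floats(min_value=0.0, max_value=500.0), min_size=4, max_size=12
    ),
    cut=st.integers(min_value=1, max_value=10),
)
def test_auc_additivity_at_interior_sample(data, cut):
    times = np.arange(len(data), dtype=float)
    prof = make_profile(times, data)
    cut = min(cut, len(data) - 2)
    t_mid = float(times[cut])
    whole = pp.auc_trapezoid(prof, times[0], times[-1])
    parts = pp.auc_trapezoid(prof, times[0], t_mid) + pp.auc_trapezoid(
        prof, t_mid, times[-1]
    )
    assert whole == pytest.approx(parts, rel=1e-12, abs=1e-12)


@given(
    base=st.lists(st.floats(min_value=0.0, max_value=300.0), min_size=3, max_size=9),
    bump=st.floats(min_value=0.0, max_value=50.0),
)
def test_auc_monotone_in_concentrations(base, bump):
    times = np.arange(len(base), dtype=float)
    lo = make_profile(times, base)
    hi = make_profile(times, np.asarray(base) + bump)
    assert pp.auc_trapezoid(hi) >= pp.auc_trapezoid(lo)


def test_auc_window_validation():
    prof = make_profile([0, 1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        pp.auc_trapezoid(prof, 2, 1)
    with pytest.raises(ValueError):
        pp.auc_trapezoid(prof, 0, 5)
    with pytest.raises(InsufficientDataError):
        pp.auc_trapezoid(make_profile([0], [1]))


# ------------------------------------------------------------ lambda_z ----

def test_lambda_z_exact_on_monoexponential():
    lam = 0.21
    t = np.linspace(0, 20, 8)
    prof = make_profile(t, 50 * np.exp(-lam * t))
    fit = pp.fit_lambda_z(prof)
    assert fit.lambda_z == pytest.approx(lam, rel=1e-10)
    assert fit.r2_adjusted == pytest.approx(1.0, abs=1e-10)
    assert fit.t_half == pytest.approx(np.log(2) / lam, rel=1e-10)


def _brute_force_lambda(times, conc):
    """Independent enumeration of last-k candidate sets (k >= 3, Tmax excluded),
    max adjusted R^2, ties toward more points."""
    i_max = int(np.argmax(conc))
    idx_post = [i for i in range(len(times)) if i > i_max and conc[i] > 0]
    best = None
    for k in range(3, len(idx_post) + 1):
        sel = idx_post[-k:]
        x = np.asarray([times[i] for i in sel])
        y = np.log([conc[i] for i in sel])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        yhat = slope * x + intercept
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot
        r2a = 1 - (1 - r2) * (k - 1) / (k - 2)
        if best is None or r2a >= best[1] - 1e-12:
            best = (-slope, r2a, k)
    return best


def test_lambda_z_auto_selection_matches_exhaustive_oracle():
    """On a noise-free bi-exponential with separated phases the auto rule must
    agree with brute-force candidate enumeration and sit within 1% of the
    slow exponent."""
    t = np.array([0.25, 0.5, 1, 2, 4, 6, 9, 12, 18, 24, 36, 48], float)
    c = 120 * np.exp(-1.8 * t) + 15 * np.exp(-0.11 * t)
    prof = make_profile(t, c)
    fit = pp.fit_lambda_z(prof)
    lam_bf, r2a_bf, k_bf = _brute_force_lambda(t, c)
    assert fit.lambda_z == pytest.approx(lam_bf, rel=1e-12)
    assert fit.n_points == k_bf
    assert fit.lambda_z == pytest.approx(0.11, rel=0.01)


def test_lambda_z_explicit_selection():
    t = np.array([0.0, 1, 2, 4, 8, 12], float)
    c = 100 * np.exp(-0.2 * t)
    fit = pp.fit_lambda_z(make_profile(t, c), selection=[3, 4, 5])
    assert fit.n_points == 3
    assert fit.lambda_z == pytest.approx(0.2, rel=1e-10)


def test_lambda_z_failures():
    rising = make_profile([0, 1, 2, 3, 4], [5, 1, 2, 3, 4])
    with pytest.raises(NoValidTerminalFit):
        pp.fit_lambda_z(rising)
    short = make_profile([0, 1, 2], [5, 4, 3])
    with pytest.raises(InsufficientDataError):
        pp.fit_lambda_z(short)  # only 2 post-Tmax points


# ------------------------------------------------------------- run_nca ----

def test_run_nca_recovers_generating_two_compartment_model(pk_default):
    """Dense noise-free sampling to ~5 terminal half-lives recovers CL, Vss
    and t1/2 of the generating model (AUC_inf = Dose/CL analytically)."""
    times = np.concatenate([[0.0], np.geomspace(0.01, 24.0, 600)])
    prof = pp.simulate_2cmt_bolus(pk_default, pp.DoseRegimen.single(3.3), times)
    res = pp.run_nca(prof, 3.3)
    mc = pp.macro_constants(pk_default)
    assert res.cl == pytest.approx(pk_default.cl, rel=0.02)
    assert res.v_ss == pytest.approx(pk_default.vss, rel=0.05)
    assert res.t_half == pytest.approx(np.log(2) / mc.beta, rel=0.02)
    assert res.auc_0_inf >= res.auc_0_t > 0
    assert 0 <= res.pct_extrapolated < 100


def test_run_nca_internal_identities(mono_profile_factory, paper_times):
    res = pp.run_nca(mono_profile_factory(100.0, 4.6, paper_times), 3.3)
    assert res.t_half * res.lambda_z == pytest.approx(np.log(2), rel=1e-12)
    assert res.cl * res.auc_0_inf == pytest.approx(1000.0 * 3.3, rel=1e-12)
    assert res.v_z == pytest.approx(res.cl / res.lambda_z, rel=1e-12)
    assert res.v_ss == pytest.approx(res.cl * res.mrt, rel=1e-12)


def test_run_nca_cmax_at_interior_maximum():
    t = np.array([0, 0.5, 1, 2, 4, 8], float)
    c = np.array([0, 40, 90, 60, 20, 5], float)
    res = pp.run_nca(make_profile(t, c))
    assert res.c_max == 90.0 and res.t_max == 1.0


@given(scale=st.floats(min_value=0.1, max_value=50))
def test_dose_proportionality(scale):
    """Scaling concentrations scales AUC and Cmax and leaves t1/2 unchanged."""
    t = np.array([0.25, 0.5, 1, 2, 4, 6, 12, 24], float)
    c = 120 * np.exp(-1.8 * t) + 15 * np.exp(-0.11 * t)
    base = pp.run_nca(make_profile(t, c))
    scaled = pp.run_nca(make_profile(t, scale * c))
    assert scaled.auc_0_t == pytest.approx(scale * base.auc_0_t, rel=1e-9)
    assert scaled.c_max == pytest.approx(scale * base.c_max, rel=1e-12)
    assert scaled.t_half == pytest.approx(base.t_half, rel=1e-9)


def test_run_nca_without_terminal_fit_returns_auc_only():
    prof = make_profile([0, 1, 2, 3], [1, 2, 3, 4])  # rising: no lambda_z
    res = pp.run_nca(prof, 3.3)
    assert res.auc_0_t > 0
    assert np.isnan(res.auc_0_inf) and np.isnan(res.cl)
    assert res.lambda_fit is None


# ----------------------------------------------------------------- BLQ ----

def test_handle_blq_identity_without_flags():
    prof = make_profile([0, 1, 2], [3, 2, 1])
    out = pp.handle_blq(prof)
    np.testing.assert_array_equal(out.conc, prof.conc)
    assert out.blq_policy == "drop_after_first_terminal_blq"


def test_handle_blq_24h_point_excluded(paper_times):
    """When the 24-h sample is below the quantification limit, t_last becomes
    12 h and the 24-h point leaves the terminal fit and the AUC."""
    c = 100 * np.exp(-0.3 * paper_times)
    lloq = c[-1] * 1.5  # only the 24-h point is BLQ
    prof = make_profile(paper_times, c, lloq=lloq)
    assert prof.blq_flags[-1] and not prof.blq_flags[:-1].any()
    res = pp.run_nca(prof, 3.3)
    assert res.t_last == 12.0
    assert res.auc_0_t == pytest.approx(
        np.trapezoid(c[:-1], paper_times[:-1]), rel=1e-12
    )


def test_handle_blq_pre_tmax_zeroed_and_trailing_excluded():
    t = np.arange(8, dtype=float)
    c = np.array([0.4, 5, 9, 6, 3, 2, 0.5, 0.5])
    prof = make_profile(t, c, lloq=1.0)
    out = pp.handle_blq(prof)
    assert out.conc[0] == 0.0  # pre-Tmax BLQ set to zero
    assert len(out) == 6  # two trailing BLQ points dropped
    manual = np.trapezoid(np.concatenate([[0.0], c[1:6]]), t[:6])
    assert pp.auc_trapezoid(out) == pytest.approx(manual, rel=1e-12)


def test_handle_blq_all_blq_rejected():
    prof = make_profile([0, 1, 2], [0.1, 0.1, 0.1], lloq=1.0)
    with pytest.raises(InsufficientDataError):
        pp.handle_blq(prof)


def test_aumc_is_first_moment_area():
    t = np.array([0.0, 1.0, 2.0])
    c = np.array([10.0, 10.0, 10.0])
    # t*C is a straight line 10t: integral over [0,2] = 20
    assert aumc_trapezoid(make_profile(t, c)) == pytest.approx(20.0, rel=1e-14)
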