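import numpy as np
import pytest

import prodrugpk as pp
from prodrugpk.synthetic import PAPER_SAMPLING_TIMES_H

NO_NOISE = pp.NoiseSpec(conc_cv=0.0, count_cv=0.0, burden_cv=0.0, lloq=0.0)


def default_design(**kw):
    base = dict(dose_mg_per_kg=3.3, n_subjects=4, seed=11)
    base.update(kw)
    return pp.StudyDesign(**base)


# -------------------------------------------------------------- plasma ----

def test_zero_noise_plasma_equals_model_curve(pk_default):
    design = default_design()
    profiles = pp.generate_plasma_profiles(pk_default, design, NO_NOISE)
    ref = pp.simulate_2cmt_bolus(
        pk_default, pp.DoseRegimen.single(3.3), design.sampling_times_h
    )
    for p in profiles:
        np.testing.assert_array_equal(p.conc, ref.conc)


def test_study_shape_matches_design(pk_default):
    profiles = pp.generate_plasma_profiles(pk_default, default_design(), NO_NOISE)
    assert len(profiles) == 4
    assert all(len(p) == 9 for p in profiles)
    assert profiles[0].times_h[0] == pytest.approx(1 / 12)
    assert profiles[0].times_h[-1] == 24.0


def test_plasma_empirical_cv_matches_nominal(pk_default):
    """Monte-Carlo over 2000 subjects: per-time-point CV within [0.18, 0.22]
    for a nominal CV of 0.2."""
    design = default_design(n_subjects=2000, seed=97)
    noise = pp.NoiseSpec(conc_cv=0.2, count_cv=0.0, burden_cv=0.0, lloq=0.0)
    profiles = pp.generate_plasma_profiles(pk_default, design, noise)
    mat = np.array([p.conc for p in profiles])
    cv = mat.std(axis=0, ddof=1) / mat.mean(axis=0)
    assert np.all(cv > 0.18) and np.all(cv < 0.22)


def test_blq_values_flagged_not_dropped(pk_default):
    noise = pp.NoiseSpec(conc_cv=0.0, count_cv=0.0, burden_cv=0.0, lloq=1.0)
    profiles = pp.generate_plasma_profiles(pk_default, default_design(), noise)
    p = profiles[0]
    assert len(p) == 9  # nothing dropped
    assert p.blq_flags[-1]  # 24-h point is below 1 ng/mL under the defaults
    assert not p.blq_flags[:-1].any()


def test_seed_determinism(pk_default):
    noise = pp.NoiseSpec(conc_cv=0.25, count_cv=0.0, burden_cv=0.0, lloq=0.0)
    a = pp.generate_plasma_profiles(pk_default, default_design(seed=5), noise)
    b = pp.generate_plasma_profiles(pk_default, default_design(seed=5), noise)
    c = pp.generate_plasma_profiles(pk_default, default_design(seed=6), noise)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.conc, pb.conc)
    assert not np.array_equal(a[0].conc, c[0].conc)


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        default_design(dose_mg_per_kg=0.0)
    with pytest.raises(ValueError):
        default_design(sampling_times_h=())
    with pytest.raises(ValueError):
        default_design(sampling_times_h=(1.0, 0.5))
    with pytest.raises(ValueError):
        default_design(n_subjects=0)


# --------------------------------------------------------------- tumor ----

def _dense_plasma(pk, dose=3.3):
    t = np.concatenate([np.arange(0.0, 2.0, 0.005), np.arange(2.0, 24.01, 0.05)])
    return pp.simulate_2cmt_bolus(pk, pp.DoseRegimen.single(dose), t)


def test_tumor_zero_input_zero_output(pk_default):
    plasma = _dense_plasma(pk_default).with_values(
        conc=np.zeros(len(_dense_plasma(pk_default)))
    )
    tum = pp.generate_tumor_profile(plasma, pp.LinkParams(), NO_NOISE, n_substeps=5)
    np.testing.assert_array_equal(tum.conc, 0.0)


def test_tumor_default_calibration_anchors(cfg, pk_default):
    """Peak within [10, 30] min and > 10-fold decline by 24 h."""
    tum = pp.generate_tumor_profile(
        _dense_plasma(pk_default), cfg.link, NO_NOISE, n_substeps=10
    )
    i = int(np.argmax(tum.conc))
    t_peak_min = tum.times_h[i] * 60.0
    assert 10.0 <= t_peak_min <= 30.0
    assert tum.conc[-1] < tum.conc[i] / 10.0
    assert tum.units == "ng/g"


def test_tumor_step_input_closed_form():
    """Constant plasma input C: Ct(t) = (k_in/k_out) C (1 - exp(-k_out t))."""
    t = np.linspace(0.0, 24.0, 241)
    plasma = pp.ConcentrationProfile(
        subject_id="s", matrix="plasma", analyte="CNOB",
        times_h=t, conc=np.full_like(t, 30.0),
    )
    link = pp.LinkParams(k_in=1.3, k_out=0.7)
    tum = pp.generate_tumor_profile(plasma, link, NO_NOISE, n_substeps=4)
    expected = (link.k_in / link.k_out) * 30.0 * (1.0 - np.exp(-link.k_out * t))
    np.testing.assert_allclose(tum.conc, expected, rtol=1e-9, atol=1e-12)


def test_tumor_requires_24h_coverage(pk_default):
    short = pp.simulate_2cmt_bolus(
        pk_default, pp.DoseRegimen.single(3.3), np.linspace(0, 12, 50)
    )
    with pytest.raises(ValueError):
        pp.generate_tumor_profile(short, pp.LinkParams(), NO_NOISE)


def test_negative_link_rates_rejected():
    with pytest.raises(ValueError):
        pp.LinkParams(k_in=-1.0, k_out=1.0)


# -------------------------------------------------------------- growth ----

def test_untreated_growth_is_exponential(cfg, pk_default):
    days = np.array([0.0, 5.0, 10.0, 20.0])
    series = pp.generate_tumor_growth(
        cfg.pd, pk_default, pp.DoseRegimen(events=()), default_design(),
        NO_NOISE, days=days, n_subjects=1,
    )
    np.testing.assert_allclose(
        series.burden_mean, cfg.pd.t0 * np.exp(cfg.pd.kg * days), rtol=1e-12
    )
    np.testing.assert_array_equal(series.burden_sd, 0.0)


def test_growth_series_reports_sd_over_subjects(cfg, pk_default):
    noise = pp.NoiseSpec(conc_cv=0.0, count_cv=0.0, burden_cv=0.2, lloq=0.0)
    series = pp.generate_tumor_growth(
        cfg.pd, pk_default, cfg.regimens[0], default_design(seed=3),
        noise, n_subjects=5,
    )
    assert series.n == 5
    assert np.all(series.burden_sd[1:] > 0)


def test_growth_large_n_mean_converges_to_truth(cfg, pk_default):
    noise = pp.NoiseSpec(conc_cv=0.0, count_cv=0.0, burden_cv=0.15, lloq=0.0)
    days = np.array([0.0, 7.0, 14.0, 21.0])
    series = pp.generate_tumor_growth(
        cfg.pd, pk_default, cfg.regimens[0], default_design(seed=21),
        noise, days=days, n_subjects=4000,
    )
    truth = pp.simulate_tumor_growth(
        pk_default, cfg.pd, cfg.regimens[0], 21.0, eval_days=days
    )
    np.testing.assert_allclose(series.burden_mean, truth.burden_mean, rtol=0.02)


def test_growth_horizon_must_cover_last_dose(cfg, pk_default):
    with pytest.raises(ValueError):
        pp.generate_tumor_growth(
            cfg.pd, pk_default, cfg.regimens[0], default_design(),
            NO_NOISE, days=np.array([0.0, 1.0]),
        )


def test_all_generated_quantities_non_negative(cfg, pk_default):
    noise = pp.NoiseSpec(conc_cv=0.5, count_cv=0.5, burden_cv=0.5, lloq=1.0)
    rng = np.random.default_rng(8)
    plasma = pp.generate_plasma_profiles(
        pk_default, default_design(), noise, rng=rng
    )
    for p in plasma:
        assert np.all(p.conc >= 0)
    tum = pp.generate_tumor_profile(_dense_plasma(pk_default), cfg.link, noise,
                                    rng=rng, n_substeps=5)
    assert np.all(tum.conc >= 0)
    curve = pp.StandardCurve(slope=1e5, intercept=0.0, r_squared=1.0)
    series = pp.generate_imaging_series(tum, curve, 5000.0, noise, rng=rng)
    assert np.all(series.counts_per_s >= 0)


def test_imaging_blank_and_linearity():
    curve = pp.StandardCurve(slope=2.0e4, intercept=7.0, r_squared=1.0)
    zero = pp.ConcentrationProfile(
        subject_id="z", matrix="tumor", analyte="MCHB",
        times_h=[0.0, 1.0], conc=[0.0, 0.0], units="uM",
    )
    blank = pp.generate_imaging_series(zero, curve, background=100.0, noise=NO_NOISE)
    np.testing.assert_allclose(blank.counts_per_s, 107.0)
    # doubling concentrations doubles counts when background and intercept are 0
    curve0 = pp.StandardCurve(slope=2.0e4, intercept=0.0, r_squared=1.0)
    prof = zero.with_values(conc=np.array([1.0, 2.0]))
    prof2 = zero.with_values(conc=np.array([2.0, 4.0]))
    s1 = pp.generate_imaging_series(prof, curve0, 0.0, NO_NOISE)
    s2 = pp.generate_imaging_series(prof2, curve0, 0.0, NO_NOISE)
    np.testing.assert_allclose(s2.counts_per_s, 2.0 * s1.counts_per_s, rtol=1e-12)


def test_imaging_negative_background_rejected(cfg):
    curve = pp.StandardCurve(slope=1.0, intercept=0.0, r_squared=1.0)
    prof = pp.ConcentrationProfile(
        subject_id="x", matrix="tumor", analyte="MCHB",
        times_h=[0.0], conc=[1.0], units="uM",
    )
    with pytest.raises(ValueError):
        pp.generate_imaging_series(prof, curve, background=-1.0, noise=NO_NOISE)
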