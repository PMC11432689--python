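"""CMC break-point estimation, kinetics fitting and group statistics."""

import numpy as np
import pytest

from seroraft.errors import ValidationError
from seroraft.synthetic_data import (KineticsSpec, TensiometrySpec,
                                     gen_kinetics_curve, gen_tensiometry_curve,
                                     tensiometry_model)
from seroraft.tensiometry import (KineticsCurve, TensiometryCurve, anova_tukey,
                                  estimate_cmc, fit_binding_kinetics,
                                  monolayer_mole_ratio)


def _noiseless_curve(break_point=42.0, axis_mode="linear"):
    c = np.linspace(5.0, 100.0, 30)
    y = tensiometry_model(c, break_point, -0.5, -0.02, 72.0, axis_mode)
    return TensiometryCurve(c, y, axis_mode=axis_mode)


@pytest.mark.parametrize("axis_mode", ["linear", "log"])
def test_cmc_noiseless_identity(axis_mode):
    """Exact two-segment data recovers the planted break to 1e-6."""
    est = estimate_cmc(_noiseless_curve(42.0, axis_mode))
    assert est.cmc == pytest.approx(42.0, abs=1e-6)
    assert not est.degenerate
    assert est.ssr == pytest.approx(0.0, abs=1e-12)


def test_cmc_recovers_slopes_and_intercept():
    est = estimate_cmc(_noiseless_curve())
    assert est.slope_below == pytest.approx(-0.5, abs=1e-6)
    assert est.slope_above == pytest.approx(-0.02, abs=1e-6)
    assert est.intercept == pytest.approx(72.0, abs=1e-6)


def test_cmc_degenerate_on_straight_line():
    c = np.linspace(5.0, 100.0, 30)
    est = estimate_cmc(TensiometryCurve(c, 72.0 - 0.3 * c))
    assert est.degenerate


def test_cmc_scale_equivariance():
    """Multiplying all concentrations by s multiplies the estimate by s."""
    b = gen_tensiometry_curve(TensiometrySpec(break_point=42.0,
                                              noise_sigma=0.3, seed=8))
    base = estimate_cmc(b.curve).cmc
    for s in (0.1, 3.0):
        scaled = TensiometryCurve(b.curve.concentration * s, b.curve.tension)
        assert estimate_cmc(scaled).cmc == pytest.approx(s * base, rel=1e-9)


def test_cmc_bias_shrinks_with_noise():
    """Mean |error| decreases towards zero as the noise level does."""
    mean_abs_err = []
    for sigma in (0.3, 0.1, 0.0):
        errs = []
        for seed in range(30):
            b = gen_tensiometry_curve(TensiometrySpec(
                break_point=42.0, noise_sigma=sigma, seed=seed))
            errs.append(abs(estimate_cmc(b.curve).cmc - 42.0))
        mean_abs_err.append(np.mean(errs))
    assert mean_abs_err[0] >= mean_abs_err[1] >= mean_abs_err[2]
    assert mean_abs_err[2] < 1e-6


def test_cmc_bootstrap_ci_covers_truth():
    b = gen_tensiometry_curve(TensiometrySpec(break_point=42.0,
                                              noise_sigma=0.3, seed=3))
    est = estimate_cmc(b.curve, n_boot=199, seed=12)
    lo, hi = est.ci
    assert lo < 42.0 < hi
    assert hi - lo < 10.0


def test_cmc_validation_errors():
    with pytest.raises(ValidationError):
        estimate_cmc(TensiometryCurve(np.array([1.0, 2, 3, 4, 5]),
                                      np.full(5, 70.0)))
    with pytest.raises(ValidationError):
        TensiometryCurve(np.array([5.0, 3.0, 10.0, 20.0, 30.0, 40.0]),
                         np.full(6, 70.0))
    with pytest.raises(ValidationError):
        TensiometryCurve(np.array([-1.0, 3.0, 10.0, 20.0, 30.0, 40.0]),
                         np.full(6, 70.0))


@pytest.mark.parametrize("dpi,k", [(10.0, 0.1), (3.0, 0.02), (25.0, 0.7)])
def test_kinetics_noiseless_exact(dpi, k):
    b = gen_kinetics_curve(KineticsSpec(pi0=20.0, delta_pi_inf=dpi, rate_k=k,
                                        noise_sigma=0.0))
    fit = fit_binding_kinetics(b.curve)
    assert fit.pi0 == pytest.approx(20.0, abs=1e-6)
    assert fit.delta_pi_inf == pytest.approx(dpi, abs=1e-6)
    assert fit.rate_k == pytest.approx(k, abs=1e-6)


def test_kinetics_flat_curve_gives_zero_rise():
    b = gen_kinetics_curve(KineticsSpec(pi0=21.5, delta_pi_inf=0.0,
                                        rate_k=0.0, noise_sigma=0.0))
    fit = fit_binding_kinetics(b.curve)
    assert fit.delta_pi_inf == pytest.approx(0.0, abs=1e-6)
    assert fit.delta_pi_at(60.0) == pytest.approx(0.0, abs=1e-6)


def test_kinetics_noisy_recovery_within_5_percent():
    b = gen_kinetics_curve(KineticsSpec(pi0=20.0, delta_pi_inf=10.0,
                                        rate_k=0.1, noise_sigma=0.2, seed=6))
    fit = fit_binding_kinetics(b.curve)
    assert fit.delta_pi_inf == pytest.approx(10.0, rel=0.05)
    assert fit.rate_k == pytest.approx(0.1, rel=0.05)


def test_kinetics_too_few_points_rejected():
    with pytest.raises(ValidationError):
        fit_binding_kinetics(KineticsCurve(np.arange(3.0),
                                           np.array([20.0, 21.0, 21.5])))


def test_two_group_anova_equals_squared_t(rng):
    """With two groups, F is the square of the pooled two-sample t statistic."""
    from scipy import stats as sps

    a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 12)
    cmp_ = anova_tukey({"a": a, "b": b})
    t, p = sps.ttest_ind(a, b)
    assert cmp_.f_stat == pytest.approx(t ** 2, rel=1e-10)
    assert cmp_.p_value == pytest.approx(p, rel=1e-10)


def test_identical_observations_give_f_zero_p_one():
    cmp_ = anova_tukey({"a": [5.0, 5.0, 5.0], "b": [5.0, 5.0]})
    assert cmp_.f_stat == 0.0 and cmp_.p_value == 1.0
    assert (cmp_.table["p_adj"] == 1.0).all()


def test_anova_matches_textbook_formulas(rng):
    """5 groups × n=3: F and Tukey q from explicit sums of squares."""
    groups = {f"g{i}": rng.normal(i * 0.5, 1.0, 3) for i in range(5)}
    cmp_ = anova_tukey(groups)
    vals = {k: np.asarray(v) for k, v in groups.items()}
    grand = np.concatenate(list(vals.values())).mean()
    ssb = sum(3 * (v.mean() - grand) ** 2 for v in vals.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals.values())
    f_expected = (ssb / 4) / (ssw / 10)
    assert cmp_.f_stat == pytest.approx(f_expected, rel=1e-12)
    msw = ssw / 10
    for row in cmp_.table.itertuples():
        diff = vals[row.group_a].mean() - vals[row.group_b].mean()
        assert row.q == pytest.approx(abs(diff) / np.sqrt(msw / 3), rel=1e-12)


def test_tukey_agrees_with_statsmodels(rng):
    """Adjusted p-values match the reference implementation within 1e-3."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = {f"g{i}": rng.normal(i * 0.7, 1.0, 6) for i in range(4)}
    cmp_ = anova_tukey(groups)
    values = np.concatenate(list(groups.values()))
    labels = np.repeat(list(groups), [len(v) for v in groups.values()])
    ref = pairwise_tukeyhsd(values, labels)
    ref_p = {(a, b): p for (a, b), p in
             zip([(r[0], r[1]) for r in ref.summary().data[1:]],
                 ref.pvalues)}
    for row in cmp_.table.itertuples():
        key = (row.group_a, row.group_b)
        expected = ref_p.get(key, ref_p.get(key[::-1]))
        assert row.p_adj == pytest.approx(expected, abs=1e-3)


def test_anova_null_p_is_roughly_uniform(rng):
    """Type-I error at α=0.05 stays near nominal under the null."""
    n_sim = 400
    rejections = sum(
        anova_tukey({c: rng.normal(0, 1, 8) for c in "abc"}).p_value < 0.05
        for _ in range(n_sim)
    )
    assert 0.02 <= rejections / n_sim <= 0.09


def test_anova_group_too_small_rejected():
    with pytest.raises(ValidationError):
        anova_tukey({"a": [1.0, 2.0], "b": [3.0]})


@pytest.mark.parametrize("area_a,area_b,expected", [
    (40.0, 1000.0, 25.0),
    (50.0, 50.0, 1.0),
    (50.0, 200.0, 4.0),
])
def test_monolayer_mole_ratio(area_a, area_b, expected):
    assert monolayer_mole_ratio(area_a, area_b) == pytest.approx(expected)


def test_mole_ratio_equals_count_then_divide():
    """The ratio equals N_a/N_b = (A/area_a)/(A/area_b) at any trough area."""
    for total in (1e4, 5e6):
        n_a = total / 50.0
        n_b = total / 200.0
        assert monolayer_mole_ratio(50.0, 200.0) == pytest.approx(n_a / n_b)


def test_mole_ratio_rejects_non_positive_area():
    with pytest.raises(ValidationError):
        monolayer_mole_ratio(0.0, 10.0)


def test_curve_csv_round_trips(tmp_path):
    c = np.linspace(5.0, 100.0, 10)
    tc = TensiometryCurve(c, 72.0 - 0.4 * c)
    tc.to_csv(tmp_path / "t.csv")
    back = TensiometryCurve.from_csv(tmp_path / "t.csv")
    assert np.allclose(back.tension, tc.tension)
    kc = KineticsCurve(np.arange(6.0), 20.0 + np.arange(6.0) * 0.5)
    kc.to_csv(tmp_path / "k.csv")
    back = KineticsCurve.from_csv(tmp_path / "k.csv")
    assert np.allclose(back.pressure, kc.pressure)
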