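import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aridphen.response import (
    bootstrap_x0_ci,
    compute_tr_from_log,
    compute_vpd,
    fit_segmented,
    predict_segmented,
    saturation_vapour_pressure,
)
from aridphen.synthetic import simulate_tr_response, simulate_vpd_steps
from aridphen.types import ResponseDataset, TruthParams, VPDStep, VPDStepLog

from conftest import ACCESSION_TR_PARAMS, tr_truth


class P:
    def __init__(self, intercept1, slope1, x0, slope2):
        self.intercept1, self.slope1, self.x0, self.slope2 = intercept1, slope1, x0, slope2


# ---------------------------------------------------------------------------
# predict_segmented
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [(0.25, 0.25), (0.9, 0.5), (0.5, 0.5)],
)
def test_predict_rise_then_plateau(x, expected):
    params = P(0.0, 1.0, 0.5, 0.0)
    assert predict_segmented(params, x) == pytest.approx(expected)


def test_predict_continuous_at_breakpoint_for_published_params():
    # both branch formulas agree at X0 for the Marina di Andora parameter set
    i1, s1, x0, s2 = ACCESSION_TR_PARAMS["Marina di Andora"]
    y1 = s1 * x0 + i1
    y2 = (s1 * x0 + i1) + s2 * (x0 - x0)
    assert y1 == pytest.approx(y2)
    assert predict_segmented(P(i1, s1, x0, s2), x0) == pytest.approx(y1)


@settings(derandomize=True, max_examples=100)
@given(
    i1=st.floats(-50, 50),
    s1=st.floats(-40, 40),
    x0=st.floats(0.1, 5),
    s2=st.floats(-40, 40),
    eps=st.floats(1e-9, 1e-6),
)
def test_predict_continuity_property(i1, s1, x0, s2, eps):
    params = P(i1, s1, x0, s2)
    below, above = predict_segmented(params, x0 - eps), predict_segmented(params, x0 + eps)
    assert abs(above - below) < 1e-3 * (1 + abs(below))


# ---------------------------------------------------------------------------
# fit_segmented
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("accession", list(ACCESSION_TR_PARAMS))
def test_noiseless_fit_recovers_truth(accession):
    truth = tr_truth(accession)
    data = simulate_tr_response(truth, n_points=30, noise_sd=0.0)
    fit = fit_segmented(data)
    for p in ("intercept1", "slope1", "x0", "slope2"):
        assert getattr(fit, p) == pytest.approx(getattr(truth, p), rel=1e-6, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_moderate_noise_breakpoint_recovery():
    # 200 replicate fits at noise sd 1.5 recover the steep/flat response's
    # breakpoint (2.97 kPa) essentially without bias
    truth = tr_truth("Castel Maggiore", noise_sd=1.5)
    rng = np.random.default_rng(0)
    est = []
    for _ in range(200):
        data = simulate_tr_response(truth, n_points=30, rng=rng)
        est.append(fit_segmented(data).x0)
    assert abs(np.mean(est) - truth.x0) <= 0.15


def test_fit_requires_five_points_and_varying_x():
    with pytest.raises(ValueError):
        fit_segmented(ResponseDataset([1, 2, 3, 4], [1, 2, 3, 4]))
    with pytest.raises(ValueError):
        fit_segmented(ResponseDataset([2.0] * 6, [1, 2, 3, 4, 5, 6]))


def test_fit_equivariance_under_y_scaling_and_x_shift():
    truth = tr_truth("Zambana", noise_sd=1.0)
    data = simulate_tr_response(truth, n_points=24, rng=np.random.default_rng(3))
    base = fit_segmented(data)

    c = 3.7
    scaled = fit_segmented(ResponseDataset(data.x, c * data.y))
    assert scaled.x0 == pytest.approx(base.x0, abs=1e-6)
    assert scaled.r2 == pytest.approx(base.r2, abs=1e-9)
    for p in ("intercept1", "slope1", "slope2"):
        assert getattr(scaled, p) == pytest.approx(c * getattr(base, p), rel=1e-6)

    shift = 2.5
    shifted = fit_segmented(ResponseDataset(data.x + shift, data.y))
    assert shifted.x0 == pytest.approx(base.x0 + shift, abs=1e-5)
    assert shifted.slope1 == pytest.approx(base.slope1, rel=1e-5)


def test_segmented_sse_not_worse_than_straight_line():
    rng = np.random.default_rng(7)
    for _ in range(10):
        x = np.sort(rng.uniform(0, 1, 20))
        y = rng.normal(0, 1, 20)
        fit = fit_segmented(ResponseDataset(x, y))
        sse_fit = np.sum((y - predict_segmented(fit, x)) ** 2)
        slope, intercept = np.polyfit(x, y, 1)
        sse_line = np.sum((y - (slope * x + intercept)) ** 2)
        assert sse_fit <= sse_line + 1e-9


def test_breakpoint_rmse_decreases_with_sample_size():
    truth = tr_truth("Marina di Andora", noise_sd=2.0)
    rng = np.random.default_rng(11)
    rmse = {}
    for n in (10, 30, 100):
        errs = [
            fit_segmented(simulate_tr_response(truth, n_points=n, rng=rng)).x0 - truth.x0
            for _ in range(60)
        ]
        rmse[n] = np.sqrt(np.mean(np.square(errs)))
    assert rmse[10] > rmse[30] > rmse[100]


def test_bootstrap_ci_brackets_truth_on_clean_data():
    truth = tr_truth("Marina di Andora", noise_sd=1.0)
    data = simulate_tr_response(truth, n_points=40, rng=np.random.default_rng(5))
    lo, hi = bootstrap_x0_ci(data, n_boot=200, seed=1)
    assert lo < truth.x0 < hi
    assert hi - lo < 1.0


# ---------------------------------------------------------------------------
# compute_vpd
# ---------------------------------------------------------------------------


def test_vpd_zero_at_saturation():
    assert compute_vpd(25.0, 100.0) == pytest.approx(0.0, abs=1e-12)


def test_vpd_closed_form_at_25C_50RH():
    # es(25) = 0.61078 * exp(17.27*25/(25+237.3)) ~= 3.17 kPa, halved
    assert saturation_vapour_pressure(25.0) == pytest.approx(3.17, abs=0.01)
    assert compute_vpd(25.0, 50.0) == pytest.approx(1.58, abs=0.01)


def test_vpd_monotone_in_rh_and_bounds():
    rh = np.array([90.0, 70.0, 50.0, 30.0])
    vpd = compute_vpd(25.0, rh)
    assert np.all(np.diff(vpd) > 0)
    for bad in (0.0, -5.0, 101.0):
        with pytest.raises(ValueError):
            compute_vpd(25.0, bad)


# ---------------------------------------------------------------------------
# compute_tr_from_log
# ---------------------------------------------------------------------------


def _one_step_log(loss_g, duration_s=3600, leaf_area=0.05):
    t0 = dt.datetime(2020, 3, 10, 9, 0)
    step = VPDStep(
        2.0, t0, t0 + dt.timedelta(seconds=duration_s), 25.0, 50.0, 3000.0, 3000.0 - loss_g
    )
    return VPDStepLog("p1", leaf_area, [step])


def test_tr_unit_conversion():
    # 10 g over 3600 s on 0.05 m^2 -> 55.6 mg m^-2 s^-1
    data = compute_tr_from_log(_one_step_log(10.0))
    assert data.y[0] == pytest.approx(55.56, abs=0.01)
    assert data.x[0] == pytest.approx(compute_vpd(25.0, 50.0))


def test_tr_zero_mass_change_and_negative_flagging():
    assert compute_tr_from_log(_one_step_log(0.0)).y[0] == 0.0
    flagged = compute_tr_from_log(_one_step_log(-5.0))
    assert flagged.flags and "negative" in flagged.flags[0]


def test_noiseless_vpd_log_roundtrip():
    truth = tr_truth("Castel Maggiore", noise_sd=0.0)
    log = simulate_vpd_steps(truth, [1.0, 1.5, 2.5, 3.5])
    data = compute_tr_from_log(log)
    np.testing.assert_allclose(data.x, [1.0, 1.5, 2.5, 3.5], rtol=1e-9)
    np.testing.assert_allclose(data.y, predict_segmented(truth, data.x), rtol=1e-9)
    # slope2 > 0 for this accession: TR keeps rising across all steps
    assert np.all(np.diff(data.y) > 0)
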