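import datetime as dt

import numpy as np
import pytest

from aridphen.gravimetric import (
    compute_ftsw,
    compute_ttsw,
    find_endpoint,
    mean_daily_water_use,
    partition_water_use,
    recovery_percent,
)
from aridphen.synthetic import simulate_drydown, simulate_soil_pot
from aridphen.types import PotWeightSeries, TruthParams, WeightRecord


def _shifted(series: PotWeightSeries, delta: float) -> PotWeightSeries:
    recs = [WeightRecord(r.timestamp, r.weight + delta, r.rewatered) for r in series.records]
    return PotWeightSeries(series.plant_id, series.species, series.accession, series.watering, recs)


# ---------------------------------------------------------------------------
# partition_water_use
# ---------------------------------------------------------------------------


def test_soil_only_pot_self_corrects_to_zero(ftsw_truth):
    pot = simulate_soil_pot(ftsw_truth, 8)
    recs = partition_water_use(pot, ftsw_truth.soil_evap_day, ftsw_truth.soil_evap_night)
    assert recs and all(abs(r.wu_day) < 1e-9 and abs(r.wu_night) < 1e-9 for r in recs)


@pytest.mark.parametrize("watering", ["WS", "WW"])
def test_partition_recovers_generator_truth(ftsw_truth, watering):
    series = simulate_drydown(ftsw_truth, 12, watering)
    recs = partition_water_use(
        series,
        ftsw_truth.soil_evap_day,
        ftsw_truth.soil_evap_night,
        target_weight=series.truth["target_weight"],
    )
    assert len(recs) == 12
    for rec, wd, wn in zip(recs, series.truth["wu_day"], series.truth["wu_night"]):
        assert rec.wu_day == pytest.approx(wd, abs=1e-9)
        assert rec.wu_night == pytest.approx(wn, abs=1e-9)


def test_missing_paired_record_skipped(ftsw_truth, caplog):
    series = simulate_drydown(ftsw_truth, 6, "WS")
    # drop one evening weighing in the middle of the run
    gap = series.records[5].timestamp.date()
    series.records = [
        r for r in series.records
        if not (r.timestamp.date() == gap and r.timestamp.hour >= 12)
    ]
    with caplog.at_level("WARNING"):
        recs = partition_water_use(series, 0.0, 0.0)
    assert len(recs) == 5
    assert any("skipped" in m for m in caplog.messages)


def test_rewatering_requires_target_weight(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 5, "WW")
    with pytest.raises(ValueError):
        partition_water_use(series, 0.0, 0.0)


# ---------------------------------------------------------------------------
# compute_ttsw / find_endpoint / compute_ftsw
# ---------------------------------------------------------------------------


def test_ttsw_is_the_weight_difference():
    assert compute_ttsw(3750.0, 1250.0) == 2500.0
    with pytest.raises(ValueError):
        compute_ttsw(1250.0, 1250.0)


def test_ttsw_recovered_from_simulated_drydown(ftsw_truth):
    # run long enough to exhaust the transpirable pool
    series = simulate_drydown(ftsw_truth, 25, "WS")
    control = ftsw_truth.intercept1 + ftsw_truth.slope1 * ftsw_truth.x0
    _, wtf = find_endpoint(
        series,
        control,
        soil_mean_day=ftsw_truth.soil_evap_day,
        soil_mean_night=ftsw_truth.soil_evap_night,
    )
    ttsw_est = compute_ttsw(series.records[0].weight, wtf)
    # endpoint triggers once daily WU <= 10% of control, i.e. at a small
    # positive FTSW, so the estimate overshoots slightly
    assert ttsw_est == pytest.approx(ftsw_truth.ttsw, rel=0.05)


def test_endpoint_examples(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 25, "WS")
    with pytest.raises(ValueError):
        find_endpoint(series, 0.0)
    # threshold 1.0: the very first stress day qualifies
    date, _ = find_endpoint(
        series,
        260.0,
        threshold_fraction=1.0,
        soil_mean_day=ftsw_truth.soil_evap_day,
        soil_mean_night=ftsw_truth.soil_evap_night,
    )
    assert date == series.records[0].timestamp.date()
    # too short a run never crosses 10%
    short = simulate_drydown(ftsw_truth, 4, "WS")
    with pytest.raises(ValueError, match="too short"):
        find_endpoint(short, 250.0, soil_mean_day=ftsw_truth.soil_evap_day,
                      soil_mean_night=ftsw_truth.soil_evap_night)


def test_endpoint_invariant_to_constant_weight_offset(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 25, "WS")
    kwargs = dict(
        soil_mean_day=ftsw_truth.soil_evap_day,
        soil_mean_night=ftsw_truth.soil_evap_night,
    )
    date, wtf = find_endpoint(series, 250.0, **kwargs)
    date2, wtf2 = find_endpoint(_shifted(series, 500.0), 250.0, **kwargs)
    assert date2 == date
    assert wtf2 == pytest.approx(wtf + 500.0)


def test_ftsw_construction_and_monotonicity(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 25, "WS")
    wtf = series.records[0].weight - ftsw_truth.ttsw
    ftsw = compute_ftsw(series, wtf, ftsw_truth.ttsw)
    values = [v for _, v in ftsw.entries]
    assert values[0] == pytest.approx(1.0, abs=1e-9)
    assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))
    # degenerate endpoints
    assert compute_ftsw(series, series.records[0].weight, ftsw_truth.ttsw).entries[0][1] == 0.0
    with pytest.raises(ValueError):
        compute_ftsw(series, wtf, 0.0)


def test_ww_ftsw_stays_near_one(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 10, "WW")
    wtf = series.truth["target_weight"] - ftsw_truth.ttsw
    values = [v for _, v in compute_ftsw(series, wtf, ftsw_truth.ttsw).entries]
    # overnight transpiration only: WW stays within a few percent of 1
    assert min(values) > 0.95


# ---------------------------------------------------------------------------
# recovery_percent
# ---------------------------------------------------------------------------


def test_recovery_examples():
    pre = [200.0] * 5
    assert recovery_percent([200.0] * 6, pre) == pytest.approx(100.0)
    assert recovery_percent([0.742 * 200.0] * 6, pre) == pytest.approx(74.2)
    assert recovery_percent([150.0] * 7, pre, mode="mean") == pytest.approx(75.0)
    with pytest.raises(ValueError):
        recovery_percent([100.0] * 6, [0.0] * 5)
    with pytest.raises(ValueError):
        recovery_percent([100.0] * 3, pre)  # day-6 value not yet observed


def test_mean_daily_water_use_reference(ftsw_truth):
    series = simulate_drydown(ftsw_truth, 8, "WW")
    recs = partition_water_use(
        series, ftsw_truth.soil_evap_day, ftsw_truth.soil_evap_night,
        target_weight=series.truth["target_weight"],
    )
    plateau = ftsw_truth.intercept1 + ftsw_truth.slope1 * ftsw_truth.x0 \
        + ftsw_truth.slope2 * (1.0 - ftsw_truth.x0)
    assert mean_daily_water_use(recs) == pytest.approx(plateau, rel=0.02)
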