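import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weedvision import (
    SprayerGeometry,
    SprayPlanner,
    application_rate,
    flow_error,
    measured_flows,
    rate_table,
    select_mode,
    theoretical_flows,
)
from weedvision.errors import ValidationError
from weedvision.spray import MODE_NOZZLES, PRESSURES
from weedvision.weedmap import InterRowInterval, WeedMap


def test_mode_nozzle_combinations():
    assert MODE_NOZZLES[7] == {1, 2, 3}
    assert MODE_NOZZLES[5] == {1, 3}
    assert MODE_NOZZLES[6] == {2, 3}  # the only unused pair
    assert len({frozenset(v) for v in MODE_NOZZLES.values()}) == 7


def test_application_rate_reference_points():
    assert application_rate(0.36, 2.5, 100) == pytest.approx(86.4)
    assert application_rate(2.81, 2.5, 100) == pytest.approx(674.4)
    assert application_rate(0.0) == 0.0


@settings(deadline=None, derandomize=True)
@given(
    q=st.floats(0.01, 10),
    v=st.floats(0.5, 10),
    w=st.floats(10, 500),
    k=st.floats(1.1, 5),
)
def test_application_rate_scaling_laws(q, v, w, k):
    r = application_rate(q, v, w)
    assert application_rate(k * q, v, w) == pytest.approx(k * r)
    assert application_rate(q, k * v, w) == pytest.approx(r / k)
    assert application_rate(q, v, k * w) == pytest.approx(r / k)


def test_application_rate_rejects_bad_geometry():
    with pytest.raises(ValidationError):
        application_rate(1.0, 0.0, 100)
    with pytest.raises(ValidationError):
        application_rate(1.0, 2.5, -1)


def test_rate_table_is_240_times_flow():
    flows = measured_flows()
    rates = rate_table(flows, SprayerGeometry(2.5, 100.0))
    np.testing.assert_allclose(rates.values, 240.0 * flows.flows.values)


def test_rate_table_nonzero_range():
    rates = rate_table(measured_flows())
    nonzero = rates.values[rates.values > 0]
    assert nonzero.min() == pytest.approx(84.0)
    assert nonzero.max() == pytest.approx(674.4)


def test_nozzle_spacing_consistent_with_rates():
    """The spacing W implied by R = 60000 Q / (V W) at V = 2.5 m/s is 100 cm
    for every nonzero cell of the bundled tables."""
    flows = measured_flows().flows
    rates = rate_table(measured_flows())
    q = flows.values[flows.values > 0]
    r = rates.values[rates.values > 0]
    np.testing.assert_allclose(60000.0 * q / (2.5 * r), 100.0)


def test_flow_error_identical_tables_zero():
    err = flow_error(theoretical_flows(), theoretical_flows())
    assert np.nanmax(np.abs(err.values)) == 0.0


def test_flow_error_reference_cell():
    err = flow_error(measured_flows(), theoretical_flows())
    # mode-7 at 400 kPa: (2.81 - 2.72) / 2.72
    assert err.at[400, 7] == pytest.approx(100 * (2.81 - 2.72) / 2.72)
    assert round(err.at[400, 7], 2) == 3.31
    # the undetectable mode-1 cell at 200 kPa reads -100%
    assert err.at[200, 1] == pytest.approx(-100.0)


def test_flow_error_key_mismatch_rejected():
    import pandas as pd

    from weedvision.spray import FlowTable

    bad = FlowTable(pd.DataFrame({1: [0.3]}, index=pd.Index([999], name="pressure")))
    with pytest.raises(ValidationError):
        flow_error(bad, theoretical_flows())


def test_select_mode_default_mapping():
    assert select_mode(0) is None
    assert select_mode(5) == 7
    assert select_mode(4) == 5
    assert select_mode(5, {5: 6}) == 6
    with pytest.raises(ValidationError):
        select_mode(9)


def test_select_mode_warns_on_mode_4():
    with pytest.warns(UserWarning):
        select_mode(2, {2: 4})


def _weed_map(levels):
    ivs = [InterRowInterval(10 * i, 10 * i + 5, 0) for i in range(len(levels))]
    return WeedMap(
        intervals=ivs, fractions=[0.0] * len(levels), levels=list(levels), image_shape=(100, 100)
    )


def test_planner_decisions_deterministic_and_off_at_level_zero():
    wm = _weed_map([0, 2, 5])
    planner = SprayPlanner(pressure=300)
    d1 = planner.predict(wm)
    d2 = planner.predict(wm)
    assert [x.to_json() for x in d1] == [x.to_json() for x in d2]
    assert d1[0].mode is None and d1[0].rate == 0.0
    assert d1[1].mode == 2 and d1[1].rate == pytest.approx(199.2)
    assert d1[2].mode == 7 and d1[2].nozzles == (1, 2, 3)


def test_planner_rejects_unknown_pressure():
    wm = _weed_map([3])
    with pytest.raises(ValidationError):
        SprayPlanner(pressure=123).predict(wm)


def test_flow_tables_cover_all_tabulated_pressures():
    assert tuple(measured_flows().flows.index) == PRESSURES
    assert tuple(theoretical_flows().flows.index) == PRESSURES


def test_flow_table_csv_round_trip(tmp_path):
    from weedvision.spray import FlowTable

    path = tmp_path / "flows.csv"
    measured_flows().to_csv(path)
    back = FlowTable.from_csv(path)
    np.testing.assert_allclose(back.flows.values, measured_flows().flows.values)
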