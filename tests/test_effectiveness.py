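import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emwater as ew

from conftest import make_dataset

AUG = ("2021-08-09", "2021-08-16", "2021-08-23")


def august_dataset(point_factors):
    """Three August series; after-values scaled per (site, depth) factor."""
    recs = []
    for (site, depth), factor in point_factors.items():
        for i, date in enumerate(AUG):
            for rep in (1, 2, 3):
                base = 100.0 + 10 * rep + site + depth / 100
                value = base if i == 0 else base * factor
                recs.append((date, site, depth, rep, "CBN", value))
    return make_dataset(recs)


def test_uniform_reduction_all_cells_and_aggregates():
    points = {(s, d): 0.5 for s in (1, 2, 3) for d in (30, 100)}
    table = ew.effectiveness_table(august_dataset(points),
                                   parameters=("CBN",))
    assert len(table.cells) == 6
    for cell in table.cells:
        assert cell.pct_change == pytest.approx(-50.0)
    assert table.overall_pooled["CBN"] == pytest.approx(-50.0)
    assert table.overall_cell_mean["CBN"] == pytest.approx(-50.0)


def test_single_point_direct_ratio():
    recs = []
    for i, date in enumerate(AUG):
        for rep in (1, 2, 3):
            recs.append((date, 1, 30, rep, "FEN", 100.0 if i == 0 else 40.0))
    table = ew.effectiveness_table(make_dataset(recs), parameters=("FEN",))
    [cell] = table.cells
    assert cell.pct_change == pytest.approx(-60.0)


def test_heterogeneous_pooled_equals_grand_mean_ratio():
    points = {
        (1, 30): 0.2, (1, 100): 0.6, (2, 30): 1.1,
        (2, 100): 0.5, (3, 30): 0.9, (3, 100): 0.3,
    }
    ds = august_dataset(points)
    table = ew.effectiveness_table(ds, parameters=("CBN",))
    # brute-force oracle straight from the raw records
    f = ds.frame
    before = f[f["date"].astype(str) == AUG[0]]["value"].mean()
    after = f[f["date"].astype(str) != AUG[0]]["value"].mean()
    assert table.overall_pooled["CBN"] == pytest.approx(
        100.0 * (after - before) / before
    )
    # heterogeneity makes the two aggregates differ
    assert table.overall_pooled["CBN"] != pytest.approx(
        table.overall_cell_mean["CBN"]
    )


def test_effectiveness_frame_layout():
    points = {(s, d): 0.5 for s in (1, 2, 3) for d in (30, 100)}
    frame = ew.effectiveness_table(
        august_dataset(points), parameters=("CBN",)
    ).to_frame()
    assert "overall (pooled)" in frame.index
    assert frame.loc["1 (30 cm)", "CBN"] == -50.0


# -- duration of action ----------------------------------------------------


@pytest.mark.parametrize(
    "v0, v1, v2, days, censored",
    [
        (100.0, 40.0, 70.0, 21.00, False),  # rho = 30/7 -> T = 14 + 7 = 21
        (100.0, 40.0, 40.0, 60.00, True),  # still down: censored at horizon
        (100.0, 100.0, 100.0, 0.00, False),  # never departed baseline
        (100.0, 40.0, 120.0, 12.25, False),  # re-crossed between day 7 and 14
        (100.0, 99.0, 42.0, 60.00, True),  # monotone decline
    ],
)
def test_duration_cases(v0, v1, v2, days, censored):
    est = ew.duration_of_action(v0, v1, v2)
    assert est.days == pytest.approx(days)
    assert est.censored is censored


def test_duration_rebound_formula():
    # rho = (v2 - v1)/7 = 2; T = 14 + (v0 - v2)/rho = 14 + 30
    est = ew.duration_of_action(100.0, 26.0, 40.0)
    assert est.days == pytest.approx(44.0)
    assert est.hours == pytest.approx(44.0 * 24)
    assert est.minutes == 44 * 24 * 60


def test_duration_errors():
    with pytest.raises(ew.ValidationError):
        ew.duration_of_action(0.0, 1.0, 2.0)
    with pytest.raises(ew.ValidationError):
        ew.duration_of_action(10.0, -1.0, 2.0)


@given(
    st.floats(1.0, 1e4),
    st.floats(0.0, 0.99),
    st.floats(0.0, 0.99),
    st.floats(1e-3, 1e3),
)
@settings(deadline=None, max_examples=80)
def test_duration_scale_invariance(v0, f1, f2, c):
    v1, v2 = v0 * f1, v0 * f2
    a = ew.duration_of_action(v0, v1, v2)
    b = ew.duration_of_action(c * v0, c * v1, c * v2)
    assert a.days == pytest.approx(b.days)
    assert a.censored == b.censored


def test_duration_monotone_in_rebound_rate():
    # faster rebound (larger rho) -> shorter duration
    slow = ew.duration_of_action(100.0, 40.0, 50.0, horizon_days=1000)
    fast = ew.duration_of_action(100.0, 40.0, 90.0, horizon_days=1000)
    assert fast.days < slow.days


@pytest.mark.parametrize(
    "hours, minutes, days",
    [
        (819.2, 49152, 34.13),
        (468.5, 28110, 19.52),
        (472.1, 28326, 19.67),
        (0.0, 0, 0.00),
    ],
)
def test_convert_duration_triples(hours, minutes, days):
    m, d = ew.convert_duration(hours)
    assert m == minutes
    assert d == days


def test_convert_duration_negative_raises():
    with pytest.raises(ew.ValidationError):
        ew.convert_duration(-1.0)


@given(st.floats(0.0, 5000.0))
@settings(deadline=None)
def test_convert_duration_round_trip(hours):
    minutes, _days = ew.convert_duration(hours)
    assert abs(minutes / 60.0 - hours) < 0.05


def test_duration_table_on_synthetic(sim_dataset):
    ds, _ = ew.exclude_constant_parameters(sim_dataset)
    table = ew.duration_table(ds)
    assert set(table.index) == set(ew.MICROBIOLOGICAL_COUNTS)
    assert (table["days"] >= 0).all()
    assert (table["days"] <= 60.0).all()
    # triple consistency: hours canonical
    for _, row in table.iterrows():
        m, d = ew.convert_duration(row["hours"])
        assert row["minutes"] == m and row["days"] == d
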