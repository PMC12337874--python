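"""Energy-partition arithmetic against the published ad-libitum table and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netenergy import (
    ImplausibleRecordWarning,
    PenRecord,
    balance_pen,
    balance_table,
    compute_avg_weight,
    compute_bwg,
    compute_hi,
    compute_hp,
    compute_mei,
    compute_ne,
    compute_re,
    me_n_corrected,
    metabolic_weight,
    summarize_partition,
)
from conftest import balances_from_table4


@pytest.mark.parametrize(
    "bw_start, bw_end, days, expected, tol",
    [
        (0.158, 0.813, 14, 46.80, 0.02),   # published basal ADG
        (0.166, 0.969, 14, 57.36, 0.02),   # published soybean-oil ADG
        (0.5, 0.5 + 14 / 1000, 14, 1.0, 1e-12),
    ],
)
def test_bwg(bw_start, bw_end, days, expected, tol):
    assert compute_bwg(bw_start, bw_end, days) == pytest.approx(expected, abs=tol)


def test_bwg_rejects_bad_input():
    with pytest.raises(ValueError):
        compute_bwg(0.5, 0.4, 14)
    with pytest.raises(ValueError):
        compute_bwg(0.1, 0.5, 0)


@pytest.mark.parametrize(
    "bw_start, bw_end, expected",
    [(0.158, 0.813, 0.4855), (0.166, 0.969, 0.5675), (0.42, 0.42, 0.42)],
)
def test_avg_weight_is_arithmetic_mean(bw_start, bw_end, expected):
    assert compute_avg_weight(bw_start, bw_end) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "w, expected, tol",
    [(0.486, 0.582, 5e-4), (0.563, 0.650, 5e-4), (1.0, 1.0, 0), (16.0, 8.0, 1e-12)],
)
def test_metabolic_weight(w, expected, tol):
    assert metabolic_weight(w) == pytest.approx(expected, abs=tol)


@given(st.floats(0.01, 20), st.floats(0.01, 20))
def test_metabolic_weight_monotone(a, b):
    lo, hi = sorted([a, b])
    if hi > lo:
        assert metabolic_weight(hi) > metabolic_weight(lo)


@pytest.mark.parametrize(
    "ge_in, ge_out, n_ret, fi, expected",
    [
        (4444, 1400, 0, 1000, 3.044),
        (4444, 1400, 10, 1000, 2.9618),  # hand arithmetic at 8.22 kcal/g N
        (4444, 4444, 0, 500, 0.0),
    ],
)
def test_me_n_corrected(ge_in, ge_out, n_ret, fi, expected):
    assert me_n_corrected(ge_in, ge_out, n_ret, fi) == pytest.approx(expected, abs=1e-9)


def test_me_n_corrected_negative_flagged():
    with pytest.warns(ImplausibleRecordWarning):
        me_n_corrected(1000, 990, 50, 100)


def test_mei_matches_published_cell():
    assert compute_mei(3.0, 58.16) == pytest.approx(174.47, abs=0.1)


@pytest.mark.parametrize(
    "re_start, re_end, days, expected",
    [(100, 1268.16, 14, 83.44), (100, 1784.9, 14, 120.35), (42, 42, 14, 0.0)],
)
def test_re(re_start, re_end, days, expected):
    assert compute_re(re_start, re_end, days) == pytest.approx(expected, abs=1e-9)


def test_negative_retention_warns_but_returns():
    with pytest.warns(ImplausibleRecordWarning):
        assert compute_re(100, 30, 14) == pytest.approx(-5.0)


def test_partition_identities_reproduce_published_cells(table4):
    """HP = MEI − RE, HI = HP − NEm, NE = NEm + RE match all printed cells to 0.02."""
    for _, r in table4.iterrows():
        assert compute_hp(r.mei_kcal_day, r.re_kcal_day) == pytest.approx(
            r.hp_kcal_day, abs=0.02
        )
        assert compute_hi(r.hp_kcal_day, r.nem_kcal_day) == pytest.approx(
            r.hi_kcal_day, abs=0.02
        )
        assert compute_ne(r.nem_kcal_day, r.re_kcal_day) == pytest.approx(
            r.ne_kcal_day, abs=0.02
        )


@given(
    mei=st.floats(50, 400),
    re=st.floats(-50, 200),
    nem=st.floats(10, 100),
)
def test_conservation_identities(mei, re, nem):
    hp = compute_hp(mei, re)
    hi = compute_hi(hp, nem)
    ne = compute_ne(nem, re)
    assert mei - re - hp == pytest.approx(0, abs=1e-9)
    assert hp - nem - hi == pytest.approx(0, abs=1e-9)
    assert ne - nem - re == pytest.approx(0, abs=1e-9)


def _pen(**over):
    base = dict(
        diet_id="basal",
        feeding_level=1.0,
        replicate_id="r1",
        bw_start=0.158,
        bw_end=0.813,
        n_birds=5,
        feed_intake_total=174.47 / 3.0 * 14,
        me_diet=3.0,
        re_start=100.0,
        re_end=100.0 + 83.44 * 14,
    )
    base.update(over)
    return PenRecord(**base)


def test_balance_pen_reproduces_published_basal_column():
    bal = balance_pen(_pen(), nem_coef=75.28)
    assert bal.mei == pytest.approx(174.47, abs=0.01)
    assert bal.re == pytest.approx(83.44, abs=0.01)
    assert bal.hp == pytest.approx(91.03, abs=0.02)
    assert bal.w_meta == pytest.approx(0.582, abs=5e-4)
    assert bal.nem == pytest.approx(43.80, abs=0.05)
    assert bal.ne == pytest.approx(127.24, abs=0.06)


def test_pen_totals_scaling_matches_per_bird_entry():
    per_bird = balance_pen(_pen(), nem_coef=75.28)
    pen_level = balance_pen(
        _pen(
            feed_intake_total=5 * 174.47 / 3.0 * 14,
            re_start=500.0,
            re_end=5 * (100.0 + 83.44 * 14),
        ),
        nem_coef=75.28,
        pen_totals=True,
    )
    assert pen_level.mei == pytest.approx(per_bird.mei, rel=1e-12)
    assert pen_level.re == pytest.approx(per_bird.re, rel=1e-12)


def test_protein_lipid_split_uses_combustion_equivalents():
    bal = balance_pen(_pen(protein_gain=114.4, lipid_gain=55.66))
    assert bal.re_protein == pytest.approx(5.66 * 114.4 / 14, rel=1e-12)
    assert bal.re_lipid == pytest.approx(9.35 * 55.66 / 14, rel=1e-12)


def test_pen_record_validation():
    with pytest.raises(ValueError):
        _pen(bw_end=0.1)
    with pytest.raises(ValueError):
        _pen(feeding_level=1.5)
    with pytest.raises(ValueError):
        _pen(feed_intake_total=0)
    with pytest.warns(ImplausibleRecordWarning):
        _pen(re_end=50.0)  # negative retention: flagged, not fatal


def test_summary_reproduces_published_partition_means(table4):
    """Mean-of-ratios summaries match the published averages to 0.05 points."""
    summary = summarize_partition(balances_from_table4(table4))
    val = lambda q, s: float(
        summary.query("quantity == @q and statistic == @s")["value"].iloc[0]
    )
    assert val("hp_kcal_day", "mean") == pytest.approx(104.59, abs=0.05)
    assert val("re_kcal_day", "mean") == pytest.approx(88.65, abs=0.05)
    assert val("hp_pct_mei", "mean") == pytest.approx(54.35, abs=0.05)
    assert val("re_pct_mei", "mean") == pytest.approx(45.6, abs=0.05)
    assert val("ne_pct_mei", "mean") == pytest.approx(70.55, abs=0.05)
    assert val("nem_pct_mei", "mean") == pytest.approx(24.90, abs=0.05)
    assert val("hi_pct_mei", "mean") == pytest.approx(29.45, abs=0.05)
    assert val("hi_pct_mei", "min") == pytest.approx(25.56, abs=0.05)
    assert val("hi_pct_mei", "max") == pytest.approx(35.98, abs=0.05)


def test_summary_of_repeated_group_is_that_group(table4):
    one = balances_from_table4(table4)[0]
    summary = summarize_partition([one] * 4)
    row = summary.query("quantity == 'hp_kcal_day' and statistic == 'mean'")
    assert float(row["value"].iloc[0]) == pytest.approx(one.hp, rel=1e-12)


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        summarize_partition([])


def test_balance_table_shape():
    df = balance_table([_pen(), _pen(replicate_id="r2")], nem_coefs={"basal": 75.28})
    assert len(df) == 2
    assert not df["ne_kcal_day"].isna().any()
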