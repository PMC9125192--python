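"""pSOFA domain scoring: threshold behavior, totals, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from psofa.samples import MonitoringSample, TherapyState
from psofa.scoring import (
    compute_psofa,
    score_cardiovascular,
    score_coagulation,
    score_liver,
    score_renal,
    score_respiration,
    score_timeseries,
)

from _oracle import (
    oracle_cardiovascular,
    oracle_coagulation,
    oracle_liver,
    oracle_renal,
    oracle_respiration,
)


@pytest.mark.parametrize(
    "pf,expected",
    [(450, 0), (400, 0), (399.9, 1), (300, 1), (250, 2), (200, 2),
     (150, 3), (100, 3), (99.9, 4), (50, 4), (0, 4)],
)
def test_respiration_thresholds(pf, expected):
    assert score_respiration(pf).score == expected


@pytest.mark.parametrize(
    "map_mmHg,norepi,expected",
    [(80, 0.0, 0), (75, 0.0, 0), (70, 0.0, 1), (65, 0.0, 1), (60, 0.0, 2),
     (60, 0.05, 3), (60, 0.1, 3), (60, 0.2, 4), (90, 0.2, 4)],
)
def test_cardiovascular_thresholds(map_mmHg, norepi, expected):
    ther = TherapyState(norepinephrine_ug_kg_min=norepi)
    assert score_cardiovascular(map_mmHg, ther).score == expected


@pytest.mark.parametrize(
    "urine,furo,expected",
    [(0.6, 0.0, 0), (0.5, 0.0, 0), (0.4, 0.0, 1), (0.25, 0.0, 1),
     (0.2, 0.0, 2), (0.1, 10.0, 3), (0.1, 20.0, 4), (0.9, 5.0, 3)],
)
def test_renal_thresholds(urine, furo, expected):
    ther = TherapyState(furosemide_cum_mg=furo)
    assert score_renal(urine, ther).score == expected


@pytest.mark.parametrize(
    "bili,expected",
    [(15, 0), (20, 0), (25, 1), (32, 1), (50, 2), (101, 2), (150, 3),
     (204, 3), (250, 4)],
)
def test_liver_thresholds(bili, expected):
    assert score_liver(bili).score == expected


@pytest.mark.parametrize(
    "plate,expected",
    [(250, 0), (200, 0), (180, 1), (150, 1), (120, 2), (100, 2), (80, 3),
     (50, 3), (30, 4), (0, 4)],
)
def test_coagulation_thresholds(plate, expected):
    assert score_coagulation(plate).score == expected


@pytest.mark.parametrize(
    "fn,args",
    [
        (score_respiration, (-1,)),
        (score_respiration, (float("nan"),)),
        (score_liver, (-5,)),
        (score_coagulation, (-1,)),
        (score_cardiovascular, (0,)),
        (score_cardiovascular, (-10,)),
    ],
)
def test_invalid_inputs_rejected(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        TherapyState(norepinephrine_ug_kg_min=-0.1)


def _sample(**kw):
    defaults = dict(time_h=18.0, pao2_fio2=450, map_mmHg=80,
                    urine_output_ml_kg_h=1.0)
    defaults.update(kw)
    return MonitoringSample(**defaults)


class TestComputePsofa:
    def test_best_category_totals_zero(self):
        r = compute_psofa(_sample(bilirubin_umol_L=10, platelets_1e9_L=300))
        assert r.total_3d == 0 and r.total_5d == 0

    def test_worst_category_totals(self):
        r = compute_psofa(
            _sample(pao2_fio2=50, map_mmHg=40, urine_output_ml_kg_h=0.1,
                    bilirubin_umol_L=300, platelets_1e9_L=20),
            TherapyState(norepinephrine_ug_kg_min=0.3, furosemide_cum_mg=30),
        )
        assert r.total_3d == 12 and r.total_5d == 20

    def test_total_is_sum_of_independent_domain_calls(self):
        # 2 + 1 + 1 + 1 + 1 = 6 by summing the five separate calls
        r = compute_psofa(
            _sample(pao2_fio2=250, map_mmHg=70, urine_output_ml_kg_h=0.4,
                    bilirubin_umol_L=25, platelets_1e9_L=180)
        )
        parts = (
            score_respiration(250).score
            + score_cardiovascular(70).score
            + score_renal(0.4).score
            + score_liver(25).score
            + score_coagulation(180).score
        )
        assert parts == 6
        assert r.total_5d == parts
        assert r.total_5d == r.total_3d + r.liver + r.coagulation

    def test_missing_lab_values_flag_3d_only(self):
        r = compute_psofa(_sample(bilirubin_umol_L=25))  # platelets absent
        assert r.three_d_only
        assert r.total_5d is None and r.liver is None

    def test_missing_online_inputs_error(self):
        with pytest.raises(ValueError, match="missing"):
            compute_psofa(MonitoringSample(time_h=18.0, bilirubin_umol_L=25))


class TestScoreTimeseries:
    def _series(self, totals_proxy):
        # urine steps through categories to realize different totals
        return [
            _sample(time_h=16.0 + i, urine_output_ml_kg_h=u)
            for i, u in enumerate(totals_proxy)
        ]

    def test_identical_samples_mean_equals_single_total(self):
        samples = [_sample(time_h=16.0 + i, pao2_fio2=250) for i in range(9)]
        summ = score_timeseries(samples)
        assert summ.mean_3d == 2.0
        assert summ.n_hours == 9

    def test_mean_of_hourly_totals(self):
        # construct hourly totals 1..9 via respiration+cardio+renal mixes
        combos = [  # (pf, map, urine) giving 3D totals 1..9
            (300, 80, 1.0), (300, 70, 1.0), (300, 70, 0.4),
            (250, 70, 0.4), (150, 70, 0.4), (150, 60, 0.4),
            (150, 60, 0.2), (50, 60, 0.2), (50, 40, 0.1),
        ]
        samples = [
            _sample(time_h=16.0 + i, pao2_fio2=pf, map_mmHg=m,
                    urine_output_ml_kg_h=u)
            for i, (pf, m, u) in enumerate(combos)
        ]
        # a drug-free cardiovascular score tops out at 2; the last hour
        # needs norepinephrine to realize a 3D total of 9
        therapies = [TherapyState()] * 8 + [
            TherapyState(norepinephrine_ug_kg_min=0.05)
        ]
        summ = score_timeseries(samples, therapies)
        assert [r.total_3d for r in summ.results] == list(range(1, 10))
        assert summ.mean_3d == pytest.approx(5.0)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            score_timeseries([_sample(time_h=2.0)])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            score_timeseries([_sample(time_h=18.0), _sample(time_h=17.0)])


def test_grid_matches_independent_oracle():
    """Dense threshold-straddling grid agrees with the chain-of-ifs oracle."""
    eps = 1e-9
    pf_grid = np.concatenate([
        np.linspace(0, 500, 2000),
        np.array([100, 200, 300, 400]) + eps,
        np.array([100, 200, 300, 400]) - eps,
    ])
    for pf in pf_grid:
        assert score_respiration(pf).score == oracle_respiration(pf)
    for m in np.concatenate([np.linspace(30, 110, 500),
                             [65 - eps, 65, 75 - eps, 75]]):
        for ne in (0.0, 0.05, 0.1, 0.1 + eps, 0.3):
            got = score_cardiovascular(m, TherapyState(norepinephrine_ug_kg_min=ne))
            assert got.score == oracle_cardiovascular(m, ne)
    for u in np.concatenate([np.linspace(0, 2, 500),
                             [0.25 - eps, 0.25, 0.5 - eps, 0.5]]):
        for f in (0.0, 5.0, 10.0, 10.0 + eps, 20.0):
            got = score_renal(u, TherapyState(furosemide_cum_mg=f))
            assert got.score == oracle_renal(u, f)
    for b in np.concatenate([np.linspace(0, 300, 1000),
                             np.array([20, 32, 101, 204]) + eps,
                             np.array([20, 32, 101, 204])]):
        assert score_liver(b).score == oracle_liver(b)
    for p in np.concatenate([np.linspace(0, 400, 1000),
                             [50, 100, 150, 200],
                             np.array([50, 100, 150, 200]) - eps]):
        assert score_coagulation(p).score == oracle_coagulation(p)


@given(x=st.floats(0, 600), y=st.floats(0, 600))
def test_respiration_monotone(x, y):
    lo, hi = sorted((x, y))
    assert score_respiration(lo).score >= score_respiration(hi).score


@given(x=st.floats(0.01, 150), y=st.floats(0.01, 150),
       ne=st.floats(0, 0.5))
def test_cardiovascular_monotone_in_map_and_dose(x, y, ne):
    lo, hi = sorted((x, y))
    t = TherapyState(norepinephrine_ug_kg_min=ne)
    assert score_cardiovascular(lo, t).score >= score_cardiovascular(hi, t).score
    t2 = TherapyState(norepinephrine_ug_kg_min=ne + 0.05)
    assert score_cardiovascular(lo, t2).score >= score_cardiovascular(lo, t).score


@given(b=st.floats(0, 400), delta=st.floats(0, 100))
def test_liver_monotone(b, delta):
    assert score_liver(b + delta).score >= score_liver(b).score


@given(u=st.floats(0, 2), f=st.floats(0, 30), df=st.floats(0, 30))
def test_renal_monotone_in_furosemide(u, f, df):
    a = score_renal(u, TherapyState(furosemide_cum_mg=f)).score
    b = score_renal(u, TherapyState(furosemide_cum_mg=f + df)).score
    assert b >= a


def test_pig_and_human_modes_agree_where_thresholds_agree():
    # respiration has one shared threshold row; MAP >= 75 is normal in both
    for m in (80, 90, 120):
        assert (
            score_cardiovascular(m, mode="pig").score
            == score_cardiovascular(m, mode="human").score
            == 0
        )
    # heavy norepinephrine scores 4 in both modes
    t = TherapyState(norepinephrine_ug_kg_min=0.5)
    assert (
        score_cardiovascular(60, t, mode="pig").score
        == score_cardiovascular(60, t, mode="human").score
        == 4
    )
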