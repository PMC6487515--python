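"""Transition windowing, matrix estimation, stationarity, Dirichlet."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ratarget as rt
from ratarget.estimation import (
    MissingDataError,
    Transition,
    TransitionModel,
    count_transitions,
)


def _visits(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "visit_day", "das28", "treatment_key"]
    )


class TestWindowTransitions:
    def test_exact_cycle_gap(self):
        v = _visits([("p", 0, 4.0, "A"), ("p", 91, 2.0, "A")])
        out = rt.window_transitions(v)
        assert out == [Transition("A", rt.HealthState.MODERATE,
                                  rt.HealthState.REMISSION, 0.0)]

    def test_gap_outside_window_is_dropped(self):
        v = _visits([("p", 0, 4.0, "A"), ("p", 200, 2.0, "A")])
        assert rt.window_transitions(v) == []

    def test_closest_successor_wins_ties_to_earlier(self):
        # gaps 80 and 102: |80-91| = |102-91| = 11 -> earlier visit paired
        v = _visits([("p", 0, 4.0, "A"), ("p", 80, 2.0, "A"),
                     ("p", 102, 6.0, "A")])
        out = rt.window_transitions(v)
        assert out[0].to_state == rt.HealthState.REMISSION

    def test_key_map_pools_dose_levels(self):
        v = _visits([("p", 0, 4.0, "mtx_15mg"), ("p", 91, 2.0, "mtx_25mg"),
                     ("p", 182, 2.0, "mtx_25mg")])
        out = rt.window_transitions(
            v, treatment_key_map={"mtx_15mg": "mtx", "mtx_25mg": "mtx"})
        assert {t.treatment_key for t in out} == {"mtx"}

    def test_label_is_treatment_at_earlier_visit(self):
        v = _visits([("p", 0, 4.0, "A"), ("p", 91, 2.0, "B")])
        assert rt.window_transitions(v)[0].treatment_key == "A"

    def test_unsorted_input_rejected(self):
        v = _visits([("p", 91, 4.0, "A"), ("p", 0, 2.0, "A")])
        with pytest.raises(ValueError):
            rt.window_transitions(v)

    def test_empty_input(self):
        assert rt.window_transitions(_visits([])) == []

    def test_matches_brute_force_pairing(self):
        """Jittered multi-patient schedule agrees with an O(n^2) oracle."""
        rng = np.random.default_rng(3)
        rows = []
        for pid in range(30):
            day = 0.0
            for v in range(12):
                rows.append((f"p{pid}", day, rng.uniform(0, 8), "A"))
                day += rng.uniform(30, 160)
        v = _visits(rows)
        got = rt.window_transitions(v)

        expected = []
        for pid, grp in v.groupby("patient_id", sort=False):
            days = grp["visit_day"].to_numpy()
            das = grp["das28"].to_numpy()
            for i in range(len(days)):
                best = None
                for j in range(i + 1, len(days)):
                    gap = days[j] - days[i]
                    if 45 <= gap <= 137:
                        if best is None or (abs(gap - 91)
                                            < abs(days[best] - days[i] - 91)):
                            best = j
                if best is not None:
                    expected.append(
                        ("A", rt.classify_das28(das[i]),
                         rt.classify_das28(das[best]), days[i]))
        assert [(t.treatment_key, t.from_state, t.to_state, t.source_day)
                for t in got] == expected


@given(
    days_a=st.lists(st.integers(0, 400), min_size=2, max_size=8, unique=True),
    days_b=st.lists(st.integers(0, 400), min_size=2, max_size=8, unique=True),
)
@settings(deadline=None, max_examples=50)
def test_windowing_never_pairs_across_patients(days_a, days_b):
    rows = [("a", d, 4.0, f"a{d}") for d in sorted(days_a)]
    rows += [("b", d, 4.0, f"b{d}") for d in sorted(days_b)]
    out = rt.window_transitions(_visits(rows))
    for t in out:
        src_patient = t.treatment_key[0]
        src_days = sorted(days_a if src_patient == "a" else days_b)
        assert any(45 <= d2 - t.source_day <= 137 for d2 in src_days)


class TestEstimateMatrices:
    def test_degenerate_row(self):
        ts = [Transition("A", rt.HealthState.REMISSION,
                         rt.HealthState.REMISSION, 0.0)] * 10
        tm = rt.estimate_matrices(ts)
        assert np.allclose(tm.probs["A"][0], [1, 0, 0, 0])

    def test_uniform_row(self):
        ts = [Transition("A", rt.HealthState.LOW, rt.HealthState(j), 0.0)
              for j in range(4) for _ in range(2)]
        tm = rt.estimate_matrices(ts)
        assert np.allclose(tm.probs["A"][1], [0.25] * 4)

    def test_missing_key_named_in_error(self):
        ts = [Transition("A", rt.HealthState.LOW,
                         rt.HealthState.LOW, 0.0)] * 3
        with pytest.raises(MissingDataError, match="B"):
            rt.estimate_matrices(ts, required_keys=["A", "B"])

    def test_recovers_known_matrix(self):
        """2,000 multinomial transitions per row reproduce the matrix to
        within 0.05 max absolute error."""
        rng = np.random.default_rng(42)
        truth = np.array([
            [0.7, 0.2, 0.08, 0.02],
            [0.3, 0.4, 0.2, 0.1],
            [0.1, 0.3, 0.4, 0.2],
            [0.05, 0.15, 0.3, 0.5],
        ])
        ts = []
        for r in range(4):
            dest = rng.choice(4, size=2000, p=truth[r])
            ts += [Transition("K", rt.HealthState(r), rt.HealthState(int(d)),
                              0.0) for d in dest]
        tm = rt.estimate_matrices(ts)
        assert np.abs(tm.probs["K"] - truth).max() < 0.05

    def test_row_sums_and_roundtrip(self, fitted):
        tm = fitted.transition_model
        for key in tm.keys:
            assert np.allclose(tm.probs[key].sum(axis=1), 1.0, atol=1e-12)
        back = TransitionModel.from_frame(tm.to_frame())
        for key in tm.keys:
            assert np.allclose(back.probs[key], tm.probs[key])
            assert np.allclose(back.counts[key], tm.counts[key])


class TestStationarity:
    def _transitions(self, dests_before, dests_after, from_state=1):
        ts = []
        for d in dests_before:
            ts.append(Transition("A", rt.HealthState(from_state),
                                 rt.HealthState(d), 0.0))
        for d in dests_after:
            ts.append(Transition("A", rt.HealthState(from_state),
                                 rt.HealthState(d), 100.0))
        return ts

    def test_identical_halves_give_zero_statistic(self):
        dests = [0] * 10 + [1] * 10 + [2] * 10
        df = rt.stationarity_test(self._transitions(dests, dests),
                                  split_day=50)
        row = df.iloc[0]
        assert row["statistic"] == pytest.approx(0.0)
        assert row["pvalue"] == pytest.approx(1.0)

    def test_hand_computed_pearson_statistic(self):
        """Collapsed 2x2 table [[10,0],[0,10]] has chi-square 20."""
        df = rt.stationarity_test(
            self._transitions([0] * 10, [1] * 10), split_day=50)
        assert df.iloc[0]["statistic"] == pytest.approx(20.0)
        assert df.iloc[0]["df"] == 1

    def test_one_sided_split_flagged(self):
        df = rt.stationarity_test(self._transitions([0] * 10, []),
                                  split_day=50)
        assert bool(df.iloc[0]["flagged"])

    def test_type_i_error_rate_near_nominal(self):
        """Time-homogeneous data rejects at ~5% across 500 replicates."""
        rng = np.random.default_rng(2024)
        p = np.array([0.4, 0.3, 0.2, 0.1])
        rejections = 0
        tested = 0
        for _ in range(500):
            before = rng.choice(4, size=120, p=p)
            after = rng.choice(4, size=120, p=p)
            ts = self._transitions(before, after)
            row = rt.stationarity_test(ts, split_day=50).iloc[0]
            if not row["flagged"]:
                tested += 1
                rejections += row["pvalue"] < 0.05
        assert tested > 400
        assert 0.02 <= rejections / tested <= 0.08


class TestDirichletParams:
    def test_identity_mapping_with_zero_prior(self):
        counts = np.zeros((4, 4))
        counts[0] = [8, 1, 1, 0]
        counts[1:] = 1
        conc = rt.dirichlet_params(counts, prior_per_cell=0)
        assert np.allclose(conc[0], [8, 1, 1, 0])

    def test_zero_row_zero_prior_rejected(self):
        with pytest.raises(ValueError):
            rt.dirichlet_params(np.zeros((4, 4)), prior_per_cell=0)

    def test_monte_carlo_mean_matches_closed_form(self):
        rng = np.random.default_rng(9)
        alpha = np.array([8.0, 1.0, 1.0, 0.0])
        draws = np.stack([
            rt.psa._dirichlet_row(alpha, rng) for _ in range(10_000)])
        mean = alpha / alpha.sum()
        var = mean * (1 - mean) / (alpha.sum() + 1)
        se = np.sqrt(var / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - mean) <= 3 * se + 1e-12)
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_more_data_means_less_uncertainty(self):
        def var_first(alpha):
            a = np.asarray(alpha, dtype=float)
            m = a / a.sum()
            return m[0] * (1 - m[0]) / (a.sum() + 1)

        assert var_first([80, 10, 10, 0]) < var_first([8, 1, 1, 0])
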