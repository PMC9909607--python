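"""Outcome measures: LDI, REC, d', validity filters and bin curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from mstkit.scoring import (
    LOG_COLUMNS,
    ResponseLog,
    ScoreReport,
    bin_curve,
    dprime,
    ldi,
    rec,
    score_session,
    tabulate,
    validity_filter,
)


def _make_log(condition_responses, prompt="OSN", lure_bins=None):
    """Build a test-phase log from {condition: [responses...]}."""
    rows = []
    idx = 0
    for cond, responses in condition_responses.items():
        for j, resp in enumerate(responses):
            rows.append(
                {
                    "trial_index": idx,
                    "phase": "test",
                    "condition": cond,
                    "set_id": 1,
                    "pair_id": idx + 1,
                    "exemplar": "b" if cond == "lure" else "a",
                    "lure_bin": (
                        lure_bins[j] if (lure_bins and cond == "lure") else 3
                    ),
                    "lag": np.nan,
                    "response": resp,
                    "rt_ms": 900.0,
                }
            )
            idx += 1
    return ResponseLog(trials=pd.DataFrame(rows, columns=LOG_COLUMNS), prompt=prompt)


class TestLdiRec:
    def test_ldi_from_exact_counts(self):
        # 22/44 "similar" to lures, 2/20 "similar" to foils -> 0.40
        log = _make_log(
            {
                "lure": ["similar"] * 22 + ["new"] * 22,
                "foil": ["similar"] * 2 + ["new"] * 18,
                "repeat": ["old"] * 20,
            }
        )
        assert ldi(tabulate(log)) == pytest.approx(0.40)

    def test_ldi_zero_when_rates_identical(self):
        log = _make_log(
            {
                "lure": ["similar"] * 5 + ["new"] * 5,
                "foil": ["similar"] * 5 + ["new"] * 5,
                "repeat": ["old"] * 4,
            }
        )
        assert ldi(tabulate(log)) == pytest.approx(0.0)

    def test_ldi_maximum_is_one(self):
        log = _make_log(
            {"lure": ["similar"] * 10, "foil": ["new"] * 10, "repeat": ["old"] * 4}
        )
        assert ldi(tabulate(log)) == pytest.approx(1.0)

    def test_rec_from_exact_counts(self):
        log = _make_log(
            {
                "repeat": ["old"] * 18 + ["new"] * 2,
                "foil": ["old"] * 1 + ["new"] * 19,
                "lure": ["similar"] * 4,
            }
        )
        assert rec(tabulate(log)) == pytest.approx(0.85)

    def test_rec_perfect_performance(self):
        log = _make_log(
            {"repeat": ["old"] * 8, "foil": ["new"] * 8, "lure": ["similar"] * 4}
        )
        assert rec(tabulate(log)) == pytest.approx(1.0)

    def test_ldi_requires_osn(self):
        log = _make_log(
            {"repeat": ["old"] * 4, "foil": ["new"] * 4, "lure": ["new"] * 4},
            prompt="ON",
        )
        with pytest.raises(ValueError, match="OSN"):
            ldi(tabulate(log))

    def test_first_trials_serve_as_foils_in_continuous_logs(self):
        log = _make_log(
            {
                "repeat": ["old"] * 9 + ["new"],
                "first": ["similar"] * 2 + ["new"] * 18,
                "lure": ["similar"] * 5 + ["new"] * 5,
            }
        )
        rates = tabulate(log)
        assert rec(rates) == pytest.approx(0.9 - 0.0)
        assert ldi(rates) == pytest.approx(0.5 - 0.1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_order_and_pair_id_invariance(self, seed):
        rng = np.random.default_rng(seed)
        log = _make_log(
            {
                "lure": list(rng.choice(["old", "similar", "new"], 20)),
                "foil": list(rng.choice(["old", "similar", "new"], 12)),
                "repeat": list(rng.choice(["old", "similar", "new"], 12)),
            }
        )
        base_ldi, base_rec = ldi(tabulate(log)), rec(tabulate(log))
        df = log.trials.sample(frac=1, random_state=seed).reset_index(drop=True)
        df["pair_id"] = rng.permutation(len(df)) + 1000
        shuffled = ResponseLog(trials=df, prompt="OSN")
        assert ldi(tabulate(shuffled)) == pytest.approx(base_ldi)
        assert rec(tabulate(shuffled)) == pytest.approx(base_rec)


class TestDprime:
    def test_matches_normal_quantile_oracle(self):
        assert dprime(0.8, 0.2) == pytest.approx(2 * norm.ppf(0.8), abs=1e-9)

    def test_no_discriminability_at_equal_rates(self):
        assert dprime(0.37, 0.37) == pytest.approx(0.0)

    def test_extreme_rate_uses_half_count_adjustment(self):
        # hit 1.0 with 20 signal trials -> treated as 1 - 1/40 = 0.975
        expected = norm.ppf(0.975) - norm.ppf(0.5)
        assert dprime(1.0, 0.5, n_signal=20, n_noise=20) == pytest.approx(expected)

    def test_extreme_rate_without_count_is_an_error(self):
        with pytest.raises(ValueError, match="trial count"):
            dprime(1.0, 0.5)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            dprime(1.2, 0.5)


class TestTabulate:
    def test_counts_reconcile_exactly_with_raw_log(self):
        log = _make_log(
            {
                "lure": ["similar"] * 3 + ["old"] * 2 + ["none"],
                "foil": ["new"] * 4,
                "repeat": ["old"] * 5,
            }
        )
        rates = tabulate(log)
        assert int(rates.counts.loc["lure", "similar"]) == 3
        assert int(rates.counts.loc["lure", "old"]) == 2
        assert int(rates.counts.loc["lure", "none"]) == 1
        assert int(rates.counts.to_numpy().sum()) == 15
        assert int(rates.n_omitted.loc["lure"]) == 1

    def test_omission_policies_differ_only_in_denominator(self):
        log = _make_log(
            {
                "lure": ["similar"] * 4 + ["none"] * 4,
                "foil": ["new"] * 4,
                "repeat": ["old"] * 4,
            }
        )
        excl = tabulate(log, omission="exclude")
        as_new = tabulate(log, omission="count-as-new")
        assert excl.rate("lure", "similar") == pytest.approx(1.0)
        assert as_new.rate("lure", "similar") == pytest.approx(0.5)
        assert as_new.rate("lure", "new") == pytest.approx(0.5)

    def test_study_phase_trials_are_not_tabulated(self, full_st):
        responses = ["none"] * len(full_st.trials)
        for i, t in enumerate(full_st.trials):
            if t.phase == "test":
                responses[i] = "new"
        log = ResponseLog.from_schedule(full_st, responses)
        rates = tabulate(log)
        assert int(rates.counts.to_numpy().sum()) == 192


class TestValidity:
    def _report(self, **kw):
        base = dict(
            participant="p", variant="v", prompt="OSN", session=1,
            ldi=0.3, rec=None, dprime_tl=None, dprime_tf=None,
        )
        base.update(kw)
        return ScoreReport(**base)

    def test_rec_just_below_threshold_is_invalid(self):
        ok, reason = validity_filter(self._report(rec=0.49))
        assert not ok and "REC" in reason

    def test_rec_threshold_is_inclusive(self):
        ok, _ = validity_filter(self._report(rec=0.5))
        assert ok

    def test_on_prompt_uses_dprime_tf(self):
        ok, _ = validity_filter(self._report(prompt="ON", dprime_tf=1.6))
        assert ok
        bad, reason = validity_filter(self._report(prompt="ON", dprime_tf=1.49))
        assert not bad and "TF" in reason

    def test_thresholds_are_configurable(self):
        ok, _ = validity_filter(self._report(rec=0.3), rec_threshold=0.25)
        assert ok


class TestScoreSession:
    def test_osn_report_has_all_metrics_and_collapsed_dprimes(self):
        log = _make_log(
            {
                "repeat": ["old"] * 18 + ["similar"] * 2,
                "lure": ["similar"] * 10 + ["old"] * 5 + ["new"] * 5,
                "foil": ["new"] * 19 + ["old"],
            }
        )
        rep = score_session(log)
        assert rep.ldi == pytest.approx(10 / 20 - 0 / 20)
        assert rep.rec == pytest.approx(18 / 20 - 1 / 20)
        # collapsed ON view: similar -> new
        assert rep.dprime_tl == pytest.approx(
            norm.ppf(18 / 20) - norm.ppf(5 / 20)
        )
        assert rep.dprime_tf is not None and rep.valid

    def test_similar_overuse_is_flagged_not_dropped(self):
        log = _make_log(
            {
                "repeat": ["similar"] * 18 + ["old"] * 2,
                "lure": ["similar"] * 20,
                "foil": ["similar"] * 20,
            }
        )
        rep = score_session(log)
        assert rep.similar_use_flag
        assert rep.ldi is not None  # still scored

    def test_illegal_response_under_on_prompt_names_row(self):
        df = _make_log(
            {"repeat": ["old"] * 3, "foil": ["new"] * 3, "lure": ["new"] * 3}
        ).trials
        df.loc[4, "response"] = "similar"
        with pytest.raises(ValueError, match="row 4"):
            ResponseLog(trials=df, prompt="ON")


class TestBinCurve:
    def test_per_bin_rates_computed_without_enforcing_monotonicity(self):
        bins = [1] * 4 + [2] * 4 + [3] * 4
        # deliberately non-monotone responding: computed as-is
        responses = (
            ["old"] * 1 + ["new"] * 3
            + ["old"] * 3 + ["new"] * 1
            + ["old"] * 2 + ["similar"] * 2
        )
        log = _make_log(
            {"lure": responses, "foil": ["new"] * 4, "repeat": ["old"] * 4},
            lure_bins=bins,
        )
        old_curve, sim_curve = bin_curve(log)
        assert old_curve == {1: 0.25, 2: 0.75, 3: 0.5}
        assert sim_curve[3] == 0.5
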