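"""Scoring of MST response logs into the task's outcome measures.

The primary outcome of the three-choice (old/similar/new, OSN) task is
the **Lure Discrimination Index**::

    LDI = p("similar" | lure) - p("similar" | foil)

a bias-corrected index of how often similar lures are correctly
recognised as merely similar.  The secondary measure is corrected
recognition::

    REC = p("old" | repeat) - p("old" | foil)

Under the two-choice (old/new, ON) prompt a signal-detection framework
is used instead: ``d'(TL)`` indexes repeat-vs-lure discriminability
(hits = "old"|repeat, false alarms = "old"|lure) and ``d'(TF)`` indexes
repeat-vs-foil discriminability (false alarms = "old"|foil).

In the continuous format first presentations serve as the novel foils,
so wherever a "foil" condition is referenced below, ``first`` trials
stand in when no ``foil`` trials exist.

Engagement filtering: OSN sessions are valid when REC >= 0.5; ON
sessions when d'(TF) >= 1.5 (thresholds configurable, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sequencer import TrialSchedule

__all__ = [
    "ResponseLog",
    "RateTable",
    "ScoreReport",
    "tabulate",
    "ldi",
    "rec",
    "dprime",
    "score_session",
    "validity_filter",
    "bin_curve",
    "REC_THRESHOLD",
    "DPRIME_TF_THRESHOLD",
    "SIMILAR_USE_RANGE",
]

RESPONSES = ("old", "similar", "new", "none")
OSN_RESPONSES = frozenset({"old", "similar", "new", "none"})
ON_RESPONSES = frozenset({"old", "new", "none"})

#: Default validity thresholds (inclusive).
REC_THRESHOLD = 0.5
DPRIME_TF_THRESHOLD = 1.5
#: Overall p("similar") outside this range flags a session for review
#: (extreme over/under-use of the middle response; flag only, never
#: an automatic exclusion).
SIMILAR_USE_RANGE = (0.05, 0.90)

OmissionPolicy = Literal["exclude", "count-as-new"]

LOG_COLUMNS = [
    "trial_index", "phase", "condition", "set_id", "pair_id",
    "exemplar", "lure_bin", "lag", "response", "rt_ms",
]


@dataclass
class ResponseLog:
    """Per-trial responses joined to schedule metadata.

    ``trials`` is a DataFrame with columns ``trial_index, phase,
    condition, set_id, pair_id, exemplar, lure_bin, lag, response,
    rt_ms`` (``lag``/``rt_ms`` may be missing/NaN).
    """

    trials: pd.DataFrame
    participant: str = ""
    variant: str = ""
    prompt: str = "OSN"
    session: int = 1

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"response log missing columns {missing}")
        allowed = OSN_RESPONSES if self.prompt == "OSN" else ON_RESPONSES
        resp = self.trials["response"]
        bad = ~resp.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"illegal response {resp.iloc[row]!r} under {self.prompt} "
                f"prompt at row {row}"
            )

    @property
    def scored(self) -> pd.DataFrame:
        return self.trials[
            self.trials["phase"].isin(("study", "test", "continuous"))
        ]

    @classmethod
    def from_schedule(
        cls,
        schedule: TrialSchedule,
        responses,
        rts=None,
        participant: str = "",
        session: int = 1,
    ) -> "ResponseLog":
        """Join responses (one per trial, schedule order) to a schedule."""
        trials = schedule.trials
        responses = list(responses)
        if len(responses) != len(trials):
            raise ValueError(
                f"{len(responses)} responses for {len(trials)} trials"
            )
        rts = list(rts) if rts is not None else [np.nan] * len(trials)
        template = getattr(schedule, "_log_template", None)
        if template is None:
            template = pd.DataFrame(
                {
                    "trial_index": [t.index for t in trials],
                    "phase": [t.phase for t in trials],
                    "condition": [t.condition for t in trials],
                    "set_id": [t.pair.set_id for t in trials],
                    "pair_id": [t.pair.pair_id for t in trials],
                    "exemplar": [t.exemplar for t in trials],
                    "lure_bin": [t.pair.lure_bin for t in trials],
                    "lag": [t.lag for t in trials],
                }
            )
            schedule._log_template = template  # cache: schedules are reused
        df = template.copy()
        df["response"] = responses
        df["rt_ms"] = rts
        return cls(
            trials=df,
            variant=schedule.variant_label,
            prompt=schedule.design.prompt,
            participant=participant,
            session=session,
        )


@dataclass
class RateTable:
    """Response counts and rates per scored test condition.

    ``counts`` has one row per condition (``repeat``, ``lure``,
    ``foil``/``first``) and one column per response including ``none``;
    ``rates`` are over emitted responses only under the default
    omission policy, so each row sums to 1 when any response was made.
    """

    counts: pd.DataFrame
    rates: pd.DataFrame
    n_scored: pd.Series
    n_omitted: pd.Series
    prompt: str = "OSN"
    omission_policy: OmissionPolicy = "exclude"

    def rate(self, condition: str, response: str) -> float:
        if condition == "foil" and condition not in self.rates.index:
            condition = "first"  # continuous format: firsts are the foils
        if condition not in self.rates.index:
            raise ValueError(f"no {condition!r} trials in this log")
        return float(self.rates.loc[condition, response])

    def n(self, condition: str) -> int:
        if condition == "foil" and condition not in self.n_scored.index:
            condition = "first"
        return int(self.n_scored.loc[condition])


def tabulate(
    log: ResponseLog, omission: OmissionPolicy = "exclude"
) -> RateTable:
    """Tally responses by test condition.

    Study-phase (encoding) trials and practice trials are not test
    probes and are excluded.  Omitted responses (``none``) are tallied
    separately; under ``omission="exclude"`` rates are computed over
    emitted responses, under ``"count-as-new"`` omissions count as
    "new" responses.
    """
    df = log.scored
    df = df[df["condition"].isin(("repeat", "lure", "foil", "first"))]
    conds = ("repeat", "lure", "foil", "first")
    cond_code = df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()
    resp_code = df["response"].map(
        {r: i for i, r in enumerate(RESPONSES)}
    ).to_numpy()
    flat = np.bincount(
        cond_code * len(RESPONSES) + resp_code,
        minlength=len(conds) * len(RESPONSES),
    ).reshape(len(conds), len(RESPONSES))
    present = [i for i, c in enumerate(conds) if flat[i].sum() > 0]
    counts = pd.DataFrame(
        flat[present],
        index=pd.Index([conds[i] for i in present], name="condition"),
        columns=list(RESPONSES),
    )

    effective = counts.copy()
    if omission == "count-as-new":
        effective["new"] = effective["new"] + effective["none"]
        effective["none"] = 0
    elif omission != "exclude":
        raise ValueError(f"unknown omission policy {omission!r}")

    emitted = effective[["old", "similar", "new"]]
    denom = emitted.sum(axis=1)
    rates = emitted.div(denom.where(denom > 0), axis=0).fillna(0.0)
    return RateTable(
        counts=counts,
        rates=rates,
        n_scored=denom.astype(int),
        n_omitted=counts["none"].astype(int),
        prompt=log.prompt,
        omission_policy=omission,
    )


def ldi(rates: RateTable) -> float:
    """Lure Discrimination Index: p(similar|lure) - p(similar|foil)."""
    if rates.prompt != "OSN":
        raise ValueError("LDI is defined for the OSN prompt only")
    for cond in ("lure", "foil"):
        if rates.n(cond) < 1:
            raise ValueError(f"no scored {cond} trials")
    return rates.rate("lure", "similar") - rates.rate("foil", "similar")


def rec(rates: RateTable) -> float:
    """Corrected recognition: p(old|repeat) - p(old|foil)."""
    for cond in ("repeat", "foil"):
        if rates.n(cond) < 1:
            raise ValueError(f"no scored {cond} trials")
    return rates.rate("repeat", "old") - rates.rate("foil", "old")


def dprime(
    hit_rate: float,
    fa_rate: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> float:
    """Equal-variance signal-detection d' = z(hit) - z(fa).

    Extreme rates are adjusted with the standard 1/(2N) correction
    (0 -> 1/(2N), 1 -> 1 - 1/(2N)), which requires the trial counts.
    """
    def adjust(rate: float, n: int | None, name: str) -> float:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if rate in (0.0, 1.0):
            if n is None or n < 1:
                raise ValueError(
                    f"{name}={rate} needs its trial count for the 1/(2N) "
                    "extreme-rate adjustment"
                )
            return 1 - 1 / (2 * n) if rate == 1.0 else 1 / (2 * n)
        return rate

    h = adjust(hit_rate, n_signal, "hit_rate")
    f = adjust(fa_rate, n_noise, "fa_rate")
    return float(norm.ppf(h) - norm.ppf(f))


@dataclass
class ScoreReport:
    """All outcome measures for one session."""

    participant: str
    variant: str
    prompt: str
    session: int
    ldi: float | None
    rec: float | None
    dprime_tl: float | None
    dprime_tf: float | None
    per_bin_old_rate: dict[int, float] = field(default_factory=dict)
    per_bin_similar_rate: dict[int, float] = field(default_factory=dict)
    valid: bool = True
    reason: str = ""
    similar_use_flag: bool = False
    counts: Mapping | None = None

    def to_dict(self) -> dict:
        d = {
            "participant": self.participant,
            "variant": self.variant,
            "prompt": self.prompt,
            "session": self.session,
            "ldi": self.ldi,
            "rec": self.rec,
            "dprime_tl": self.dprime_tl,
            "dprime_tf": self.dprime_tf,
            "per_bin_old_rate": {str(k): v for k, v in self.per_bin_old_rate.items()},
            "per_bin_similar_rate": {
                str(k): v for k, v in self.per_bin_similar_rate.items()
            },
            "valid": self.valid,
            "reason": self.reason,
            "similar_use_flag": self.similar_use_flag,
        }
        if self.counts is not None:
            d["counts"] = {
                cond: {r: int(v) for r, v in row.items()}
                for cond, row in self.counts.items()
            }
        return d


def _collapsed_on_rates(rates: RateTable) -> RateTable:
    """Map "similar" -> "new" to obtain the ON-equivalent rate table."""
    counts = rates.counts.copy()
    counts["new"] = counts["new"] + counts["similar"]
    counts["similar"] = 0
    emitted = counts[["old", "similar", "new"]]
    denom = emitted.sum(axis=1)
    collapsed = emitted.div(denom.where(denom > 0), axis=0).fillna(0.0)
    return RateTable(
        counts=counts,
        rates=collapsed,
        n_scored=rates.n_scored,
        n_omitted=rates.n_omitted,
        prompt="ON",
        omission_policy=rates.omission_policy,
    )


def bin_curve(log: ResponseLog) -> tuple[dict[int, float], dict[int, float]]:
    """Per-lure-bin response rates to lure trials.

    Returns ``(old_rate_by_bin, similar_rate_by_bin)``; the similar
    curve is empty for ON logs.  Monotonicity over bins is an empirical
    property of participants and is computed, never enforced.
    """
    df = log.scored
    lures = df[(df["condition"] == "lure") & (df["response"] != "none")]
    bins = lures["lure_bin"].to_numpy(dtype=int)
    resp = lures["response"].to_numpy()
    n_by_bin = np.bincount(bins, minlength=6)
    old_by_bin = np.bincount(bins, weights=(resp == "old"), minlength=6)
    sim_by_bin = np.bincount(bins, weights=(resp == "similar"), minlength=6)
    old_curve: dict[int, float] = {}
    sim_curve: dict[int, float] = {}
    for b in range(1, 6):
        if n_by_bin[b]:
            old_curve[b] = float(old_by_bin[b] / n_by_bin[b])
            if log.prompt == "OSN":
                sim_curve[b] = float(sim_by_bin[b] / n_by_bin[b])
    return old_curve, sim_curve


def validity_filter(
    report: ScoreReport,
    prompt: str | None = None,
    rec_threshold: float = REC_THRESHOLD,
    dprime_tf_threshold: float = DPRIME_TF_THRESHOLD,
) -> tuple[bool, str]:
    """Engagement check: OSN needs REC >= threshold, ON needs d'(TF) >=
    threshold.  Thresholds are inclusive."""
    prompt = prompt or report.prompt
    if prompt == "OSN":
        if report.rec is None:
            return False, "REC unavailable"
        ok = report.rec >= rec_threshold
        return ok, "" if ok else f"REC {report.rec:.3f} < {rec_threshold}"
    if report.dprime_tf is None:
        return False, "d'(TF) unavailable"
    ok = report.dprime_tf >= dprime_tf_threshold
    return ok, "" if ok else (
        f"d'(TF) {report.dprime_tf:.3f} < {dprime_tf_threshold}"
    )


def score_session(
    log: ResponseLog, omission: OmissionPolicy = "exclude"
) -> ScoreReport:
    """Compute every applicable outcome measure for one session.

    OSN sessions get LDI and REC plus the d' measures computed from the
    collapsed (similar -> new) responses, which makes OSN sessions
    comparable to ON ones; ON sessions get the d' measures only.
    """
    rates = tabulate(log, omission=omission)
    on_rates = _collapsed_on_rates(rates) if log.prompt == "OSN" else rates

    ldi_val = rec_val = None
    if log.prompt == "OSN":
        ldi_val = ldi(rates)
        rec_val = rec(rates)

    hit = on_rates.rate("repeat", "old")
    d_tl = dprime(
        hit, on_rates.rate("lure", "old"),
        on_rates.n("repeat"), on_rates.n("lure"),
    )
    d_tf = dprime(
        hit, on_rates.rate("foil", "old"),
        on_rates.n("repeat"), on_rates.n("foil"),
    )

    old_curve, sim_curve = bin_curve(log)

    test = log.scored
    test = test[test["condition"].isin(("repeat", "lure", "foil", "first"))]
    emitted = test[test["response"] != "none"]
    p_sim = (
        float((emitted["response"] == "similar").mean())
        if log.prompt == "OSN" and len(emitted)
        else 0.0
    )
    lo, hi = SIMILAR_USE_RANGE
    sim_flag = log.prompt == "OSN" and not (lo <= p_sim <= hi)

    report = ScoreReport(
        participant=log.participant,
        variant=log.variant,
        prompt=log.prompt,
        session=log.session,
        ldi=ldi_val,
        rec=rec_val,
        dprime_tl=d_tl,
        dprime_tf=d_tf,
        per_bin_old_rate=old_curve,
        per_bin_similar_rate=sim_curve,
        similar_use_flag=sim_flag,
        counts=rates.counts.to_dict(orient="index"),
    )
    report.valid, report.reason = validity_filter(report)
    return report


def reports_to_long(reports) -> pd.DataFrame:
    """Long-format export `participant,session,variant,metric,value`
    for downstream mixed-model analysis."""
    rows = []
    for r in reports:
        for metric in ("ldi", "rec", "dprime_tl", "dprime_tf"):
            val = getattr(r, metric)
            if val is not None:
                rows.append(
                    {
                        "participant": r.participant,
                        "session": r.session,
                        "variant": r.variant,
                        "metric": metric,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows, columns=["participant", "session", "variant", "metric", "value"])
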