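"""File formats, run configuration, fixtures and experiment replays.

All formats are plain text: CSV (comma-separated, UTF-8, header
required, no quoting of numerics) and JSON with snake_case keys that
match the CSV headers exactly.

* bank CSV             ``set_id,pair_id,lure_bin``
* schedule CSV         ``trial_index,phase,condition,set_id,pair_id,
                       exemplar,lure_bin,lag,guided`` (lag empty when
                       undefined); a JSON mirror carries the design
                       spec for provenance
* response-log CSV     schedule columns + ``response,rt_ms``; a
                       jsPsych-style JSON dialect (an array of trial
                       objects with the same keys, optionally wrapped
                       in ``{"metadata": ..., "trials": [...]}``) is
                       read to the identical in-memory log
* score-report JSON    all ScoreReport fields plus raw counts
* paired-scores CSV    ``participant,baseline,variant``
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .psychometrics import (
    DEFAULT_CONVERSION_INTERCEPT,
    DEFAULT_CONVERSION_SLOPE,
    PairedScores,
    fisher_compare,
    robust_fit_with_outliers,
)
from .scoring import LOG_COLUMNS, ResponseLog, ScoreReport, score_session
from .sequencer import (
    DesignSpec,
    LagBand,
    PracticeSpec,
    TimingSpec,
    TrialSchedule,
    Trial,
    build_schedule,
    design_variant,
)
from .simulator import (
    CohortSimParams,
    older_adult_cohort,
    simulate_cohort,
    young_adult_cohort,
)
from .stimulus_bank import StimulusPair, make_synthetic_bank

__all__ = [
    "RunConfig",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_schedule_json",
    "read_schedule_json",
    "write_log_csv",
    "read_log_csv",
    "read_log_json",
    "write_log_json",
    "write_report_json",
    "read_paired_csv",
    "write_paired_csv",
    "make_fixtures",
    "experiment_replay",
    "EXPERIMENTS",
]


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Default thresholds and constants, overridable per run.

    Round-trips losslessly through JSON (`save`/`load`).
    """

    seed: int = 0
    rec_threshold: float = scoring.REC_THRESHOLD
    dprime_tf_threshold: float = scoring.DPRIME_TF_THRESHOLD
    rout_q: float = 0.01
    conversion_slope: float = DEFAULT_CONVERSION_SLOPE
    conversion_intercept: float = DEFAULT_CONVERSION_INTERCEPT
    stim_duration_s: float = 2.0
    min_isi_s: float = 0.5
    min_trial_s: float = 2.5
    assumed_response_latency_s: float = 1.5
    omission_policy: str = "exclude"

    def timing(self) -> TimingSpec:
        return TimingSpec(
            stim_duration_s=self.stim_duration_s,
            min_isi_s=self.min_isi_s,
            min_trial_s=self.min_trial_s,
            assumed_response_latency_s=self.assumed_response_latency_s,
        )

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Schedule files

SCHEDULE_COLUMNS = [
    "trial_index", "phase", "condition", "set_id", "pair_id",
    "exemplar", "lure_bin", "lag", "guided",
]


def write_schedule_csv(schedule: TrialSchedule, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_NONE)
        w.writerow(SCHEDULE_COLUMNS)
        for t in schedule.trials:
            w.writerow(
                [
                    t.index, t.phase, t.condition, t.pair.set_id,
                    t.pair.pair_id, t.exemplar, t.pair.lure_bin,
                    "" if t.lag is None else t.lag,
                    "true" if t.guided else "false",
                ]
            )


def _parse_int(value: str, col: str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"line {line}: non-integer {col} value {value!r}") from None


def _read_schedule_rows(rows, source: str) -> list[Trial]:
    trials = []
    for ln, row in rows:
        if isinstance(row, dict):
            get = row.get
        else:
            get = dict(zip(SCHEDULE_COLUMNS, row)).get
        lag_raw = get("lag")
        lag = (
            None
            if lag_raw in (None, "", "NA")
            else _parse_int(str(lag_raw), "lag", ln)
        )
        guided_raw = str(get("guided", "false")).lower()
        if guided_raw not in ("true", "false"):
            raise ValueError(f"line {ln}: guided must be true/false")
        trials.append(
            Trial(
                index=_parse_int(str(get("trial_index")), "trial_index", ln),
                phase=str(get("phase")),
                condition=str(get("condition")),
                pair=StimulusPair(
                    _parse_int(str(get("set_id")), "set_id", ln),
                    _parse_int(str(get("pair_id")), "pair_id", ln),
                    _parse_int(str(get("lure_bin")), "lure_bin", ln),
                ),
                exemplar=str(get("exemplar")),
                lag=lag,
                guided=guided_raw == "true",
            )
        )
    return trials


def read_schedule_csv(path, design: DesignSpec | None = None) -> TrialSchedule:
    """Read a schedule CSV.  Without a design spec, a permissive spec
    is reconstructed from the trial counts."""
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header != SCHEDULE_COLUMNS:
            raise ValueError(
                f"schedule CSV header must be {','.join(SCHEDULE_COLUMNS)}"
            )
        trials = _read_schedule_rows(
            ((ln, row) for ln, row in enumerate(r, start=2)), str(path)
        )
    if design is None:
        design = _infer_design(trials)
    return TrialSchedule(design=design, trials=trials, variant_label=design.label)


def _infer_design(trials: list[Trial]) -> DesignSpec:
    scored = [t for t in trials if t.phase in ("study", "test", "continuous")]
    counts: dict[str, int] = {}
    for t in scored:
        counts[t.condition] = counts.get(t.condition, 0) + 1
    continuous = any(t.phase == "continuous" for t in scored)
    if continuous:
        return DesignSpec(
            format="continuous",
            n_repeat=counts.get("repeat", 1),
            n_lure=counts.get("lure", 1),
            n_foil=None,
            n_first=counts.get("first", 1),
        )
    return DesignSpec(
        format="study_test",
        n_repeat=counts.get("repeat", 1),
        n_lure=counts.get("lure", 1),
        n_foil=counts.get("foil", 0),
    )


def _design_to_dict(spec: DesignSpec) -> dict:
    d = {
        "format": spec.format,
        "prompt": spec.prompt,
        "n_repeat": spec.n_repeat,
        "n_lure": spec.n_lure,
        "n_foil": spec.n_foil,
        "n_study": spec.n_study,
        "n_first": spec.n_first,
        "repeat_lags": [[b.lo, b.hi, b.n] for b in spec.repeat_lags],
        "lure_lags": [[b.lo, b.hi, b.n] for b in spec.lure_lags],
        "practice": (
            None
            if spec.practice is None
            else asdict(spec.practice)
        ),
        "timing": asdict(spec.timing),
        "seed": spec.seed,
        "label": spec.label,
    }
    return d


def design_from_dict(d: dict) -> DesignSpec:
    return DesignSpec(
        format=d["format"],
        prompt=d.get("prompt", "OSN"),
        n_repeat=d["n_repeat"],
        n_lure=d["n_lure"],
        n_foil=d.get("n_foil"),
        n_study=d.get("n_study") if d["format"] == "study_test" else None,
        n_first=d.get("n_first") if d["format"] == "continuous" else None,
        repeat_lags=tuple(LagBand(*b) for b in d.get("repeat_lags", [])),
        lure_lags=tuple(LagBand(*b) for b in d.get("lure_lags", [])),
        practice=(
            None if d.get("practice") is None else PracticeSpec(**d["practice"])
        ),
        timing=TimingSpec(**d.get("timing", {})),
        seed=d.get("seed", 0),
        label=d.get("label", ""),
    )


def write_schedule_json(schedule: TrialSchedule, path) -> None:
    """JSON mirror of a schedule, carrying the full design spec."""
    payload = {
        "design": _design_to_dict(schedule.design),
        "variant_label": schedule.variant_label,
        "set_ids": list(schedule.set_ids),
        "trials": [
            {
                "trial_index": t.index,
                "phase": t.phase,
                "condition": t.condition,
                "set_id": t.pair.set_id,
                "pair_id": t.pair.pair_id,
                "exemplar": t.exemplar,
                "lure_bin": t.pair.lure_bin,
                "lag": t.lag,
                "guided": t.guided,
            }
            for t in schedule.trials
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=1) + "\n", encoding="utf-8"
    )


def read_schedule_json(path) -> TrialSchedule:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    design = design_from_dict(payload["design"])
    rows = [
        (i + 1, {**row, "guided": "true" if row.get("guided") else "false"})
        for i, row in enumerate(payload["trials"])
    ]
    trials = _read_schedule_rows(rows, str(path))
    return TrialSchedule(
        design=design,
        trials=trials,
        variant_label=payload.get("variant_label", design.label),
        set_ids=tuple(payload.get("set_ids", ())),
    )


# ---------------------------------------------------------------------------
# Response logs

def write_log_csv(log: ResponseLog, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_NONE)
        w.writerow(LOG_COLUMNS)
        for row in log.trials.itertuples(index=False):
            lag = getattr(row, "lag")
            rt = getattr(row, "rt_ms")
            w.writerow(
                [
                    int(row.trial_index), row.phase, row.condition,
                    int(row.set_id), int(row.pair_id), row.exemplar,
                    int(row.lure_bin),
                    "" if lag is None or (isinstance(lag, float) and math.isnan(lag)) else int(lag),
                    row.response,
                    "" if rt is None or (isinstance(rt, float) and math.isnan(rt)) else int(rt),
                ]
            )


def _log_frame_from_records(records, source: str) -> pd.DataFrame:
    rows = []
    for ln, rec_ in records:
        missing = [c for c in LOG_COLUMNS if c not in rec_]
        if missing:
            raise ValueError(f"{source} line {ln}: missing fields {missing}")
        row = dict(rec_)
        for col in ("trial_index", "set_id", "pair_id", "lure_bin"):
            row[col] = _parse_int(str(row[col]), col, ln)
        for col in ("lag", "rt_ms"):
            v = row[col]
            row[col] = (
                np.nan
                if v in (None, "", "NA") or (isinstance(v, float) and math.isnan(v))
                else float(v)
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def read_log_csv(
    path, prompt: str = "OSN", participant: str = "", variant: str = "",
    session: int = 1,
) -> ResponseLog:
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames != LOG_COLUMNS:
            raise ValueError(
                f"response-log CSV header must be {','.join(LOG_COLUMNS)}"
            )
        df = _log_frame_from_records(
            ((ln, row) for ln, row in enumerate(r, start=2)), str(path)
        )
    return ResponseLog(
        trials=df, prompt=prompt, participant=participant,
        variant=variant, session=session,
    )


def read_log_json(path, prompt: str | None = None) -> ResponseLog:
    """Read a jsPsych-style JSON response log.

    Accepts either a bare JSON array of trial objects (one per trial,
    snake_case keys identical to the CSV header) or an object
    ``{"metadata": {...}, "trials": [...]}`` whose metadata may carry
    ``participant``, ``variant``, ``prompt`` and ``session``.
    """
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    meta: dict = {}
    if isinstance(payload, dict):
        meta = payload.get("metadata", {})
        payload = payload["trials"]
    if not isinstance(payload, list):
        raise ValueError("jsPsych log must be a JSON array of trial objects")
    df = _log_frame_from_records(
        ((i + 1, row) for i, row in enumerate(payload)), str(path)
    )
    return ResponseLog(
        trials=df,
        prompt=prompt or meta.get("prompt", "OSN"),
        participant=str(meta.get("participant", "")),
        variant=str(meta.get("variant", "")),
        session=int(meta.get("session", 1)),
    )


def write_log_json(log: ResponseLog, path) -> None:
    trials = []
    for row in log.trials.itertuples(index=False):
        rec_ = {c: getattr(row, c) for c in LOG_COLUMNS}
        for col in ("lag", "rt_ms"):
            v = rec_[col]
            rec_[col] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        for col in ("trial_index", "set_id", "pair_id", "lure_bin"):
            rec_[col] = int(rec_[col])
        trials.append(rec_)
    payload = {
        "metadata": {
            "participant": log.participant,
            "variant": log.variant,
            "prompt": log.prompt,
            "session": log.session,
        },
        "trials": trials,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def write_report_json(report: ScoreReport, path) -> None:
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Paired scores

def write_paired_csv(
    participants, baseline, variant, path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_NONE)
        w.writerow(["participant", "baseline", "variant"])
        for p, b, v in zip(participants, baseline, variant):
            w.writerow([p, repr(float(b)), repr(float(v))])


def read_paired_csv(path) -> tuple[list[str], PairedScores]:
    with open(path, newline="", encoding="utf-8") as fh:
        r = csv.DictReader(fh)
        if r.fieldnames != ["participant", "baseline", "variant"]:
            raise ValueError(
                "paired-scores CSV header must be participant,baseline,variant"
            )
        ids, base, var = [], [], []
        for ln, row in enumerate(r, start=2):
            ids.append(row["participant"])
            try:
                base.append(float(row["baseline"]))
                var.append(float(row["variant"]))
            except ValueError:
                raise ValueError(f"line {ln}: non-numeric score") from None
    return ids, PairedScores(np.array(base), np.array(var))


# ---------------------------------------------------------------------------
# Fixtures

def make_fixtures(seed: int = 0, out_dir=None) -> dict:
    """Generate the bundled synthetic test fixtures.

    A synthetic bank, one schedule per named variant, and simulated
    response logs for a young-adult-like and a low-performing cohort.
    Bit-identical for identical seeds.  When ``out_dir`` is given the
    fixtures are also written as CSV/JSON files.
    """
    bank = make_synthetic_bank(seed=seed)
    schedules = {}
    for i, variant in enumerate(("full-st", "full-cont", "reduced-st", "reduced-cont")):
        spec = design_variant(variant, seed=seed + i)
        schedules[variant] = build_schedule(spec, bank.pairs_for_set(i % 6 + 1))

    logs = {}
    for name, cohort in (
        ("young", young_adult_cohort(seed=seed)),
        ("low", older_adult_cohort(seed=seed, d_rep_mean=2.2)),
    ):
        logs[name] = simulate_cohort(
            [schedules["full-st"].design, schedules["reduced-cont"].design],
            cohort,
            n_participants=4,
            n_sessions=2,
            schedules=[schedules["full-st"], schedules["reduced-cont"]],
            seed=seed + 101,
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .stimulus_bank import write_bank_csv

        write_bank_csv(bank, out / "bank.csv")
        for variant, sched in schedules.items():
            write_schedule_csv(sched, out / f"schedule_{variant}.csv")
            write_schedule_json(sched, out / f"schedule_{variant}.json")
        for name, cohort_logs in logs.items():
            for log in cohort_logs:
                write_log_csv(
                    log,
                    out / f"log_{name}_{log.participant}_s{log.session}.csv",
                )
    return {"bank": bank, "schedules": schedules, "logs": logs}


# ---------------------------------------------------------------------------
# Experiment replays

#: Structure of the variant-comparison experiments: session 1 is always
#: the full-length study-test OSN baseline; session 2 the alternate
#: variant.  Values: (variant, prompt, practice, cohort, enrolled n).
EXPERIMENTS: dict[str, dict] = {
    "1": dict(variant="full-st", prompt="OSN", practice=False, cohort="young", n=60),
    "2": dict(variant="full-cont", prompt="OSN", practice=False, cohort="young", n=65),
    "3": dict(variant="full-st", prompt="ON", practice=False, cohort="young", n=48),
    "4": dict(variant="full-cont", prompt="ON", practice=False, cohort="young", n=61),
    "5a": dict(variant="reduced-st", prompt="OSN", practice=False, cohort="young", n=46),
    "5b": dict(variant="reduced-cont", prompt="OSN", practice=False, cohort="young", n=49),
    "6a": dict(variant="reduced-st", prompt="OSN", practice=True, cohort="young", n=85),
    "6b": dict(variant="reduced-cont", prompt="OSN", practice=True, cohort="young", n=82),
    "7": dict(variant="reduced-cont", prompt="OSN", practice=True, cohort="older", n=57),
}

#: Reference test-retest correlation of the baseline task (and its
#: post-outlier n) against which variant correlations are compared.
REFERENCE_R = 0.73
REFERENCE_N = 46


def _variant_metric(report: ScoreReport) -> float:
    if report.prompt == "OSN":
        assert report.ldi is not None
        return report.ldi
    assert report.dprime_tl is not None
    return report.dprime_tl


def experiment_replay(
    experiment_id,
    cohort_config: CohortSimParams | None = None,
    seed: int = 0,
    n_participants: int | None = None,
    q: float = 0.01,
) -> dict:
    """Re-run one experiment's pipeline on a synthetic cohort.

    Experiments "1"-"7" (with "5a"/"5b"/"6a"/"6b" sub-variants): each
    simulated participant performs the full-length baseline and the
    experiment's alternate variant; sessions are scored, validity-
    filtered, and the baseline-variant correlation is computed with
    robust outlier removal, then compared to the reference baseline
    reliability by a one-tailed Fisher r-to-z test.

    Experiment "8": four weekly half-length study-test sessions under
    Repeat and No-repeat stimulus-reuse conditions; reports per-session
    mean LDI/REC per group.

    The statistics mirror the human experiments' *pipeline*, computed
    on synthetic data — they are not reproductions of human results.
    """
    eid = str(experiment_id)
    if eid == "5":
        return {k: experiment_replay(k, cohort_config, seed, n_participants, q)
                for k in ("5a", "5b")}
    if eid == "6":
        return {k: experiment_replay(k, cohort_config, seed, n_participants, q)
                for k in ("6a", "6b")}
    if eid == "8":
        return _replay_exp8(cohort_config, seed, n_participants)
    if eid not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment_id!r}")

    exp = EXPERIMENTS[eid]
    n = n_participants or exp["n"]
    if cohort_config is None:
        cohort_config = (
            older_adult_cohort(seed=seed)
            if exp["cohort"] == "older"
            else young_adult_cohort(seed=seed)
        )
    baseline = design_variant("full-st", prompt="OSN", seed=seed)
    variant = design_variant(
        exp["variant"], prompt=exp["prompt"], seed=seed + 1,
        practice=exp["practice"],
    )
    logs = simulate_cohort(
        [baseline, variant], cohort_config, n_participants=n,
        n_sessions=2, seed=seed,
    )
    by_pid: dict[str, dict[int, ScoreReport]] = {}
    for log in logs:
        by_pid.setdefault(log.participant, {})[log.session] = score_session(log)

    ids, base_scores, var_scores = [], [], []
    for pid, sessions in by_pid.items():
        r1, r2 = sessions[1], sessions[2]
        if r1.valid and r2.valid:
            ids.append(pid)
            assert r1.ldi is not None
            base_scores.append(r1.ldi)
            var_scores.append(_variant_metric(r2))

    n_valid = len(ids)
    result: dict = {
        "experiment": eid,
        "n_enrolled": n,
        "n_valid": n_valid,
        "baseline_variant": "full-st",
        "alternate_variant": exp["variant"],
        "prompt": exp["prompt"],
    }
    if n_valid >= 5:
        scores = PairedScores(np.array(base_scores), np.array(var_scores))
        fit = robust_fit_with_outliers(scores, q=q)
        n_used = fit.n_clean
        z, p = fisher_compare(fit.r_clean, n_used, REFERENCE_R, REFERENCE_N)
        result.update(
            baseline_mean=float(np.mean(base_scores)),
            variant_mean=float(np.mean(var_scores)),
            r_clean=fit.r_clean,
            n_removed=fit.n_removed,
            n_after_outliers=n_used,
            slope=fit.slope,
            intercept=fit.intercept,
            fisher_z_vs_reference=z,
            fisher_one_tailed_p=p,
        )
    return result


def _replay_exp8(
    cohort_config: CohortSimParams | None,
    seed: int,
    n_participants: int | None,
) -> dict:
    n = n_participants or 72  # valid participants across both groups
    cohort = cohort_config or young_adult_cohort(seed=seed)
    half = DesignSpec(
        format="study_test", prompt="OSN", n_repeat=32, n_lure=32, n_foil=32,
        seed=seed, label="half-st",
    )
    out: dict = {"experiment": "8", "groups": {}}
    rows = []
    for g, group in enumerate(("no_repeat", "repeat")):
        n_g = n // 2
        logs = simulate_cohort(
            half, cohort, n_participants=n_g, n_sessions=4, seed=seed + g,
        )
        reports = [score_session(log) for log in logs]
        valid = [r for r in reports if r.valid]
        df = pd.DataFrame(
            {
                "participant": [f"{group}_{r.participant}" for r in valid],
                "session": [r.session for r in valid],
                "ldi": [r.ldi for r in valid],
                "rec": [r.rec for r in valid],
            }
        )
        rows.append(df.assign(group=group))
        out["groups"][group] = {
            "n": n_g,
            "n_valid_sessions": len(valid),
            "ldi_by_session": df.groupby("session")["ldi"].mean().to_dict(),
            "rec_by_session": df.groupby("session")["rec"].mean().to_dict(),
        }
    long = pd.concat(rows, ignore_index=True)
    first = long[long["session"] == 1]["ldi"].mean()
    later = long[long["session"] > 1]["ldi"].mean()
    out["ldi_first_session"] = float(first)
    out["ldi_later_sessions"] = float(later)
    out["first_session_deficit"] = float(later - first)
    out["long_table"] = long
    return out
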