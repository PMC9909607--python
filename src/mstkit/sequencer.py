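"""Trial-schedule generation for Mnemonic Similarity Task variants.

Two test formats are supported:

* **study-test** — an incidental-encoding (study) phase followed by a
  test phase mixing true repetitions of studied items, similar lures of
  studied items, and novel foils.  The full-length task uses 128 study
  items and a 64/64/64 test phase (320 trials in all); the reduced task
  uses 64 study items and a 20/44/20 test phase (148 trials).
* **continuous** — a single interleaved block in which the first
  presentation of each item doubles as its novel-foil observation and a
  repeat or lure probe follows after a controlled *lag* (difference of
  trial indices).  The full-length task has 128 firsts + 64 repeats +
  64 lures (256 trials); the reduced task 64 + 20 + 44 (128 trials).

Either format can use the three-choice old/similar/new (OSN) prompt or
the two-choice old/new (ON) prompt.

Exemplar convention: the first/study presentation of a pair shows
exemplar ``a``; a repeat re-shows ``a``; a lure probe shows ``b``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .stimulus_bank import StimulusPair

__all__ = [
    "TimingSpec",
    "PracticeSpec",
    "LagBand",
    "DesignSpec",
    "Trial",
    "TrialSchedule",
    "ScheduleError",
    "ScheduleInfeasibleError",
    "build_study_test",
    "build_continuous",
    "build_practice",
    "build_schedule",
    "estimate_duration",
    "plan_sessions",
    "check_schedule",
    "design_variant",
    "VARIANTS",
    "MEASURED_PHASE_DURATIONS_S",
    "variant_duration_minutes",
]

Format = Literal["study_test", "continuous"]
Prompt = Literal["OSN", "ON"]

SCORED_PHASES = ("study", "test", "continuous")


@dataclass(frozen=True)
class TimingSpec:
    """Per-trial timing of the task.

    ``stim_duration_s`` is how long the image stays up, ``min_isi_s``
    the minimum inter-stimulus interval, and ``min_trial_s`` the minimum
    total trial length (the prompt stays up until a response, so slow
    responders stretch a trial beyond the minimum).
    ``assumed_response_latency_s`` feeds expected-duration estimates: a
    trial is assumed to last ``max(min_trial_s, latency + min_isi_s)``.
    """

    stim_duration_s: float = 2.0
    min_isi_s: float = 0.5
    min_trial_s: float = 2.5
    assumed_response_latency_s: float = 1.5

    def __post_init__(self) -> None:
        vals = (
            self.stim_duration_s,
            self.min_isi_s,
            self.min_trial_s,
            self.assumed_response_latency_s,
        )
        if any(v < 0 for v in vals):
            raise ValueError("timing values must be non-negative")
        if self.min_trial_s < self.stim_duration_s:
            raise ValueError("min_trial_s must be >= stim_duration_s")


@dataclass(frozen=True)
class PracticeSpec:
    """Counts of practice trials preceding the scored task.

    ``study_trials`` practice encoding trials (study-test format only),
    then ``guided`` trials on which the correct answer is forced and
    shown, followed by ``unguided`` free-response practice trials.
    """

    study_trials: int = 0
    guided: int = 0
    unguided: int = 0

    def __post_init__(self) -> None:
        if min(self.study_trials, self.guided, self.unguided) < 0:
            raise ValueError("practice counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.study_trials + self.guided + self.unguided


#: Standard practice blocks for the two formats: the study-test variant
#: uses 4 practice study trials and 6 practice test trials (3 guided,
#: 3 unguided); the continuous variant uses 9 trials (5 guided, 4 unguided).
PRACTICE_STUDY_TEST = PracticeSpec(study_trials=4, guided=3, unguided=3)
PRACTICE_CONTINUOUS = PracticeSpec(study_trials=0, guided=5, unguided=4)


@dataclass(frozen=True)
class LagBand:
    """``n`` trials of one condition probed at lags in ``[lo, hi]`` inclusive."""

    lo: int
    hi: int
    n: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"lag band requires 1 <= lo <= hi, got {self}")
        if self.n < 0:
            raise ValueError("lag band count must be non-negative")


@dataclass(frozen=True)
class DesignSpec:
    """Full specification of one task variant.

    For the study-test format, ``n_study`` must equal
    ``n_repeat + n_lure`` (every tested repeat or lure was studied) and
    ``n_foil`` novel pairs appear only at test.  For the continuous
    format ``n_first >= n_repeat + n_lure`` (firsts double as foils, so
    ``n_foil`` is not used) and per-condition lag bands say how many
    repeats/lures fall in each lag range.
    """

    format: Format
    prompt: Prompt = "OSN"
    n_repeat: int = 64
    n_lure: int = 64
    n_foil: int | None = 64
    n_study: int | None = None
    n_first: int | None = None
    repeat_lags: tuple[LagBand, ...] = ()
    lure_lags: tuple[LagBand, ...] = ()
    practice: PracticeSpec | None = None
    timing: TimingSpec = field(default_factory=TimingSpec)
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.format not in ("study_test", "continuous"):
            raise ValueError(f"unknown format {self.format!r}")
        if self.prompt not in ("OSN", "ON"):
            raise ValueError(f"unknown prompt {self.prompt!r}")
        if self.n_repeat < 1 or self.n_lure < 1:
            raise ValueError("n_repeat and n_lure must be positive")
        if self.format == "study_test":
            if self.n_foil is None or self.n_foil < 0:
                raise ValueError("study_test requires n_foil >= 0")
            n_study = self.n_study
            if n_study is None:
                object.__setattr__(self, "n_study", self.n_repeat + self.n_lure)
            elif n_study != self.n_repeat + self.n_lure:
                raise ValueError(
                    "n_study must equal n_repeat + n_lure "
                    f"({self.n_repeat + self.n_lure}), got {n_study}"
                )
        else:
            if self.n_foil is not None:
                raise ValueError(
                    "continuous format takes no n_foil: first presentations "
                    "of later repeats and lures serve as the novel foils"
                )
            n_first = self.n_first
            if n_first is None:
                object.__setattr__(self, "n_first", self.n_repeat + self.n_lure)
            elif n_first < self.n_repeat + self.n_lure:
                raise ValueError("n_first must be >= n_repeat + n_lure")
            for bands, n, name in (
                (self.repeat_lags, self.n_repeat, "repeat"),
                (self.lure_lags, self.n_lure, "lure"),
            ):
                if bands and sum(b.n for b in bands) != n:
                    raise ValueError(
                        f"{name} lag-band counts sum to "
                        f"{sum(b.n for b in bands)}, expected {n}"
                    )

    @property
    def n_scored_trials(self) -> int:
        """Total scored trials (practice excluded)."""
        if self.format == "study_test":
            assert self.n_study is not None and self.n_foil is not None
            return self.n_study + self.n_repeat + self.n_lure + self.n_foil
        assert self.n_first is not None
        return self.n_first + self.n_repeat + self.n_lure

    @property
    def n_pairs_needed(self) -> int:
        scored = (
            self.n_repeat + self.n_lure + (self.n_foil or 0)
            if self.format == "study_test"
            else self.n_first or 0
        )
        return scored + _practice_pairs_needed(self.practice, self.format)


@dataclass(frozen=True)
class Trial:
    index: int
    phase: str  # practice_study, practice_test, study, test, continuous
    condition: str  # study_target, first, repeat, lure, foil
    pair: StimulusPair
    exemplar: str  # "a" or "b"
    lag: int | None = None
    guided: bool = False


@dataclass
class TrialSchedule:
    design: DesignSpec
    trials: list[Trial]
    variant_label: str = ""
    set_ids: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def scored_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.phase in SCORED_PHASES]

    @property
    def n_scored(self) -> int:
        return len(self.scored_trials)

    def condition_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.scored_trials:
            out[t.condition] = out.get(t.condition, 0) + 1
        return out


class ScheduleError(ValueError):
    """A schedule violates its declared design."""


class ScheduleInfeasibleError(RuntimeError):
    """Lag constraints could not be satisfied within the retry budget."""


# ---------------------------------------------------------------------------
# Practice blocks

def _practice_pairs_needed(practice: PracticeSpec | None, fmt: Format) -> int:
    if practice is None or practice.n_total == 0:
        return 0
    if fmt == "study_test":
        # repeats+lures probe the practice study items; every third test
        # trial is a fresh foil (the repeat/lure/foil cycle)
        n_test = practice.guided + practice.unguided
        return practice.study_trials + n_test // 3
    # continuous practice: one pair per first presentation (upper bound)
    return practice.n_total


def build_practice(
    practice: PracticeSpec,
    fmt: Format,
    pairs: Sequence[StimulusPair],
    seed: int = 0,
) -> list[Trial]:
    """Build the practice block for one format.

    Study-test: ``study_trials`` practice encoding trials, then practice
    test trials cycling repeat/lure/foil (repeats and lures probe the
    practice study items; foils are fresh pairs), guided trials first.
    Continuous: a short interleaved block of firsts with immediate
    repeat/lure probes, guided trials first.

    ``pairs`` must be a reserved pool never reused in the scored block.
    """
    rng = np.random.default_rng(seed)
    pool = list(pairs)
    rng.shuffle(pool)  # type: ignore[arg-type]
    trials: list[Trial] = []

    if fmt == "study_test":
        n_test = practice.guided + practice.unguided
        studied = pool[: practice.study_trials]
        if len(studied) < practice.study_trials:
            raise ValueError("not enough reserved pairs for practice study")
        for i, p in enumerate(studied):
            trials.append(Trial(i, "practice_study", "study_target", p, "a"))
        conditions = list(
            itertools.islice(itertools.cycle(["repeat", "lure", "foil"]), n_test)
        )
        foil_pool = pool[practice.study_trials:]
        studied_cycle = itertools.cycle(studied)
        fi = 0
        for j, cond in enumerate(conditions):
            guided = j < practice.guided
            if cond == "foil":
                if fi >= len(foil_pool):
                    raise ValueError("not enough reserved pairs for practice foils")
                p, fi = foil_pool[fi], fi + 1
                trials.append(
                    Trial(len(trials), "practice_test", "foil", p, "a", guided=guided)
                )
            else:
                p = next(studied_cycle)
                ex = "a" if cond == "repeat" else "b"
                trials.append(
                    Trial(len(trials), "practice_test", cond, p, ex, guided=guided)
                )
        return trials

    # continuous: lay out firsts and probe roughly half of them at lag 1-2
    n = practice.n_total
    layout: list[tuple[str, int, int | None]] = []  # (condition, item, lag)
    item = 0
    probe_kind = itertools.cycle(["repeat", "lure"])
    open_items: list[int] = []
    while len(layout) < n:
        if open_items and (len(layout) % 2 == 1 or item >= len(pool)):
            it = open_items.pop(0)
            first_pos = next(i for i, e in enumerate(layout) if e[1] == it)
            layout.append((next(probe_kind), it, len(layout) - first_pos))
        else:
            if item >= len(pool):
                raise ValueError("not enough reserved pairs for continuous practice")
            layout.append(("first", item, None))
            open_items.append(item)
            item += 1
    for j, (cond, it, lag) in enumerate(layout):
        trials.append(
            Trial(
                j,
                "practice_test",
                cond,
                pool[it],
                "b" if cond == "lure" else "a",
                lag=lag,
                guided=j < practice.guided,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Scored blocks

def build_study_test(
    spec: DesignSpec, pairs: Sequence[StimulusPair]
) -> TrialSchedule:
    """Generate a study-test schedule from a design spec and pair pool.

    The study phase presents exemplar ``a`` of every later-tested repeat
    and lure pair in seeded random order; the test phase mixes repeats
    (``a`` again), lures (``b``) and novel foils (``a``, never studied)
    in seeded random order.
    """
    if spec.format != "study_test":
        raise ValueError("spec.format must be 'study_test'")
    assert spec.n_study is not None and spec.n_foil is not None
    rng = np.random.default_rng(spec.seed)

    pool = list(pairs)
    if len(pool) < spec.n_pairs_needed:
        raise ValueError(
            f"need {spec.n_pairs_needed} pairs "
            f"(incl. practice reserve), got {len(pool)}"
        )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    trials: list[Trial] = []
    cursor = 0
    if spec.practice is not None and spec.practice.n_total:
        n_reserve = _practice_pairs_needed(spec.practice, "study_test")
        reserve, cursor = pool[:n_reserve], n_reserve
        trials.extend(
            build_practice(spec.practice, "study_test", reserve, seed=spec.seed)
        )

    repeats = pool[cursor: cursor + spec.n_repeat]
    cursor += spec.n_repeat
    lures = pool[cursor: cursor + spec.n_lure]
    cursor += spec.n_lure
    foils = pool[cursor: cursor + spec.n_foil]

    studied = repeats + lures
    study_order = rng.permutation(len(studied))
    for i in study_order:
        trials.append(
            Trial(len(trials), "study", "study_target", studied[i], "a")
        )

    test_items = (
        [("repeat", p, "a") for p in repeats]
        + [("lure", p, "b") for p in lures]
        + [("foil", p, "a") for p in foils]
    )
    test_order = rng.permutation(len(test_items))
    for i in test_order:
        cond, p, ex = test_items[i]
        trials.append(Trial(len(trials), "test", cond, p, ex))

    return TrialSchedule(
        design=spec,
        trials=trials,
        variant_label=spec.label or "study_test",
        set_ids=tuple(sorted({p.set_id for p in pool[: spec.n_pairs_needed]})),
    )


def _place_continuous(
    spec: DesignSpec, rng: np.random.Generator
) -> list[tuple[str, int, int | None]]:
    """Randomized-greedy slot assignment for the continuous block.

    Returns a list of (condition, item_index, lag) per slot.  Probes are
    placed longest-lag first; a probe whose lag cannot be realised is
    re-sampled within its band, and the whole layout restarts on
    exhaustion.  Bounded at 10,000 placement attempts overall.
    """
    assert spec.n_first is not None
    n_total = spec.n_first + spec.n_repeat + spec.n_lure

    probes: list[tuple[str, LagBand]] = []
    rep_bands = spec.repeat_lags or (LagBand(1, n_total - 1, spec.n_repeat),)
    lure_bands = spec.lure_lags or (LagBand(1, n_total - 1, spec.n_lure),)
    for band in rep_bands:
        probes.extend([("repeat", band)] * band.n)
    for band in lure_bands:
        probes.extend([("lure", band)] * band.n)

    n_pure_first = spec.n_first - len(probes)
    attempts = 0
    max_attempts = 10_000
    last_fail = "none"
    while attempts < max_attempts:
        attempts += 1
        # Build the block left to right.  At each position either emit a
        # probe already scheduled for it, or start a new item and book
        # its probe at a free future slot inside the item's lag band.
        slots: list[tuple[str, int, int | None] | None] = [None] * n_total
        booked: dict[int, tuple[str, int, int]] = {}  # pos -> (cond, item, lag)
        remaining = list(rng.permutation(len(probes)))
        pure_left = n_pure_first
        item_counter = len(probes)
        failed = False
        for pos in range(n_total):
            if pos in booked:
                cond, item, lag = booked.pop(pos)
                slots[pos] = (cond, item, lag)
                continue
            horizon = n_total - 1 - pos
            # candidate probed items whose band can still fit
            placeable = [
                i for i in remaining if probes[i][1].lo <= horizon
            ]
            placed = False
            rng.shuffle(placeable)  # type: ignore[arg-type]
            for i in placeable[:20]:
                band = probes[i][1]
                hi = min(band.hi, horizon)
                options = [
                    la
                    for la in range(band.lo, hi + 1)
                    if (pos + la) not in booked
                ]
                if not options:
                    continue
                lag = int(options[rng.integers(len(options))])
                slots[pos] = ("first", i, None)
                booked[pos + lag] = (probes[i][0], i, lag)
                remaining.remove(i)
                placed = True
                break
            if placed:
                continue
            if pure_left > 0:
                slots[pos] = ("first", item_counter, None)
                item_counter += 1
                pure_left -= 1
                continue
            last_fail = (
                f"no probed item fits at position {pos} "
                f"(horizon {horizon}, {len(remaining)} probes unplaced)"
            )
            failed = True
            break
        if not failed and not remaining and pure_left == 0:
            return [s for s in slots if s is not None]
        if not failed:
            last_fail = f"{len(remaining)} probes or {pure_left} firsts unplaced"
    raise ScheduleInfeasibleError(
        f"could not satisfy lag bands {rep_bands} / {lure_bands} "
        f"within {max_attempts} layout attempts: {last_fail}"
    )


def build_continuous(
    spec: DesignSpec, pairs: Sequence[StimulusPair]
) -> TrialSchedule:
    """Generate a continuous (single-block) schedule.

    Every repeat/lure probe appears after its pair's first presentation
    at a lag (difference of trial indices) inside the assigned band.
    """
    if spec.format != "continuous":
        raise ValueError("spec.format must be 'continuous'")
    assert spec.n_first is not None
    rng = np.random.default_rng(spec.seed)

    pool = list(pairs)
    if len(pool) < spec.n_pairs_needed:
        raise ValueError(
            f"need {spec.n_pairs_needed} pairs "
            f"(incl. practice reserve), got {len(pool)}"
        )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    trials: list[Trial] = []
    cursor = 0
    if spec.practice is not None and spec.practice.n_total:
        n_reserve = _practice_pairs_needed(spec.practice, "continuous")
        reserve, cursor = pool[:n_reserve], n_reserve
        trials.extend(
            build_practice(spec.practice, "continuous", reserve, seed=spec.seed)
        )

    layout = _place_continuous(spec, rng)
    n_items = spec.n_first
    items = pool[cursor: cursor + n_items]
    offset = len(trials)
    for slot_idx, (cond, item, lag) in enumerate(layout):
        p = items[item]
        ex = "b" if cond == "lure" else "a"
        trials.append(
            Trial(offset + slot_idx, "continuous", cond, p, ex, lag=lag)
        )

    return TrialSchedule(
        design=spec,
        trials=trials,
        variant_label=spec.label or "continuous",
        set_ids=tuple(sorted({p.set_id for p in pool[: spec.n_pairs_needed]})),
    )


def build_schedule(
    spec: DesignSpec, pairs: Sequence[StimulusPair]
) -> TrialSchedule:
    """Dispatch on ``spec.format``."""
    if spec.format == "study_test":
        return build_study_test(spec, pairs)
    return build_continuous(spec, pairs)


# ---------------------------------------------------------------------------
# Duration estimates

def estimate_duration(
    schedule: TrialSchedule, timing: TimingSpec | None = None
) -> tuple[float, float]:
    """(minimum, expected) scored-block duration in seconds.

    Minimum assumes every trial takes exactly ``min_trial_s``; expected
    assumes a response latency of ``assumed_response_latency_s`` after
    stimulus onset plus the minimum ISI, floored at the trial minimum.
    """
    t = timing or schedule.design.timing
    n = schedule.n_scored
    min_s = n * t.min_trial_s
    per_trial = max(t.min_trial_s, t.assumed_response_latency_s + t.min_isi_s)
    return min_s, n * per_trial


# ---------------------------------------------------------------------------
# Session planning

def plan_sessions(
    n_participants: int,
    variants: Sequence[str],
    sets_available: Sequence[int],
    mode: str = "counterbalanced_order",
    seed: int = 0,
) -> list[list[dict]]:
    """Assign variants, orders and stimulus sets to participants.

    Modes
    -----
    ``counterbalanced_order``
        Each participant receives every variant once; the order of the
        variants and the set-to-variant assignment both rotate across
        participants, so each ordering is used within +-1 of equally.
    ``repeat``
        Four sessions of ``variants[0]`` reusing the identical
        difficulty-matched half-set on sessions (1,2) and on (3,4)
        (e.g. 1a, 1a, 2a, 2a).
    ``no_repeat``
        Four sessions of ``variants[0]`` with four pairwise-distinct
        half-sets (e.g. 1a, 1b, 2a, 2b).

    Returns one list of session dicts (keys ``session``, ``variant``,
    ``set_id``, ``half``) per participant.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if not variants:
        raise ValueError("at least one variant required")
    rng = np.random.default_rng(seed)
    sets = list(sets_available)
    plans: list[list[dict]] = []

    if mode == "counterbalanced_order":
        orders = list(itertools.permutations(range(len(variants))))
        set_rotations = [
            tuple(sets[(i + r) % len(sets)] for i in range(len(variants)))
            for r in range(len(sets))
        ]
        start = int(rng.integers(len(orders)))
        for p in range(n_participants):
            order = orders[(start + p) % len(orders)]
            setrot = set_rotations[p % len(set_rotations)]
            plans.append(
                [
                    {
                        "session": s + 1,
                        "variant": variants[v],
                        "set_id": setrot[v],
                        "half": None,
                    }
                    for s, v in enumerate(order)
                ]
            )
        return plans

    if mode in ("repeat", "no_repeat"):
        if len(sets) < 2:
            raise ValueError("repeat/no_repeat planning needs >= 2 sets")
        variant = variants[0]
        for p in range(n_participants):
            s1, s2 = sets[p % len(sets)], sets[(p + 1) % len(sets)]
            if mode == "repeat":
                halves = [(s1, "a"), (s1, "a"), (s2, "a"), (s2, "a")]
            else:
                halves = [(s1, "a"), (s1, "b"), (s2, "a"), (s2, "b")]
            plans.append(
                [
                    {"session": i + 1, "variant": variant, "set_id": sid, "half": h}
                    for i, (sid, h) in enumerate(halves)
                ]
            )
        return plans

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Independent schedule checker

def check_schedule(schedule: TrialSchedule) -> dict:
    """Re-derive a schedule's structure from its raw trial list.

    Verifies, independently of how the schedule was built:

    * condition counts equal the design's declared counts;
    * every repeat/lure probe has an earlier presentation of exemplar
      ``a`` of the same pair, at the declared lag (continuous) or in the
      study phase (study-test);
    * no stimulus pair is used in more than one scored condition;
    * practice pairs are disjoint from scored pairs;
    * lag-band membership counts match the design.

    Returns a summary dict; raises :class:`ScheduleError` on violation.
    """
    spec = schedule.design
    scored = schedule.scored_trials
    counts: dict[str, int] = {}
    for t in scored:
        counts[t.condition] = counts.get(t.condition, 0) + 1

    if spec.format == "study_test":
        expected = {
            "study_target": spec.n_study,
            "repeat": spec.n_repeat,
            "lure": spec.n_lure,
        }
        if spec.n_foil:
            expected["foil"] = spec.n_foil
    else:
        expected = {
            "first": spec.n_first,
            "repeat": spec.n_repeat,
            "lure": spec.n_lure,
        }
    if counts != {k: v for k, v in expected.items() if v}:
        raise ScheduleError(f"condition counts {counts} != declared {expected}")

    # pair-condition uniqueness (study_target pairs back repeats/lures,
    # and a continuous first legitimately precedes its own probe)
    probe_cond: dict[tuple[int, int], str] = {}
    for t in scored:
        key = (t.pair.set_id, t.pair.pair_id)
        if t.condition in ("study_target", "first"):
            continue
        if key in probe_cond:
            raise ScheduleError(f"pair {key} probed twice")
        probe_cond[key] = t.condition

    seen_a: dict[tuple[int, int], int] = {}
    by_index = {t.index: t for t in scored}
    band_tally: dict[tuple[str, int, int], int] = {}
    for t in scored:
        key = (t.pair.set_id, t.pair.pair_id)
        if t.condition in ("study_target", "first"):
            if key in seen_a:
                raise ScheduleError(f"pair {key} presented first twice")
            seen_a[key] = t.index
        elif t.condition in ("repeat", "lure"):
            if key not in seen_a:
                raise ScheduleError(
                    f"{t.condition} of pair {key} has no earlier presentation"
                )
            if seen_a[key] >= t.index:
                raise ScheduleError(f"probe of pair {key} precedes its first")
            if spec.format == "continuous":
                true_lag = t.index - seen_a[key]
                if t.lag != true_lag:
                    raise ScheduleError(
                        f"declared lag {t.lag} != index difference {true_lag} "
                        f"for pair {key}"
                    )
            want_ex = "b" if t.condition == "lure" else "a"
            if t.exemplar != want_ex:
                raise ScheduleError(
                    f"{t.condition} trial shows exemplar {t.exemplar}"
                )
        elif t.condition == "foil":
            if key in seen_a:
                raise ScheduleError(f"foil pair {key} was studied")
            seen_a[key] = t.index

    for cond, bands in (("repeat", spec.repeat_lags), ("lure", spec.lure_lags)):
        if not bands:
            continue
        lags = [
            t.lag for t in scored if t.condition == cond and t.lag is not None
        ]
        for band in bands:
            got = sum(1 for la in lags if band.lo <= la <= band.hi)
            band_tally[(cond, band.lo, band.hi)] = got
        # bands may overlap in principle; the standard ones do not
        for band in bands:
            got = band_tally[(cond, band.lo, band.hi)]
            if got != band.n:
                raise ScheduleError(
                    f"{cond} lag band [{band.lo},{band.hi}]: {got} trials, "
                    f"declared {band.n}"
                )

    practice_keys = {
        (t.pair.set_id, t.pair.pair_id)
        for t in schedule.trials
        if t.phase not in SCORED_PHASES
    }
    scored_keys = {(t.pair.set_id, t.pair.pair_id) for t in scored}
    if practice_keys & scored_keys:
        raise ScheduleError("practice pairs reused in the scored block")

    del by_index
    return {
        "n_scored": len(scored),
        "condition_counts": counts,
        "lag_band_counts": band_tally,
    }


# ---------------------------------------------------------------------------
# Named variants

#: Canonical task variants studied when optimizing the MST.
VARIANTS = ("full-st", "full-cont", "reduced-st", "reduced-cont")


def design_variant(
    variant: str,
    prompt: Prompt = "OSN",
    seed: int = 0,
    practice: bool | None = None,
    timing: TimingSpec | None = None,
) -> DesignSpec:
    """Build the DesignSpec for a named variant.

    ``full-st``      320 trials: 128 study + 64/64/64 test.
    ``full-cont``    256 trials: 128 firsts + 64 repeats + 64 lures,
                     with 32 repeats and 32 lures in each lag band
                     [4, 11] and [20, 99].
    ``reduced-st``   148 trials: 64 study + 20/44/20 test.
    ``reduced-cont`` 128 trials: 64 firsts + 20 repeats + 44 lures; the
                     published reduced design states no band split, so
                     each condition is divided as evenly as possible
                     across the two bands (repeats 10/10, lures 22/22).

    ``practice`` defaults to the format's standard practice block for
    reduced variants and to none for full-length ones (which
    historically used video instructions).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    timing = timing or TimingSpec()
    if practice is None:
        practice = variant.startswith("reduced")
    if variant == "full-st":
        return DesignSpec(
            format="study_test", prompt=prompt, n_repeat=64, n_lure=64,
            n_foil=64,
            practice=PRACTICE_STUDY_TEST if practice else None,
            timing=timing, seed=seed, label=variant,
        )
    if variant == "reduced-st":
        return DesignSpec(
            format="study_test", prompt=prompt, n_repeat=20, n_lure=44,
            n_foil=20,
            practice=PRACTICE_STUDY_TEST if practice else None,
            timing=timing, seed=seed, label=variant,
        )
    if variant == "full-cont":
        return DesignSpec(
            format="continuous", prompt=prompt, n_repeat=64, n_lure=64,
            n_foil=None, n_first=128,
            repeat_lags=(LagBand(4, 11, 32), LagBand(20, 99, 32)),
            lure_lags=(LagBand(4, 11, 32), LagBand(20, 99, 32)),
            practice=PRACTICE_CONTINUOUS if practice else None,
            timing=timing, seed=seed, label=variant,
        )
    return DesignSpec(
        format="continuous", prompt=prompt, n_repeat=20, n_lure=44,
        n_foil=None, n_first=64,
        repeat_lags=(LagBand(4, 11, 10), LagBand(20, 99, 10)),
        lure_lags=(LagBand(4, 11, 22), LagBand(20, 99, 22)),
        practice=PRACTICE_CONTINUOUS if practice else None,
        timing=timing, seed=seed, label=variant,
    )


# ---------------------------------------------------------------------------
# Duration accounting from measured component medians

#: Median component durations (seconds) measured in web-based
#: administrations of each variant.  The baseline (full study-test) was
#: measured in two independent replications, hence two values per
#: component; reduced variants were measured once.  The continuous
#: format has a single instruction+task block.
MEASURED_PHASE_DURATIONS_S: dict[str, dict[str, tuple[float, ...]]] = {
    "baseline": {
        "study_instructions": (21.3, 24.3),
        "study_phase": (240.7, 240.1),
        "test_instructions": (95.06, 99.64),
        "test_phase": (377.5, 370.0),
    },
    "reduced-st": {
        "study_instructions": (25.4,),
        "study_phase": (123.6,),
        "test_instructions": (49.5,),
        "test_phase": (167.5,),
    },
    "reduced-cont": {
        "instructions": (64.7,),
        "task": (251.0,),
    },
}


def variant_duration_minutes(variant: str) -> float:
    """Total measured duration of a variant in minutes.

    Sums the median component durations (averaging replicated
    measurements of the same component) for ``baseline``,
    ``reduced-st`` or ``reduced-cont``.
    """
    try:
        components = MEASURED_PHASE_DURATIONS_S[variant]
    except KeyError:
        raise ValueError(
            f"no measured durations for {variant!r}; "
            f"known: {sorted(MEASURED_PHASE_DURATIONS_S)}"
        ) from None
    total_s = sum(float(np.mean(v)) for v in components.values())
    return total_s / 60.0
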