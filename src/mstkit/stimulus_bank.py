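"""Stimulus-set structure for the Mnemonic Similarity Task.

The MST stimulus pool is organised as independent *sets* of target/lure
image pairs.  Each pair carries a *lure bin*, a difficulty stratum 1-5
derived (in the published norming work) from the empirical false-alarm
rate to that pair's lure across a large normative sample.

Bin polarity
------------
Throughout this package **bin 1 is the most similar (hardest) lure** —
the one with the highest historical false-alarm rate — and bin 5 the
least similar (easiest).  The simulator's per-bin similarity parameters
follow the same convention.

No image files are involved anywhere: a pair is identified purely by
``(set_id, pair_id)`` plus its bin, which is all that schedule
generation, scoring and simulation need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusPair",
    "StimulusBank",
    "make_synthetic_bank",
    "split_matched_halves",
    "sample_subset",
    "read_bank_csv",
    "write_bank_csv",
    "LURE_BINS",
]

#: Valid lure-difficulty bins, bin 1 = most similar lure.
LURE_BINS = (1, 2, 3, 4, 5)


@dataclass(frozen=True, order=True)
class StimulusPair:
    """One target/lure image pair.

    Parameters
    ----------
    set_id : int
        Stimulus set the pair belongs to (1-6 in the canonical pool).
    pair_id : int
        Identifier of the pair within its set (1-192 canonically).
    lure_bin : int
        Difficulty bin 1-5; bin 1 is the most similar lure.
    """

    set_id: int
    pair_id: int
    lure_bin: int

    def __post_init__(self) -> None:
        if self.lure_bin not in LURE_BINS:
            raise ValueError(
                f"lure_bin must be in {LURE_BINS}, got {self.lure_bin!r}"
            )


@dataclass
class StimulusBank:
    """A collection of stimulus pairs with unique (set_id, pair_id) keys."""

    pairs: list[StimulusPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(p.set_id, p.pair_id) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (set_id, pair_id) in bank")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def set_ids(self) -> list[int]:
        return sorted({p.set_id for p in self.pairs})

    def pairs_for_set(self, set_id: int) -> list[StimulusPair]:
        return [p for p in self.pairs if p.set_id == set_id]

    def bin_counts(self) -> pd.DataFrame:
        """Per-set tally of pairs in each lure bin (rows: set, cols: bin)."""
        df = self.to_frame()
        counts = (
            df.groupby(["set_id", "lure_bin"]).size().unstack(fill_value=0)
        )
        return counts.reindex(columns=list(LURE_BINS), fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": [p.set_id for p in self.pairs],
                "pair_id": [p.pair_id for p in self.pairs],
                "lure_bin": [p.lure_bin for p in self.pairs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusBank":
        pairs = [
            StimulusPair(int(r.set_id), int(r.pair_id), int(r.lure_bin))
            for r in df.itertuples(index=False)
        ]
        return cls(pairs)


def make_synthetic_bank(
    n_sets: int = 6,
    pairs_per_set: int = 192,
    bin_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> StimulusBank:
    """Construct a synthetic stimulus bank emulating the canonical pool.

    The canonical MST pool has six independent sets of 192 pairs each,
    stratified into five lure bins.  The true per-bin composition of the
    real sets is not published, so the synthetic default assigns bins
    i.i.d. with uniform weights; pass ``bin_weights`` to emulate a known
    composition, or load real metadata via :func:`read_bank_csv`.

    Parameters
    ----------
    n_sets, pairs_per_set : int
        Number of sets and pairs per set; both must be positive.
    bin_weights : sequence of 5 floats, optional
        Probability of each lure bin (bin 1 first).  Default uniform.
    seed : int
        Seed for the bin assignment; identical seeds give identical banks.
    """
    if n_sets <= 0 or pairs_per_set <= 0:
        raise ValueError("n_sets and pairs_per_set must be positive")
    if bin_weights is None:
        bin_weights = np.full(5, 0.2)
    w = np.asarray(bin_weights, dtype=float)
    if w.shape != (5,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("bin_weights must be 5 non-negative values summing to 1")

    rng = np.random.default_rng(seed)
    pairs: list[StimulusPair] = []
    for s in range(1, n_sets + 1):
        bins = rng.choice(np.arange(1, 6), size=pairs_per_set, p=w)
        pairs.extend(
            StimulusPair(s, i + 1, int(b)) for i, b in enumerate(bins)
        )
    return StimulusBank(pairs)


def split_matched_halves(
    bank_set: Iterable[StimulusPair], seed: int = 0
) -> tuple[list[StimulusPair], list[StimulusPair]]:
    """Split one set's pairs into two difficulty-matched halves.

    Within each lure bin the pairs are shuffled and dealt alternately to
    the two halves, so per-bin counts differ by at most 1.  The side that
    receives a bin's odd leftover alternates with the running size
    imbalance, so total sizes also differ by at most 1.

    Raises ``ValueError`` if the pairs span more than one set.
    """
    pairs = list(bank_set)
    if len({p.set_id for p in pairs}) > 1:
        raise ValueError("split_matched_halves expects pairs from a single set")
    rng = np.random.default_rng(seed)
    half_a: list[StimulusPair] = []
    half_b: list[StimulusPair] = []
    for b in LURE_BINS:
        in_bin = sorted(p for p in pairs if p.lure_bin == b)
        order = rng.permutation(len(in_bin))
        shuffled = [in_bin[i] for i in order]
        # start the deal on whichever half is currently smaller
        first_a = len(half_a) <= len(half_b)
        for i, p in enumerate(shuffled):
            to_a = (i % 2 == 0) == first_a
            (half_a if to_a else half_b).append(p)
    return half_a, half_b


def sample_subset(
    bank: StimulusBank,
    n_pairs: int,
    bin_profile: Sequence[int] | str = "proportional",
    exclude: Iterable[tuple[int, int]] = (),
    seed: int = 0,
) -> list[StimulusPair]:
    """Sample pairs from a bank, optionally with an exact per-bin profile.

    Parameters
    ----------
    bank : StimulusBank
    n_pairs : int
        Total pairs to draw.
    bin_profile : "proportional" or sequence of 5 counts
        With a count vector the per-bin composition is honoured exactly
        (and must sum to ``n_pairs``); ``"proportional"`` draws uniformly
        from the available pool, so the expected composition matches it.
    exclude : iterable of (set_id, pair_id)
        Pairs already used elsewhere; never returned.
    seed : int
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    excluded = set(exclude)
    avail = [p for p in bank if (p.set_id, p.pair_id) not in excluded]
    rng = np.random.default_rng(seed)

    if isinstance(bin_profile, str):
        if bin_profile != "proportional":
            raise ValueError(f"unknown bin_profile {bin_profile!r}")
        if len(avail) < n_pairs:
            raise ValueError(
                f"requested {n_pairs} pairs but only {len(avail)} available"
            )
        idx = rng.choice(len(avail), size=n_pairs, replace=False)
        return [avail[i] for i in sorted(idx)]

    profile = np.asarray(bin_profile, dtype=int)
    if profile.shape != (5,) or profile.sum() != n_pairs:
        raise ValueError("bin_profile must be 5 counts summing to n_pairs")
    out: list[StimulusPair] = []
    for b, need in zip(LURE_BINS, profile):
        pool = [p for p in avail if p.lure_bin == b]
        if len(pool) < need:
            raise ValueError(
                f"bin {b}: requested {need} pairs, only {len(pool)} available"
            )
        idx = rng.choice(len(pool), size=int(need), replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out


# ---------------------------------------------------------------------------
# CSV interface: header `set_id,pair_id,lure_bin`, strict integers, UTF-8.

def write_bank_csv(bank: StimulusBank, path) -> None:
    bank.to_frame().to_csv(path, index=False)


def read_bank_csv(path) -> StimulusBank:
    df = pd.read_csv(path, encoding="utf-8")
    required = ["set_id", "pair_id", "lure_bin"]
    if list(df.columns) != required:
        raise ValueError(
            f"bank CSV must have header {','.join(required)}, got {list(df.columns)}"
        )
    for col in required:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals != vals.round())]
        if len(bad):
            raise ValueError(f"non-integer {col} at row {int(bad[0]) + 2}")
        df[col] = vals.astype(int)
    return StimulusBank.from_frame(df)
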