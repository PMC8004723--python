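"""Labeled-stream replay: scoring bandit policies on event streams.

In the replay protocol each incoming instance carries one or more class
labels from a fixed alphabet of size K.  The policy picks an arm before
seeing the instance; it earns reward 1 if the chosen arm's class is
among the instance's labels and 0 otherwise, and is updated online with
that reward.  Accuracy (mean reward) is the headline metric, since no
ground-truth reward distribution exists for a logged stream.

A second protocol replays a table of per-bin class *frequencies*: the
bin's frequency vector is held fixed for ``m`` consecutive steps and
each step's reward is a Bernoulli draw at the chosen arm's frequency.
Here the dynamic oracle plays the per-bin argmax frequency and RCR is
the metric.

Synthetic stream generators build class-prior schedules from the drift
primitives in :mod:`fdswts.environments`, providing controlled
stand-ins for the kinds of real streams this protocol targets:
crime-like (many classes, pseudo-stationary noisy priors), insects-like
(imbalanced single-label with abrupt/incremental/reoccurring drifts),
news-like (multi-label with one sudden and one gradual drift) and
microbes-like (a per-bin community frequency table).  These emulate
drift shape and imbalance only, not the content of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .environments import drift_schedule
from .evaluation import _as_policy, _rng
from .policies import PolicyConfig

__all__ = [
    "LabeledStream",
    "FrequencyTable",
    "ReplayResult",
    "load_stream",
    "save_stream",
    "replay",
    "frequency_replay",
    "synth_stream",
    "crime_like_priors",
    "insects_like_priors",
    "news_like_priors",
    "microbes_like_table",
]


@dataclass(frozen=True)
class LabeledStream:
    """Ordered labeled instances over a fixed label alphabet.

    ``labels[i]`` is the non-empty set of classes attached to the
    instance at step ``steps[i]``; in single-label mode every instance
    carries exactly one class.
    """

    steps: np.ndarray                    # strictly increasing step indices
    labels: tuple[frozenset, ...]
    alphabet: tuple[str, ...]
    mode: str = "single"

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=np.int64)
        if len(steps) != len(self.labels):
            raise ValueError("steps and labels must have equal length")
        if len(steps) > 1 and np.any(np.diff(steps) <= 0):
            raise ValueError("step indices must be strictly increasing")
        if self.mode not in ("single", "multi"):
            raise ValueError(f"mode must be 'single' or 'multi', got {self.mode!r}")
        alpha = set(self.alphabet)
        labels = []
        for i, lab in enumerate(self.labels):
            lab = frozenset(lab)
            if not lab:
                raise ValueError(f"instance at position {i} has an empty label set")
            unknown = lab - alpha
            if unknown:
                raise ValueError(f"labels {sorted(unknown)} not in alphabet")
            if self.mode == "single" and len(lab) != 1:
                raise ValueError(
                    f"single-label stream has {len(lab)} labels at position {i}"
                )
            labels.append(lab)
        steps.setflags(write=False)
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "labels", tuple(labels))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def arm_count(self) -> int:
        return len(self.alphabet)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-bin relative class frequencies, each bin held for ``steps_per_bin`` steps."""

    freqs: np.ndarray                    # (n_bins, K), values in [0, 1]
    steps_per_bin: int = 120
    alphabet: tuple[str, ...] = ()

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[0] < 1 or freqs.shape[1] < 1:
            raise ValueError(f"freqs must be (n_bins, K), got shape {freqs.shape}")
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.steps_per_bin < 1:
            raise ValueError(f"steps_per_bin must be >= 1, got {self.steps_per_bin}")
        freqs.setflags(write=False)
        object.__setattr__(self, "freqs", freqs)
        if not self.alphabet:
            object.__setattr__(
                self, "alphabet", tuple(f"C{k}" for k in range(freqs.shape[1]))
            )
        elif len(self.alphabet) != freqs.shape[1]:
            raise ValueError("alphabet length must match the number of columns")

    @property
    def arm_count(self) -> int:
        return self.freqs.shape[1]

    @property
    def n_bins(self) -> int:
        return self.freqs.shape[0]


# ---------------------------------------------------------------------------
# CSV round-trip  (format: header "t,labels", labels ';'-separated)
# ---------------------------------------------------------------------------


def load_stream(path, mode: str = "single", alphabet: Sequence[str] | None = None) -> LabeledStream:
    """Read a labeled stream from CSV (columns ``t`` and ``labels``)."""
    df = pd.read_csv(path, dtype={"labels": str}, keep_default_na=False)
    if not {"t", "labels"} <= set(df.columns):
        raise ValueError(f"stream CSV must have columns 't' and 'labels', got {list(df.columns)}")
    labels = []
    for i, raw in enumerate(df["labels"]):
        parts = [p.strip() for p in str(raw).split(";") if p.strip()]
        if not parts:
            raise ValueError(f"empty label set at row {i}")
        labels.append(frozenset(parts))
    if alphabet is None:
        alphabet = tuple(sorted(set().union(*labels)))
    return LabeledStream(
        steps=df["t"].to_numpy(),
        labels=tuple(labels),
        alphabet=tuple(alphabet),
        mode=mode,
    )


def save_stream(stream: LabeledStream, path) -> None:
    df = pd.DataFrame(
        {
            "t": stream.steps,
            "labels": [";".join(sorted(lab)) for lab in stream.labels],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replay protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplayResult:
    """Outcome of replaying a policy against a stream or frequency table."""

    arms: np.ndarray
    rewards: np.ndarray
    policy: str = ""
    oracle_rewards: np.ndarray | None = None

    @property
    def cumulative_reward(self) -> int:
        return int(self.rewards.sum())

    @property
    def accuracy(self) -> float:
        if len(self.rewards) == 0:
            raise ValueError("empty replay has no accuracy")
        return self.cumulative_reward / len(self.rewards)

    @property
    def rcr(self) -> float:
        if self.oracle_rewards is None:
            raise ValueError("no oracle stream recorded for this replay")
        denom = int(self.oracle_rewards.sum())
        if denom == 0:
            raise ZeroDivisionError("oracle collected no reward")
        return self.cumulative_reward / denom


def replay(policy, stream: LabeledStream, seed=None, rng=None) -> ReplayResult:
    """Score a policy on a labeled stream (reward 1 iff chosen class is labeled)."""
    agent, label = _as_policy(policy, stream.arm_count)
    if agent.arm_count != stream.arm_count:
        raise ValueError(
            f"policy has {agent.arm_count} arms but alphabet has {stream.arm_count} classes"
        )
    if rng is None:
        rng = _rng(*np.atleast_1d(0 if seed is None else seed))
    index = {c: k for k, c in enumerate(stream.alphabet)}
    label_sets = [frozenset(index[c] for c in lab) for lab in stream.labels]
    n = len(stream)
    arms = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    for i in range(n):
        arm = agent.select(rng)
        r = int(arm in label_sets[i])
        agent.update(arm, r)
        arms[i] = arm
        rewards[i] = r
    return ReplayResult(arms=arms, rewards=rewards, policy=label)


def frequency_replay(policy, table: FrequencyTable, seed=None, rng=None) -> ReplayResult:
    """Score a policy on a per-bin class-frequency table.

    Each bin's frequency vector is held for ``table.steps_per_bin``
    steps; the reward for playing arm ``k`` is Bernoulli(freq[bin, k]).
    The oracle plays each bin's argmax frequency, drawing rewards from
    its own substream, and the result's ``rcr`` compares the two
    realised totals.
    """
    agent, label = _as_policy(policy, table.arm_count)
    if agent.arm_count != table.arm_count:
        raise ValueError(
            f"policy has {agent.arm_count} arms but table has {table.arm_count} classes"
        )
    if rng is None:
        rng = _rng(*np.atleast_1d(0 if seed is None else seed))
    oracle_rng = np.random.default_rng(rng.integers(2**31))
    m = table.steps_per_bin
    T = table.n_bins * m
    arms = np.empty(T, dtype=np.int64)
    rewards = np.empty(T, dtype=np.int64)
    oracle_rewards = np.empty(T, dtype=np.int64)
    t = 0
    for b in range(table.n_bins):
        freq = table.freqs[b]
        best = int(np.argmax(freq))
        for _ in range(m):
            arm = agent.select(rng)
            r = int(rng.random() < freq[arm])
            agent.update(arm, r)
            arms[t] = arm
            rewards[t] = r
            oracle_rewards[t] = int(oracle_rng.random() < freq[best])
            t += 1
    return ReplayResult(arms=arms, rewards=rewards, policy=label, oracle_rewards=oracle_rewards)


# ---------------------------------------------------------------------------
# synthetic stream generation
# ---------------------------------------------------------------------------


def synth_stream(
    prior_schedule: np.ndarray,
    mode: str = "single",
    rng=None,
    alphabet: Sequence[str] | None = None,
) -> LabeledStream:
    """Sample a labeled stream from a T x K class-prior schedule.

    In single-label mode row ``t`` must sum to 1 and yields one class
    per instance.  In multi-label mode each class is included
    independently with its scheduled probability; all-empty draws are
    rejected and redrawn so every instance carries at least one label.
    """
    priors = np.asarray(prior_schedule, dtype=float)
    if priors.ndim != 2:
        raise ValueError(f"prior schedule must be T x K, got shape {priors.shape}")
    T, K = priors.shape
    if np.any((priors < 0) | (priors > 1)):
        raise ValueError("priors must lie in [0, 1]")
    if alphabet is None:
        alphabet = tuple(f"C{k}" for k in range(K))
    alphabet = tuple(alphabet)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    if mode == "single":
        row_sums = priors.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-8):
            bad = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(f"single-label priors must sum to 1 per step (row {bad} sums to {row_sums[bad]:g})")
        cum = np.cumsum(priors, axis=1)
        u = rng.random(T)
        picks = (u[:, None] > cum).sum(axis=1)
        labels = tuple(frozenset({alphabet[k]}) for k in picks)
    elif mode == "multi":
        include = rng.random((T, K)) < priors
        empty = np.flatnonzero(~include.any(axis=1))
        for t in empty:
            while not include[t].any():            # rejection: redraw empty rows
                include[t] = rng.random(K) < priors[t]
        labels = tuple(
            frozenset(alphabet[k] for k in np.flatnonzero(include[t])) for t in range(T)
        )
    else:
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    return LabeledStream(steps=np.arange(T), labels=labels, alphabet=alphabet, mode=mode)


# ---------------------------------------------------------------------------
# fixture recipes — synthetic stand-ins for the real-stream archetypes
# ---------------------------------------------------------------------------


def _normalize_rows(w: np.ndarray) -> np.ndarray:
    return w / w.sum(axis=1, keepdims=True)


def crime_like_priors(T: int = 5000, K: int = 9, noise: float = 0.02, rng=None) -> np.ndarray:
    """Pseudo-stationary noisy priors over many classes (incident-report style).

    Base class weights are fixed and mildly imbalanced; small smooth
    noise perturbs them so the stream looks drifting without any real
    concept change.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base = np.linspace(1.0, 2.0, K)
    wiggle = rng.normal(0.0, noise, size=(T, K))
    # smooth the noise with a short moving average so bins look correlated
    kernel = np.ones(25) / 25
    for k in range(K):
        wiggle[:, k] = np.convolve(wiggle[:, k], kernel, mode="same")
    w = np.clip(base + wiggle, 1e-3, None)
    return _normalize_rows(w)


def insects_like_priors(T: int = 6000, rng=None) -> np.ndarray:
    """Imbalanced 6-class single-label priors with mixed drifts.

    One class undergoes an abrupt switch, one a slow ramp, one a
    reoccurring on/off alternation; the remainder stay stationary at
    unequal weights.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = np.empty((T, 6))
    w[:, 0] = drift_schedule("sudden", T, start=0.40, end=0.05, t_change=T // 3)
    w[:, 1] = drift_schedule(
        "incremental", T, start=0.05, end=0.35, t_start=T // 3, t_end=2 * T // 3
    )
    w[:, 2] = drift_schedule(
        "reoccurring", T, base=0.10, new=0.30, t_start=T // 4, t_end=T // 2, cycle=T // 2
    )
    w[:, 3] = 0.20
    w[:, 4] = 0.10
    w[:, 5] = 0.05
    return _normalize_rows(w)


def news_like_priors(T: int = 4000, rng=None) -> np.ndarray:
    """Multi-label inclusion probabilities for 5 topics.

    One topic has a sudden popularity jump, another a gradual
    (stochastically alternating) decline; the rest are stationary.
    Rows are inclusion probabilities, not normalised.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    p = np.empty((T, 5))
    p[:, 0] = drift_schedule("sudden", T, start=0.10, end=0.45, t_change=T // 2)
    p[:, 1] = drift_schedule(
        "gradual", T, start=0.40, end=0.10, t_start=T // 4, t_end=3 * T // 4, rng=rng
    )
    p[:, 2] = 0.30
    p[:, 3] = 0.20
    p[:, 4] = 0.15
    return p


def microbes_like_table(
    n_bins: int = 48, K: int = 10, steps_per_bin: int = 120, rng=None
) -> FrequencyTable:
    """Per-bin community frequency table with slow compositional turnover.

    Community weights follow a smooth random walk on the simplex so the
    dominant class changes a handful of times across the bins, as in
    longitudinal community profiling.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    logw = rng.normal(0.0, 1.0, size=K)
    rows = np.empty((n_bins, K))
    for b in range(n_bins):
        logw = logw + rng.normal(0.0, 0.25, size=K)
        w = np.exp(logw)
        rows[b] = w / w.sum()
    return FrequencyTable(freqs=rows, steps_per_bin=steps_per_bin)
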