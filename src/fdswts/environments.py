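"""Non-stationary Bernoulli environments and concept-drift schedules.

An :class:`Environment` is a fully materialised T x K matrix of
Bernoulli parameters ``mu[t, k]`` — the expected reward of arm ``k`` at
step ``t`` — plus the provenance needed to regenerate it.  Materialising
the whole schedule up front makes the dynamic oracle (argmax over the
true means at every step) well defined.

Two randomly generated families mirror the synthetic study conditions:

* ``random-abrupt`` — every arm starts at mu ~ U[0, 1] and at each step
  independently jumps, with probability ``d``, to a fresh U[0, 1] value;
* ``random-incremental`` — with probability ``d`` an idle arm starts a
  linear drift toward a fresh U[0, 1] target at a per-step rate
  delta ~ U(0.001, 0.01), clamping exactly at the target; an arm cannot
  begin a new drift while one is in progress.

Three hand-set 4-arm, 1000-step environments (``decreasing``,
``increasing``, ``stationary``) probe sudden loss of the best arm,
emergence of a new best arm, and the no-drift case.  The generic
:func:`drift_schedule` builds single-arm trajectories for the four drift
archetypes (sudden, incremental, gradual, reoccurring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Environment",
    "make_random_abrupt",
    "make_random_incremental",
    "make_custom",
    "drift_schedule",
    "CUSTOM_NAMES",
]

DEFAULT_DELTA_RANGE = (0.001, 0.01)


@dataclass(frozen=True)
class Environment:
    """A materialised non-stationary Bernoulli bandit environment.

    ``mu`` has shape (T, K): row ``t`` holds the per-arm success
    probabilities in force at step ``t`` (0-based).
    """

    mu: np.ndarray
    name: str = "custom"
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        if mu.ndim != 2 or mu.shape[0] < 1 or mu.shape[1] < 1:
            raise ValueError(f"mu must be a T x K matrix with T, K >= 1, got shape {mu.shape}")
        if np.any((mu < 0) | (mu > 1)):
            raise ValueError("all Bernoulli parameters must lie in [0, 1]")
        mu.setflags(write=False)
        object.__setattr__(self, "mu", mu)

    @property
    def horizon(self) -> int:
        return self.mu.shape[0]

    @property
    def arm_count(self) -> int:
        return self.mu.shape[1]

    def reward(self, t: int, arm: int, rng: np.random.Generator) -> int:
        """Draw the binary reward of ``arm`` at step ``t`` (one rng draw)."""
        if not 0 <= t < self.horizon:
            raise IndexError(f"step {t} out of range [0, {self.horizon})")
        if not 0 <= arm < self.arm_count:
            raise IndexError(f"arm {arm} out of range for {self.arm_count} arms")
        return int(rng.random() < self.mu[t, arm])

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (columns t, arm, mu) for export/inspection."""
        T, K = self.mu.shape
        return pd.DataFrame(
            {
                "t": np.repeat(np.arange(T), K),
                "arm": np.tile(np.arange(K), T),
                "mu": self.mu.ravel(),
            }
        )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_random_abrupt(K: int, T: int, d: float, rng=None) -> Environment:
    """Environment with sudden, independent per-arm jumps.

    Each arm starts at mu ~ U[0, 1]; at every later step, independently
    and with probability ``d``, its parameter is replaced by a fresh
    U[0, 1] draw (applied before the step's reward is sampled).
    """
    _check_dims(K, T)
    d = _check_prob(d, "d")
    rng = _as_rng(rng)
    mu = np.empty((T, K))
    mu[0] = rng.uniform(size=K)
    for t in range(1, T):
        jump = rng.random(K) < d
        fresh = rng.uniform(size=K)
        mu[t] = np.where(jump, fresh, mu[t - 1])
    return Environment(mu, name="random-abrupt", params={"K": K, "T": T, "d": d})


def make_random_incremental(
    K: int, T: int, d: float, delta_range: tuple[float, float] = DEFAULT_DELTA_RANGE, rng=None
) -> Environment:
    """Environment with gradual linear per-arm drifts.

    With probability ``d`` per step an *idle* arm begins moving toward a
    fresh target mu_new ~ U[0, 1] in steps of delta ~ U(delta_range),
    clamping exactly at the target; while a drift is in progress the arm
    cannot start another.
    """
    _check_dims(K, T)
    d = _check_prob(d, "d")
    lo, hi = map(float, delta_range)
    if not (0 < lo <= hi):
        raise ValueError(f"delta_range must satisfy 0 < lo <= hi, got {delta_range}")
    rng = _as_rng(rng)
    mu = np.empty((T, K))
    mu[0] = rng.uniform(size=K)
    target = mu[0].copy()          # equal to current value => idle
    delta = np.zeros(K)
    for t in range(1, T):
        current = mu[t - 1].copy()
        idle = current == target
        starts = idle & (rng.random(K) < d)
        if np.any(starts):
            target[starts] = rng.uniform(size=int(starts.sum()))
            delta[starts] = rng.uniform(lo, hi, size=int(starts.sum()))
        moving = current != target
        step = np.sign(target - current) * delta
        nxt = current + np.where(moving, step, 0.0)
        # clamp on overshoot so the trajectory ends exactly on target
        overshoot = (step > 0) & (nxt > target) | (step < 0) & (nxt < target)
        nxt[overshoot] = target[overshoot]
        mu[t] = nxt
    return Environment(
        mu,
        name="random-incremental",
        params={"K": K, "T": T, "d": d, "delta_range": (lo, hi)},
    )


# Hand-set 4-arm, 1000-step scenarios.  Change-points are half-open:
# steps 0..249 hold the initial values, step 250 onward the second
# block, step 500 onward the third.
CUSTOM_NAMES = ("decreasing", "increasing", "stationary")

_CUSTOM_BLOCKS = {
    # name: (initial mu, {(step, arm): new value})
    "decreasing": ([0.9, 0.7, 0.1, 0.3], {(250, 0): 0.0, (500, 1): 0.0}),
    "increasing": ([0.0, 0.0, 0.1, 0.3], {(250, 0): 0.7, (500, 1): 0.9}),
    "stationary": ([0.2, 0.3, 0.4, 0.5], {}),
}


def make_custom(name: str, T: int = 1000) -> Environment:
    """One of the three hand-set 4-arm scenarios (1000 steps by default)."""
    if name not in _CUSTOM_BLOCKS:
        raise ValueError(f"unknown custom scenario {name!r}; expected one of {CUSTOM_NAMES}")
    initial, changes = _CUSTOM_BLOCKS[name]
    mu = np.tile(np.asarray(initial, dtype=float), (T, 1))
    for (step, arm), value in changes.items():
        if step < T:
            mu[step:, arm] = value
    return Environment(mu, name=f"custom-{name}", params={"T": T})


def drift_schedule(kind: str, T: int, *, rng=None, **params) -> np.ndarray:
    """Build one length-T trajectory in [0, 1] for a drift archetype.

    Parameters by kind (all step indices 0-based, within [0, T]):

    - ``stationary``: ``value``
    - ``sudden``: ``start`` (before), ``end`` (after), ``t_change``
    - ``incremental``: ``start``, ``end``, ``t_start``, ``t_end`` —
      linear ramp over [t_start, t_end], endpoints exact
    - ``gradual``: ``start``, ``end``, ``t_start``, ``t_end`` — during
      the transition each step takes the new value with a probability
      rising linearly from 0 to 1 (needs ``rng``)
    - ``reoccurring``: ``base``, ``new``, ``t_start``, ``t_end``,
      optional ``cycle`` — the new value holds on [t_start, t_end) and
      reverts; with ``cycle`` the on/off pattern repeats with that period
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    t = np.arange(T)

    if kind == "stationary":
        value = _check_prob(params["value"], "value")
        return np.full(T, value)

    if kind == "sudden":
        a = _check_prob(params["start"], "start")
        b = _check_prob(params["end"], "end")
        tc = _check_step(params["t_change"], T)
        return np.where(t < tc, a, b)

    if kind == "incremental":
        a = _check_prob(params["start"], "start")
        b = _check_prob(params["end"], "end")
        t0, t1 = _check_step(params["t_start"], T), _check_step(params["t_end"], T)
        if t1 <= t0:
            raise ValueError(f"t_end must exceed t_start, got ({t0}, {t1})")
        return np.interp(t, [t0, t1], [a, b])

    if kind == "gradual":
        a = _check_prob(params["start"], "start")
        b = _check_prob(params["end"], "end")
        t0, t1 = _check_step(params["t_start"], T), _check_step(params["t_end"], T)
        if t1 <= t0:
            raise ValueError(f"t_end must exceed t_start, got ({t0}, {t1})")
        rng = _as_rng(rng)
        out = np.where(t < t0, a, b).astype(float)
        span = np.arange(t0, min(t1, T))
        p_new = (span - t0 + 1) / (t1 - t0)          # rises to 1 at t_end
        use_new = rng.random(span.size) < p_new
        out[span] = np.where(use_new, b, a)
        return out

    if kind == "reoccurring":
        base = _check_prob(params["base"], "base")
        new = _check_prob(params["new"], "new")
        t0, t1 = _check_step(params["t_start"], T), _check_step(params["t_end"], T)
        if t1 <= t0:
            raise ValueError(f"t_end must exceed t_start, got ({t0}, {t1})")
        cycle = params.get("cycle")
        if cycle is None:
            on = (t >= t0) & (t < t1)
        else:
            cycle = int(cycle)
            if cycle < t1 - t0:
                raise ValueError("cycle must be at least the on-interval length")
            phase = (t - t0) % cycle
            on = (t >= t0) & (phase < (t1 - t0))
        return np.where(on, new, base)

    raise ValueError(f"unknown drift kind {kind!r}")


def _check_dims(K: int, T: int) -> None:
    if K < 1 or T < 1:
        raise ValueError(f"K and T must be >= 1, got K={K}, T={T}")


def _check_prob(x, name: str) -> float:
    x = float(x)
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


def _check_step(x, T: int) -> int:
    x = int(x)
    if not 0 <= x <= T:
        raise ValueError(f"change-point {x} outside [0, {T}]")
    return x
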