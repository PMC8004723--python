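"""Arm-selection policies for the non-stationary Bernoulli bandit.

The central algorithm is f-Discounted-Sliding-Window Thompson Sampling
(f-dsw TS).  Each arm keeps two Beta posteriors over its Bernoulli
parameter:

* a **historic trace** — discounted pseudo-counts ``(s, f)`` over the
  whole reward history, decayed by a factor ``gamma`` every step so that
  old evidence fades out and posterior variance stays inflated;
* a **hot trace** — a Beta posterior built from only the last ``n``
  rewards observed for that arm (a per-arm FIFO window).

At selection time one sample is drawn from each trace and the two are
combined by an aggregation function ``f`` (min / max / mean); the arm
with the largest aggregated score is played.

Baselines implemented alongside: plain Thompson Sampling, Discounted TS
(historic trace only), Sliding-Window TS (one *global* window shared by
all arms), a uniform-random policy and the dynamic oracle.

RNG discipline: every policy draws its per-step Beta samples with a
single vectorised call in fixed arm order, so that policies which are
mathematically equivalent in a limit (e.g. Discounted TS with gamma=1
and plain TS) consume the random stream identically and produce
byte-identical trajectories from the same seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BetaTrace",
    "HotWindow",
    "ArmScore",
    "PolicyConfig",
    "Policy",
    "ThompsonSampling",
    "DiscountedTS",
    "SlidingWindowTS",
    "FDSWThompsonSampling",
    "RandomPolicy",
    "OraclePolicy",
    "AGGREGATIONS",
    "make_policy",
    "policy_from_spec",
]


# ---------------------------------------------------------------------------
# per-arm state containers
# ---------------------------------------------------------------------------


class BetaTrace:
    """Discounted success/failure pseudo-counts behind one arm's historic trace.

    The stored evidence ``(s, f)`` starts at ``(0, 0)`` and the posterior
    sampled from is ``Beta(s + 1, f + 1)``: the uniform Beta(1, 1) prior
    is a fixed offset that is never decayed, so the posterior shapes stay
    >= 1 no matter how small ``gamma**t`` becomes.
    """

    __slots__ = ("s", "f")

    def __init__(self, s: float = 0.0, f: float = 0.0) -> None:
        if s < 0 or f < 0:
            raise ValueError(f"pseudo-counts must be non-negative, got ({s}, {f})")
        self.s = float(s)
        self.f = float(f)

    @property
    def alpha(self) -> float:
        """Posterior first shape parameter (prior included)."""
        return self.s + 1.0

    @property
    def beta(self) -> float:
        """Posterior second shape parameter (prior included)."""
        return self.f + 1.0

    def discount(self, gamma: float) -> None:
        self.s *= gamma
        self.f *= gamma

    def add(self, reward: int) -> None:
        reward = _check_reward(reward)
        self.s += reward
        self.f += 1 - reward

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value from the posterior Beta(s + 1, f + 1)."""
        return float(rng.beta(self.alpha, self.beta))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BetaTrace(s={self.s:g}, f={self.f:g})"


class HotWindow:
    """Bounded FIFO of the last ``capacity`` binary rewards of one arm.

    The hot-trace posterior is ``Beta(1 + successes, 1 + failures)`` over
    the current contents; while fewer than ``capacity`` rewards have been
    seen the window simply holds all of them, and an empty window yields
    the uniform prior.
    """

    __slots__ = ("capacity", "_buf", "_successes")

    def __init__(self, capacity: int, contents: Sequence[int] = ()) -> None:
        capacity = int(capacity)
        if capacity < 1:
            raise ValueError(f"window capacity must be >= 1, got {capacity}")
        self.capacity = capacity
        self._buf: deque[int] = deque(maxlen=capacity)
        self._successes = 0
        for r in contents:
            self.append(r)

    def append(self, reward: int) -> None:
        reward = _check_reward(reward)
        if len(self._buf) == self.capacity:
            self._successes -= self._buf[0]  # evicted by maxlen below
        self._buf.append(reward)
        self._successes += reward

    @property
    def contents(self) -> tuple[int, ...]:
        return tuple(self._buf)

    @property
    def successes(self) -> int:
        return self._successes

    @property
    def failures(self) -> int:
        return len(self._buf) - self._successes

    @property
    def alpha(self) -> float:
        return 1.0 + self._successes

    @property
    def beta(self) -> float:
        return 1.0 + self.failures

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))

    def __len__(self) -> int:
        return len(self._buf)

    def __repr__(self) -> str:  # pragma: no cover
        return f"HotWindow(capacity={self.capacity}, contents={list(self._buf)})"


@dataclass(frozen=True)
class ArmScore:
    """Audit record of one arm's draws at a selection step."""

    theta: float        # sample from the historic trace
    theta_hot: float    # sample from the hot trace
    score: float        # f(theta, theta_hot)


def _check_reward(reward) -> int:
    r = float(reward)
    if r not in (0.0, 1.0):
        raise ValueError(f"reward must be binary (0 or 1), got {reward!r}")
    return int(r)


# ---------------------------------------------------------------------------
# aggregation functions for f-dsw
# ---------------------------------------------------------------------------

AGGREGATIONS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "min": np.minimum,
    "max": np.maximum,
    "mean": lambda a, b: 0.5 * (a + b),
}


# ---------------------------------------------------------------------------
# policies
# ---------------------------------------------------------------------------


class Policy:
    """Interface shared by all policies.

    ``select`` consumes randomness from ``rng`` and returns the arm to
    play; ``update`` feeds back the observed binary reward.  ``mu_t`` is
    the true per-arm expected-reward vector for the current step and is
    only consulted by the oracle.
    """

    kind: str = "abstract"

    def __init__(self, arm_count: int) -> None:
        arm_count = int(arm_count)
        if arm_count < 1:
            raise ValueError(f"arm_count must be >= 1, got {arm_count}")
        self.arm_count = arm_count

    def select(self, rng: np.random.Generator, mu_t: np.ndarray | None = None) -> int:
        raise NotImplementedError

    def update(self, arm: int, reward: int) -> None:
        raise NotImplementedError

    def _check_arm(self, arm: int) -> int:
        arm = int(arm)
        if not 0 <= arm < self.arm_count:
            raise IndexError(f"arm {arm} out of range for {self.arm_count} arms")
        return arm

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}(K={self.arm_count})"


class ThompsonSampling(Policy):
    """Standard Beta-Bernoulli Thompson Sampling (stationary baseline)."""

    kind = "ts"

    def __init__(self, arm_count: int) -> None:
        super().__init__(arm_count)
        self._s = np.zeros(arm_count)
        self._f = np.zeros(arm_count)

    @property
    def traces(self) -> list[BetaTrace]:
        return [BetaTrace(s, f) for s, f in zip(self._s, self._f)]

    def select(self, rng: np.random.Generator, mu_t=None) -> int:
        theta = rng.beta(self._s + 1.0, self._f + 1.0)
        return int(np.argmax(theta))  # argmax breaks ties at the lowest index

    def update(self, arm: int, reward) -> None:
        arm = self._check_arm(arm)
        r = _check_reward(reward)
        self._s[arm] += r
        self._f[arm] += 1 - r


class DiscountedTS(ThompsonSampling):
    """Thompson Sampling with geometrically discounted pseudo-counts.

    Every step all arms' evidence is multiplied by ``gamma`` in (0, 1]
    and the played arm then receives the fresh reward, so an unplayed
    arm's posterior relaxes toward the uniform prior.  With
    ``discount_unplayed=False`` only the played arm is decayed (a
    sensitivity variant; the default decays everything).
    """

    kind = "d-ts"

    def __init__(self, arm_count: int, gamma: float, discount_unplayed: bool = True) -> None:
        super().__init__(arm_count)
        self.gamma = _check_gamma(gamma)
        self.discount_unplayed = bool(discount_unplayed)

    def update(self, arm: int, reward) -> None:
        arm = self._check_arm(arm)
        r = _check_reward(reward)
        if self.discount_unplayed:
            self._s *= self.gamma
            self._f *= self.gamma
        else:
            self._s[arm] *= self.gamma
            self._f[arm] *= self.gamma
        self._s[arm] += r
        self._f[arm] += 1 - r


class SlidingWindowTS(Policy):
    """Thompson Sampling over one global FIFO window of the last ``n`` plays.

    The window stores ``(arm, reward)`` pairs across *all* arms; at
    selection time each arm's posterior is Beta(1 + its successes in the
    window, 1 + its failures in the window).  An arm absent from the
    window is sampled from the uniform prior.
    """

    kind = "sw-ts"

    def __init__(self, arm_count: int, window: int) -> None:
        super().__init__(arm_count)
        window = int(window)
        if window < 1:
            raise ValueError(f"window size must be >= 1, got {window}")
        self.window = window
        self._buf: deque[tuple[int, int]] = deque()
        self._s = np.zeros(arm_count)
        self._f = np.zeros(arm_count)

    @property
    def window_contents(self) -> tuple[tuple[int, int], ...]:
        return tuple(self._buf)

    def select(self, rng: np.random.Generator, mu_t=None) -> int:
        theta = rng.beta(self._s + 1.0, self._f + 1.0)
        return int(np.argmax(theta))

    def update(self, arm: int, reward) -> None:
        arm = self._check_arm(arm)
        r = _check_reward(reward)
        if len(self._buf) == self.window:
            old_arm, old_r = self._buf.popleft()
            self._s[old_arm] -= old_r
            self._f[old_arm] -= 1 - old_r
        self._buf.append((arm, r))
        self._s[arm] += r
        self._f[arm] += 1 - r


class FDSWThompsonSampling(Policy):
    """f-Discounted-Sliding-Window Thompson Sampling.

    Parameters
    ----------
    arm_count
        Number of arms K.
    gamma
        Discount factor in (0, 1] applied to the historic traces each step.
    window
        Capacity ``n`` of each arm's hot window.
    aggregation
        ``"min"`` (pessimistic), ``"max"`` (optimistic) or ``"mean"``
        (averaged), or any callable combining two score vectors
        element-wise.
    discount_unplayed
        If True (default) every arm's historic trace is decayed each
        step; if False only the played arm's.
    """

    kind = "f-dsw"

    def __init__(
        self,
        arm_count: int,
        gamma: float,
        window: int,
        aggregation: str | Callable = "mean",
        discount_unplayed: bool = True,
    ) -> None:
        super().__init__(arm_count)
        self.gamma = _check_gamma(gamma)
        if int(window) < 1:
            raise ValueError(f"window size must be >= 1, got {window}")
        self.window = int(window)
        if callable(aggregation):
            self.aggregation = aggregation
            self.aggregation_name = getattr(aggregation, "__name__", "custom")
        else:
            if aggregation not in AGGREGATIONS:
                raise ValueError(
                    f"unknown aggregation {aggregation!r}; expected one of {sorted(AGGREGATIONS)}"
                )
            self.aggregation = AGGREGATIONS[aggregation]
            self.aggregation_name = aggregation
        self.discount_unplayed = bool(discount_unplayed)
        self._s = np.zeros(arm_count)
        self._f = np.zeros(arm_count)
        self.windows = [HotWindow(self.window) for _ in range(arm_count)]
        # hot posterior shapes mirrored as arrays so select() stays vectorised
        self._hot_a = np.ones(arm_count)
        self._hot_b = np.ones(arm_count)
        self._last_draws: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def traces(self) -> list[BetaTrace]:
        return [BetaTrace(s, f) for s, f in zip(self._s, self._f)]

    def select(self, rng: np.random.Generator, mu_t=None) -> int:
        theta = rng.beta(self._s + 1.0, self._f + 1.0)
        theta_hot = rng.beta(self._hot_a, self._hot_b)
        score = self.aggregation(theta, theta_hot)
        self._last_draws = (theta, theta_hot, score)
        return int(np.argmax(score))

    @property
    def last_scores(self) -> list[ArmScore]:
        """Audit record of the most recent selection's per-arm draws."""
        if self._last_draws is None:
            return []
        theta, theta_hot, score = self._last_draws
        return [
            ArmScore(float(t), float(th), float(s))
            for t, th, s in zip(theta, theta_hot, score)
        ]

    def update(self, arm: int, reward) -> None:
        arm = self._check_arm(arm)
        r = _check_reward(reward)
        if self.discount_unplayed:
            self._s *= self.gamma
            self._f *= self.gamma
        else:
            self._s[arm] *= self.gamma
            self._f[arm] *= self.gamma
        self._s[arm] += r
        self._f[arm] += 1 - r
        self.windows[arm].append(r)
        w = self.windows[arm]
        self._hot_a[arm] = w.alpha
        self._hot_b[arm] = w.beta


class RandomPolicy(Policy):
    """Uniform-random arm selection (sanity-floor baseline)."""

    kind = "random"

    def select(self, rng: np.random.Generator, mu_t=None) -> int:
        return int(rng.integers(self.arm_count))

    def update(self, arm: int, reward) -> None:
        self._check_arm(arm)
        _check_reward(reward)


class OraclePolicy(Policy):
    """Dynamic oracle: plays argmax of the true expected-reward vector.

    Requires ``mu_t`` at selection time; ties go to the lowest index.
    """

    kind = "oracle"

    def select(self, rng: np.random.Generator, mu_t: np.ndarray | None = None) -> int:
        if mu_t is None:
            raise ValueError("oracle policy requires the true mu_t vector")
        mu_t = np.asarray(mu_t, dtype=float)
        if mu_t.size == 0:
            raise ValueError("mu_t vector is empty")
        if mu_t.size != self.arm_count:
            raise ValueError(
                f"mu_t has {mu_t.size} entries but policy has {self.arm_count} arms"
            )
        return int(np.argmax(mu_t))

    def update(self, arm: int, reward) -> None:
        self._check_arm(arm)
        _check_reward(reward)


def _check_gamma(gamma: float) -> float:
    gamma = float(gamma)
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    return gamma


# ---------------------------------------------------------------------------
# configuration / construction
# ---------------------------------------------------------------------------

_KIND_ALIASES = {
    "ts": "ts",
    "thompson": "ts",
    "d-ts": "d-ts",
    "dts": "d-ts",
    "sw-ts": "sw-ts",
    "swts": "sw-ts",
    "f-dsw": "f-dsw",
    "fdsw": "f-dsw",
    "random": "random",
    "oracle": "oracle",
}


@dataclass(frozen=True)
class PolicyConfig:
    """Immutable recipe for building a fresh policy instance.

    ``kind`` is one of ``ts``, ``d-ts``, ``sw-ts``, ``f-dsw``, ``random``
    or ``oracle``; parameters not used by a kind are ignored when
    building but kept for the record.
    """

    kind: str
    arm_count: int
    gamma: float = 1.0
    window: int | None = None
    aggregation: str = "mean"
    discount_unplayed: bool = True
    label: str = field(default="", compare=False)

    def __post_init__(self):
        kind = _KIND_ALIASES.get(self.kind)
        if kind is None:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    def default_label(self) -> str:
        if self.kind == "f-dsw":
            return f"{self.aggregation}-dsw"
        return self.kind

    def build(self) -> Policy:
        """Instantiate a fresh, state-free policy from this config."""
        k = self.kind
        if k == "ts":
            return ThompsonSampling(self.arm_count)
        if k == "d-ts":
            return DiscountedTS(self.arm_count, self.gamma, self.discount_unplayed)
        if k == "sw-ts":
            if self.window is None:
                raise ValueError("sw-ts requires a window size n")
            return SlidingWindowTS(self.arm_count, self.window)
        if k == "f-dsw":
            if self.window is None:
                raise ValueError("f-dsw requires a window size n")
            return FDSWThompsonSampling(
                self.arm_count,
                self.gamma,
                self.window,
                self.aggregation,
                self.discount_unplayed,
            )
        if k == "random":
            return RandomPolicy(self.arm_count)
        if k == "oracle":
            return OraclePolicy(self.arm_count)
        raise AssertionError(k)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "arm_count": self.arm_count,
            "gamma": self.gamma,
            "window": self.window,
            "aggregation": self.aggregation,
            "discount_unplayed": self.discount_unplayed,
            "label": self.label,
        }


def make_policy(kind: str, arm_count: int, **kwargs) -> Policy:
    """Convenience constructor: build a policy directly from keyword args."""
    return PolicyConfig(kind=kind, arm_count=arm_count, **kwargs).build()


# spec tokens like "fdsw-mean:gamma=0.95,n=25" or "min-dsw:gamma=0.95,n=100"
_SPEC_NAMES = {
    "ts": ("ts", {}),
    "d-ts": ("d-ts", {}),
    "dts": ("d-ts", {}),
    "sw-ts": ("sw-ts", {}),
    "swts": ("sw-ts", {}),
    "random": ("random", {}),
    "oracle": ("oracle", {}),
    "fdsw-min": ("f-dsw", {"aggregation": "min"}),
    "fdsw-max": ("f-dsw", {"aggregation": "max"}),
    "fdsw-mean": ("f-dsw", {"aggregation": "mean"}),
    "min-dsw": ("f-dsw", {"aggregation": "min"}),
    "max-dsw": ("f-dsw", {"aggregation": "max"}),
    "mean-dsw": ("f-dsw", {"aggregation": "mean"}),
}


def policy_from_spec(spec: str, arm_count: int) -> PolicyConfig:
    """Parse a compact policy token into a :class:`PolicyConfig`.

    Tokens have the form ``name[:key=value,...]``, e.g. ``ts``,
    ``d-ts:gamma=0.98``, ``sw-ts:n=100`` or ``fdsw-mean:gamma=0.95,n=25``.
    Recognised keys: ``gamma``, ``n``/``window``, ``f``/``aggregation``,
    ``discount_unplayed``.
    """
    name, _, tail = spec.strip().partition(":")
    name = name.lower()
    if name not in _SPEC_NAMES:
        raise ValueError(f"unknown policy name {name!r} in spec {spec!r}")
    kind, kwargs = _SPEC_NAMES[name]
    kwargs = dict(kwargs)
    if tail:
        for item in tail.split(","):
            key, _, value = item.partition("=")
            if not value:
                raise ValueError(f"malformed parameter {item!r} in spec {spec!r}")
            key = key.strip().lower()
            value = value.strip()
            if key == "gamma":
                kwargs["gamma"] = float(value)
            elif key in ("n", "window"):
                kwargs["window"] = int(value)
            elif key in ("f", "aggregation"):
                kwargs["aggregation"] = value
            elif key == "discount_unplayed":
                kwargs["discount_unplayed"] = value.lower() in ("1", "true", "yes")
            else:
                raise ValueError(f"unknown parameter {key!r} in spec {spec!r}")
    return PolicyConfig(kind=kind, arm_count=arm_count, label=spec.strip(), **kwargs)
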