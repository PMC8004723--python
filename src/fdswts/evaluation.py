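"""Episode runner, performance metrics and scenario-level aggregation.

Metrics
-------
Against a fully materialised environment the clairvoyant *dynamic
oracle* plays ``argmax_k mu[t, k]`` at every step; its cumulative
expected reward is ``D(T) = sum_t max_k mu[t, k]``.  A policy's dynamic
regret is measured in expected value,

    R(t) = sum_{s<=t} mu*_s - sum_{s<=t} mu_{s, I(s)},

while the relative cumulative reward RCR = CR(M) / CR(O) compares
*realised* reward sums, with the oracle drawing its own reward stream.
Accuracy is simply CR(T) / T.

A *scenario* is a family of environments (many random draws, or many
replicate episodes of one fixed environment); :func:`run_scenario` runs
every policy on each member with paired seeds and averages.
:func:`grid_tune` evaluates a (gamma, n) grid by mean RCR and returns
the argmax.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environments import (
    CUSTOM_NAMES,
    DEFAULT_DELTA_RANGE,
    Environment,
    make_custom,
    make_random_abrupt,
    make_random_incremental,
)
from .policies import Policy, PolicyConfig, policy_from_spec

__all__ = [
    "RunResult",
    "ScenarioSummary",
    "run_episode",
    "oracle_value",
    "regret",
    "rcr",
    "accuracy",
    "run_scenario",
    "grid_tune",
    "episode_frame",
]


def _rng(*key: int) -> np.random.Generator:
    """Named substream: a fresh generator keyed by a tuple of integers."""
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


@dataclass(frozen=True)
class RunResult:
    """Record of one policy episode on one environment."""

    arms: np.ndarray        # chosen arm per step, shape (T,)
    rewards: np.ndarray     # realised binary rewards, shape (T,)
    mu_star: np.ndarray     # oracle expected value per step
    mu_chosen: np.ndarray   # true mean of the chosen arm per step
    policy: str = ""
    environment: str = ""

    @property
    def horizon(self) -> int:
        return len(self.rewards)

    @property
    def cumulative_reward(self) -> int:
        """CR(T): total realised reward."""
        return int(self.rewards.sum())

    @property
    def accuracy(self) -> float:
        """CR(T) / T."""
        if self.horizon == 0:
            raise ValueError("empty run has no accuracy")
        return self.cumulative_reward / self.horizon

    def reward_curve(self) -> np.ndarray:
        return np.cumsum(self.rewards)

    def regret_curve(self) -> np.ndarray:
        """Expected-value dynamic regret, cumulative over steps."""
        return np.cumsum(self.mu_star - self.mu_chosen)


def _as_policy(policy, arm_count: int) -> tuple[Policy, str]:
    if isinstance(policy, Policy):
        return policy, policy.kind
    if isinstance(policy, PolicyConfig):
        return policy.build(), policy.label
    if isinstance(policy, str):
        cfg = policy_from_spec(policy, arm_count)
        return cfg.build(), cfg.label
    raise TypeError(f"cannot interpret {policy!r} as a policy")


def run_episode(policy, env: Environment, seed=None, rng=None) -> RunResult:
    """Play one full episode of ``policy`` on ``env``.

    ``policy`` may be a :class:`Policy` instance (updated in place), a
    :class:`PolicyConfig`, or a spec string like ``"fdsw-mean:gamma=0.95,n=25"``
    (a fresh instance is built).  Deterministic given the seed.
    """
    agent, label = _as_policy(policy, env.arm_count)
    if agent.arm_count != env.arm_count:
        raise ValueError(
            f"policy has {agent.arm_count} arms but environment has {env.arm_count}"
        )
    if rng is None:
        rng = _rng(*np.atleast_1d(0 if seed is None else seed))
    T = env.horizon
    mu = env.mu
    arms = np.empty(T, dtype=np.int64)
    rewards = np.empty(T, dtype=np.int64)
    for t in range(T):
        arm = agent.select(rng, mu_t=mu[t])
        r = env.reward(t, arm, rng)
        agent.update(arm, r)
        arms[t] = arm
        rewards[t] = r
    return RunResult(
        arms=arms,
        rewards=rewards,
        mu_star=mu.max(axis=1),
        mu_chosen=mu[np.arange(T), arms],
        policy=label,
        environment=env.name,
    )


def oracle_value(env: Environment) -> tuple[float, np.ndarray]:
    """Return (D(T), per-step mu*) for the dynamic oracle."""
    mu_star = env.mu.max(axis=1)
    return float(mu_star.sum()), mu_star


def regret(run: RunResult) -> np.ndarray:
    """Cumulative expected-value dynamic regret curve R(t)."""
    return run.regret_curve()


def rcr(run: RunResult, oracle_run: RunResult, expected: bool = False) -> float:
    """Relative cumulative reward CR(M) / CR(O).

    By default both numerator and denominator are realised reward sums
    (the oracle run having drawn its own stream).  With ``expected=True``
    the ratio of cumulative *expected* values is used instead, in which
    case ``R(T)/D(T) + RCR = 1`` holds exactly.
    """
    if expected:
        denom = run.mu_star.sum()
        if denom == 0:
            raise ZeroDivisionError("degenerate environment: oracle expected reward is 0")
        return float(run.mu_chosen.sum() / denom)
    denom = oracle_run.cumulative_reward
    if denom == 0:
        raise ZeroDivisionError("degenerate environment: oracle collected no reward")
    return run.cumulative_reward / denom


def accuracy(run: RunResult) -> float:
    """Mean realised reward CR(T) / T."""
    return run.accuracy


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

# substream tags: one per purpose so streams never collide
_TAG_ENV, _TAG_EPISODE, _TAG_ORACLE = 0, 1, 2


@dataclass
class ScenarioSummary:
    """Aggregate of many paired policy/oracle episodes."""

    scenario: str
    params: Mapping
    n_envs: int
    table: pd.DataFrame                      # per-policy means/dispersion
    per_env: pd.DataFrame                    # one row per (policy, env)
    regret_curves: dict[str, np.ndarray] = field(default_factory=dict)
    reward_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_rcr(self, policy: str) -> float:
        return float(self.table.loc[policy, "mean_rcr"])


def _normalize_policies(policy_configs, arm_count: int) -> dict[str, PolicyConfig]:
    if isinstance(policy_configs, Mapping):
        items = policy_configs.items()
        out = {}
        for label, cfg in items:
            if isinstance(cfg, str):
                cfg = policy_from_spec(cfg, arm_count)
            out[label] = cfg
        return out
    out = {}
    for cfg in policy_configs:
        if isinstance(cfg, str):
            cfg = policy_from_spec(cfg, arm_count)
        if cfg.label in out:
            raise ValueError(f"duplicate policy label {cfg.label!r}")
        out[cfg.label] = cfg
    return out


def _scenario_builder(scenario, delta_range=DEFAULT_DELTA_RANGE):
    """Normalise a scenario description to (name, params, builder(seed_key))."""
    if isinstance(scenario, Environment):
        return scenario.name, dict(scenario.params), lambda key: scenario
    if isinstance(scenario, str):
        name = scenario.removeprefix("custom-")
        if name not in CUSTOM_NAMES:
            raise ValueError(f"unknown scenario {scenario!r}")
        env = make_custom(name)
        return env.name, dict(env.params), lambda key: env
    if isinstance(scenario, Mapping):
        cfg = dict(scenario)
        name = cfg.pop("scenario")
        if name in CUSTOM_NAMES or name.removeprefix("custom-") in CUSTOM_NAMES:
            env = make_custom(name.removeprefix("custom-"))
            return env.name, dict(env.params), lambda key: env
        K = int(cfg.get("K", 4))
        T = int(cfg.get("T", 1000))
        d = float(cfg["d"])
        if name == "random-abrupt":
            return name, {"K": K, "T": T, "d": d}, (
                lambda key: make_random_abrupt(K, T, d, rng=_rng(*key))
            )
        if name == "random-incremental":
            dr = tuple(cfg.get("delta_range", delta_range))
            return name, {"K": K, "T": T, "d": d, "delta_range": dr}, (
                lambda key: make_random_incremental(K, T, d, dr, rng=_rng(*key))
            )
        raise ValueError(f"unknown scenario {name!r}")
    raise TypeError(f"cannot interpret {scenario!r} as a scenario")


def run_scenario(
    policy_configs,
    scenario,
    n_envs: int,
    base_seed: int = 0,
    keep_curves: bool = True,
) -> ScenarioSummary:
    """Run every policy over ``n_envs`` environments with paired seeds.

    For random scenarios each of the ``n_envs`` members is an
    independently generated environment; for a fixed (custom)
    environment they are replicate episodes differing only in seed.
    All candidate policies share the same episode substream per member
    (paired comparison); the oracle draws its own reward stream.
    """
    if n_envs < 1:
        raise ValueError(f"n_envs must be >= 1, got {n_envs}")
    name, params, build = _scenario_builder(scenario)
    probe = build((base_seed, 0, _TAG_ENV))
    K, T = probe.arm_count, probe.horizon
    policies = _normalize_policies(policy_configs, K)

    labels = list(policies)
    rcr_vals = {lab: np.empty(n_envs) for lab in labels}
    reg_final = {lab: np.empty(n_envs) for lab in labels}
    acc_vals = {lab: np.empty(n_envs) for lab in labels}
    reg_sum = {lab: np.zeros(T) for lab in labels} if keep_curves else None
    rew_sum = {lab: np.zeros(T) for lab in labels} if keep_curves else None

    for i in range(n_envs):
        env = build((base_seed, i, _TAG_ENV))
        oracle_run = run_episode(
            PolicyConfig("oracle", K), env, rng=_rng(base_seed, i, _TAG_ORACLE)
        )
        for lab in labels:
            run = run_episode(
                policies[lab], env, rng=_rng(base_seed, i, _TAG_EPISODE)
            )
            rcr_vals[lab][i] = rcr(run, oracle_run)
            curve = run.regret_curve()
            reg_final[lab][i] = curve[-1]
            acc_vals[lab][i] = run.accuracy
            if keep_curves:
                reg_sum[lab] += curve
                rew_sum[lab] += run.reward_curve()

    table = pd.DataFrame(
        {
            "mean_rcr": [rcr_vals[lab].mean() for lab in labels],
            "std_rcr": [rcr_vals[lab].std(ddof=1) if n_envs > 1 else 0.0 for lab in labels],
            "mean_final_regret": [reg_final[lab].mean() for lab in labels],
            "std_final_regret": [
                reg_final[lab].std(ddof=1) if n_envs > 1 else 0.0 for lab in labels
            ],
            "mean_accuracy": [acc_vals[lab].mean() for lab in labels],
        },
        index=pd.Index(labels, name="policy"),
    )
    per_env = pd.DataFrame(
        {
            "policy": np.repeat(labels, n_envs),
            "env_id": np.tile(np.arange(n_envs), len(labels)),
            "rcr": np.concatenate([rcr_vals[lab] for lab in labels]),
            "final_regret": np.concatenate([reg_final[lab] for lab in labels]),
            "accuracy": np.concatenate([acc_vals[lab] for lab in labels]),
        }
    )
    return ScenarioSummary(
        scenario=name,
        params=params,
        n_envs=n_envs,
        table=table,
        per_env=per_env,
        regret_curves={lab: reg_sum[lab] / n_envs for lab in labels} if keep_curves else {},
        reward_curves={lab: rew_sum[lab] / n_envs for lab in labels} if keep_curves else {},
    )


# ---------------------------------------------------------------------------
# hyper-parameter tuning
# ---------------------------------------------------------------------------

# grid defaults: the union of discount factors and window sizes that are
# sensible for horizons around 10^3 (synthetic) up to 10^5 (replays)
DEFAULT_GAMMA_GRID = (0.9, 0.95, 0.98, 0.99, 0.999, 0.9999)
DEFAULT_WINDOW_GRID = (25, 50, 75, 100, 200, 400, 800, 3200, 12800)


def grid_tune(
    policy_family: str,
    param_grid: Mapping[str, Sequence] | Sequence[Mapping] | None,
    tuning_scenario=None,
    n_envs: int = 100,
    n_reps: int = 20,
    base_seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Grid-search (gamma, n) for one policy family by mean RCR.

    ``policy_family`` is a spec name (``fdsw-mean``, ``d-ts``, ...);
    ``param_grid`` maps parameter names to candidate values (or is a
    list of explicit parameter dicts).  Each grid point is evaluated on
    the same ``n_envs`` environments with ``n_reps`` independent policy
    replicates per environment, all grid points paired on identical
    seeds.  Default tuning scenario: random-abrupt with d = 0.005.

    Returns ``(best_params, table)`` with the table sorted by mean RCR.
    """
    if tuning_scenario is None:
        tuning_scenario = {"scenario": "random-abrupt", "K": 4, "T": 1000, "d": 0.005}
    if param_grid is None:
        points: list[dict] = [{}]
    elif isinstance(param_grid, Mapping):
        keys = list(param_grid)
        points = [dict(zip(keys, combo)) for combo in itertools.product(*param_grid.values())]
    else:
        points = [dict(p) for p in param_grid]
    if not points:
        raise ValueError("empty parameter grid")

    name, params, build = _scenario_builder(tuning_scenario)
    probe = build((base_seed, 0, _TAG_ENV))
    K = probe.arm_count

    def to_config(pt: dict) -> PolicyConfig:
        spec = policy_family
        if pt:
            spec += ":" + ",".join(f"{k}={v}" for k, v in pt.items())
        return policy_from_spec(spec, K)

    configs = [to_config(pt) for pt in points]
    scores = np.zeros(len(points))
    for i in range(n_envs):
        env = build((base_seed, i, _TAG_ENV))
        for rep in range(n_reps):
            oracle_run = run_episode(
                PolicyConfig("oracle", K), env, rng=_rng(base_seed, i, _TAG_ORACLE, rep)
            )
            for j, cfg in enumerate(configs):
                run = run_episode(cfg, env, rng=_rng(base_seed, i, _TAG_EPISODE, rep))
                scores[j] += rcr(run, oracle_run)
    scores /= n_envs * n_reps

    table = pd.DataFrame(points)
    table["mean_rcr"] = scores
    table = table.sort_values("mean_rcr", ascending=False).reset_index(drop=True)
    best = points[int(np.argmax(scores))]
    return best, table


def episode_frame(
    run: RunResult, scenario: str = "", policy: str | None = None, env_id: int = 0
) -> pd.DataFrame:
    """Tidy per-step view of one run (for CSV export)."""
    T = run.horizon
    return pd.DataFrame(
        {
            "scenario": scenario or run.environment,
            "policy": run.policy if policy is None else policy,
            "env_id": env_id,
            "t": np.arange(T),
            "arm": run.arms,
            "reward": run.rewards,
            "regret": run.regret_curve(),
        }
    )
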