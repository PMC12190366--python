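"""Stochastic and scripted responder models.

The simulated participant makes every protocol exercisable at desk scale:
per-condition lognormal RT kernels, a linear-in-block fatigue drift on RT and
accuracy, a PVT lapse mixture whose lapse probability inflates after the
task, and saturating-exponential subjective-scale trajectories (the increase
is largest after the first block and diminishes thereafter).

These are generative stand-ins with behavior on the scale of published group
descriptives — emulation for testing the machinery, never a reproduction of
any human dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import pool_from_seed
from .config import SessionConfig, tot_config
from .paradigm import expected_key
from .types import TLX_DIMENSIONS, VAS_ITEMS, KeyMapping, SessionLog, Trial, TwoBackTrial


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to a target mean and SD: returns (mu, sigma)."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class VasCurve:
    """Mean VAS trajectory m(b) = baseline + asymptote * (1 - exp(-rate * b))."""

    baseline: float
    asymptote: float
    rate: float
    noise_sd: float = 0.0

    def mean(self, block_index: int) -> float:
        return self.baseline + self.asymptote * (1.0 - math.exp(-self.rate * block_index))


@dataclass(frozen=True)
class ResponderParams:
    """Everything that parameterizes one simulated participant."""

    rt_mean_ms: dict[int, float]
    rt_sd_ms: dict[int, float]
    accuracy: dict[int, float]
    d_rt: float = 0.0   # fractional RT increase per block
    d_acc: float = 0.0  # absolute accuracy decrease per block
    pvt_mean_ms: float = 276.0
    pvt_sd_ms: float = 28.0
    pvt_lapse_prob: float = 0.006
    pvt_post_lapse_multiplier: float = 3.5
    pvt_post_rt_multiplier: float = 1.05
    pvt_lapse_excess_scale_ms: float = 120.0
    vas: dict[str, VasCurve] = field(default_factory=dict)
    tlx_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    tlx_noise_sd: float = 2.5
    twoback_rt_mean_ms: float = 900.0
    twoback_rt_sd_ms: float = 230.0
    twoback_accuracy: float = 0.95
    key_variant: str = "A"

    def __post_init__(self) -> None:
        for cond, acc in self.accuracy.items():
            if not (0.0 <= acc <= 1.0):
                raise ValueError(f"accuracy for condition {cond} outside [0, 1]")
        if not (0.0 <= self.pvt_lapse_prob <= 1.0):
            raise ValueError("pvt_lapse_prob must be in [0, 1]")
        for item, curve in self.vas.items():
            if not (0.0 <= curve.baseline <= 100.0 and 0.0 <= curve.baseline + curve.asymptote <= 100.0):
                raise ValueError(f"VAS curve for {item!r} leaves [0, 100]")


class SimulatedParticipant:
    """A stochastic responder implementing the engine's Responder protocol."""

    def __init__(self, params: ResponderParams, seed: int = 0):
        self.params = params
        self.key_mapping = KeyMapping.from_variant(params.key_variant)
        self._pool = pool_from_seed(seed)
        self._kernels = {
            cond: lognormal_params(params.rt_mean_ms[cond], params.rt_sd_ms[cond])
            for cond in params.rt_mean_ms
        }
        self._pvt_kernel = lognormal_params(params.pvt_mean_ms, params.pvt_sd_ms)

    # -- BS task ---------------------------------------------------------

    def respond_bs(self, trial: Trial, block_index: int) -> tuple[str, float]:
        cond = trial.condition
        mu, sigma = self._kernels[cond]
        rt = math.exp(mu + sigma * self._pool.normal()) * (1.0 + self.params.d_rt * block_index)
        acc = min(1.0, max(0.0, self.params.accuracy[cond] - self.params.d_acc * block_index))
        target = expected_key(cond, self.key_mapping)
        if self._pool.bernoulli(acc):
            key = target
        else:
            key = (
                self.key_mapping.diff_key
                if target == self.key_mapping.same_key
                else self.key_mapping.same_key
            )
        return key, rt

    # -- 2-back ----------------------------------------------------------

    def respond_2back(self, trial: TwoBackTrial, block_index: int) -> tuple[Optional[bool], float]:
        mu, sigma = lognormal_params(self.params.twoback_rt_mean_ms, self.params.twoback_rt_sd_ms)
        rt = math.exp(mu + sigma * self._pool.normal())
        correct = self._pool.bernoulli(self.params.twoback_accuracy)
        judgment = trial.is_match if correct else not trial.is_match
        return judgment, rt

    # -- PVT -------------------------------------------------------------

    def respond_pvt(self, phase: str) -> float:
        p_lapse = self.params.pvt_lapse_prob
        rt_mult = 1.0
        if phase == "post":
            p_lapse = min(1.0, p_lapse * self.params.pvt_post_lapse_multiplier)
            rt_mult = self.params.pvt_post_rt_multiplier
        if self._pool.bernoulli(p_lapse):
            # exponential excess above the 500 ms lapse threshold
            u = max(self._pool.uniform(), 1e-12)
            return 500.0 - self.params.pvt_lapse_excess_scale_ms * math.log(u)
        mu, sigma = self._pvt_kernel
        mu += math.log(rt_mult)
        # base kernel truncated at the 100 ms validity floor
        for _ in range(1000):
            rt = math.exp(mu + sigma * self._pool.normal())
            if rt >= 100.0:
                return rt
        return 100.0

    # -- Subjective scales -------------------------------------------------

    def report_vas(self, block_index: int, item: str) -> int:
        curve = self.params.vas[item]
        value = curve.mean(block_index)
        if curve.noise_sd > 0:
            value += curve.noise_sd * self._pool.normal()
        return int(min(100, max(0, round(value))))

    def report_tlx(self, task: str) -> dict[str, float]:
        means = self.params.tlx_mean[task]
        out = {}
        for dim in TLX_DIMENSIONS:
            v = means[dim] + self.params.tlx_noise_sd * self._pool.normal()
            out[dim] = float(min(20.0, max(0.0, v)))
        return out


class ScriptedResponder:
    """Deterministic responder replaying fixed keys/RTs — for contract tests."""

    def __init__(
        self,
        bs_script: Optional[list[tuple[str, float]]] = None,
        pvt_script: Optional[list[float]] = None,
        vas_value: int = 0,
        tlx_value: float = 0.0,
        key_variant: str = "A",
        always_correct: bool = False,
        fixed_rt_ms: float = 1.0,
    ):
        self.key_mapping = KeyMapping.from_variant(key_variant)
        self._bs = list(bs_script) if bs_script else None
        self._pvt = list(pvt_script) if pvt_script else None
        self._pvt_i = 0
        self._vas = vas_value
        self._tlx = tlx_value
        self._always_correct = always_correct
        self._fixed_rt = fixed_rt_ms

    def respond_bs(self, trial: Trial, block_index: int) -> tuple[str, float]:
        if self._always_correct or self._bs is None:
            return expected_key(trial.condition, self.key_mapping), self._fixed_rt
        return self._bs.pop(0)

    def respond_2back(self, trial: TwoBackTrial, block_index: int) -> tuple[Optional[bool], float]:
        return trial.is_match, self._fixed_rt

    def respond_pvt(self, phase: str) -> float:
        if self._pvt is None:
            return self._fixed_rt
        rt = self._pvt[self._pvt_i % len(self._pvt)]  # cycles if the bout outruns the script
        self._pvt_i += 1
        return rt

    def report_vas(self, block_index: int, item: str) -> int:
        return self._vas

    def report_tlx(self, task: str) -> dict[str, float]:
        return {dim: self._tlx for dim in TLX_DIMENSIONS}


# -- Presets and cohort generation ----------------------------------------

def calibration_preset() -> ResponderParams:
    """Unlimited-time responder on the scale of published group descriptives."""
    return ResponderParams(
        rt_mean_ms={1: 1815.0, 2: 2394.0, 3: 2110.0, 4: 2251.0},
        rt_sd_ms={1: 504.0, 2: 573.0, 3: 559.0, 4: 545.0},
        accuracy={1: 0.92, 2: 0.88, 3: 0.91, 4: 0.91},
        vas=_flat_vas(),
        tlx_mean=_tlx_means(),
    )


def tot_preset(drift: bool = True) -> ResponderParams:
    """Time-pressured responder with (optionally) a fatigue drift.

    Under the 2300-2800 ms deadlines participants answer faster than in the
    unlimited-time calibration; means here are chosen so a 5-minute block
    holds roughly 150 scored trials, with accuracy in the low-to-mid 90s
    declining a few points over six blocks when drift is on.
    """
    return ResponderParams(
        rt_mean_ms={1: 1300.0, 2: 1700.0, 3: 1500.0, 4: 1600.0},
        rt_sd_ms={1: 300.0, 2: 300.0, 3: 300.0, 4: 300.0},
        accuracy={1: 0.965, 2: 0.94, 3: 0.955, 4: 0.955},
        d_rt=0.02 if drift else 0.0,
        d_acc=0.006 if drift else 0.0,
        vas=_rising_vas() if drift else _flat_vas(),
        tlx_mean=_tlx_means(),
    )


def _rising_vas() -> dict[str, VasCurve]:
    return {
        "mental_fatigue": VasCurve(baseline=4.6, asymptote=57.0, rate=0.55, noise_sd=9.0),
        "mental_effort": VasCurve(baseline=30.0, asymptote=32.0, rate=0.50, noise_sd=10.0),
        "mental_stress": VasCurve(baseline=10.0, asymptote=15.0, rate=0.40, noise_sd=8.0),
        "boredom": VasCurve(baseline=2.0, asymptote=19.0, rate=0.35, noise_sd=6.0),
    }


def _flat_vas() -> dict[str, VasCurve]:
    return {item: VasCurve(baseline=10.0, asymptote=0.0, rate=0.0, noise_sd=6.0) for item in VAS_ITEMS}


def _tlx_means() -> dict[str, dict[str, float]]:
    return {
        "bs": {
            "mental_demand": 11.6,
            "physical_demand": 3.1,
            "temporal_demand": 9.1,
            "performance": 6.3,
            "effort": 12.8,
            "frustration": 7.7,
        },
        "2back": {
            "mental_demand": 9.9,
            "physical_demand": 3.2,
            "temporal_demand": 7.0,
            "performance": 4.9,
            "effort": 11.4,
            "frustration": 6.1,
        },
    }


def sample_participant_params(
    base: ResponderParams, rng: np.random.Generator
) -> ResponderParams:
    """Draw one participant's parameters around a preset.

    Between-participant spread: RT means jittered by ~8% (lognormal-ish
    multiplicative), accuracies by SD 0.02 (clipped), VAS asymptotes by ~25%,
    PVT mean by ~7%.  The published group tables carry no individual-level
    variance decomposition, so these spreads are a package choice.
    """
    rt_scale = float(np.exp(rng.normal(0.0, 0.08)))
    acc_shift = float(rng.normal(0.0, 0.02))
    vas_scale = float(np.exp(rng.normal(0.0, 0.25)))
    pvt_scale = float(np.exp(rng.normal(0.0, 0.07)))
    new_vas = {}
    for item, curve in base.vas.items():
        asymptote = min(curve.asymptote * vas_scale, 100.0 - curve.baseline)
        new_vas[item] = replace(curve, asymptote=asymptote)
    return replace(
        base,
        rt_mean_ms={c: m * rt_scale for c, m in base.rt_mean_ms.items()},
        accuracy={c: float(min(1.0, max(0.0, a + acc_shift))) for c, a in base.accuracy.items()},
        vas=new_vas,
        pvt_mean_ms=base.pvt_mean_ms * pvt_scale,
        key_variant="A" if rng.random() < 0.5 else "B",
    )


def generate_cohort(
    n_participants: int,
    protocol_config: Optional[SessionConfig] = None,
    seed: int = 0,
    base_params: Optional[ResponderParams] = None,
    heterogeneous: bool = True,
) -> list[SessionLog]:
    """Simulate a cohort of independent sessions, reproducible from one seed.

    Each participant gets a spawned seed stream for parameter sampling, for
    the responder's own noise, and for the session engine.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    from .engine import run_hmw_protocol, run_tot_protocol

    if protocol_config is None:
        protocol_config = tot_config()
    if base_params is None:
        base_params = tot_preset()
    logs: list[SessionLog] = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_participants)):
        param_seed, responder_seed, session_seed = (
            int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in child.spawn(3)
        )
        if heterogeneous:
            params = sample_participant_params(base_params, np.random.default_rng(param_seed))
        else:
            params = base_params
        responder = SimulatedParticipant(params, seed=responder_seed)
        pid = f"sim_{i:03d}"
        if protocol_config.protocol == "tot_induction":
            log = run_tot_protocol(responder, protocol_config, seed=session_seed, participant_id=pid)
        elif protocol_config.protocol == "hmw_blocks":
            log = run_hmw_protocol(responder, protocol_config, seed=session_seed, participant_id=pid)
        else:
            raise ValueError(f"cohort generation not defined for protocol {protocol_config.protocol!r}")
        log.seeds["participant_index"] = i
        logs.append(log)
    return logs
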