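"""Synthetic predation-trial and detection-table generators.

The generators mirror the study design the analysis assumes: bottles at
prey densities 5, 10, 15, 20, 25, 30 with four replicates each and a one-day
exposure. Expected consumption follows the chosen Holling disc equation;
observed consumption is a binomial thinning of the offered prey,

    consumed ~ Binomial(N, min(1, mu(N)/N)),

which keeps counts inside [0, N] — a Poisson noise layer was rejected
because it can exceed the prey actually present in a bottle. Where the disc
expectation exceeds availability (large a' at small N) the per-prey
probability clamps at 1 with a logged warning.

A single user seed expands through :class:`numpy.random.SeedSequence`
substreams, one per density (or per taxon), so extending the design does not
perturb draws already made for earlier strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import InvalidConfigError
from .functional_response import (
    HollingFit,
    PredationTrial,
    PreyStage,
    ResponseType,
    TrialSet,
    classify_response,
    fit_holling,
    fit_polynomial_type,
    holling_expectation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "DetectionSimConfig",
    "RecoveryReport",
    "simulate_trials",
    "simulate_detection_table",
    "recovery_experiment",
]

#: Density treatments of the emulated bottle design.
DEFAULT_DENSITIES = (5, 10, 15, 20, 25, 30)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative truth for one predator x prey-stage trial set.

    Defaults reproduce the emulated study design: densities 5-30 in steps
    of 5, four replicate bottles per density, one-day exposure, binomial
    consumption noise.
    """

    model: ResponseType = ResponseType.II
    attack_rate: float = 1.2
    handling_time: float = 0.03
    exposure_T: float = 1.0
    densities: tuple[int, ...] = DEFAULT_DENSITIES
    replicates: int = 4
    noise: str = "binomial"
    seed: int = 0
    predator_id: str = "simulated"
    prey_stage: PreyStage = PreyStage.NYMPH_4_5
    #: Under noise="none": keep exact real expectations (False, default) or
    #: round half-up to whole prey (True), emulating countable bottle data.
    integer_counts: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", ResponseType(self.model))
        object.__setattr__(self, "prey_stage", PreyStage(self.prey_stage))
        object.__setattr__(self, "densities", tuple(int(d) for d in self.densities))
        if self.model not in (ResponseType.II, ResponseType.III):
            raise InvalidConfigError("model must be II or III")
        if self.attack_rate <= 0 or self.handling_time <= 0 or self.exposure_T <= 0:
            raise InvalidConfigError(
                "attack_rate, handling_time and exposure_T must be positive"
            )
        if not self.densities or any(d <= 0 for d in self.densities):
            raise InvalidConfigError("densities must be non-empty positive integers")
        if len(set(self.densities)) != len(self.densities):
            raise InvalidConfigError("densities must be distinct")
        if self.replicates < 1:
            raise InvalidConfigError("replicates must be >= 1")
        if self.noise not in ("binomial", "none"):
            raise InvalidConfigError("noise must be 'binomial' or 'none'")


@dataclass(frozen=True)
class DetectionSimConfig:
    """Per-taxon assay sizes and true positivity rates for a synthetic survey."""

    taxa: tuple[tuple[str, int, float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "taxa", tuple((str(s), int(n), float(r)) for s, n, r in self.taxa)
        )
        if not self.taxa:
            raise InvalidConfigError("taxa must be non-empty")
        for species, n, rate in self.taxa:
            if n < 0:
                raise InvalidConfigError(f"{species}: n_detected must be >= 0")
            if not 0.0 <= rate <= 1.0:
                raise InvalidConfigError(
                    f"{species}: true_rate must lie in [0, 1], got {rate}"
                )


def _consumption_probability(config: SimulationConfig, density: int) -> float:
    """Per-prey consumption probability mu(N)/N, clamped at 1."""
    mu = holling_expectation(
        density, config.attack_rate, config.handling_time,
        config.exposure_T, config.model,
    )
    p = mu / density
    if p > 1.0:
        logger.warning(
            "expected consumption %.3f exceeds density %d; clamping p to 1",
            mu, density,
        )
        return 1.0
    return p


def simulate_trials(config: SimulationConfig) -> TrialSet:
    """Generate one TrialSet from the configured disc-equation truth.

    Deterministic for a given config+seed; each density treatment draws from
    its own seed substream.
    """
    streams = np.random.SeedSequence(config.seed).spawn(len(config.densities))
    trials: list[PredationTrial] = []
    for dens, stream in zip(config.densities, streams):
        p = _consumption_probability(config, dens)
        if config.noise == "binomial":
            rng = np.random.default_rng(stream)
            consumed = [
                int(v) for v in rng.binomial(dens, p, size=config.replicates)
            ]
        elif config.integer_counts:
            consumed = [int(round_half_up(p * dens, 0))] * config.replicates
        else:
            consumed = [p * dens] * config.replicates
        for rep, na in enumerate(consumed, start=1):
            trials.append(
                PredationTrial(
                    predator_id=config.predator_id,
                    prey_stage=config.prey_stage,
                    density=dens,
                    consumed=na,
                    replicate=rep,
                )
            )
    return TrialSet(
        predator_id=config.predator_id,
        prey_stage=config.prey_stage,
        trials=tuple(trials),
        exposure_T=config.exposure_T,
    )


def simulate_detection_table(config: DetectionSimConfig):
    """Generate a DetectionTable with Binomial(n_detected, true_rate) positives.

    Collected counts equal detected counts (no extraction failures are
    simulated); order/family labels are marked synthetic.
    """
    from .gut_detection import DetectionRecord, DetectionTable

    streams = np.random.SeedSequence(config.seed).spawn(len(config.taxa))
    records = []
    for (species, n, rate), stream in zip(config.taxa, streams):
        rng = np.random.default_rng(stream)
        k = int(rng.binomial(n, rate)) if n > 0 else 0
        records.append(
            DetectionRecord(
                order="synthetic", family="synthetic", species=species,
                n_collected=n, n_detected=n, n_positive=k,
            )
        )
    return DetectionTable(records=tuple(records))


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery diagnostics from repeated simulate-and-refit rounds."""

    n_runs: int
    n_failures: int
    bias_attack_rate: float
    bias_handling_time: float
    rmse_attack_rate: float
    rmse_handling_time: float
    type_frequencies: dict = field(default_factory=dict)
    truth: SimulationConfig | None = None


def recovery_experiment(config: SimulationConfig, n_runs: int) -> RecoveryReport:
    """Simulate ``n_runs`` datasets from ``config``, refit each, and report
    bias and RMSE of the attack-rate and handling-time estimates plus the
    frequency of each functional-response type call.

    Per-run failures (fit errors) are counted, not raised.
    """
    if n_runs < 1:
        raise InvalidConfigError("n_runs must be >= 1")
    root = np.random.SeedSequence(config.seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n_runs)]

    a_hats, th_hats = [], []
    type_counts: dict[str, int] = {}
    failures = 0
    for run_seed in run_seeds:
        trials = simulate_trials(replace(config, seed=run_seed))
        try:
            fit = fit_holling(trials, model=config.model)
            a_hats.append(fit.attack_rate)
            th_hats.append(fit.handling_time)
            poly = fit_polynomial_type(trials)
            call = poly.response_type.value
            type_counts[call] = type_counts.get(call, 0) + 1
        except Exception:
            failures += 1

    a_arr = np.array(a_hats)
    th_arr = np.array(th_hats)
    if a_arr.size == 0:
        raise InvalidConfigError("every run failed; nothing to report")
    return RecoveryReport(
        n_runs=n_runs,
        n_failures=failures,
        bias_attack_rate=float(a_arr.mean() - config.attack_rate),
        bias_handling_time=float(th_arr.mean() - config.handling_time),
        rmse_attack_rate=float(
            np.sqrt(np.mean((a_arr - config.attack_rate) ** 2))
        ),
        rmse_handling_time=float(
            np.sqrt(np.mean((th_arr - config.handling_time) ** 2))
        ),
        type_frequencies={k: v / max(n_runs - failures, 1) for k, v in type_counts.items()},
        truth=config,
    )
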