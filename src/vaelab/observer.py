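"""Parametric observer model generating synthetic test-phase responses.

The observer reports a perceived azimuth that is linear in the stimulus
azimuth (per-participant gain and baseline bias), shifted by an
adaptation-induced recalibration whose sign follows the visual offset
direction and whose magnitude saturates exponentially with adaptation
duration, plus Gaussian response noise and a small uniform
outlier-contamination mixture:

    r = g * a + b - sign(disparity) * (M_c / 2) * (1 - exp(-T / tau_c)) + eps

so the -20 > +20 disparity contrast of the fitted intercepts converges to
M_c * (1 - exp(-T / tau_c)): a leftward audio offset (-20) drags perceived
azimuth rightward, and vice versa.  M_c is therefore the full contrast at
saturation, per fixation condition.

The generator reproduces the statistical structure the analysis pipeline
assumes; its default population parameters are plausible for this paradigm
but are not estimates of any measured dataset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .paradigm import (
    BlockSpec,
    FixationCondition,
    generate_experiment,
)

__all__ = ["ObserverParams", "PopulationSpec", "SimulatedDataset",
           "simulate_response", "simulate_dataset", "DEFAULT_POPULATION"]


_COND_KEYS = {
    FixationCondition.EYE_HEAD_CONSISTENT: "eye_head_consistent",
    FixationCondition.EYE_CONSISTENT: "eye_consistent",
    FixationCondition.HEAD_CONSISTENT: "head_consistent",
    FixationCondition.VARIABLE_DISPARITY: "variable_disparity",
}


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant.

    gain
        Slope of the stimulus -> response mapping (unitless; 1 = veridical).
    baseline_bias
        Constant response offset in degrees.
    vae_asymptote
        Per-condition saturated VAE contrast M_c in degrees (the full
        -20 > +20 intercept difference at infinite adaptation duration).
    vae_timeconstant
        Per-condition exponential time constant tau_c in seconds of
        adaptation.
    response_noise_sd
        Gaussian response noise sigma in degrees.
    outlier_rate, outlier_range
        With probability ``outlier_rate`` a response is replaced by a uniform
        draw over ``outlier_range`` (degrees), emulating lapses.
    """

    gain: float = 0.9
    baseline_bias: float = 0.0
    vae_asymptote: dict[str, float] = field(default_factory=lambda: {
        "eye_head_consistent": 6.0,
        "eye_consistent": 4.0,
        "head_consistent": 4.0,
        "variable_disparity": 4.0,
    })
    vae_timeconstant: dict[str, float] = field(default_factory=lambda: {
        "eye_head_consistent": 40.0,
        "eye_consistent": 60.0,
        "head_consistent": 60.0,
        "variable_disparity": 40.0,
    })
    response_noise_sd: float = 5.0
    outlier_rate: float = 0.02
    outlier_range: tuple[float, float] = (-90.0, 90.0)

    def __post_init__(self) -> None:
        if self.response_noise_sd <= 0:
            raise ValueError("response_noise_sd must be > 0")
        if not (0.0 <= self.outlier_rate < 0.5):
            raise ValueError("outlier_rate must lie in [0, 0.5)")
        for k, v in self.vae_timeconstant.items():
            if v <= 0:
                raise ValueError(f"vae_timeconstant[{k}] must be > 0")
        for k, v in self.vae_asymptote.items():
            if v < 0:
                raise ValueError(f"vae_asymptote[{k}] must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Population means plus between-participant jitter SDs."""

    mean: ObserverParams = field(default_factory=ObserverParams)
    gain_sd: float = 0.08
    bias_sd: float = 2.0
    asymptote_sd: float = 1.5
    timeconstant_sd: float = 10.0

    def draw(self, rng: np.random.Generator) -> ObserverParams:
        m = self.mean
        return ObserverParams(
            gain=rng.normal(m.gain, self.gain_sd),
            baseline_bias=rng.normal(m.baseline_bias, self.bias_sd),
            vae_asymptote={k: max(0.0, rng.normal(v, self.asymptote_sd))
                           for k, v in m.vae_asymptote.items()},
            vae_timeconstant={k: max(5.0, rng.normal(v, self.timeconstant_sd))
                              for k, v in m.vae_timeconstant.items()},
            response_noise_sd=m.response_noise_sd,
            outlier_rate=m.outlier_rate,
            outlier_range=m.outlier_range,
        )


DEFAULT_POPULATION = PopulationSpec()


def expected_shift(params: ObserverParams, condition: FixationCondition,
                   duration_s: float, disparity: float) -> float:
    """Noise-free adaptation shift for one condition cell (degrees)."""
    key = _COND_KEYS[condition]
    m = params.vae_asymptote[key]
    tau = params.vae_timeconstant[key]
    return -math.copysign(1.0, disparity) * (m / 2.0) * (1.0 - math.exp(-duration_s / tau))


def simulate_response(
    stimulus_az: float,
    block: BlockSpec,
    params: ObserverParams,
    rng: np.random.Generator,
) -> float:
    """One simulated response azimuth (degrees) to a test stimulus."""
    if rng.random() < params.outlier_rate:
        lo, hi = params.outlier_range
        return float(rng.uniform(lo, hi))
    shift = expected_shift(params, block.condition, block.duration_s, block.disparity)
    mean = params.gain * stimulus_az + params.baseline_bias + shift
    return float(mean + rng.normal(0.0, params.response_noise_sd))


@dataclass
class SimulatedDataset:
    """Trial table plus the generative parameters that produced it."""

    trials: pd.DataFrame
    params: dict[str, ObserverParams]  # keyed by participant id
    population: PopulationSpec
    experiment: int

    def params_json(self) -> str:
        payload = {
            "experiment": self.experiment,
            "population": asdict(self.population),
            "participants": {k: asdict(v) for k, v in self.params.items()},
        }
        return json.dumps(payload, indent=2, default=list)


def simulate_dataset(
    experiment: int,
    n_participants: int,
    population: PopulationSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Simulate a full crossed-design cohort for one experiment.

    Every participant completes every block of the design (24 for experiment
    1, 8 for experiment 2) with 40 test responses per block; per-participant
    parameters are drawn around the population means.  Deterministic for a
    fixed seed/generator.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    population = population or DEFAULT_POPULATION
    rng = np.random.default_rng(rng)

    rows = []
    params: dict[str, ObserverParams] = {}
    for i in range(1, n_participants + 1):
        pid = f"p{i:02d}"
        p = population.draw(rng)
        params[pid] = p
        schedule = generate_experiment(experiment, rng)
        for block in schedule.blocks:
            spec = block.spec
            for trial in block.test_trials:
                resp = simulate_response(trial.auditory_az, spec, p, rng)
                rows.append((pid, experiment, spec.condition.value,
                             spec.duration_s, spec.disparity, trial.cycle_idx,
                             trial.auditory_az, resp))
    trials = pd.DataFrame(rows, columns=[
        "participant", "experiment", "condition", "duration_s",
        "disparity", "cycle", "stimulus_az", "response_az"])
    return SimulatedDataset(trials=trials, params=params,
                            population=population, experiment=experiment)
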