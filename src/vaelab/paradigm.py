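"""Adaptation/test schedule generation for the ventriloquism-aftereffect paradigm.

The paradigm pairs visual stimuli on a 7-location azimuth grid (0, ±10, ±20,
±30 degrees) with spatially offset auditory stimuli, in blocks of four
alternating adaptation and test phases.  Three fixation conditions decouple
eye-centred from head-centred audio-visual disparity; a fourth
(variable-disparity) condition replaces the fixed ±20 degree offset with a
uniform spread of offsets around that mean.

Conventions: azimuths are signed degrees, positive rightward, 0 straight
ahead; all auditory positions are head-centred.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FixationCondition",
    "TimingSpec",
    "AdaptEvent",
    "TestTrial",
    "BlockSpec",
    "Block",
    "ExperimentSchedule",
    "VISUAL_AZIMUTHS",
    "TEST_AZIMUTHS",
    "ADAPT_DURATIONS_S",
    "DISPARITIES",
    "phase_duration",
    "generate_adapt_sequence",
    "exp2_offsets",
    "generate_block",
    "generate_experiment",
    "disparity_profile",
    "adapt_events_to_frame",
    "test_trials_to_frame",
]

#: Visual adaptation azimuth grid (degrees, head-centred).
VISUAL_AZIMUTHS: tuple[int, ...] = (-30, -20, -10, 0, 10, 20, 30)

#: Test-phase auditory azimuth grid: ±30 degrees in 5 degree steps.
TEST_AZIMUTHS: tuple[int, ...] = tuple(range(-30, 35, 5))

#: Adaptation-phase durations (s) for 1..4 passes.
ADAPT_DURATIONS_S: tuple[int, ...] = (35, 70, 105, 140)

#: The two audio-visual disparity conditions (degrees; mean offsets in Exp 2).
DISPARITIES: tuple[int, ...] = (-20, 20)


class FixationCondition(str, Enum):
    """Fixation/offset rule for adaptation phases.

    ``EYE_HEAD_CONSISTENT``: central fixation, audio offset relative to the
    visual stimulus — disparity consistent in both reference frames.
    ``EYE_CONSISTENT``: fixation tracks the visual stimulus, audio offset
    relative to 0 degrees — consistent eye-centred disparity only.
    ``HEAD_CONSISTENT``: fixation tracks the visual stimulus, audio offset
    relative to the visual stimulus — consistent head-centred disparity only.
    ``VARIABLE_DISPARITY``: central fixation, audio offset drawn per set from
    a 7-value uniform spread around the mean disparity (experiment 2 only).
    """

    EYE_HEAD_CONSISTENT = "eye_head_consistent"
    EYE_CONSISTENT = "eye_consistent"
    HEAD_CONSISTENT = "head_consistent"
    VARIABLE_DISPARITY = "variable_disparity"

    @property
    def experiment(self) -> int:
        return 2 if self is FixationCondition.VARIABLE_DISPARITY else 1


EXP1_CONDITIONS = (
    FixationCondition.EYE_HEAD_CONSISTENT,
    FixationCondition.EYE_CONSISTENT,
    FixationCondition.HEAD_CONSISTENT,
)


@dataclass(frozen=True)
class TimingSpec:
    """Adaptation/test phase timing parameters (seconds)."""

    stim_dur_s: float = 0.5
    isi_s: float = 0.3
    reps_per_set: int = 5
    interset_isi_s: float = 1.0
    n_azimuths: int = 7
    test_iti_s: float = 0.2

    def __post_init__(self) -> None:
        for name in ("stim_dur_s", "isi_s", "reps_per_set", "interset_isi_s",
                     "n_azimuths", "test_iti_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TimingSpec.{name} must be strictly positive")


@dataclass(frozen=True)
class AdaptEvent:
    """One audio-visual adaptation presentation."""

    onset_s: float
    visual_az: float
    auditory_az: float
    fixation_az: float
    offset: float
    pass_idx: int  # 1-based pass over the 7 locations
    set_idx: int   # 1..7 within pass
    rep_idx: int   # 1..5 within set


@dataclass
class TestTrial:
    """One unimodal auditory test trial."""

    trial_idx: int
    cycle_idx: int  # 1..4
    auditory_az: float
    response_az: float | None = None


@dataclass(frozen=True)
class BlockSpec:
    """One block: a fixation condition x adaptation duration x disparity cell."""

    condition: FixationCondition
    n_passes: int
    disparity: int
    n_cycles: int = 4
    n_test_trials: int = 10
    timing: TimingSpec = field(default_factory=TimingSpec)

    def __post_init__(self) -> None:
        if self.n_passes not in (1, 2, 3, 4):
            raise ValueError(f"n_passes must be in 1..4, got {self.n_passes}")
        if self.disparity not in DISPARITIES:
            raise ValueError(f"disparity must be one of {DISPARITIES}, got {self.disparity}")
        if not isinstance(self.condition, FixationCondition):
            raise ValueError(f"invalid condition: {self.condition!r}")

    @property
    def duration_s(self) -> float:
        return phase_duration(self.n_passes, self.timing)


@dataclass
class Block:
    spec: BlockSpec
    cycles: list[tuple[list[AdaptEvent], list[TestTrial]]]
    #: schedule metadata, e.g. the 10 s inter-cycle countdown
    metadata: dict = field(default_factory=dict)

    @property
    def test_trials(self) -> list[TestTrial]:
        return [t for _, trials in self.cycles for t in trials]

    @property
    def adapt_events(self) -> list[AdaptEvent]:
        return [e for events, _ in self.cycles for e in events]


@dataclass
class ExperimentSchedule:
    experiment: int
    blocks: list[Block]

    def to_json(self) -> str:
        payload = {
            "experiment": self.experiment,
            "blocks": [
                {
                    "condition": b.spec.condition.value,
                    "n_passes": b.spec.n_passes,
                    "disparity": b.spec.disparity,
                    "n_cycles": b.spec.n_cycles,
                    "n_test_trials": b.spec.n_test_trials,
                    "timing": asdict(b.spec.timing),
                }
                for b in self.blocks
            ],
        }
        return json.dumps(payload, indent=2)


def phase_duration(n_passes: int, timing: TimingSpec | None = None) -> float:
    """Scheduled duration (s) of an adaptation phase of ``n_passes`` passes.

    One pass visits each of the ``n_azimuths`` locations once; a set of
    ``reps_per_set`` presentations (each ``stim_dur_s`` + ``isi_s``) is
    followed by one ``interset_isi_s``, counted after every set including the
    last.  With the default timing this gives 35 s per pass.
    """
    if timing is None:
        timing = TimingSpec()
    if not isinstance(n_passes, (int, np.integer)) or n_passes < 1:
        raise ValueError(f"n_passes must be a positive integer, got {n_passes!r}")
    per_set = timing.reps_per_set * (timing.stim_dur_s + timing.isi_s) + timing.interset_isi_s
    return n_passes * timing.n_azimuths * per_set


def exp2_offsets(mean_disparity: int) -> tuple[int, ...]:
    """The 7 auditory offsets of the variable-disparity design.

    Offsets span ±30 degrees around the mean in 10 degree steps, e.g. a −20
    degree mean gives offsets −50 … +10.
    """
    if mean_disparity not in DISPARITIES:
        raise ValueError(f"mean_disparity must be one of {DISPARITIES}")
    return tuple(mean_disparity + d for d in range(-30, 40, 10))


def _auditory_az(cond: FixationCondition, visual_az: float, offset: float) -> float:
    if cond is FixationCondition.EYE_CONSISTENT:
        return 0.0 + offset
    return visual_az + offset


def _fixation_az(cond: FixationCondition, visual_az: float) -> float:
    if cond in (FixationCondition.EYE_HEAD_CONSISTENT, FixationCondition.VARIABLE_DISPARITY):
        return 0.0
    return visual_az


def generate_adapt_sequence(
    cond: FixationCondition,
    disparity: int,
    n_passes: int,
    rng: np.random.Generator,
    timing: TimingSpec | None = None,
) -> list[AdaptEvent]:
    """Generate the adaptation events of one phase.

    Each pass presents the 7 visual azimuths in random order, 5 consecutive
    repetitions per azimuth (35 events per pass).  In the variable-disparity
    condition each pass additionally uses each of the 7 offsets around the
    mean exactly once, in random order, one offset per visual-azimuth set.
    """
    if not isinstance(cond, FixationCondition):
        raise ValueError(f"invalid condition: {cond!r}")
    if disparity not in DISPARITIES:
        raise ValueError(f"disparity must be one of {DISPARITIES}, got {disparity}")
    if timing is None:
        timing = TimingSpec()
    # validates n_passes
    phase_duration(n_passes, timing)

    per_rep = timing.stim_dur_s + timing.isi_s
    per_set = timing.reps_per_set * per_rep + timing.interset_isi_s

    events: list[AdaptEvent] = []
    t = 0.0
    for p in range(1, n_passes + 1):
        order = rng.permutation(VISUAL_AZIMUTHS)
        if cond is FixationCondition.VARIABLE_DISPARITY:
            offsets = rng.permutation(exp2_offsets(disparity))
        else:
            offsets = np.full(len(order), float(disparity))
        for s, (vaz, off) in enumerate(zip(order, offsets), start=1):
            for r in range(1, timing.reps_per_set + 1):
                events.append(AdaptEvent(
                    onset_s=round(t + (r - 1) * per_rep, 9),
                    visual_az=float(vaz),
                    auditory_az=_auditory_az(cond, float(vaz), float(off)),
                    fixation_az=_fixation_az(cond, float(vaz)),
                    offset=float(off),
                    pass_idx=p,
                    set_idx=s,
                    rep_idx=r,
                ))
            t += per_set
    return events


def generate_block(spec: BlockSpec, rng: np.random.Generator) -> Block:
    """Generate one block: 4 cycles of adaptation phase + 10-trial test phase.

    Test azimuths are drawn uniformly with replacement from the 13-value
    ±30 degree grid, with an independent stream per test phase.  The 10 s
    inter-cycle countdown is recorded as metadata only.
    """
    cycles = []
    trial_idx = 1
    for c in range(1, spec.n_cycles + 1):
        events = generate_adapt_sequence(
            spec.condition, spec.disparity, spec.n_passes, rng, spec.timing)
        azs = rng.choice(TEST_AZIMUTHS, size=spec.n_test_trials, replace=True)
        trials = [TestTrial(trial_idx=trial_idx + i, cycle_idx=c, auditory_az=float(a))
                  for i, a in enumerate(azs)]
        trial_idx += spec.n_test_trials
        cycles.append((events, trials))
    meta = {"intercycle_countdown_s": 10.0, "interblock_break_s_min": 60.0}
    return Block(spec=spec, cycles=cycles, metadata=meta)


def generate_experiment(experiment: int, rng: np.random.Generator,
                        timing: TimingSpec | None = None) -> ExperimentSchedule:
    """Generate a full, randomised block schedule for one participant.

    Experiment 1 crosses 3 fixation conditions x 4 durations x 2 disparities
    (24 blocks); experiment 2 crosses 4 durations x 2 mean disparities under
    the variable-disparity condition (8 blocks).  Block order is a uniform
    random permutation.
    """
    if experiment not in (1, 2):
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")
    timing = timing or TimingSpec()
    if experiment == 1:
        conds: Sequence[FixationCondition] = EXP1_CONDITIONS
    else:
        conds = (FixationCondition.VARIABLE_DISPARITY,)
    specs = [
        BlockSpec(condition=c, n_passes=n, disparity=d, timing=timing)
        for c in conds for n in (1, 2, 3, 4) for d in DISPARITIES
    ]
    order = rng.permutation(len(specs))
    blocks = [generate_block(specs[i], rng) for i in order]
    return ExperimentSchedule(experiment=experiment, blocks=blocks)


def disparity_profile(events: Iterable[AdaptEvent], frame: str) -> np.ndarray:
    """Per-event audio-visual disparity in the eye- or head-centred frame.

    The head-centred visual position is ``visual_az``; the eye-centred one is
    ``visual_az - fixation_az`` (a fixated stimulus has eye-centred
    eccentricity 0).  The head-centred auditory azimuth is combined directly
    with either visual coordinate, mirroring how spatially naive integration
    of the two signals would register the disparity.
    """
    events = list(events)
    if not events:
        raise ValueError("disparity_profile requires a non-empty event list")
    if frame == "head":
        v = np.array([e.visual_az for e in events])
    elif frame == "eye":
        v = np.array([e.visual_az - e.fixation_az for e in events])
    else:
        raise ValueError(f"frame must be 'eye' or 'head', got {frame!r}")
    a = np.array([e.auditory_az for e in events])
    return a - v


def adapt_events_to_frame(events: Iterable[AdaptEvent]) -> pd.DataFrame:
    """Tabulate adaptation events (one row per presentation)."""
    return pd.DataFrame([asdict(e) for e in events])


def test_trials_to_frame(trials: Iterable[TestTrial]) -> pd.DataFrame:
    """Tabulate test trials (one row per trial)."""
    return pd.DataFrame([asdict(t) for t in trials])
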