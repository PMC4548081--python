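"""Behavioral task simulators.

Applies a participant's latent profile to the four task designs: the adaptive
intertemporal-choice staircase (fixed 20 EUR immediate reward vs. a
larger-but-later amount adjusted by bisection toward the indifference point,
at seven delays), the 27-item fixed questionnaire, the circle-size time-
perception session (18 delays, two symmetric presentation sets, ceiling
rule), and the circle-size calibration session (targets as percent of a
reference circle).  The produced circle *diameter*, as a fraction of the
maximum scale, is the dependent variable throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .cohort import LatentProfile
from .discounting import choice_probability, subjective_value

__all__ = [
    "ChoiceItem",
    "ChoiceTrial",
    "ChoiceDataset",
    "RatingTrial",
    "RatingSession",
    "StaircaseConfig",
    "TimeSessionConfig",
    "KIRBY_ITEMS",
    "DEFAULT_DELAYS",
    "STANDARD_CIRCLE_TARGETS",
    "run_adaptive_task",
    "run_fixed_item_task",
    "simulate_time_session",
    "simulate_circle_session",
    "read_choice_csv",
    "read_rating_csv",
]


@dataclass(frozen=True)
class ChoiceItem:
    """Template for one binary intertemporal item (no choice recorded yet)."""

    ss_amount: float
    ll_amount: float
    ll_delay: float
    ss_delay: float = 0.0

    def __post_init__(self):
        if self.ss_amount <= 0 or self.ll_amount <= 0:
            raise ValueError("amounts must be > 0")
        if self.ll_delay <= self.ss_delay:
            raise ValueError("LL delay must exceed SS delay")


@dataclass(frozen=True)
class ChoiceTrial:
    ss_amount: float
    ss_delay: float
    ll_amount: float
    ll_delay: float
    choice: str  # "SS" or "LL"
    task: str  # "adaptive" or "fixed_items"

    def __post_init__(self):
        if self.choice not in ("SS", "LL"):
            raise ValueError("choice must be 'SS' or 'LL'")
        if self.ll_delay <= self.ss_delay:
            raise ValueError("LL delay must exceed SS delay")
        if self.ss_amount <= 0 or self.ll_amount <= 0:
            raise ValueError("amounts must be > 0")


@dataclass
class ChoiceDataset:
    """All binary choices of one participant on one task."""

    participant: str
    trials: list = field(default_factory=list)

    def __len__(self):
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(t) for t in self.trials])
        df.insert(0, "participant", self.participant)
        return df


@dataclass(frozen=True)
class RatingTrial:
    stimulus_kind: str  # "delay" (days) or "percent" (of reference circle)
    stimulus_value: float
    diameter: float  # fraction of the maximum scale, in (0, 1]
    trial_index: int
    set_id: str = ""  # "asc"/"desc" for time sessions

    def __post_init__(self):
        if not 0.0 < self.diameter <= 1.0:
            raise ValueError("diameter must lie in (0, 1]")
        if self.stimulus_value <= 0:
            raise ValueError("stimulus value must be > 0")


@dataclass
class RatingSession:
    participant: str
    kind: str  # "time" or "circle"
    trials: list = field(default_factory=list)

    def __len__(self):
        return len(self.trials)

    @property
    def stimuli(self) -> np.ndarray:
        return np.array([t.stimulus_value for t in self.trials])

    @property
    def diameters(self) -> np.ndarray:
        return np.array([t.diameter for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(t) for t in self.trials])
        df.insert(0, "kind", self.kind)
        df.insert(0, "participant", self.participant)
        return df


@dataclass
class StaircaseConfig:
    """Adaptive-task design: a bisection staircase on the LL amount per delay."""

    delays: Sequence[float] = (1, 7, 14, 30, 60, 120, 180)
    ss_amount: float = 20.0
    ll_lower: float = 20.5
    ll_upper: float = 80.0
    n_trials: int = 6

    def validate(self):
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials per delay")
        if not 0 < self.ll_lower < self.ll_upper:
            raise ValueError("invalid LL amount bounds")
        if self.ll_upper <= self.ss_amount:
            raise ValueError("amount bounds exclude any LL reward above the SS amount")


# 18 delays spanning 1-190 days, roughly log-spaced like delay sets used in
# magnitude-estimation work.
DEFAULT_DELAYS: tuple = (1, 2, 3, 5, 7, 10, 14, 21, 30, 45, 60, 75, 90, 110, 130, 150, 170, 190)

STANDARD_CIRCLE_TARGETS: tuple = (20.0, 40.0, 60.0, 80.0)


@dataclass
class TimeSessionConfig:
    min_delay: float = 1.0
    max_delay: float = 190.0
    ceiling: float = 0.9  # fraction of scale that triggers exclusion of longer delays


# 27-item monetary-choice questionnaire (Kirby et al.): (SS amount, LL amount,
# LL delay in days), SS always immediate.  Configurable, bundled for convenience.
KIRBY_ITEMS: tuple = tuple(
    ChoiceItem(ss, ll, d)
    for ss, ll, d in [
        (54, 55, 117), (55, 75, 61), (19, 25, 53), (31, 85, 7), (14, 25, 19),
        (47, 50, 160), (15, 35, 13), (25, 60, 14), (78, 80, 162), (40, 55, 62),
        (11, 30, 7), (67, 75, 119), (34, 35, 186), (27, 50, 21), (69, 85, 91),
        (49, 60, 89), (80, 85, 157), (24, 35, 29), (33, 80, 14), (28, 30, 179),
        (34, 50, 30), (25, 30, 80), (41, 75, 20), (54, 60, 111), (54, 80, 30),
        (22, 25, 136), (20, 55, 7),
    ]
)


def _sample_choice(profile: LatentProfile, item: ChoiceItem, rng: np.random.Generator) -> str:
    sv_ll = subjective_value(item.ll_amount, profile.k, item.ll_delay)
    sv_ss = subjective_value(item.ss_amount, profile.k, item.ss_delay)
    p_ll = choice_probability(sv_ll, sv_ss, profile.beta)
    return "LL" if rng.random() < p_ll else "SS"


def run_adaptive_task(profile: LatentProfile, config: StaircaseConfig | None = None,
                      seed: int = 0, participant: str = "sim") -> tuple[ChoiceDataset, dict]:
    """Simulate the adaptive staircase; returns choices and per-delay
    indifference points.

    Per delay the LL amount starts at the midpoint of the bounds and moves by
    a step that halves every trial: down after an LL choice, up after an SS
    choice, clipped to the bounds.  The indifference point is the final LL
    amount; for a noiseless agent it lands within one final step of the
    closed form ``ss_amount * (1 + k*D)``.
    """
    config = config or StaircaseConfig()
    config.validate()
    rng = substream(seed, "adaptive", participant)
    dataset = ChoiceDataset(participant)
    indifference: dict = {}
    for delay in config.delays:
        # start at the midpoint with a half-range initial step: the first
        # move lands exactly on a bound, so agents whose indifference value
        # lies outside the tested range saturate at that bound, and for
        # bracketed values the final error is at most the final step size,
        # range / 2**n_trials.
        amount = 0.5 * (config.ll_lower + config.ll_upper)
        step = 0.5 * (config.ll_upper - config.ll_lower)
        for _ in range(config.n_trials):
            item = ChoiceItem(config.ss_amount, amount, delay)
            choice = _sample_choice(profile, item, rng)
            dataset.trials.append(ChoiceTrial(item.ss_amount, item.ss_delay,
                                              item.ll_amount, item.ll_delay,
                                              choice, "adaptive"))
            amount += -step if choice == "LL" else step
            amount = float(np.clip(amount, config.ll_lower, config.ll_upper))
            step *= 0.5
        indifference[float(delay)] = amount
    return dataset, indifference


def run_fixed_item_task(profile: LatentProfile, items: Iterable[ChoiceItem] | None = None,
                        seed: int = 0, participant: str = "sim") -> ChoiceDataset:
    """Simulate the fixed-item questionnaire (default: the 27 bundled items)."""
    items = list(KIRBY_ITEMS if items is None else items)
    if not items:
        raise ValueError("item list is empty")
    rng = substream(seed, "fixed", participant)
    dataset = ChoiceDataset(participant)
    for item in items:
        choice = _sample_choice(profile, item, rng)
        dataset.trials.append(ChoiceTrial(item.ss_amount, item.ss_delay,
                                          item.ll_amount, item.ll_delay,
                                          choice, "fixed_items"))
    return dataset


def _split_symmetric(delays: Sequence[float]) -> tuple[list, list]:
    """Two symmetric presentation sets: odd-indexed delays ascending,
    even-indexed delays descending."""
    asc = [d for i, d in enumerate(delays) if i % 2 == 1]
    desc = [d for i, d in enumerate(delays) if i % 2 == 0][::-1]
    return asc, desc


def _produce(mean: float, pi: float, rng: np.random.Generator) -> float:
    sd = 0.0 if np.isinf(pi) else 1.0 / np.sqrt(pi)
    return float(np.clip(mean + sd * rng.standard_normal(), 1e-9, 1.0))


def simulate_time_session(profile: LatentProfile, delays: Sequence[float] | None = None,
                          config: TimeSessionConfig | None = None, seed: int = 0,
                          participant: str = "sim") -> RatingSession:
    """Simulate the circle-size time-perception session.

    The noiseless production composes the subjective-time power law with the
    circle-production power law, ``a_circ * (a_time * D**b_time)**b_circ``;
    Gaussian noise of precision ``pi`` is added on the diameter scale and the
    result clipped to (0, 1].  Within each presentation set, once a produced
    diameter exceeds the ceiling fraction of the scale, all longer delays of
    that set are dropped from the output.
    """
    config = config or TimeSessionConfig()
    delays = list(DEFAULT_DELAYS if delays is None else delays)
    if any(delays[i] >= delays[i + 1] for i in range(len(delays) - 1)):
        raise ValueError("delays must be sorted strictly ascending")
    if delays[0] < config.min_delay or delays[-1] > config.max_delay:
        raise ValueError(f"delays must lie in [{config.min_delay}, {config.max_delay}]")
    if not profile.pi > 0:
        raise ValueError("rating precision pi must be > 0")

    rng = substream(seed, "time", participant)
    session = RatingSession(participant, "time")
    index = 0
    asc, desc = _split_symmetric(delays)
    for set_id, ordered in (("asc", asc), ("desc", desc)):
        trigger_delay = np.inf
        for d in ordered:
            if d > trigger_delay:
                continue
            mean = profile.a_circ * (profile.a_time * d ** profile.b_time) ** profile.b_circ
            diameter = _produce(mean, profile.pi, rng)
            session.trials.append(RatingTrial("delay", float(d), diameter, index, set_id))
            index += 1
            if diameter > config.ceiling:
                trigger_delay = min(trigger_delay, d)
    return session


def simulate_circle_session(profile: LatentProfile, targets: Sequence[float] | None = None,
                            seed: int = 0, participant: str = "sim") -> RatingSession:
    """Simulate the circle-size calibration session.

    Targets are percentages of the reference circle; the produced diameter is
    ``a_circ * (target/100)**b_circ`` plus Gaussian noise, clipped to (0, 1].
    """
    targets = list(STANDARD_CIRCLE_TARGETS if targets is None else targets)
    if any(not 0 < t <= 100 for t in targets):
        raise ValueError("targets must lie in (0, 100]")
    rng = substream(seed, "circle", participant)
    session = RatingSession(participant, "circle")
    for i, t in enumerate(targets):
        mean = profile.a_circ * (t / 100.0) ** profile.b_circ
        session.trials.append(RatingTrial("percent", float(t),
                                          _produce(mean, profile.pi, rng), i))
    return session


def read_choice_csv(path) -> dict:
    """Load a tidy choice CSV into per-participant ChoiceDataset objects,
    re-validating trial invariants."""
    df = pd.read_csv(path)
    out: dict = {}
    for pid, sub in df.groupby("participant", sort=False):
        ds = ChoiceDataset(str(pid))
        for row in sub.itertuples(index=False):
            ds.trials.append(ChoiceTrial(row.ss_amount, row.ss_delay,
                                         row.ll_amount, row.ll_delay,
                                         row.choice, row.task))
        out[str(pid)] = ds
    return out


def read_rating_csv(path) -> dict:
    """Load a tidy rating CSV into per-participant RatingSession objects."""
    df = pd.read_csv(path)
    out: dict = {}
    for (pid, kind), sub in df.groupby(["participant", "kind"], sort=False):
        sess = RatingSession(str(pid), str(kind))
        for row in sub.itertuples(index=False):
            sess.trials.append(RatingTrial(row.stimulus_kind, row.stimulus_value,
                                           row.diameter, int(row.trial_index),
                                           str(row.set_id) if isinstance(row.set_id, str) else ""))
        out[(str(pid), str(kind))] = sess
    return out
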