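"""Transformed up–down staircases for the two-interval choice task.

Each rectangle is paired with a circle whose radius is driven by an
adaptive staircase: after ``n_down`` consecutive "circle is easier"
responses the radius is decreased (the circle is made harder), after
``n_up`` consecutive "rectangle is easier" responses it is increased.
Updates are multiplicative — the radius moves by a fixed step in log
units — and the step shrinks after each reversal according to a
schedule.  A 1-up/2-down track converges near the 70.7% choose-circle
point of the responder's psychometric function, 2-up/1-down near 29.3%,
and 1-up/1-down near 50%.

Experiment presets (exposed through the pipeline): design 1 pairs each
rectangle with one 1-up/2-down and one 2-up/1-down staircase of 50
trials, steps 0.115/0.075/0.05/0.04 log10 units for the first, second,
third and remaining reversals; design 2 uses a single 1-up/1-down
staircase of 60 trials with steps 0.15/0.1/0.08/0.06.  All staircases of
a session are interleaved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hit_probability import TargetShape

__all__ = [
    "StaircaseSpec",
    "ChoiceTrial",
    "Staircase",
    "run_staircases",
    "trials_to_frame",
    "write_choices_csv",
    "read_choices_csv",
]

EXP1_STEPS = (0.115, 0.075, 0.05, 0.04)
EXP2_STEPS = (0.15, 0.1, 0.08, 0.06)


@dataclass(frozen=True)
class StaircaseSpec:
    """Rule and schedule of one staircase.

    ``rule`` is (n_up, n_down): consecutive "rectangle" responses needed
    to move up (radius increase) and consecutive "circle" responses to
    move down.  ``step_schedule`` lists log steps by reversal epoch
    (before the 1st reversal, after the 1st, after the 2nd, after the
    3rd and thereafter); ``log_base`` fixes the log convention (default
    log10, the usual one in adaptive psychophysics).
    """

    rule: tuple[int, int] = (1, 2)
    step_schedule: tuple[float, ...] = EXP1_STEPS
    n_trials: int = 50
    start_radius: float = 1.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not (self.rule[0] >= 1 and self.rule[1] >= 1):
            raise ValueError("rule counts must be >= 1")
        steps = tuple(self.step_schedule)
        if not steps or any(s <= 0 for s in steps):
            raise ValueError("step schedule must be positive")
        if any(b > a for a, b in zip(steps, steps[1:])):
            raise ValueError("step schedule must be non-increasing")
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if not self.start_radius > 0:
            raise ValueError("start_radius must be positive")
        if not self.log_base > 1:
            raise ValueError("log_base must exceed 1")


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary two-interval judgment produced by a staircase."""

    trial_index: int
    staircase_id: str
    rect_id: str
    rect_w_mm: float
    rect_h_mm: float
    circle_r_mm: float
    response: str  # "circle" | "rectangle"


class Staircase:
    """Mutable staircase state; ``step`` consumes one response."""

    def __init__(self, spec: StaircaseSpec, staircase_id: str = "sc",
                 rect: TargetShape | None = None, rect_id: str = ""):
        self.spec = spec
        self.staircase_id = staircase_id
        self.rect = rect
        self.rect_id = rect_id
        self.radius = float(spec.start_radius)
        self.n_presented = 0
        self.n_reversals = 0
        self._run_circle = 0
        self._run_rect = 0
        self._last_move: int | None = None  # +1 up, -1 down
        self.history: list[tuple[float, str]] = []

    @property
    def terminated(self) -> bool:
        return self.n_presented >= self.spec.n_trials

    def current_step(self) -> float:
        """Log step in effect for the next update (by reversal epoch)."""
        idx = min(self.n_reversals, len(self.spec.step_schedule) - 1)
        return self.spec.step_schedule[idx]

    def step(self, response: str) -> None:
        """Record a response at the current radius and update the track.

        The move uses the step of the current reversal epoch; if the move
        reverses direction, the reversal counter advances so the smaller
        step applies from the next update.
        """
        if self.terminated:
            raise RuntimeError("stepping a terminated staircase")
        if response not in ("circle", "rectangle"):
            raise ValueError(f"unknown response {response!r}")
        self.history.append((self.radius, response))
        self.n_presented += 1

        n_up, n_down = self.spec.rule
        if response == "circle":
            self._run_circle += 1
            self._run_rect = 0
            if self._run_circle >= n_down:
                self._move(-1)
        else:
            self._run_rect += 1
            self._run_circle = 0
            if self._run_rect >= n_up:
                self._move(+1)

    def _move(self, direction: int) -> None:
        step = self.current_step()
        self.radius *= self.spec.log_base ** (direction * step)
        self._run_circle = 0
        self._run_rect = 0
        if self._last_move is not None and direction != self._last_move:
            self.n_reversals += 1
        self._last_move = direction


def run_staircases(staircases: Sequence[Staircase],
                   responder: Callable[[TargetShape, float], str],
                   interleave: bool = True,
                   seed: int | np.random.Generator | None = None,
                   ) -> list[ChoiceTrial]:
    """Run a set of staircases against a responder.

    Interleaving is round-robin: each round presents one trial of every
    live staircase in a freshly shuffled order (seeded), matching the
    interleaved presentation of the experiments.  With
    ``interleave=False`` each staircase runs to termination in turn.
    Returns one :class:`ChoiceTrial` per presentation.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    trials: list[ChoiceTrial] = []
    index = 0

    def present(sc: Staircase) -> None:
        nonlocal index
        radius = sc.radius
        response = responder(sc.rect, radius)
        sc.step(response)
        trials.append(ChoiceTrial(
            trial_index=index, staircase_id=sc.staircase_id,
            rect_id=sc.rect_id,
            rect_w_mm=sc.rect.w if sc.rect is not None else float("nan"),
            rect_h_mm=sc.rect.h if sc.rect is not None else float("nan"),
            circle_r_mm=radius, response=response))
        index += 1

    if interleave:
        alive = [sc for sc in staircases if not sc.terminated]
        while alive:
            order = rng.permutation(len(alive))
            for i in order:
                present(alive[i])
            alive = [sc for sc in alive if not sc.terminated]
    else:
        for sc in staircases:
            while not sc.terminated:
                present(sc)
    return trials


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def trials_to_frame(trials: Sequence[ChoiceTrial]) -> pd.DataFrame:
    return pd.DataFrame({
        "trial_index": [t.trial_index for t in trials],
        "staircase_id": [t.staircase_id for t in trials],
        "rect_id": [t.rect_id for t in trials],
        "rect_w_mm": [t.rect_w_mm for t in trials],
        "rect_h_mm": [t.rect_h_mm for t in trials],
        "circle_r_mm": [t.circle_r_mm for t in trials],
        "response": [t.response for t in trials],
    })


def write_choices_csv(trials: Sequence[ChoiceTrial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_choices_csv(path) -> list[ChoiceTrial]:
    df = pd.read_csv(path)
    return [ChoiceTrial(trial_index=int(r.trial_index),
                        staircase_id=str(r.staircase_id),
                        rect_id=str(r.rect_id),
                        rect_w_mm=float(r.rect_w_mm),
                        rect_h_mm=float(r.rect_h_mm),
                        circle_r_mm=float(r.circle_r_mm),
                        response=str(r.response))
            for r in df.itertuples()]
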