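"""Behavioural state space and its structural transition constraints.

Five broad states for a semi-aquatic freshwater turtle, ordered so that
starting values anchor the labels (no post-hoc relabelling):

    1 ActiveWater    swimming, diving, surfacing
    2 ActiveLand     walking on land
    3 InactiveWater  resting in the water column
    4 InactiveLand   basking on rocks / logs
    5 Nesting        rhythmic hind-leg digging (gravid females only)

Certain transitions are ecologically impossible within a 30-s step (a turtle
resting on the bottom cannot appear on land in the next window without first
swimming) and are excluded structurally: those transition probabilities are
exactly zero and carry no parameter.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "StateLabel",
    "N_STATES",
    "FORBIDDEN_TRANSITIONS",
    "STATE_NAMES",
    "allowed_states",
]


class StateLabel(IntEnum):
    """Behavioural states, fixed order used everywhere in the package."""

    ActiveWater = 1
    ActiveLand = 2
    InactiveWater = 3
    InactiveLand = 4
    Nesting = 5


N_STATES = 5

STATE_NAMES = tuple(s.name for s in StateLabel)

#: Ordered (from, to) pairs whose transition probability is structurally zero.
#: A resting turtle in water can only stay put or become active in water; a
#: nesting female must walk (or rest on land) before re-entering the water;
#: a swimming turtle must haul out actively before it can bask or nest.
FORBIDDEN_TRANSITIONS: frozenset[tuple[StateLabel, StateLabel]] = frozenset(
    {
        (StateLabel.InactiveWater, StateLabel.Nesting),
        (StateLabel.Nesting, StateLabel.InactiveWater),
        (StateLabel.Nesting, StateLabel.ActiveWater),
        (StateLabel.InactiveWater, StateLabel.ActiveLand),
        (StateLabel.InactiveWater, StateLabel.InactiveLand),
        (StateLabel.ActiveWater, StateLabel.Nesting),
        (StateLabel.ActiveWater, StateLabel.InactiveLand),
    }
)


def forbidden_mask(
    forbidden: frozenset[tuple[StateLabel, StateLabel]] = FORBIDDEN_TRANSITIONS,
    n_states: int = N_STATES,
) -> np.ndarray:
    """Boolean (n_states, n_states) matrix, True where a transition is forbidden."""
    mask = np.zeros((n_states, n_states), dtype=bool)
    for a, b in forbidden:
        mask[int(a) - 1, int(b) - 1] = True
    return mask


def allowed_states(gravid: bool) -> np.ndarray:
    """0-based indices of the states an individual can occupy.

    Only gravid females can nest; everyone else lives in the 4-state
    sub-space with Nesting removed.
    """
    if gravid:
        return np.arange(N_STATES)
    return np.array([0, 1, 2, 3])
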