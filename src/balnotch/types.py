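"""Shared domain types for the notched-noise active-learning test.

A trial presents a pure-tone signal at frequency ``f_s`` inside a two-band
noise masker with spectrum level ``L_m`` (dB SPL per 1-Hz band).  The spectral
notch around the signal is described by the offsets of the inner band edges
from ``f_s``, expressed as proportions of ``f_s``; each band is 0.4*f_s wide.
Frequencies are handled internally in octaves re 1 kHz so that the GP's
0.5-octave length scale is literal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

OCTAVE_REF_HZ = 1000.0

#: Trial phases recorded in a log.
PHASE_INITIAL_GRID = "initial_grid"
PHASE_BAL = "bal"
PHASE_CATCH = "catch"
PHASES = (PHASE_INITIAL_GRID, PHASE_BAL, PHASE_CATCH)


def hz_to_octaves(f_hz):
    """Frequency in octaves relative to 1 kHz (log2(f/1000))."""
    return np.log2(np.asarray(f_hz, dtype=float) / OCTAVE_REF_HZ)


def octaves_to_hz(oct_):
    """Inverse of :func:`hz_to_octaves`."""
    return OCTAVE_REF_HZ * 2.0 ** np.asarray(oct_, dtype=float)


@dataclass(frozen=True)
class NotchCondition:
    """Spectral notch geometry, in proportions of the signal frequency.

    ``delta_l`` is the gap between the signal and the upper edge of the lower
    noise band; ``delta_u`` the gap to the lower edge of the upper band.  Both
    bands have width ``bandwidth`` (default 0.4) times the signal frequency.
    """

    delta_l: float
    delta_u: float
    bandwidth: float = 0.4

    def __post_init__(self):
        if self.delta_l < 0 or self.delta_u < 0:
            raise ValueError("notch offsets must be non-negative")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    @property
    def symmetric(self) -> bool:
        return self.delta_l == self.delta_u

    def __str__(self) -> str:  # e.g. "(0.1|0.3)"
        return f"({self.delta_l:g}|{self.delta_u:g})"


#: The standard nine-condition set: five symmetric and four asymmetric
#: notches, each band 0.4*f_s wide.
DEFAULT_NOTCH_SET: tuple[NotchCondition, ...] = (
    NotchCondition(0.0, 0.0),
    NotchCondition(0.1, 0.1),
    NotchCondition(0.2, 0.2),
    NotchCondition(0.3, 0.3),
    NotchCondition(0.4, 0.4),
    NotchCondition(0.1, 0.3),
    NotchCondition(0.3, 0.1),
    NotchCondition(0.2, 0.4),
    NotchCondition(0.4, 0.2),
)


@dataclass(frozen=True)
class StimulusPoint:
    """A candidate or presented stimulus.

    ``f_hz`` is the signal frequency (for catch trials, the frequency the
    masker notch is centred on; no signal is played), ``L_m`` the masker
    spectrum level in dB SPL, ``notch_idx`` the index into the run's notch
    set, ``is_catch`` marks signal-absent trials.
    """

    f_hz: float
    L_m: float
    notch_idx: int
    is_catch: bool = False

    @property
    def log2f(self) -> float:
        return float(np.log2(self.f_hz / OCTAVE_REF_HZ))


@dataclass(frozen=True)
class TrialRecord:
    """One presented stimulus and the listener's binary response."""

    stimulus: StimulusPoint
    response: bool  # True = "Yes, I heard the tone"
    phase: str

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
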