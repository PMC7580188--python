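"""Virtual hearing-impaired listeners for simulation.

A listener profile holds an audiogram (absolute threshold vs frequency,
piecewise-linear in log-frequency), roex filter slopes p_l(f) and p_u(f), an
efficiency K, and response parameters.  Ground-truth masked thresholds come
from the roex forward model with the signal fixed at 15 dB SL; stochastic
Yes/No responses follow a Gaussian-CDF psychometric function in masker level
(SD 3 dB by default) with a 1% lapse rate, and catch trials elicit a false
alarm with probability 1%.  2AFC responses compose the heard-probability
with a fair guess on unheard tones.

An optional smooth "model-mismatch" perturbation can be added to the
ground-truth thresholds so that recovery studies can probe sensitivity to
listeners whose thresholds do not come from the roex family itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr

from .roex_filter import RoexParams, predict_masked_threshold
from .types import NotchCondition, StimulusPoint, hz_to_octaves

SIGNAL_SENSATION_LEVEL_DB = 15.0

#: Normal-hearing baseline roex slope; gives ERB = 4 f / 30 ~ 13% of f_c.
NORMAL_P = 30.0

PRESETS = ("normal", "flat_loss", "sloping_loss")

__all__ = [
    "ListenerProfile",
    "make_profile",
    "ground_truth_threshold",
    "respond_yes_no",
    "respond_2afc",
    "p_yes",
    "p_heard",
    "PRESETS",
]


def _interp_log2f(f_hz, f_knots, values):
    return float(
        np.interp(hz_to_octaves(f_hz), hz_to_octaves(np.asarray(f_knots)), values)
    )


@dataclass
class ListenerProfile:
    """Ground truth for a simulated listener."""

    audiogram_f_hz: tuple[float, ...]
    audiogram_db_spl: tuple[float, ...]
    p_l_values: tuple[float, ...]
    p_u_values: tuple[float, ...]
    K_db: float = 1.0
    psychometric_sd: float = 3.0
    lapse: float = 0.01
    false_alarm: float = 0.01
    f_max: float = 4000.0
    name: str = "custom"
    # Smooth threshold perturbation: amplitude (dB) and per-notch phases for a
    # sinusoid in log2-frequency; zero amplitude means pure roex thresholds.
    mismatch_db: float = 0.0
    mismatch_phases: tuple[float, ...] = field(default_factory=tuple)
    mismatch_cycles_per_octave: float = 0.5

    def __post_init__(self):
        if len(self.audiogram_f_hz) != len(self.audiogram_db_spl):
            raise ValueError("audiogram knots and values must align")
        if min(self.p_l_values) <= 0 or min(self.p_u_values) <= 0:
            raise ValueError("roex slopes must be positive")
        if not 0.0 <= self.lapse <= 0.05:
            raise ValueError("lapse must lie in [0, 0.05]")
        if self.psychometric_sd <= 0:
            raise ValueError("psychometric_sd must be positive")

    def audiogram(self, f_hz: float) -> float:
        """Absolute threshold (dB SPL), piecewise-linear in log2 frequency."""
        return _interp_log2f(f_hz, self.audiogram_f_hz, self.audiogram_db_spl)

    def p_l(self, f_hz: float) -> float:
        return _interp_log2f(f_hz, self.audiogram_f_hz, self.p_l_values)

    def p_u(self, f_hz: float) -> float:
        return _interp_log2f(f_hz, self.audiogram_f_hz, self.p_u_values)

    def signal_level(self, f_hz: float) -> float:
        """Signal level L_s: 15 dB above the listener's absolute threshold."""
        return self.audiogram(f_hz) + SIGNAL_SENSATION_LEVEL_DB

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ListenerProfile":
        d = json.loads(text)
        for k in (
            "audiogram_f_hz",
            "audiogram_db_spl",
            "p_l_values",
            "p_u_values",
            "mismatch_phases",
        ):
            d[k] = tuple(d[k])
        return cls(**d)


#: Audiogram presets: knot frequencies (Hz) and absolute thresholds (dB SPL).
_AUDIOGRAM_PRESETS = {
    "normal": ((500.0, 1000.0, 2000.0, 4000.0), (10.0, 10.0, 10.0, 10.0)),
    "flat_loss": ((500.0, 1000.0, 2000.0, 4000.0), (40.0, 40.0, 40.0, 40.0)),
    "sloping_loss": ((500.0, 1000.0, 2000.0, 4000.0), (15.0, 25.0, 40.0, 60.0)),
}

#: Linear degradation of the roex slopes with hearing loss: fractional loss
#: of p per dB of threshold elevation above the normal baseline, floored.
_P_DEGRADATION_PER_DB = 0.012
_P_MIN_FRACTION = 0.25
_NORMAL_BASELINE_DB = 10.0


def _degrade_p(loss_db: np.ndarray) -> np.ndarray:
    frac = 1.0 - _P_DEGRADATION_PER_DB * np.maximum(0.0, loss_db)
    return NORMAL_P * np.clip(frac, _P_MIN_FRACTION, 1.0)


def make_profile(
    preset: str,
    rng: np.random.Generator | None = None,
    mismatch_db: float = 0.0,
    **overrides,
) -> ListenerProfile:
    """Build a listener profile from a named preset plus overrides.

    The roex slopes are degraded from the normal-hearing baseline by a linear
    function of the audiogram elevation, so sloping losses yield broader
    filters at high frequencies.  ``rng`` is only consumed when a
    model-mismatch perturbation is requested (random phases), so profiles are
    deterministic under a fixed seed.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    f_knots, thr = _AUDIOGRAM_PRESETS[preset]
    loss = np.asarray(thr) - _NORMAL_BASELINE_DB
    p_vals = _degrade_p(loss)
    phases: tuple[float, ...] = ()
    if mismatch_db > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        phases = tuple(rng.uniform(0.0, 2.0 * np.pi, size=16))
    fields = dict(
        audiogram_f_hz=f_knots,
        audiogram_db_spl=thr,
        p_l_values=tuple(p_vals),
        p_u_values=tuple(p_vals),
        K_db=1.0,
        name=preset,
        mismatch_db=mismatch_db,
        mismatch_phases=phases,
    )
    fields.update(overrides)
    return ListenerProfile(**fields)


def _mismatch(profile: ListenerProfile, notch_idx: int, f_hz: float) -> float:
    if profile.mismatch_db == 0.0 or not profile.mismatch_phases:
        return 0.0
    phase = profile.mismatch_phases[notch_idx % len(profile.mismatch_phases)]
    x = hz_to_octaves(f_hz) * profile.mismatch_cycles_per_octave
    return profile.mismatch_db * float(np.sin(2.0 * np.pi * x + phase))


def ground_truth_threshold(
    profile: ListenerProfile,
    notch: NotchCondition,
    f_s: float,
    notch_idx: int = 0,
) -> float:
    """Masker spectrum level at 50% detection (dB SPL per Hz)."""
    if f_s > profile.f_max:
        raise ValueError(f"f_s={f_s} above profile f_max={profile.f_max}")
    params = RoexParams(
        p_l=profile.p_l(f_s), p_u=profile.p_u(f_s), K_db=profile.K_db
    )
    t = predict_masked_threshold(params, notch, f_s, profile.signal_level(f_s))
    return t + _mismatch(profile, notch_idx, f_s)


def p_yes(profile: ListenerProfile, threshold: float, L_m: float) -> float:
    """Probability of a Yes response on a signal trial at masker level L_m."""
    lam = profile.lapse
    return lam + (1.0 - 2.0 * lam) * float(
        ndtr((threshold - L_m) / profile.psychometric_sd)
    )


def p_heard(profile: ListenerProfile, threshold: float, L_m: float) -> float:
    """Probability the tone is actually heard (no lapse channel)."""
    return float(ndtr((threshold - L_m) / profile.psychometric_sd))


def _threshold_for(profile, stimulus, notch_set):
    notch = notch_set[stimulus.notch_idx]
    return ground_truth_threshold(
        profile, notch, stimulus.f_hz, notch_idx=stimulus.notch_idx
    )


def respond_yes_no(
    profile: ListenerProfile,
    stimulus: StimulusPoint,
    rng: np.random.Generator,
    notch_set=None,
    threshold: float | None = None,
) -> bool:
    """Draw a Yes/No response; catch trials yield false alarms only.

    ``threshold`` may be supplied to avoid recomputing the forward model
    (callers typically cache it per (notch, frequency) pair).
    """
    if stimulus.is_catch:
        return bool(rng.random() < profile.false_alarm)
    if threshold is None:
        from .types import DEFAULT_NOTCH_SET

        threshold = _threshold_for(profile, stimulus, notch_set or DEFAULT_NOTCH_SET)
    return bool(rng.random() < p_yes(profile, threshold, stimulus.L_m))


def respond_2afc(
    profile: ListenerProfile,
    stimulus: StimulusPoint,
    rng: np.random.Generator,
    notch_set=None,
    threshold: float | None = None,
) -> bool:
    """Draw a correct/incorrect 2I-2AFC response (guess rate 1/2)."""
    if threshold is None:
        from .types import DEFAULT_NOTCH_SET

        threshold = _threshold_for(profile, stimulus, notch_set or DEFAULT_NOTCH_SET)
    if rng.random() < p_heard(profile, threshold, stimulus.L_m):
        return True
    return bool(rng.random() < 0.5)
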