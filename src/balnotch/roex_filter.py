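"""Rounded-exponential (roex) auditory-filter model and fitting.

The power-spectrum model of masking assumes the listener detects the signal
through a single band-pass filter centred on the signal frequency.  The
two-slope roex filter weights power at normalized frequency offset
``g = |f - f_c| / f_c`` by ``W(g) = (1 + p g) exp(-p g)``, with separate
slopes ``p_l`` and ``p_u`` for the lower and upper skirts.  At threshold the
signal power P_s satisfies

    P_s = K * N_0 * f_s * (I_l + I_u)

where N_0 is the linear masker spectrum level, I_l/I_u are the integrals of W
over the two noise bands (in units of g) and K is the detection-efficiency
parameter.  In dB this gives the masked threshold used throughout:

    N_0 [dB] = L_s - K_db - 10 log10( f_s * (I_l + I_u) )

Fitting inverts this relation by least squares on the dB thresholds over the
notch conditions; the widest symmetric notch (0.4|0.4) is excluded because
the two-slope model has no tail and systematically mispredicts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .types import DEFAULT_NOTCH_SET, NotchCondition

P_LOWER_BOUND = 1.0
P_UPPER_BOUND = 200.0

__all__ = [
    "RoexParams",
    "ThresholdSet",
    "RoexFit",
    "roex_weight",
    "band_integral",
    "predict_masked_threshold",
    "fit_filter",
    "erb",
    "fit_threshold_surface",
]


@dataclass(frozen=True)
class RoexParams:
    """Roex filter parameters: skirt slopes and efficiency (10 log10 K)."""

    p_l: float
    p_u: float
    K_db: float = 0.0

    def __post_init__(self):
        if not (P_LOWER_BOUND < self.p_l < P_UPPER_BOUND):
            raise ValueError(f"p_l must lie in ({P_LOWER_BOUND}, {P_UPPER_BOUND})")
        if not (P_LOWER_BOUND < self.p_u < P_UPPER_BOUND):
            raise ValueError(f"p_u must lie in ({P_LOWER_BOUND}, {P_UPPER_BOUND})")
        if not np.isfinite(self.K_db):
            raise ValueError("K_db must be finite")


@dataclass
class ThresholdSet:
    """Masked thresholds at one centre frequency, one per notch condition."""

    f_s: float
    notches: list[NotchCondition]
    thresholds_db: np.ndarray
    L_s: float

    def __post_init__(self):
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if len(self.notches) != len(self.thresholds_db):
            raise ValueError("one threshold per notch condition required")

    def usable(self) -> tuple[list[NotchCondition], np.ndarray]:
        """Drop the (0.4|0.4) condition, which the two-slope model cannot fit."""
        keep = [
            i
            for i, nc in enumerate(self.notches)
            if not (nc.delta_l == 0.4 and nc.delta_u == 0.4)
        ]
        return [self.notches[i] for i in keep], self.thresholds_db[keep]


@dataclass
class RoexFit:
    """Fitted parameters with diagnostics at one centre frequency."""

    params: RoexParams
    f_s: float
    rms_residual_db: float
    n_points: int
    at_bound: bool = False
    erb_hz: float = field(init=False)

    def __post_init__(self):
        self.erb_hz = erb(self.params, self.f_s)


def roex_weight(g, p):
    """Filter weight ``W(g) = (1 + p g) exp(-p g)`` for g >= 0."""
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("g must be non-negative")
    if p <= 0:
        raise ValueError("p must be positive")
    return (1.0 + p * g) * np.exp(-p * g)


def band_integral(a, b, p):
    """Integral of the roex weight over [a, b] in normalized-offset units.

    Uses the antiderivative -(g + 2/p) exp(-p g), so the result is exact.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < a):
        raise ValueError("need 0 <= a <= b")
    return (a + 2.0 / p) * np.exp(-p * a) - (b + 2.0 / p) * np.exp(-p * b)


def predict_masked_threshold(
    params: RoexParams, notch: NotchCondition, f_s: float, L_s: float
) -> float:
    """Masker spectrum level N_0 (dB) at which the signal is at threshold."""
    integral = band_integral(
        notch.delta_l, notch.delta_l + notch.bandwidth, params.p_l
    ) + band_integral(notch.delta_u, notch.delta_u + notch.bandwidth, params.p_u)
    if integral <= 1e-300:
        raise FloatingPointError(
            f"degenerate filter integral for notch {notch}: no noise passes"
        )
    return L_s - params.K_db - 10.0 * np.log10(f_s * integral)


def _predict_vector(theta, notches, f_s, L_s):
    p_l, p_u, K_db = theta
    il = band_integral(
        np.array([nc.delta_l for nc in notches]),
        np.array([nc.delta_l + nc.bandwidth for nc in notches]),
        p_l,
    )
    iu = band_integral(
        np.array([nc.delta_u for nc in notches]),
        np.array([nc.delta_u + nc.bandwidth for nc in notches]),
        p_u,
    )
    return L_s - K_db - 10.0 * np.log10(f_s * (il + iu))


#: Multi-start grid for the skirt slopes; shallow local minima occur when one
#: slope is very flat, so several basins are probed.
_P_STARTS = (10.0, 20.0, 40.0)


def fit_filter(ts: ThresholdSet) -> RoexFit:
    """Least-squares fit of (p_l, p_u, K_db) to a set of notch thresholds.

    Residuals are taken in dB.  The (0.4|0.4) condition is excluded before
    fitting.  Raises ``ValueError`` with diagnostics if no start converges.
    """
    notches, obs = ts.usable()
    if len(notches) < 4:
        raise ValueError(
            f"need >= 4 usable notch thresholds to fit three parameters, got {len(notches)}"
        )

    lo = np.array([P_LOWER_BOUND + 1e-3, P_LOWER_BOUND + 1e-3, -80.0])
    hi = np.array([P_UPPER_BOUND - 1e-3, P_UPPER_BOUND - 1e-3, 80.0])

    def resid(theta):
        return _predict_vector(theta, notches, ts.f_s, ts.L_s) - obs

    best = None
    for p0l in _P_STARTS:
        for p0u in _P_STARTS:
            x0 = np.array([p0l, p0u, 0.0])
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise ValueError(
            f"roex fit failed from all starts at f_s={ts.f_s} Hz; thresholds={obs}"
        )

    p_l, p_u, K_db = best.x
    at_bound = bool(
        np.any(np.isclose(best.x[:2], lo[:2], atol=1e-2))
        or np.any(np.isclose(best.x[:2], hi[:2], atol=1e-2))
    )
    if at_bound:
        warnings.warn(
            f"roex slope at bound (p_l={p_l:.3g}, p_u={p_u:.3g}) at f_s={ts.f_s} Hz",
            RuntimeWarning,
            stacklevel=2,
        )
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return RoexFit(
        params=RoexParams(p_l=float(p_l), p_u=float(p_u), K_db=float(K_db)),
        f_s=ts.f_s,
        rms_residual_db=rms,
        n_points=len(notches),
        at_bound=at_bound,
    )


def erb(params: RoexParams, f_c: float) -> float:
    """Equivalent rectangular bandwidth, Hz: (2/p_l + 2/p_u) * f_c."""
    return (2.0 / params.p_l + 2.0 / params.p_u) * f_c


def fit_threshold_surface(
    surface: pd.DataFrame,
    L_s,
    notches: tuple[NotchCondition, ...] = DEFAULT_NOTCH_SET,
    min_notches: int = 4,
) -> pd.DataFrame:
    """Fit roex filters independently at every frequency node of a surface.

    Parameters
    ----------
    surface : DataFrame with columns ``notch_id``, ``f_hz``, ``threshold_db``
        and optionally ``flag`` (non-empty flags are dropped before fitting).
    L_s : scalar signal level (dB SPL) or callable ``L_s(f_hz)``.
    notches : notch set indexed by ``notch_id``.
    min_notches : minimum usable thresholds per node; nodes below are skipped.

    Returns a DataFrame with one row per fitted frequency node:
    ``f_hz, p_l, p_u, K_db, erb_hz, rms_residual_db, n_points, at_bound``.
    """
    rows = []
    usable = surface
    if "flag" in surface.columns:
        usable = surface[surface["flag"].isna() | (surface["flag"] == "")]
    for f_hz, grp in usable.groupby("f_hz", sort=True):
        ls = float(L_s(f_hz)) if callable(L_s) else float(L_s)
        ncs = [notches[int(i)] for i in grp["notch_id"]]
        ts = ThresholdSet(
            f_s=float(f_hz),
            notches=ncs,
            thresholds_db=grp["threshold_db"].to_numpy(),
            L_s=ls,
        )
        if len(ts.usable()[0]) < min_notches:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_filter(ts)
        except ValueError:
            continue
        rows.append(
            {
                "f_hz": float(f_hz),
                "p_l": fit.params.p_l,
                "p_u": fit.params.p_u,
                "K_db": fit.params.K_db,
                "erb_hz": fit.erb_hz,
                "rms_residual_db": fit.rms_residual_db,
                "n_points": fit.n_points,
                "at_bound": fit.at_bound,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "f_hz",
            "p_l",
            "p_u",
            "K_db",
            "erb_hz",
            "rms_residual_db",
            "n_points",
            "at_bound",
        ],
    )
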