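"""GP binary classification over the (frequency, masker-level) plane.

One GP per notch condition models the probability of a Yes response as a
function of log2-frequency (octaves re 1 kHz) and masker spectrum level
(dB SPL).  The latent function f has a constant mean (the only hyperparameter
optimized during a run, by maximizing the approximate marginal likelihood
starting from 0) and an additive kernel: a squared-exponential in frequency
with a fixed 0.5-octave length scale plus a homogeneous linear term in level
scaled so that a unit latent change corresponds to 3 dB — the prior
psychometric function is then a Gaussian CDF with SD 3 dB.  The latent is
squashed through a lapse-rate likelihood

    p(yes | f) = 0.01 + 0.98 * Phi(f)

which floors/ceils predictions at 1%/99% to absorb attention lapses.

Approximate inference uses expectation propagation; the tilted moments have
closed form because the lapse likelihood is affine in the probit.  Laplace's
method is the fallback when EP does not converge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .types import OCTAVE_REF_HZ, StimulusPoint

logger = logging.getLogger("balnotch")

_JITTER = 1e-10
_SQRT_2PI = np.sqrt(2.0 * np.pi)

__all__ = [
    "GPHyperparameters",
    "GPDataset",
    "LatentPosterior",
    "GPInferenceError",
    "ThresholdResult",
    "build_kernel",
    "infer_posterior",
    "optimize_constant_mean",
    "approx_log_marginal",
    "predict_p_yes",
    "threshold_from_gp",
    "estimate_psychometric_slope",
]


class GPInferenceError(RuntimeError):
    """Raised when both EP and Laplace inference fail; carries the dataset."""

    def __init__(self, message, dataset=None):
        super().__init__(message)
        self.dataset = dataset


@dataclass(frozen=True)
class GPHyperparameters:
    """Fixed GP hyperparameters plus the optimized constant mean.

    ``level_scale`` divides the level coordinate in the linear kernel so the
    induced psychometric SD equals ``psychometric_sd`` (both 3 dB by
    default); ``se_amplitude`` sets the prior variability of the threshold
    across frequency in latent units (5 latent units ~ 15 dB).
    """

    mean_const: float = 0.0
    ell_f: float = 0.5
    psychometric_sd: float = 3.0
    level_scale: float = 3.0
    se_amplitude: float = 5.0
    lapse_floor: float = 0.01
    lapse_span: float = 0.98

    def __post_init__(self):
        if self.ell_f <= 0 or self.level_scale <= 0:
            raise ValueError("length scale and level scale must be positive")
        if self.se_amplitude <= 0 or self.psychometric_sd <= 0:
            raise ValueError("se_amplitude and psychometric_sd must be positive")
        if not (0 <= self.lapse_floor and self.lapse_floor + self.lapse_span <= 1):
            raise ValueError("invalid lapse floor/span")


def build_kernel(hypers: GPHyperparameters):
    """Covariance function over (log2-frequency, level) points.

    k(x, x') = a^2 exp(-d_oct^2 / (2 l^2)) + L L' / s^2; the SE part moves
    the threshold smoothly across frequency, the linear part carries the
    level dependence.  Points are arrays of shape (n, 2): [octaves, dB].
    """
    ell, s, a = hypers.ell_f, hypers.level_scale, hypers.se_amplitude

    def k(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        d = X1[:, 0][:, None] - X2[:, 0][None, :]
        se = a * a * np.exp(-0.5 * (d / ell) ** 2)
        lin = np.outer(X1[:, 1], X2[:, 1]) / (s * s)
        return se + lin

    return k


@dataclass
class GPDataset:
    """Observed (log2-frequency, level) points with +/-1 (Yes/No) labels."""

    X: np.ndarray  # (n, 2): [:, 0] octaves re 1 kHz, [:, 1] level dB
    y: np.ndarray  # (n,) in {+1, -1}

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y lengths differ")
        if self.X.size and not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValueError("labels must be +1 (Yes) or -1 (No)")

    def __len__(self) -> int:
        return int(self.y.shape[0])

    @classmethod
    def empty(cls) -> "GPDataset":
        return cls(X=np.zeros((0, 2)), y=np.zeros(0))

    def add(self, log2f: float, level: float, yes: bool) -> "GPDataset":
        x = np.array([[log2f, level]])
        lab = np.array([1.0 if yes else -1.0])
        return GPDataset(X=np.vstack([self.X, x]), y=np.concatenate([self.y, lab]))

    def to_frame(self, notch_id: int = 0, phase: str = "bal") -> pd.DataFrame:
        f_hz = OCTAVE_REF_HZ * 2.0 ** self.X[:, 0]
        return pd.DataFrame(
            {
                "notch_id": notch_id,
                "f_hz": f_hz,
                "log2f": self.X[:, 0],
                "L_m_db": self.X[:, 1],
                "response": (self.y > 0).astype(int),
                "is_catch": False,
                "phase": phase,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GPDataset":
        sig = frame[~frame["is_catch"].astype(bool)]
        X = np.column_stack([sig["log2f"].to_numpy(), sig["L_m_db"].to_numpy()])
        y = np.where(sig["response"].to_numpy().astype(int) > 0, 1.0, -1.0)
        return cls(X=X, y=y)


# ---------------------------------------------------------------------------
# Lapse-probit likelihood: p(y | f) = floor_y + span * Phi(y f), where
# floor_y is `lapse_floor` for y=+1 and 1 - lapse_floor - lapse_span for
# y=-1 (both 0.01 at the defaults).
# ---------------------------------------------------------------------------


def _floor_for(y: np.ndarray, hypers: GPHyperparameters) -> np.ndarray:
    ceil_gap = 1.0 - hypers.lapse_floor - hypers.lapse_span
    return np.where(y > 0, hypers.lapse_floor, ceil_gap)


def _norm_pdf(z):
    return np.exp(-0.5 * z * z) / _SQRT_2PI


def _tilted_moments(y, m_cav, v_cav, hypers):
    """Z, dlogZ/dm, d2logZ/dm2 of the tilted distribution (closed form)."""
    span = hypers.lapse_span
    floor = _floor_for(y, hypers)
    s = np.sqrt(1.0 + v_cav)
    z = y * m_cav / s
    Z = floor + span * ndtr(z)
    pdf = _norm_pdf(z)
    alpha = span * y * pdf / (Z * s)
    d2 = -span * z * pdf / (Z * s * s) - alpha * alpha
    return Z, alpha, d2


def _log_lik_terms(f, y, hypers):
    """log p(y|f), gradient, and (negative-definite-clipped) Hessian diag."""
    span = hypers.lapse_span
    floor = _floor_for(y, hypers)
    Z = floor + span * ndtr(y * f)
    pdf = _norm_pdf(f)
    grad = span * y * pdf / Z
    hess = -f * y * span * pdf / Z - grad * grad
    return np.log(Z), grad, hess


def predict_p_yes(mu, var, hypers: GPHyperparameters | None = None):
    """Probit-averaged predictive probability of a Yes response.

    p = floor + span * Phi(mu / sqrt(1 + var)); always in [0.01, 0.99] at
    the default lapse parameters.
    """
    h = hypers or GPHyperparameters()
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    return h.lapse_floor + h.lapse_span * ndtr(mu / np.sqrt(1.0 + var))


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------


class LatentPosterior:
    """Gaussian approximation to the latent posterior, queryable anywhere.

    Predictions use mu* = m + k*^T alpha and var* = k** - k*^T P k*, where
    P = (K + S^-1)^-1 in site-precision form; this covers both the EP and
    Laplace parameterizations (sites may carry negative precision under EP,
    which lets the approximation inflate variance beyond the prior where the
    lapse floor makes the exact posterior heavy-tailed).
    """

    def __init__(self, data, hypers, alpha, P, method, converged,
                 log_marginal, site_tau=None, site_nu=None):
        self.data = data
        self.hypers = hypers
        self._alpha = alpha
        self._P = P
        self.inference_method = method
        self.converged = converged
        self.log_marginal = float(log_marginal)
        self.site_tau = site_tau
        self.site_nu = site_nu
        self._kernel = build_kernel(hypers)

    def latent(self, Xstar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and variance of the latent at query points."""
        Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
        Ks = self._kernel(self.data.X, Xstar)  # (n, m)
        mu = self.hypers.mean_const + Ks.T @ self._alpha
        kss = (
            self.hypers.se_amplitude**2
            + Xstar[:, 1] ** 2 / self.hypers.level_scale**2
        )
        var = np.maximum(kss - np.einsum("ij,ij->j", Ks, self._P @ Ks), 0.0)
        return mu, var

    def predict_p_yes(self, Xstar: np.ndarray) -> np.ndarray:
        mu, var = self.latent(Xstar)
        return predict_p_yes(mu, var, self.hypers)


def _posterior_from_sites(K, Km_inv_m, m, tau, nu):
    """Posterior (Sigma, mu) from site natural parameters; tau may be < 0.

    Sigma = (K^-1 + S)^-1 = (I + K S)^-1 K and mu = Sigma (nu + K^-1 m),
    computed by LU solves so negative site precisions are admissible.
    """
    n = K.shape[0]
    M = np.eye(n) + K * tau[None, :]
    Sigma = np.linalg.solve(M, K)
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = Sigma @ (nu + Km_inv_m)
    return Sigma, mu, M


def _ep_log_marginal(K, Km_inv_m, m, tau, nu, y, hypers, M, Sigma, mu):
    """EP approximation of log p(y | X).

    Site normalizers are fixed by zeroth-moment matching under the cavity,
    which keeps every term finite for negative site precisions as long as
    the site-plus-cavity precision stays positive.
    """
    sigma2 = np.diag(Sigma)
    tau_cav = 1.0 / sigma2 - tau
    if np.any(tau_cav <= 0) or np.any(1.0 + tau * (1.0 / tau_cav) <= 0):
        return -np.inf
    nu_cav = mu / sigma2 - nu
    v_cav = 1.0 / tau_cav
    m_cav = nu_cav * v_cav
    Z, _, _ = _tilted_moments(y, m_cav, v_cav, hypers)

    # log C_i = log Z_i + 0.5 log(1 + tau v_cav) - 0.5 p^2/q + 0.5 m_cav^2/v_cav
    q = tau_cav + tau
    p = nu_cav + nu
    log_C = (
        np.log(Z)
        + 0.5 * np.log1p(tau * v_cav)
        - 0.5 * p * p / q
        + 0.5 * m_cav * m_cav / v_cav
    )
    sign, logdet_M = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    r = nu + Km_inv_m
    return (
        float(np.sum(log_C))
        - 0.5 * logdet_M
        + 0.5 * float(r @ mu)
        - 0.5 * float(m @ Km_inv_m)
    )


def _fit_ep(data, hypers, max_sweeps=60, tol=1e-4, damping=0.8, warm=None):
    """Parallel-update EP; returns a LatentPosterior or None on failure."""
    n = len(data)
    kern = build_kernel(hypers)
    K = kern(data.X, data.X) + _JITTER * np.eye(n)
    m = np.full(n, hypers.mean_const)
    try:
        cK = cholesky(K, lower=True)
    except np.linalg.LinAlgError:
        return None
    Km_inv_m = solve_triangular(
        cK.T, solve_triangular(cK, m, lower=True), lower=False
    )
    y = data.y
    if warm is not None and len(warm[0]) == n:
        tau, nu = warm[0].copy(), warm[1].copy()
    else:
        tau = np.zeros(n)
        nu = np.zeros(n)

    converged = False
    Sigma = mu = M = None
    for _ in range(max_sweeps):
        try:
            Sigma, mu, M = _posterior_from_sites(K, Km_inv_m, m, tau, nu)
        except np.linalg.LinAlgError:
            return None
        sigma2 = np.diag(Sigma)
        if np.any(sigma2 <= 0):
            return None
        tau_cav = 1.0 / sigma2 - tau
        bad = tau_cav <= 1e-12  # skip sites with an invalid cavity this sweep
        tau_cav = np.maximum(tau_cav, 1e-12)
        nu_cav = mu / sigma2 - nu
        v_cav = 1.0 / tau_cav
        m_cav = nu_cav * v_cav

        _, alpha_t, d2 = _tilted_moments(y, m_cav, v_cav, hypers)
        mu_hat = m_cav + v_cav * alpha_t
        sig2_hat = np.clip(v_cav * (1.0 + v_cav * d2), 1e-12, None)

        tau_new = 1.0 / sig2_hat - tau_cav
        nu_new = mu_hat / sig2_hat - nu_cav
        tau_new = np.where(bad, tau, tau_new)
        nu_new = np.where(bad, nu, nu_new)

        tau_next = (1.0 - damping) * tau + damping * tau_new
        nu_next = (1.0 - damping) * nu + damping * nu_new
        # keep the damped site compatible with its cavity
        tau_next = np.maximum(tau_next, -tau_cav + 1e-8)
        delta = max(
            float(np.max(np.abs(tau_next - tau), initial=0.0)),
            float(np.max(np.abs(nu_next - nu), initial=0.0)),
        )
        tau, nu = tau_next, nu_next
        if delta < tol:
            converged = True
            break

    if not converged:
        return None
    try:
        Sigma, mu, M = _posterior_from_sites(K, Km_inv_m, m, tau, nu)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(Sigma) <= 0):
        return None
    lml = _ep_log_marginal(K, Km_inv_m, m, tau, nu, y, hypers, M, Sigma, mu)
    if not np.isfinite(lml):
        return None
    # P = (K + S^-1)^-1 = S (I + K S)^-1 and alpha with mu* = m + k*^T alpha
    P = tau[:, None] * np.linalg.solve(M, np.eye(n))
    P = 0.5 * (P + P.T)
    alpha = np.linalg.solve(np.eye(n) + tau[:, None] * K, nu) - P @ m
    return LatentPosterior(
        data, hypers, alpha, P, "EP", True, lml,
        site_tau=tau, site_nu=nu,
    )


def _fit_ep_robust(data, hypers, warm=None, deep=False, max_sweeps=60,
                   tol=1e-4):
    """EP with progressively heavier damping; ``deep`` adds a slow last try."""
    post = _fit_ep(data, hypers, max_sweeps=max_sweeps, tol=tol, warm=warm)
    if post is None:
        post = _fit_ep(data, hypers, max_sweeps=5 * max_sweeps, tol=tol,
                       damping=0.4, warm=warm)
    if post is None and deep:
        post = _fit_ep(data, hypers, max_sweeps=25 * max_sweeps, tol=tol,
                       damping=0.15, warm=warm)
    return post


def _fit_laplace(data, hypers, max_iter=60, tol=1e-8):
    """Laplace approximation (damped Newton on the latent mode)."""
    n = len(data)
    kern = build_kernel(hypers)
    K = kern(data.X, data.X) + _JITTER * np.eye(n)
    m = np.full(n, hypers.mean_const)
    y = data.y
    # start inside the informative band of the likelihood: at |f| >> 0 the
    # lapse floor flattens the log-likelihood and Newton cannot move
    f = np.clip(m, -3.0, 3.0)
    try:
        cK = cholesky(K, lower=True)
        a = solve_triangular(
            cK.T, solve_triangular(cK, f - m, lower=True), lower=False
        )
    except np.linalg.LinAlgError:
        return None

    def objective(fv, av):
        ll, _, _ = _log_lik_terms(fv, y, hypers)
        return float(np.sum(ll)) - 0.5 * float(av @ (fv - m))

    obj = objective(f, a)
    L = np.eye(n)
    W = np.zeros(n)
    for _ in range(max_iter):
        _, grad, hess = _log_lik_terms(f, y, hypers)
        W = np.clip(-hess, 1e-12, None)
        sw = np.sqrt(W)
        B = np.eye(n) + sw[:, None] * K * sw[None, :]
        try:
            L = cholesky(B, lower=True)
        except np.linalg.LinAlgError:
            return None
        b = W * (f - m) + grad
        v = solve_triangular(L, sw * (K @ b), lower=True)
        a_new = b - sw * solve_triangular(L.T, v, lower=False)
        f_new = m + K @ a_new
        # backtracking on the Newton step for robustness
        step = 1.0
        for _ in range(12):
            f_try = f + step * (f_new - f)
            a_try = a + step * (a_new - a)
            obj_try = objective(f_try, a_try)
            if obj_try >= obj - 1e-12:
                break
            step *= 0.5
        moved = float(np.max(np.abs(f_try - f), initial=0.0))
        f, a, prev_obj, obj = f_try, a_try, obj, obj_try
        if moved < 1e-6 or abs(obj - prev_obj) < tol:
            break

    ll, grad, hess = _log_lik_terms(f, y, hypers)
    W = np.clip(-hess, 1e-12, None)
    sw = np.sqrt(W)
    B = np.eye(n) + sw[:, None] * K * sw[None, :]
    try:
        L = cholesky(B, lower=True)
    except np.linalg.LinAlgError:
        return None
    lml = (
        float(np.sum(ll))
        - 0.5 * float(a @ (f - m))
        - float(np.sum(np.log(np.diag(L))))
    )
    Binv = solve_triangular(L.T, solve_triangular(L, np.eye(n), lower=True),
                            lower=False)
    P = sw[:, None] * Binv * sw[None, :]
    P = 0.5 * (P + P.T)
    return LatentPosterior(data, hypers, grad, P, "Laplace", True, lml)


def infer_posterior(
    data: GPDataset,
    hypers: GPHyperparameters,
    max_sweeps: int = 60,
    tol: float = 1e-4,
    warm=None,
) -> LatentPosterior:
    """EP posterior with Laplace fallback; raises GPInferenceError if both fail."""
    if len(data) == 0:
        raise ValueError("cannot infer a posterior from an empty dataset")
    post = _fit_ep_robust(data, hypers, warm=warm, deep=True,
                          max_sweeps=max_sweeps, tol=tol)
    if post is not None:
        return post
    logger.warning("EP did not converge (n=%d); falling back to Laplace", len(data))
    post = _fit_laplace(data, hypers)
    if post is not None:
        return post
    raise GPInferenceError(
        f"both EP and Laplace inference failed on {len(data)} points", dataset=data
    )


def approx_log_marginal(data: GPDataset, hypers: GPHyperparameters, warm=None):
    """Approximate log marginal likelihood (EP, Laplace fallback).

    Returns (value, posterior) so callers can reuse the fit.
    """
    post = _fit_ep_robust(data, hypers, warm=warm, deep=False)
    if post is None:
        post = _fit_laplace(data, hypers)
    if post is None:
        raise GPInferenceError("marginal-likelihood evaluation failed", dataset=data)
    return post.log_marginal, post


def optimize_constant_mean(
    data: GPDataset,
    hypers: GPHyperparameters,
    bounds: tuple[float, float] = (-20.0, 20.0),
    xatol: float = 1e-2,
) -> GPHyperparameters:
    """Maximize the approximate marginal likelihood over the constant mean.

    Derivative-free bounded search on [-20, 20] latent units, restarted from
    scratch (no warm start from a previous trial's optimum).  On optimizer
    failure the previous mean is kept and a warning is logged.
    """
    if len(data) == 0:
        raise ValueError("cannot optimize the mean on an empty dataset")
    warm_cache: dict = {}

    def neg(mc: float) -> float:
        h = replace(hypers, mean_const=float(mc))
        try:
            val, post = approx_log_marginal(data, h, warm=warm_cache.get("sites"))
        except GPInferenceError:
            return 1e10
        if post.site_tau is not None:
            warm_cache["sites"] = (post.site_tau, post.site_nu)
        return -val

    res = minimize_scalar(
        neg, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    if not res.success or not np.isfinite(res.fun) or res.fun >= 1e9:
        logger.warning("mean optimization failed; keeping mean=%g", hypers.mean_const)
        return hypers
    return replace(hypers, mean_const=float(res.x))


@dataclass(frozen=True)
class ThresholdResult:
    """50%-detection level, or a boundary flag when no crossing exists."""

    level: float
    flag: str | None = None  # None | "all-above" | "all-below"

    @property
    def in_range(self) -> bool:
        return self.flag is None


def threshold_from_gp(
    post: LatentPosterior, f_hz: float, level_grid: np.ndarray
) -> ThresholdResult:
    """Masker level at 50% detection at one frequency.

    Scans the 1-dB level grid for sign changes of the latent predictive mean
    (p_yes = 0.5 exactly where the mean crosses 0) and linearly interpolates;
    with multiple crossings the highest-level one is returned.  If the
    probability stays on one side of 0.5 over the whole grid, the boundary
    level is returned with a flag.
    """
    levels = np.asarray(level_grid, dtype=float)
    X = np.column_stack([np.full(levels.shape, np.log2(f_hz / OCTAVE_REF_HZ)), levels])
    mu, _ = post.latent(X)
    if mu[-1] > 0:  # still detected at the top level: threshold out of range
        return ThresholdResult(level=float(levels[-1]), flag="all-above")
    sign = np.sign(mu)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(mu == 0.0)[0]
    if crossings.size == 0 and exact.size == 0:
        return ThresholdResult(level=float(levels[0]), flag="all-below")
    candidates = []
    if exact.size:
        candidates.append(float(levels[exact[-1]]))
    if crossings.size:
        i = crossings[-1]
        frac = mu[i] / (mu[i] - mu[i + 1])
        candidates.append(float(levels[i] + frac * (levels[i + 1] - levels[i])))
    return ThresholdResult(level=max(candidates))


def estimate_psychometric_slope(
    data: GPDataset,
    hypers: GPHyperparameters,
    bounds: tuple[float, float] = (0.3, 30.0),
) -> tuple[float, bool]:
    """Post-hoc ML-II estimate of the psychometric SD, in dB.

    Rescales the level-to-latent mapping (the linear-kernel divisor) while
    holding everything else fixed and maximizes the approximate marginal
    likelihood.  Returns (sd_db, ok); non-identifiable data (all labels
    identical) yields the prior value with ok=False, and hitting the search
    bounds is also flagged.
    """
    if len(data) == 0:
        raise ValueError("cannot estimate the slope from an empty dataset")
    if np.all(data.y > 0) or np.all(data.y < 0):
        return hypers.psychometric_sd, False

    def neg(log_s: float) -> float:
        s = float(np.exp(log_s))
        h = replace(hypers, level_scale=s, psychometric_sd=s)
        try:
            val, _ = approx_log_marginal(data, h)
        except GPInferenceError:
            return 1e10
        return -val

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    if not res.success or res.fun >= 1e9:
        return hypers.psychometric_sd, False
    s = float(np.exp(res.x))
    at_bound = s < bounds[0] * 1.05 or s > bounds[1] * 0.95
    return s, not at_bound
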