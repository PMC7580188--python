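"""Shared fixtures and brute-force oracles for the test suite."""

import logging

import numpy as np
import pytest
from scipy.special import ndtr

from balnotch.gp_model import GPDataset, GPHyperparameters, build_kernel

logging.getLogger("balnotch").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def hypers():
    return GPHyperparameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_two_point(data: GPDataset, hypers: GPHyperparameters,
                          half_width: float = 80.0, n_grid: int = 1601):
    """Dense 2-D quadrature over the exact posterior of a <=2-point dataset.

    Returns a function mapping query points to (p_yes, latent mean, latent
    variance) under the exact (non-Gaussian) posterior.
    """
    X, y = data.X, data.y
    n = len(y)
    assert n in (1, 2)
    kern = build_kernel(hypers)
    K = kern(X, X) + 1e-10 * np.eye(n)
    Ki = np.linalg.inv(K)
    m = hypers.mean_const
    g = np.linspace(-half_width, half_width, n_grid)
    if n == 1:
        F = g[:, None]
    else:
        F1, F2 = np.meshgrid(g, g, indexing="ij")
        F = np.stack([F1.ravel(), F2.ravel()], axis=-1)
    dev = F - m
    log_prior = -0.5 * np.einsum("...i,ij,...j", dev, Ki, dev)
    floor = np.where(y > 0, hypers.lapse_floor,
                     1.0 - hypers.lapse_floor - hypers.lapse_span)
    lik = np.prod(floor + hypers.lapse_span * ndtr(y * F), axis=-1)
    w = np.exp(log_prior - log_prior.max()) * lik
    W = w.sum()

    def query(xstar):
        xs = np.atleast_2d(np.asarray(xstar, dtype=float))
        kss = float(kern(xs, xs)[0, 0])
        ks = kern(X, xs)[:, 0]
        A = Ki @ ks
        mu_c = m + dev @ A
        var_c = max(kss - float(ks @ Ki @ ks), 0.0)
        p_cond = hypers.lapse_floor + hypers.lapse_span * ndtr(
            mu_c / np.sqrt(1.0 + var_c)
        )
        p = float((w * p_cond).sum() / W)
        mean = float((w * mu_c).sum() / W)
        var = float((w * mu_c**2).sum() / W - mean**2 + var_c)
        return p, mean, var

    return query
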