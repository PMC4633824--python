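"""Exact Polya-Gamma PG(1, z) sampling for logistic data augmentation.

Implements the Devroye alternating-series rejection sampler for the Jacobi
J*(1, z) distribution; PG(1, psi) = J*(1, |psi|/2) / 4. The kernel is
compiled with numba when available (a pure-Python fallback keeps the module
importable without it). Correctness is checked in the test suite against the
closed-form mean E[PG(1,z)] = tanh(z/2) / (2z) and against a Metropolis
reference sampler for the logistic posterior.
"""

from __future__ import annotations

import math

import numpy as np

_T = 0.64  # Devroye left/right split point
_HALF_PI2 = math.pi * math.pi / 8.0


def _pigauss_cdf(x: float, z: float) -> float:
    """CDF at x of inverse-Gaussian(mu=1/z, lambda=1); z=0 is the Levy limit."""
    rx = 1.0 / math.sqrt(x)
    a = rx * (x * z - 1.0)
    b = rx * (x * z + 1.0)
    # Phi via erfc for numerical range
    phi_a = 0.5 * math.erfc(-a / math.sqrt(2.0))
    phi_mb = 0.5 * math.erfc(b / math.sqrt(2.0))
    return phi_a + math.exp(2.0 * z) * phi_mb


def _acoef(n: int, x: float) -> float:
    if x <= _T:
        return (
            math.pi
            * (n + 0.5)
            * math.pow(2.0 / (math.pi * x), 1.5)
            * math.exp(-2.0 * (n + 0.5) * (n + 0.5) / x)
        )
    return (
        math.pi
        * (n + 0.5)
        * math.exp(-(n + 0.5) * (n + 0.5) * math.pi * math.pi * x / 2.0)
    )


def _rtigauss(z: float) -> float:
    """Inverse-Gaussian(1/z, 1) truncated to (0, t)."""
    t = _T
    if z < 1.0 / t:  # large mu: reciprocal-chi proposal
        while True:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.uniform(0.0, 1.0) <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while True:
            y = np.random.standard_normal()
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
                4.0 * mu * y + mu * mu * y * y
            )
            if np.random.uniform(0.0, 1.0) > mu / (mu + x):
                x = mu * mu / x
            if x < t:
                return x


def _jstar(z: float) -> float:
    """One draw from J*(1, z), z >= 0 (Devroye)."""
    k = _HALF_PI2 + 0.5 * z * z
    p = (math.pi / (2.0 * k)) * math.exp(-k * _T)
    q = 2.0 * math.exp(-z) * _pigauss_cdf(_T, z)
    ratio = p / (p + q)
    while True:
        if np.random.uniform(0.0, 1.0) < ratio:
            x = _T + np.random.exponential(1.0) / k
        else:
            x = _rtigauss(z)
        s = _acoef(0, x)
        y = np.random.uniform(0.0, 1.0) * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _acoef(n, x)
                if y <= s:
                    return x
            else:
                s += _acoef(n, x)
                if y > s:
                    break


def _pg_batch(psi: np.ndarray, seed: int) -> np.ndarray:
    np.random.seed(seed)
    out = np.empty(psi.shape[0])
    for i in range(psi.shape[0]):
        out[i] = 0.25 * _jstar(0.5 * abs(psi[i]))
    return out


try:  # compile the kernel; fall back to pure Python if numba is unavailable
    import numba

    _pigauss_cdf = numba.njit(cache=False)(_pigauss_cdf)
    _acoef = numba.njit(cache=False)(_acoef)
    _rtigauss = numba.njit(cache=False)(_rtigauss)
    _jstar = numba.njit(cache=False)(_jstar)
    _pg_batch = numba.njit(cache=False)(_pg_batch)
except ImportError:  # pragma: no cover
    pass


def polya_gamma(psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vector of independent PG(1, psi_i) draws."""
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    seed = int(rng.integers(0, 2**31 - 1))
    return _pg_batch(psi, seed)


def pg_mean(psi: np.ndarray) -> np.ndarray:
    """Closed-form E[PG(1, psi)] = tanh(psi/2)/(2 psi) (1/4 at psi=0)."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 0.25)
    nz = psi != 0
    out[nz] = np.tanh(psi[nz] / 2.0) / (2.0 * psi[nz])
    return out
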