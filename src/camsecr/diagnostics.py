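"""Convergence and model-adequacy diagnostics for the SECR sampler.

Two checks mirror standard practice for SPACECAP-class analyses: the Geweke
z-score comparing early- and late-chain means (|z| > 1.6 taken as evidence
the chain has not converged), and a posterior predictive Bayesian p-value
with a Freeman-Tukey discrepancy on individual-by-trap encounter
frequencies (p near 0 or 1 indicates model inadequacy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .captures import BehaviouralIndicator, CaptureArray
from .statespace import StateSpace

__all__ = ["GewekeResult", "FitResult", "geweke_z", "freeman_tukey",
           "bayesian_pvalue", "GEWEKE_THRESHOLD"]

#: |z| above this is read as "chain has not been run long enough"
GEWEKE_THRESHOLD = 1.6


@dataclass(frozen=True)
class GewekeResult:
    z: float
    frac_early: float
    frac_late: float

    @property
    def converged(self) -> bool:
        return abs(self.z) <= GEWEKE_THRESHOLD


@dataclass(frozen=True)
class FitResult:
    p_value: float
    statistic: str = "freeman_tukey"

    @property
    def adequate(self) -> bool:
        return 0.05 < self.p_value < 0.95


def _batch_mean_se2(x: np.ndarray) -> float:
    """Squared standard error of the mean of x via batch means.

    Uses ceil(sqrt(n)) batches as a simple spectral-density-at-zero
    estimate robust to autocorrelation.
    """
    n = len(x)
    nb = int(math.ceil(math.sqrt(n)))
    bs = n // nb
    if bs < 1:
        return float(np.var(x, ddof=1) / n) if n > 1 else 0.0
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    if nb < 2:
        return float(np.var(x, ddof=1) / n)
    return float(np.var(means, ddof=1) / nb)


def geweke_z(chain, frac_early: float = 0.1, frac_late: float = 0.5) -> GewekeResult:
    """Geweke convergence diagnostic on a single chain.

    Compares the mean of the first ``frac_early`` of the chain with the mean
    of the last ``frac_late``; under convergence the standardised difference
    is approximately standard normal.  Variances of the window means come
    from batch means (ceil(sqrt(n)) batches per window).
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("Geweke diagnostic needs a chain of length >= 100")
    if not 0 < frac_early < 1 or not 0 < frac_late < 1 or frac_early + frac_late > 1:
        raise ValueError("window fractions must be in (0,1) and not overlap")
    n = len(x)
    early = x[: int(frac_early * n)]
    late = x[n - int(frac_late * n):]
    v = _batch_mean_se2(early) + _batch_mean_se2(late)
    diff = early.mean() - late.mean()
    if v <= 0:
        if diff == 0:
            warnings.warn("zero-variance chain: Geweke z defined as 0", stacklevel=2)
            return GewekeResult(0.0, frac_early, frac_late)
        # windows internally constant but at different levels: divergent
        return GewekeResult(math.copysign(math.inf, diff), frac_early, frac_late)
    z = diff / math.sqrt(v)
    return GewekeResult(float(z), frac_early, frac_late)


def freeman_tukey(observed, expected) -> float:
    """Freeman-Tukey discrepancy T = sum (sqrt(obs) - sqrt(exp))^2."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal shape")
    if (obs < 0).any() or (exp < 0).any():
        raise ValueError("counts must be non-negative")
    return float(((np.sqrt(obs) - np.sqrt(exp)) ** 2).sum())


def _expected_counts(lam0: float, sigma: float, b1: float,
                     d: np.ndarray, C: np.ndarray, effort: np.ndarray) -> np.ndarray:
    """E[sum_k y_ijk] given the realised prior-capture indicator C (N,J,K)."""
    g = lam0 * np.exp(-(d ** 2) / (2 * sigma ** 2))
    lam = g[:, :, None] * np.exp(b1 * C)
    p = -np.expm1(-lam)
    return (p * effort[None, :, :]).sum(axis=2)


def _simulate_replicate(lam0, sigma, b1, d, effort, rng) -> np.ndarray:
    from .secr_model import ModelParams, simulate_histories

    return simulate_histories(ModelParams(lam0, sigma, b1), d, effort, rng)


def bayesian_pvalue(
    arr: CaptureArray,
    C: BehaviouralIndicator,
    ss: StateSpace,
    samples,
    seed: int = 0,
) -> FitResult:
    """Posterior predictive check of the fitted SECR model.

    For each retained latent snapshot of the sampler, computes the
    Freeman-Tukey discrepancy between individual-by-trap encounter
    frequencies and their model expectations, for both the observed data
    (with its realised prior-capture indicator) and a replicate data set
    simulated from the same parameters and activity centres (with the
    replicate's own indicator).  Ties count in favour of fit:
    p = Pr(T_rep >= T_obs).
    """
    snapshots = samples.latent
    if not snapshots:
        raise ValueError("sampler was run without latent snapshots")
    rng = np.random.default_rng(seed)
    n, J, K = arr.y.shape
    effort = arr.effort if arr.effort is not None else np.ones((J, K), dtype=np.int8)
    effort = np.asarray(effort, dtype=float)
    Kj = effort.sum(axis=1)
    traps = arr.trap_xy
    pts = ss.suitable_points
    y_obs_counts = (arr.y * effort[None]).sum(axis=2)
    ge = 0
    for snap in snapshots:
        lam0, sigma, b1 = snap["lambda0"], snap["sigma"], snap["b1"]
        z = snap["z"].astype(bool)
        centres = snap["centres"]
        inc = np.flatnonzero(z)
        cxy = pts[centres[inc]]
        d = np.sqrt(((cxy[:, None, :] - traps[None, :, :]) ** 2).sum(-1))
        n_inc_obs = int((inc < n).sum())  # observed are the first n, always z=1

        # observed side: captured histories plus all-zero augmented rows
        e_obs = np.empty_like(d)
        e_obs[:n_inc_obs] = _expected_counts(lam0, sigma, b1, d[:n_inc_obs], C.C, effort)
        g = lam0 * np.exp(-(d[n_inc_obs:] ** 2) / (2 * sigma ** 2))
        e_obs[n_inc_obs:] = -np.expm1(-g) * Kj[None, :]
        obs = np.zeros_like(e_obs)
        obs[:n_inc_obs] = y_obs_counts
        t_obs = freeman_tukey(obs, e_obs)

        y_rep = _simulate_replicate(lam0, sigma, b1, d, effort, rng)
        C_rep = np.zeros_like(y_rep)
        if K > 1:
            C_rep[:, :, 1:] = np.maximum.accumulate(y_rep[:, :, :-1], axis=2)
        e_rep = _expected_counts(lam0, sigma, b1, d, C_rep, effort)
        t_rep = freeman_tukey((y_rep * effort[None]).sum(axis=2), e_rep)
        ge += t_rep >= t_obs
    return FitResult(ge / len(snapshots))
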