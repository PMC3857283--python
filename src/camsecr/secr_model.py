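"""The hierarchical SECR model under Bernoulli encounters and data augmentation.

Model
-----
Each individual i of an augmented super-population of size M carries an
inclusion indicator z_i ~ Bernoulli(psi) and a latent activity centre s_i
uniform over the suitable mesh points of the state space.  Given z_i = 1,
captures are Bernoulli per trap j and occasion k:

    y[i,j,k] ~ Bernoulli( 1 - exp(-lambda_ijk) )
    lambda_ijk = lambda0 * exp(-d(s_i, x_j)^2 / (2 sigma^2)) * exp(b1 * C[i,j,k])

a half-normal encounter-rate function of the centre-to-trap distance d, with
a trap-specific behavioural response: C[i,j,k] = 1 once i has been caught in
trap j, so b1 > 0 means encounter rate rises after first capture in that
trap ("trap-happiness" / model Mb).  Realised abundance is Ns = sum(z) and
density D = Ns / suitable area.

``sigma`` is the primary spatial-scale parameter (km).  Helpers convert to
and from the rate-decay coefficient b of lambda0 * exp(-b d^2); the
conventional relation is sigma = sqrt(1 / (2 b)).  An alternative printed
convention sigma = sqrt(1 / b^2) circulates in some software outputs and is
provided for completeness — see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from scipy.special import betaln, logsumexp

from .captures import BehaviouralIndicator, CaptureArray
from .statespace import StateSpace

__all__ = [
    "ModelParams",
    "Priors",
    "LatentState",
    "encounter_rate",
    "encounter_probability",
    "complete_data_loglik",
    "marginal_loglik_bruteforce",
    "posterior_ns_bruteforce",
    "simulate_histories",
    "sigma_to_b",
    "b_to_sigma",
    "sigma_from_printed_b",
]


@dataclass(frozen=True)
class ModelParams:
    lambda0: float  # baseline encounter rate per occasion at d = 0
    sigma: float    # half-normal spatial scale, km
    b1: float = 0.0  # behavioural log-rate offset
    psi: float = 0.5  # inclusion probability of an augmented individual

    def __post_init__(self):
        if not all(map(math.isfinite, (self.lambda0, self.sigma, self.b1, self.psi))):
            raise ValueError("parameters must be finite")
        if self.lambda0 < 0 or self.sigma <= 0:
            raise ValueError("lambda0 must be >= 0 and sigma > 0")
        if not 0 <= self.psi <= 1:
            raise ValueError("psi must lie in [0, 1]")


def sigma_to_b(sigma: float) -> float:
    """Decay coefficient b of lambda0*exp(-b d^2) for half-normal scale sigma."""
    return 1.0 / (2.0 * sigma ** 2)


def b_to_sigma(b: float) -> float:
    return math.sqrt(1.0 / (2.0 * b))


def sigma_from_printed_b(b: float) -> float:
    """The alternative printed convention sigma = sqrt(1 / b^2) = 1/|b|."""
    return math.sqrt(1.0 / b ** 2)


@dataclass(frozen=True)
class Priors:
    """Prior specifications; vague, proper defaults for SPACECAP-class models.

    log lambda0, log sigma and b1 get independent Normal(mu, sd) priors;
    psi gets Beta(a, b) (the default Beta(1,1) = Uniform(0,1) keeps the
    Gibbs update conjugate).
    """

    log_lambda0: tuple[float, float] = (0.0, 10.0)
    log_sigma: tuple[float, float] = (0.0, 10.0)
    b1: tuple[float, float] = (0.0, 10.0)
    psi_beta: tuple[float, float] = (1.0, 1.0)

    def logpdf(self, params: ModelParams) -> float:
        lp = _stats.norm.logpdf(math.log(params.lambda0), *self.log_lambda0)
        lp += _stats.norm.logpdf(math.log(params.sigma), *self.log_sigma)
        lp += _stats.norm.logpdf(params.b1, *self.b1)
        return float(lp)


@dataclass
class LatentState:
    """Augmented latent variables: inclusion flags and centre indices."""

    z: np.ndarray        # (M,) 0/1
    centres: np.ndarray  # (M,) indices into the suitable-point list

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int8)
        self.centres = np.asarray(self.centres, dtype=np.int64)
        if self.z.shape != self.centres.shape:
            raise ValueError("z and centres must have equal length M")


# ---------------------------------------------------------------------------
# encounter model
# ---------------------------------------------------------------------------

def encounter_rate(params: ModelParams, d, c=0):
    """Expected per-occasion encounter rate at centre-trap distance d (km).

    lambda = lambda0 * exp(-d^2 / (2 sigma^2)) * exp(b1 * c), where c is the
    prior-capture flag of the behavioural response.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    rate = params.lambda0 * np.exp(-(d ** 2) / (2.0 * params.sigma ** 2))
    rate = rate * np.exp(params.b1 * np.asarray(c))
    return rate if rate.ndim else float(rate)


def encounter_probability(params: ModelParams, d, c=0):
    """Per-occasion capture probability p = 1 - exp(-lambda)."""
    p = -np.expm1(-np.asarray(encounter_rate(params, d, c)))
    return p if p.ndim else float(p)


def simulate_histories(
    params: ModelParams, d: np.ndarray, effort: np.ndarray, rng,
    trap_multipliers: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-simulate Bernoulli capture histories with behavioural updating.

    ``d`` is the (N, J) matrix of centre-to-trap distances and ``effort`` the
    (J, K) trap-activity mask.  Occasions are simulated sequentially so the
    prior-capture indicator of each (individual, trap) pair switches on after
    its first capture, exactly as the model assumes.  ``trap_multipliers``
    scales the baseline rate per trap, deliberately *outside* the fitted
    model: it injects trap-level heterogeneity for misspecification probes.
    """
    d = np.asarray(d, dtype=float)
    effort = np.asarray(effort, dtype=float)
    N, J = d.shape
    K = effort.shape[1]
    g = params.lambda0 * np.exp(-(d ** 2) / (2 * params.sigma ** 2))
    if trap_multipliers is not None:
        g = g * np.asarray(trap_multipliers, dtype=float)[None, :]
    p0 = -np.expm1(-g)
    p1 = -np.expm1(-g * math.exp(params.b1))
    y = np.zeros((N, J, K), dtype=np.uint8)
    caught = np.zeros((N, J), dtype=bool)
    for k in range(K):
        p = np.where(caught, p1, p0) * effort[None, :, k]
        y[:, :, k] = rng.random((N, J)) < p
        caught |= y[:, :, k].astype(bool)
    return y


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _loglik_one(params, d, y_jk, C_jk, effort=None):
    """Bernoulli log-likelihood of one individual's history at trap distances d."""
    lam = params.lambda0 * np.exp(-(d[:, None] ** 2) / (2 * params.sigma ** 2))
    lam = lam * np.exp(params.b1 * C_jk)
    with np.errstate(divide="ignore"):
        logp = np.log(-np.expm1(-lam))
    log1mp = -lam
    ll = np.where(y_jk == 1, logp, log1mp)
    if effort is not None:
        ll = ll * effort
    return float(ll.sum())


def complete_data_loglik(
    params: ModelParams,
    latent: LatentState,
    arr: CaptureArray,
    C: BehaviouralIndicator,
    ss: StateSpace,
    effort: np.ndarray | None = None,
) -> float:
    """Joint log-likelihood of all capture histories given the latent state.

    The first ``arr.n_individuals`` members of the augmented population are
    the observed individuals and must have z = 1 (a captured animal cannot
    be excluded: that configuration has likelihood zero and is signalled).
    Excluded members contribute nothing; included uncaptured members
    contribute the probability of an all-zero history from their centre.
    """
    n, J, K = arr.y.shape
    if effort is None:
        effort = arr.effort
    M = len(latent.z)
    if M < n:
        raise ValueError("augmented size M smaller than the number observed")
    if np.any(latent.z[:n] == 0):
        raise ValueError("observed individual with z = 0: likelihood is zero")
    pts = ss.suitable_points
    if latent.centres.max() >= len(pts):
        raise ValueError("centre index outside the suitable mesh")
    # trap coordinates are carried on the array via its builder; distances are
    # recomputed from the state space each call for clarity, not speed
    traps = getattr(arr, "trap_xy", None)
    if traps is None:
        raise ValueError("capture array lacks trap coordinates (set arr.trap_xy)")
    total = 0.0
    zeros_y = np.zeros((J, K), dtype=np.uint8)
    for i in range(M):
        if latent.z[i] == 0:
            continue
        d = np.sqrt(((pts[latent.centres[i]] - traps) ** 2).sum(axis=1))
        if i < n:
            total += _loglik_one(params, d, arr.y[i], C.C[i], effort)
        else:
            total += _loglik_one(params, d, zeros_y, zeros_y, effort)
    return total


def marginal_loglik_bruteforce(
    params: ModelParams, arr: CaptureArray, ss: StateSpace, M: int,
    effort: np.ndarray | None = None,
) -> float:
    """Exact log-marginal likelihood over (z, centres) for tiny instances.

    Marginalises the inclusion indicators with fixed psi and the activity
    centres with their uniform prior over suitable points, by exhaustive
    summation.  Exact-inference oracle: refuses instances beyond M = 8 or
    60 suitable points.
    """
    n, J, K = arr.y.shape
    if effort is None:
        effort = arr.effort
    pts = ss.suitable_points
    P = len(pts)
    if M > 8 or P > 60:
        raise ValueError("instance too large for brute-force marginalisation")
    if M < n:
        raise ValueError("M must be at least the number observed")
    traps = getattr(arr, "trap_xy")
    from .captures import prior_capture_indicator

    C = prior_capture_indicator(arr).C
    zeros = np.zeros((J, K), dtype=np.uint8)
    # per-individual marginal over its centre (sum exp of log-liks / P)
    def centre_marginal(y_jk, C_jk):
        lls = np.array(
            [
                _loglik_one(params, np.sqrt(((p - traps) ** 2).sum(axis=1)), y_jk, C_jk, effort)
                for p in pts
            ]
        )
        return logsumexp(lls) - math.log(P)

    total = 0.0
    for i in range(n):  # observed: z = 1 forced by the data, weight psi
        total += math.log(params.psi) + centre_marginal(arr.y[i], C[i])
    l0 = centre_marginal(zeros, zeros)  # an augmented all-zero history
    per_aug = np.logaddexp(math.log(params.psi) + l0, math.log1p(-params.psi))
    total += (M - n) * per_aug
    return float(total)


def posterior_ns_bruteforce(
    params: ModelParams, arr: CaptureArray, ss: StateSpace, M: int,
    effort: np.ndarray | None = None, integrate_psi: bool = True,
) -> float:
    """Exact posterior mean of Ns = sum(z) for tiny instances.

    With ``integrate_psi`` the Uniform(0,1) prior on psi is integrated
    analytically (a configuration with k included members carries weight
    B(1 + k, 1 + M - k)); otherwise psi is held at ``params.psi``.  Detection
    parameters are held fixed.  Serves as the enumeration oracle for the
    sampler's Ns posterior.
    """
    n, J, K = arr.y.shape
    if effort is None:
        effort = arr.effort
    pts = ss.suitable_points
    P = len(pts)
    if M > 10 or P > 60:
        raise ValueError("instance too large for brute-force enumeration")
    traps = getattr(arr, "trap_xy")
    zeros = np.zeros((J, K), dtype=np.uint8)
    lls = np.array(
        [
            _loglik_one(params, np.sqrt(((p - traps) ** 2).sum(axis=1)), zeros, zeros, effort)
            for p in pts
        ]
    )
    l0 = logsumexp(lls) - math.log(P)  # marginal all-zero-history loglik
    A = M - n
    ks = np.arange(A + 1)
    logw = (
        np.array([math.lgamma(A + 1) - math.lgamma(k + 1) - math.lgamma(A - k + 1) for k in ks])
        + ks * l0
    )
    if integrate_psi:
        logw = logw + betaln(1.0 + n + ks, 1.0 + M - n - ks)
    else:
        logw = logw + (n + ks) * math.log(params.psi) + (M - n - ks) * math.log1p(-params.psi)
    logw -= logsumexp(logw)
    return float(np.sum((n + ks) * np.exp(logw)))
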