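"""Liability-scale Gibbs sampling for the Bayesian threshold animal model.

The ordinal response of record ``i`` is the discretisation of a latent
Gaussian liability ``l_i = x_i' beta + z_i' u + e_i`` at ordered thresholds
``t``; identifiability is fixed by ``t_0 = 0`` and ``var(e_i) = 1``.  Priors:
independent uniforms on each fixed-effect level, ``u ~ N(0, A sigma_u^2)``
with a scaled inverse chi-squared prior on ``sigma_u^2``, and (when the
misclassification layer is on) Dirichlet priors on the origin simplices.

This module exposes the individual full-conditional samplers as plain
Python/NumPy functions — these are the reference implementations used to
validate the compiled chain — plus :func:`run_chain`, the wrapper around the
numba kernel that the model front end calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

from . import _gibbs
from .misclassification import default_tau
from .pedigree import Pedigree, build_a_inverse

__all__ = [
    "PriorSpec",
    "ChainSettings",
    "ChainOutput",
    "category_probability",
    "sample_liability",
    "sample_location_effects",
    "sample_genetic_variance",
    "sample_threshold",
    "run_chain",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the model priors.

    ``beta_min``/``beta_max`` bound the uniform priors on fixed-effect
    levels (defaults effectively flat); ``nu`` and ``s2`` are the degrees of
    belief and scale of the scaled inverse chi-squared prior on the genetic
    variance; ``tau`` the Dirichlet concentrations for the misclassification
    columns (``None`` -> informative no-switch default).
    """

    beta_min: float = -1e6
    beta_max: float = 1e6
    nu: float = 4.0
    s2: float = 0.05
    tau: np.ndarray | None = None

    def __post_init__(self):
        if not self.beta_min < self.beta_max:
            raise ValueError("beta_min must be < beta_max")
        if self.nu <= 0 or self.s2 <= 0:
            raise ValueError("nu and s2 must be positive")
        if self.tau is not None:
            tau = np.asarray(self.tau, dtype=float)
            if (tau <= 0).any():
                raise ValueError("tau entries must be positive")
            object.__setattr__(self, "tau", tau)

    def tau_for(self, n_categories: int) -> np.ndarray:
        return default_tau(n_categories) if self.tau is None else self.tau


@dataclass(frozen=True)
class ChainSettings:
    """Chain length and bookkeeping (burn-in defaults to half the chain)."""

    n_iter: int = 20_000
    burnin: int | None = None
    thin: int = 10
    t_upper: float = 6.0  # fallback upper bound when the top class empties
    # iterations before the misclassification layer activates, letting the
    # location parameters adapt first (guards against an early-chain collapse
    # where a transiently mislocated scale drains a class and the Dirichlet
    # update locks it empty); default: half the burn-in, capped at 1000
    misclass_warmup: int | None = None

    def __post_init__(self):
        if self.burnin is None:
            object.__setattr__(self, "burnin", self.n_iter // 2)
        if not 0 <= self.burnin < self.n_iter:
            raise ValueError("need 0 <= burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.misclass_warmup is None:
            object.__setattr__(self, "misclass_warmup", min(1000, self.burnin // 2))
        if self.misclass_warmup > self.burnin:
            raise ValueError("misclass_warmup must not exceed burnin")

    @property
    def n_retained(self) -> int:
        return -(-(self.n_iter - self.burnin) // self.thin)


def category_probability(eta: float, t, j: int | None = None):
    """Model-implied class probabilities theta_ij at linear predictor eta.

    ``theta_ij = Phi(t_j - eta) - Phi(t_{j-1} - eta)`` with ``t_{-1} = -inf``
    and ``t_{C-1} = +inf``; ``t`` holds the C-1 finite thresholds (t_0 = 0
    first).  Returns the full vector, or entry ``j`` if given.
    """
    t = np.asarray(t, dtype=float)
    edges = np.concatenate(([-np.inf], t, [np.inf]))
    probs = np.diff(stats.norm.cdf(edges - eta))
    return probs if j is None else float(probs[j])


def sample_liability(r_i: int, eta: float, t, rng) -> float:
    """Truncated-normal liability draw on the class interval (t_{r-1}, t_r]."""
    t = np.asarray(t, dtype=float)
    C = len(t) + 1
    lo = -np.inf if r_i == 0 else t[r_i - 1]
    hi = np.inf if r_i == C - 1 else t[r_i]
    return float(stats.truncnorm.rvs(lo - eta, hi - eta, loc=eta, random_state=rng))


def sample_location_effects(l, eta, beta, u, X_levels, animal, a_inv,
                            sigma_u2, prior: PriorSpec, rng):
    """Single-site normal updates of all fixed-effect levels then all u.

    Reference (NumPy) implementation of the mixed-model-equation scan used
    by the compiled kernel: each fixed-effect level is drawn from its normal
    full conditional truncated to the prior bounds, each breeding value from
    its normal full conditional with ``A^{-1}/sigma_u^2`` in the precision.
    ``eta`` is kept current and mutated along with ``beta`` and ``u``.
    """
    lam = 1.0 / sigma_u2
    a_inv = sparse.csr_matrix(a_inv)
    for c in range(len(beta)):
        rows = np.flatnonzero((X_levels == c).any(axis=1))
        if rows.size == 0:
            continue
        mean = np.mean(l[rows] - (eta[rows] - beta[c]))
        sd = 1.0 / np.sqrt(rows.size)
        a, b = (prior.beta_min - mean) / sd, (prior.beta_max - mean) / sd
        new = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
        eta[rows] += new - beta[c]
        beta[c] = new
    for a_ix in range(len(u)):
        rows = np.flatnonzero(animal == a_ix)
        row = a_inv.getrow(a_ix)
        diag = float(row[0, a_ix])
        off = float((row @ u)[0]) - diag * u[a_ix]
        prec = rows.size + lam * diag
        mean = (np.sum(l[rows] - (eta[rows] - u[a_ix])) - lam * off) / prec
        new = rng.normal(mean, 1.0 / np.sqrt(prec))
        eta[rows] += new - u[a_ix]
        u[a_ix] = new
    return beta, u


def sample_genetic_variance(u, a_inv, prior: PriorSpec, rng) -> float:
    """Scaled inverse chi-squared draw: (u'A^{-1}u + nu s2) / chi2_{q + nu}."""
    u = np.asarray(u, dtype=float)
    q = len(u)
    ss = float(u @ (sparse.csr_matrix(a_inv) @ u))
    return (ss + prior.nu * prior.s2) / rng.chisquare(q + prior.nu)


def sample_threshold(l, r, rng, m: int = 1, t=None, t_upper: float = 6.0) -> float:
    """Uniform full-conditional draw of free threshold ``t_m``.

    Support is ``(max{l_i : r_i = m}, min{l_i : r_i = m+1})``; an empty class
    falls back to the neighbouring threshold (or ``t_upper`` at the top).
    """
    l = np.asarray(l, dtype=float)
    r = np.asarray(r)
    t = np.asarray(t, dtype=float) if t is not None else np.array([0.0])
    C = len(t) + 1
    lo = t[m - 1]
    hi = t_upper if m == C - 2 else t[m + 1]
    in_m = l[r == m]
    in_next = l[r == m + 1]
    if in_m.size:
        lo = max(lo, in_m.max())
    if in_next.size:
        hi = min(hi, in_next.min())
    if hi <= lo:
        raise ValueError("inverted threshold interval: liabilities violate classes")
    return float(rng.uniform(lo, hi))


@dataclass
class ChainOutput:
    """Raw accumulators of one Gibbs run."""

    sigma_u2_samples: np.ndarray
    t1_samples: np.ndarray
    u_mean: np.ndarray
    beta_mean: np.ndarray
    pi_mean: np.ndarray
    gamma_mean: np.ndarray
    misclass_prob: np.ndarray
    r_tally: np.ndarray
    n_retained: int
    settings: ChainSettings
    seed: int
    # final state (warm-start support / diagnostics)
    state: dict = field(default_factory=dict)


def run_chain(
    y,
    eff_idx,
    animal,
    n_levels_total: int,
    ped_or_ainv,
    prior: PriorSpec,
    settings: ChainSettings,
    *,
    misclass_enabled: bool = False,
    pi_fixed=None,
    n_categories: int = 3,
    seed: int = 0,
    state: dict | None = None,
) -> ChainOutput:
    """Execute the Gibbs sampler via the compiled kernel.

    ``y`` observed classes, ``eff_idx`` the (n, n_eff) global level index
    matrix, ``animal`` 0-based pedigree indices, ``ped_or_ainv`` either a
    :class:`Pedigree` or a prebuilt sparse A-inverse.  With the layer off the
    true classes are pinned to ``y`` (classical threshold model); with
    ``pi_fixed`` given, the origin columns stay at those values (known-P
    mode) while the indicators are still sampled.  ``state`` warm-starts the
    chain (arrays are updated in place and returned in ``ChainOutput.state``).
    """
    y = np.ascontiguousarray(y, dtype=np.int64)
    eff_idx = np.ascontiguousarray(eff_idx, dtype=np.int64)
    animal = np.ascontiguousarray(animal, dtype=np.int64)
    n = len(y)
    C = n_categories
    if y.min() < 0 or y.max() >= C:
        raise ValueError("observed classes outside 0..C-1")

    if isinstance(ped_or_ainv, Pedigree):
        a_inv = build_a_inverse(ped_or_ainv)
    else:
        a_inv = sparse.csr_matrix(ped_or_ainv)
    q = a_inv.shape[0]

    # records-per-level and records-per-animal CSR maps
    flat_levels = eff_idx.flatten()
    rec_of = np.repeat(np.arange(n), eff_idx.shape[1])
    srt = np.argsort(flat_levels, kind="stable")
    level_rows = rec_of[srt].astype(np.int64)
    level_ptr = np.zeros(n_levels_total + 1, dtype=np.int64)
    np.add.at(level_ptr[1:], flat_levels, 1)
    level_ptr = np.cumsum(level_ptr).astype(np.int64)

    srt_a = np.argsort(animal, kind="stable")
    arec_rows = srt_a.astype(np.int64)
    arec_ptr = np.zeros(q + 1, dtype=np.int64)
    np.add.at(arec_ptr[1:], animal, 1)
    arec_ptr = np.cumsum(arec_ptr).astype(np.int64)

    estimate_pi = misclass_enabled and pi_fixed is None
    tau = np.ascontiguousarray(prior.tau_for(C), dtype=np.float64)
    if misclass_enabled and pi_fixed is not None:
        pi0 = np.ascontiguousarray(pi_fixed, dtype=np.float64)
        if not np.allclose(pi0.sum(axis=1), 1.0):
            raise ValueError("fixed pi rows must sum to 1")
    else:
        pi0 = np.eye(C)

    if state is None:
        state = {
            "l": np.zeros(n),
            "r": y.copy(),
            "beta": np.zeros(n_levels_total),
            "u": np.zeros(q),
            "sigma_u2": np.array([prior.s2]),
            "thr": np.arange(C - 1, dtype=np.float64),
            "pi": pi0.copy(),
        }
    nk = settings.n_retained
    sigma_u2_samples = np.zeros(nk)
    t1_samples = np.zeros(nk)
    u_sum = np.zeros(q)
    beta_sum = np.zeros(n_levels_total)
    pi_sum = np.zeros((C, C))
    gamma_sum = np.zeros((C, C))
    mis_count = np.zeros(n, dtype=np.int64)
    r_tally = np.zeros((n, C), dtype=np.int64)

    keep = _gibbs.run_chain(
        seed & 0x7FFFFFFF,
        settings.n_iter,
        settings.burnin,
        settings.thin,
        y,
        eff_idx,
        animal,
        n_levels_total,
        level_ptr,
        level_rows,
        arec_ptr,
        arec_rows,
        a_inv.indptr.astype(np.int64),
        a_inv.indices.astype(np.int64),
        np.ascontiguousarray(a_inv.data, dtype=np.float64),
        prior.beta_min,
        prior.beta_max,
        float(prior.nu),
        float(prior.s2),
        tau,
        C,
        misclass_enabled,
        estimate_pi,
        settings.misclass_warmup,
        settings.t_upper,
        state["l"],
        state["r"],
        state["beta"],
        state["u"],
        state["sigma_u2"],
        state["thr"],
        state["pi"],
        sigma_u2_samples,
        t1_samples,
        u_sum,
        beta_sum,
        pi_sum,
        gamma_sum,
        mis_count,
        r_tally,
    )
    assert keep == nk
    return ChainOutput(
        sigma_u2_samples=sigma_u2_samples,
        t1_samples=t1_samples,
        u_mean=u_sum / nk,
        beta_mean=beta_sum / nk,
        pi_mean=pi_sum / nk,
        gamma_mean=gamma_sum / nk,
        misclass_prob=mis_count / nk,
        r_tally=r_tally,
        n_retained=nk,
        settings=settings,
        seed=seed,
        state=state,
    )
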