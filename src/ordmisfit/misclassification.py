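"""The misclassification layer: switching indicators and their conjugate updates.

An observed ordinal response ``y_i = k`` is linked to a latent true class
``r_i`` through a switching indicator ``alpha_i``.  The misclassification
matrix is parameterized generatively: ``pi[j, k] = P(recorded as k | true
class j)``, each true class's row a simplex.  The full conditional of
``alpha_i`` is multinomial with weights ``pi_{j, y_i} * theta_{ij}`` over
candidate true classes ``j``, where ``theta_{ij}`` are the model-implied
class probabilities; the rows of ``pi`` are conjugate-updated from
Dirichlet(tau_{j.} + gamma_{j.}) with ``gamma_{jk}`` the current count of
records observed as ``k`` while assigned true class ``j``.

The row-simplex convention is what makes the augmented model a coherent
probability model for ``y`` (``sum_k sum_j pi_{jk} theta_{ij} = 1``).
Treating each *observed* class's origin vector as the simplex instead
leaves the row sums unconstrained, so a chain can inflate the implied
likelihood without bound by routing every record through one true class —
a quasi-absorbing degenerate mode, not a real posterior feature.  The
derived origin probabilities ``P(true j | observed k)`` remain available
through :func:`generative_to_conditional`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MisclassState",
    "default_tau",
    "link_true_class",
    "sample_alpha",
    "count_switches",
    "sample_pi",
    "misclassification_probability",
    "generative_to_conditional",
]


def default_tau(
    n_categories: int = 3, prior_weight: float = 1.0, flat: bool = False
) -> np.ndarray:
    """Dirichlet concentrations for the misclassification rows.

    Default puts informative mass on "no switch": diagonal 90, the remaining
    weight 5 split over the ``C - 1`` miscoding directions, all scaled by
    ``prior_weight``; ``flat=True`` gives Dirichlet(1, ..., 1) instead.
    Identifiability of misclassification rates is fragile without prior mass
    on the no-switch diagonal, hence the informative default.
    """
    C = n_categories
    if flat:
        return np.ones((C, C))
    tau = np.full((C, C), prior_weight * 5.0 / (C - 1))
    np.fill_diagonal(tau, prior_weight * 90.0)
    return tau


@dataclass
class MisclassState:
    """Current misclassification parameters of a chain."""

    pi: np.ndarray  # C x C; row j = P(recorded class . | true class j)
    fixed: bool = False
    tau: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        C = self.pi.shape[0]
        if self.pi.shape != (C, C):
            raise ValueError("pi must be square")
        if (self.pi < 0).any() or (self.pi > 1).any():
            raise ValueError("pi entries must lie in [0, 1]")
        if not np.allclose(self.pi.sum(axis=1), 1.0):
            raise ValueError("each pi row (true class) must sum to 1")
        if self.tau is None:
            self.tau = default_tau(C)
        self.tau = np.asarray(self.tau, dtype=float)
        if (self.tau <= 0).any():
            raise ValueError("tau concentrations must be positive")

    @property
    def n_categories(self) -> int:
        return self.pi.shape[0]


def link_true_class(y_i: int, alpha_i: int) -> int:
    """True class implied by (observed class, switching indicator).

    The indicator is encoded directly as the putative true class, so the
    link is the identity in ``alpha``; ``alpha_i == y_i`` means no switch.
    For ``y_i = 0`` this coincides with the arithmetic form
    ``r = (1 - alpha) y + alpha (1 - y)`` extended over the three indicator
    values 0 (no switch), 1 and 2.
    """
    return alpha_i


def sample_alpha(y_i, theta_i, pi, rng) -> tuple[int, int]:
    """Draw the switching indicator for one record.

    Weights each candidate true class ``j`` by ``pi[j, y_i] * theta_i[j]``
    and samples from the normalized multinomial.  Returns ``(alpha_i, r_i)``
    (identical under the direct encoding).
    """
    pi = pi.pi if isinstance(pi, MisclassState) else np.asarray(pi)
    theta_i = np.asarray(theta_i, dtype=float)
    w = pi[:, y_i] * theta_i
    tot = w.sum()
    if tot <= 0:
        raise ValueError(
            "all switching weights are zero: degenerate pi column for "
            f"observed class {y_i}"
        )
    alpha = int(rng.choice(len(w), p=w / tot))
    return alpha, link_true_class(y_i, alpha)


def count_switches(r, y, n_categories: int | None = None) -> np.ndarray:
    """Switch-count matrix gamma[j, k] = #{i : r_i = j, y_i = k}."""
    r = np.asarray(r, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if r.shape != y.shape:
        raise ValueError("r and y must have equal length")
    C = n_categories or int(max(r.max(), y.max())) + 1
    gamma = np.zeros((C, C), dtype=np.int64)
    np.add.at(gamma, (r, y), 1)
    return gamma


def sample_pi(counts, tau, rng) -> np.ndarray:
    """Conjugate Dirichlet draw of every row: pi_j. ~ Di(tau_j. + gamma_j.)."""
    counts = np.asarray(counts, dtype=float)
    tau = np.asarray(tau, dtype=float)
    C = counts.shape[0]
    pi = np.empty((C, C))
    for j in range(C):
        pi[j] = rng.dirichlet(tau[j] + counts[j])
    return pi


def misclassification_probability(switch_tallies, n_retained: int) -> np.ndarray:
    """Per-record posterior miscoding probability.

    The fraction of retained (post burn-in) iterations in which the record's
    imputed true class differed from its observed class.
    """
    if n_retained <= 0:
        raise ValueError("no retained iterations")
    return np.asarray(switch_tallies, dtype=float) / n_retained


def generative_to_conditional(p_gen, prevalences) -> np.ndarray:
    """Convert a generative misclassification matrix to sampler convention.

    ``p_gen[j, k] = P(observed k | true j)`` (rows sum to 1) combined with
    true-class prevalences gives, by Bayes' rule, the origin simplex of each
    observed class: ``pi[j, k] = p_gen[j, k] prev_j / sum_j' p_gen[j', k]
    prev_j'`` (columns sum to 1).
    """
    p_gen = np.asarray(p_gen, dtype=float)
    prev = np.asarray(prevalences, dtype=float)
    joint = p_gen * prev[:, None]
    return joint / joint.sum(axis=0, keepdims=True)
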