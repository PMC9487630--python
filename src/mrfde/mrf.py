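"""Pairwise-interaction Markov random field over the cell-type network.

For one gene the binary DE/EE vector x over the K cell types has
unnormalized log probability

    log p(x) = gamma * n1 - beta_mrf * n01   (up to a constant),

where n1 is the number of DE cell types, n01 the number of edges whose
endpoints disagree, and gamma the difference of the DE and EE singleton
potentials (only the difference is identifiable, so the EE potential is
fixed at zero).  beta_mrf >= 0 rewards neighbors that share a state.

The full conditional of one node is logistic:

    p(x_k = 1 | rest) = sigmoid(F_k),   F_k = gamma + beta * sum_{k' ~ k} (2 x_{k'} - 1),

which is the form consistent with the joint above (checked exhaustively in
the test suite).  ``sign="anti"`` flips the coupling term's sign, turning
the smoothing prior into an antagonistic one; it exists only for
comparison and is not used by the pipeline.

Parameter estimation maximizes the pseudolikelihood (the product of full
conditionals, i.e. the coding-method surrogate), which is concave in
(gamma, beta).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .data_model import CellTypeNetwork

PHI_BOUNDS = ((-20.0, 20.0), (0.0, 20.0))


@dataclass(frozen=True)
class MRFParams:
    """Singleton potential difference ``gamma`` and edge coupling ``beta`` (>= 0)."""

    gamma: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and np.isfinite(self.beta)):
            raise ValueError(f"non-finite MRF parameters: {self}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


def _as_adj(net) -> np.ndarray:
    if isinstance(net, CellTypeNetwork):
        return net.adjacency()
    A = np.asarray(net, dtype=bool)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or (A != A.T).any() or A.diagonal().any():
        raise ValueError("adjacency must be a symmetric boolean matrix with empty diagonal")
    return A


def mrf_log_joint_unnormalized(x, phi: MRFParams, net) -> float:
    """gamma * n1 - beta * n01 for a single state vector (or rows of a matrix)."""
    A = _as_adj(net)
    x = np.asarray(x, dtype=np.int8)
    n1 = x.sum(axis=-1)
    diff = x[..., :, None] != x[..., None, :]
    n01 = (diff & A).sum(axis=(-2, -1)) / 2
    return phi.gamma * n1 - phi.beta * n01


def local_field(x, phi: MRFParams, net, sign: str = "consistent") -> np.ndarray:
    """F_k = gamma + beta * sum_{k' in N_k} (2 x_{k'} - 1) for every node.

    Works on a single state vector or a genes x K matrix (row-wise).
    """
    A = _as_adj(net)
    x = np.asarray(x, dtype=float)
    s = 1.0 if sign == "consistent" else -1.0 if sign == "anti" else None
    if s is None:
        raise ValueError(f"sign must be 'consistent' or 'anti', got {sign!r}")
    return phi.gamma + s * phi.beta * ((2.0 * x - 1.0) @ A)


def mrf_conditional(x, k: int, phi: MRFParams, net, sign: str = "consistent") -> float:
    """p(x_k = 1 | all other states) = sigmoid(F_k)."""
    F = local_field(x, phi, net, sign=sign)
    return float(expit(F[..., k])) if np.ndim(F) == 1 else expit(F[..., k])


def pseudolikelihood(x, phi: MRFParams, net) -> float:
    """Sum over nodes of log p(x_k | rest); rows of a 2-D ``x`` are summed."""
    A = _as_adj(net)
    x = np.asarray(x, dtype=float)
    F = phi.gamma + phi.beta * ((2.0 * x - 1.0) @ A)
    # log sigmoid((2x-1) F), stably
    return float(-np.logaddexp(0.0, -(2.0 * x - 1.0) * F).sum())


def fit_phi(x, net, bounds=PHI_BOUNDS) -> tuple[MRFParams, bool]:
    """Maximize the pseudolikelihood over (gamma, beta) with box bounds.

    ``x`` may be a single K-vector (per-gene fit) or a matrix of state
    vectors (aggregate fit over many genes sharing one MRF).  The objective
    is concave, so bounded L-BFGS-B with the analytic gradient reaches the
    global box-constrained optimum.  A constant ``x`` (all DE or all EE)
    pins gamma to a boundary; such fits are flagged degenerate.
    """
    A = _as_adj(net)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if (X == X[..., :1]).all():
        # constant states: the optimum sits on the gamma boundary (the
        # logistic tail is flat there, so pin it rather than iterate)
        g = bounds[0][1] if X[0, 0] == 1 else bounds[0][0]
        return MRFParams(float(g), 0.0), True
    sgn = 2.0 * X - 1.0
    nb = sgn @ A  # signed neighbor sums, rows = state vectors

    def neg(p):
        g, b = p
        F = g + b * nb
        z = sgn * F
        ll = -np.logaddexp(0.0, -z).sum()
        r = sgn * expit(-z)  # d ll / dF
        return -ll, -np.array([r.sum(), (r * nb).sum()])

    res = minimize(neg, np.array([0.0, 1.0]), jac=True, method="L-BFGS-B",
                   bounds=list(bounds), options={"ftol": 1e-12, "gtol": 1e-10})
    degenerate = bool((X == X[..., :1]).all())
    return MRFParams(float(res.x[0]), float(res.x[1])), degenerate


def gibbs_sample_states(net, phi: MRFParams, n_genes: int, n_sweeps: int,
                        init_prob: float = 0.5, seed=None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Sample per-gene state vectors by entrywise Gibbs sweeps.

    Each gene runs an independent chain: states start iid
    Bernoulli(init_prob), then ``n_sweeps`` full sweeps update nodes in
    fixed ascending order from the full conditionals.  Returns an
    ``n_genes x K`` int8 matrix.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    A = _as_adj(net)
    K = A.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    X = (rng.random((n_genes, K)) < init_prob).astype(np.int8)
    for _ in range(n_sweeps):
        for k in range(K):
            F = phi.gamma + phi.beta * ((2.0 * X - 1.0) @ A[:, k])
            X[:, k] = rng.random(n_genes) < expit(F)
    return X


def exact_state_distribution(net, phi: MRFParams):
    """Enumerate all 2^K states with their exact probabilities (small K only).

    Returns ``(states, probs)`` with states as a 2^K x K int matrix.  Used
    for validation and small-scale analysis; infeasible beyond K ~ 20.
    """
    A = _as_adj(net)
    K = A.shape[0]
    if K > 20:
        raise ValueError("exact enumeration limited to K <= 20")
    states = np.array(list(product((0, 1), repeat=K)), dtype=np.int8)
    logw = mrf_log_joint_unnormalized(states, phi, A)
    probs = np.exp(logw - logsumexp(logw))
    return states, probs
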