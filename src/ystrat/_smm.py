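"""Single-step stepwise-mutation-model (SMM) transition probabilities and
Felsenstein pruning on an explicit genealogy.

Under the SMM, mutations on a branch of length ``t`` arrive as a Poisson
process with rate ``mu`` and each shifts the repeat count by +/-1 with equal
probability. The net displacement ``k`` after time ``t`` then has probability

    P(k | mu t) = exp(-mu t) * I_|k|(mu t)

with ``I_k`` the modified Bessel function of the first kind (the difference
of two independent Poisson(mu t / 2) counts is a Skellam distribution).
``scipy.special.ive`` evaluates the exponentially scaled Bessel function,
giving the probability directly and stably.

The likelihood of STR data on a fixed genealogy integrates over unobserved
internal repeat counts by pruning over a bounded allele band; the band is
wide enough (``pad`` states beyond the observed range) that truncation error
is far below sampler tolerance for realistic mu*t.
"""
from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz
from scipy.special import ive

__all__ = ["smm_step_probabilities", "smm_transition_matrix",
           "prune_loglik"]


def smm_step_probabilities(theta: float, max_step: int) -> np.ndarray:
    """P(net displacement = k | mu t = theta) for k = 0..max_step."""
    if theta < 0:
        raise ValueError("mu*t must be non-negative")
    k = np.arange(max_step + 1)
    if theta == 0:
        out = np.zeros(max_step + 1)
        out[0] = 1.0
        return out
    return ive(k, theta)


def smm_transition_matrix(theta: float, n_states: int) -> np.ndarray:
    """Symmetric Toeplitz matrix P[i, j] = P(|i-j| net steps | theta)."""
    col = smm_step_probabilities(theta, n_states - 1)
    return toeplitz(col)


def prune_loglik(parent: np.ndarray, time: np.ndarray, tips: np.ndarray,
                 tip_states: np.ndarray, mu: float, n_states: int,
                 root_prior: np.ndarray | None = None) -> float:
    """Log-likelihood of banded STR states on a fixed genealogy.

    ``parent[v]`` is the parent node id (-1 for the root), ``time[v]`` node
    ages in generations, ``tips`` the tip node ids, ``tip_states`` an
    ``(n_tips, n_loci)`` integer matrix of band offsets in ``[0, n_states)``.
    All loci share the genealogy and ``mu``.
    """
    n_nodes = len(parent)
    n_loci = tip_states.shape[1]
    partial = np.zeros((n_nodes, n_states, n_loci))
    logscale = np.zeros((n_nodes, n_loci))      # per-locus scaling
    is_tip = np.zeros(n_nodes, dtype=bool)
    for t_i, v in enumerate(tips):
        is_tip[v] = True
        partial[v, tip_states[t_i], np.arange(n_loci)] = 1.0
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    root = -1
    for v in range(n_nodes):
        if parent[v] == -1:
            root = v
        else:
            children[parent[v]].append(v)
    order = np.argsort(time, kind="stable")
    for v in order:
        if is_tip[v]:
            continue
        acc = None
        for c in children[v]:
            m = smm_transition_matrix(mu * (time[v] - time[c]), n_states)
            vec = m @ partial[c]
            acc = vec if acc is None else acc * vec
            logscale[v] += logscale[c]
        mx = acc.max(axis=0)
        if (mx <= 0).any():
            return -np.inf
        partial[v] = acc / mx
        logscale[v] += np.log(mx)
    prior = (np.full(n_states, 1.0 / n_states) if root_prior is None
             else root_prior)
    locus_l = prior @ partial[root]
    if (locus_l <= 0).any():
        return -np.inf
    return float((np.log(locus_l) + logscale[root]).sum())
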