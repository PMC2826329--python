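"""Phylogenetic signal: independent contrasts, Blomberg's K, permutation null.

A standardized independent contrast at an internal node is the difference
between its two daughter values divided by the square root of the summed
(adjusted) branch lengths; under Brownian motion the contrasts are iid
N(0, sigma^2).  Blomberg's K compares the observed ratio of tip variance
to contrast variance with its Brownian expectation on the same tree; K = 1
under pure Brownian evolution, K < 1 means less signal than Brownian,
K > 1 more.  Significance comes from reshuffling trait values across tips:
a trait with signal yields a much smaller contrast variance than its
reshuffled versions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from phylorecomb.tree import PhyloTree, phylo_covariance, resolve_polytomies

__all__ = [
    "ContrastSet",
    "SignalResult",
    "pic",
    "pic_correlation",
    "blomberg_k",
    "signal_permutation_test",
]


@dataclass
class ContrastSet:
    """Standardized contrasts (one per internal node of a bifurcating tree).

    ``contrasts[k]`` is the k-th standardized contrast; ``variances[k]``
    the corresponding expected variance (sum of adjusted branch lengths)
    before standardization; ``nodes[k]`` the internal node id it came from.
    """

    contrasts: np.ndarray
    variances: np.ndarray
    nodes: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)

    @property
    def variance_of_contrasts(self) -> float:
        """Mean squared standardized contrast (uncentred)."""
        return float(np.mean(self.contrasts ** 2))


@dataclass
class SignalResult:
    k: float
    var_obs: float
    null_vars: np.ndarray
    p_value: float
    n_permutations: int
    seed: Optional[int]
    significant_95: bool
    null_mean: float
    k_null: Optional[np.ndarray] = None
    p_value_k: Optional[float] = None


def _order_trait(tree: PhyloTree, trait) -> np.ndarray:
    """Trait values in the tree's tip order; accepts dict or sequence."""
    tips = tree.tips()
    if isinstance(trait, dict):
        missing = [tree.labels[t] for t in tips if tree.labels[t] not in trait]
        if missing:
            raise KeyError(f"missing trait values for tips: {missing}")
        return np.array([float(trait[tree.labels[t]]) for t in tips])
    x = np.asarray(trait, dtype=float)
    if x.shape[-1] != len(tips):
        raise ValueError("trait length does not match tip count")
    return x


def _pic_matrix(tree: PhyloTree, X: np.ndarray):
    """Felsenstein contrasts for each row of X (shape (k, n_tips)).

    Returns (contrasts (k, n-1), variances (n-1,), node ids (n-1,)).
    The tree must be bifurcating; polytomies should be resolved first.
    """
    if not tree.is_bifurcating():
        raise ValueError("PIC requires a bifurcating tree")
    if not tree.has_branch_lengths():
        raise ValueError("PIC requires branch lengths")
    tips = tree.tips()
    tip_pos = {t: i for i, t in enumerate(tips)}
    k, n = X.shape
    value = np.empty((tree.n_nodes, k))
    blen = np.empty(tree.n_nodes)
    contrasts = np.empty((k, n - 1))
    variances = np.empty(n - 1)
    nodes = np.empty(n - 1, dtype=np.int64)
    ci = 0
    for node in tree.postorder():
        if not tree.children[node]:
            value[node] = X[:, tip_pos[node]]
            blen[node] = tree.branch_length[node]
            continue
        a, b = tree.children[node]
        va, vb = blen[a], blen[b]
        s = va + vb
        if s <= 0:
            raise ValueError(f"zero combined branch length at node {node}")
        contrasts[:, ci] = (value[a] - value[b]) / math.sqrt(s)
        variances[ci] = s
        nodes[ci] = node
        ci += 1
        value[node] = (vb * value[a] + va * value[b]) / s
        bl = tree.branch_length[node]
        blen[node] = (0.0 if np.isnan(bl) else bl) + va * vb / s
    return contrasts, variances, nodes


def pic(tree: PhyloTree, trait) -> ContrastSet:
    """Standardized phylogenetically independent contrasts.

    ``trait`` maps tip labels to values (dict) or lists them in the
    tree's tip order.  Polytomies are resolved into zero-length
    bifurcations (deterministic order) before the post-order pass, so a
    tree with n tips always yields n - 1 contrasts.
    """
    work = tree if tree.is_bifurcating() else resolve_polytomies(tree)
    x = _order_trait(work, trait)
    contrasts, variances, nodes = _pic_matrix(work, x[None, :])
    return ContrastSet(contrasts=contrasts[0], variances=variances, nodes=nodes)


def pic_correlation(cx: ContrastSet, cy: ContrastSet) -> float:
    """Correlation through the origin between two contrast sets."""
    if len(cx) != len(cy) or not np.array_equal(cx.nodes, cy.nodes):
        raise ValueError("contrast sets come from different trees/orders")
    sxx = float(np.sum(cx.contrasts ** 2))
    syy = float(np.sum(cy.contrasts ** 2))
    if sxx == 0 or syy == 0:
        raise ValueError("zero sum of squares in a contrast set")
    return float(np.sum(cx.contrasts * cy.contrasts) / math.sqrt(sxx * syy))


def _k_from_quadratics(x: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K via the GLS quadratic forms (x may be 1-D)."""
    return _k_matrix(x[None, :], V)[0]


def _k_matrix(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """K for each row of X (shape (k, n)) given covariance V."""
    n = V.shape[0]
    cho = linalg.cho_factor(V)
    ones = np.ones(n)
    Vi1 = linalg.cho_solve(cho, ones)
    s1 = float(ones @ Vi1)
    a_hat = (X @ Vi1) / s1                       # (k,)
    Xc = X - a_hat[:, None]
    ViXc = linalg.cho_solve(cho, Xc.T).T
    mse0 = np.sum(Xc * Xc, axis=1) / (n - 1)
    mse = np.sum(Xc * ViXc, axis=1) / (n - 1)
    if np.any(mse0 <= 0):
        raise ValueError("constant trait: K undefined")
    expected = (np.trace(V) - n / s1) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: PhyloTree, trait) -> float:
    """Blomberg's K statistic for one trait on a calibrated tree."""
    x = _order_trait(tree, trait)
    V = phylo_covariance(tree).V
    return float(_k_from_quadratics(x, V))


def signal_permutation_test(
    tree: PhyloTree,
    trait,
    n_perm: int = 999,
    seed: Optional[int] = None,
    exact: bool = False,
) -> SignalResult:
    """Permutation test of phylogenetic signal on contrast variance.

    The observed variance of the standardized contrasts (mean squared
    contrast) is compared with the distribution obtained by reshuffling
    trait values uniformly across tips.  Signal shows as a *small*
    observed variance, so the one-tailed p-value is
    ``(1 + #{null <= observed}) / (1 + n_perm)``.  K is reported
    alongside with its own upper-tail permutation p-value (large K means
    signal); the two p-values use the same reshuffles.

    With ``exact=True`` (small trees only) every assignment of the trait
    vector to the tips is enumerated instead of sampled.
    """
    work = tree if tree.is_bifurcating() else resolve_polytomies(tree)
    x = _order_trait(work, trait)
    n = len(x)
    if np.allclose(x, x[0]):
        raise ValueError("constant trait: no signal test possible")
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        n_perm = len(perms)
    else:
        if n_perm < 99:
            raise ValueError("need at least 99 permutations")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    V = phylo_covariance(work).V
    X = np.vstack([x, x[perms]])
    contrasts, _, _ = _pic_matrix(work, X)
    variances = np.mean(contrasts ** 2, axis=1)
    var_obs, null_vars = float(variances[0]), variances[1:]
    p = (1 + int(np.sum(null_vars <= var_obs))) / (1 + n_perm)

    ks = _k_matrix(X, V)
    k_obs, k_null = float(ks[0]), ks[1:]
    p_k = (1 + int(np.sum(k_null >= k_obs))) / (1 + n_perm)

    return SignalResult(
        k=k_obs,
        var_obs=var_obs,
        null_vars=null_vars,
        p_value=float(p),
        n_permutations=int(n_perm),
        seed=seed,
        significant_95=bool(var_obs < np.quantile(null_vars, 0.05)),
        null_mean=float(np.mean(null_vars)),
        k_null=k_null,
        p_value_k=float(p_k),
    )
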