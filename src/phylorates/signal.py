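"""Phylogenetic signal: Blomberg's K and Pagel's lambda.

K compares the observed ratio of among-species variance to phylogenetically
corrected variance against its Brownian-motion expectation on the same tree;
K = 1 is exactly BM, K < 1 less signal than BM, K > 1 more.  Its significance
comes from a one-sided tip-shuffling permutation test on the variance of
standardized independent contrasts (low contrast variance = signal).

lambda multiplies the off-diagonal entries of the Brownian covariance; the ML
estimate on [0, 1] is compared against the BM model (lambda = 1) with a
likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .bm import _chol_with_jitter, _mvn_profile
from .tree import CalibratedTree, vcv_matrix

__all__ = [
    "ContrastSet",
    "SignalResult",
    "pic",
    "blomberg_k",
    "k_permutation_test",
    "pagel_lambda",
    "lambda_lrt",
]


@dataclass
class ContrastSet:
    """Standardized independent contrasts and their expected variances."""

    contrasts: np.ndarray  # (n-1,) or (n-1, m) for m datasets
    variances: np.ndarray  # (n-1,) expected variance (sum of adjusted lengths)


@dataclass
class SignalResult:
    """Signal estimates for one trait on one pruned tree."""

    trait: str = ""
    group: str = ""
    k: float = np.nan
    p_k: float = np.nan
    lam: float = np.nan
    loglik_lam: float = np.nan
    loglik_lam1: float = np.nan
    p_lam: float = np.nan
    n: int = 0
    n_perm: int = 0
    seed: int = 0
    lam_at_boundary: bool = False


def _align(tree: CalibratedTree, y) -> np.ndarray:
    """Order trait values by the tree's canonical (sorted) tip labels."""
    labels = tree.tip_labels
    if isinstance(y, Mapping):
        return np.array([float(y[lab]) for lab in labels])
    arr = np.asarray(y, dtype=float)
    if arr.shape[0] != len(labels):
        raise ValueError("trait vector length does not match tip count")
    return arr


# ---------------------------------------------------------------------------
# Independent contrasts
# ---------------------------------------------------------------------------


def pic(tree: CalibratedTree, y, jitter: Optional[float] = None) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    Requires a binary tree.  ``y`` may be a 1-D vector (canonical tip order)
    a mapping species → value, or a 2-D array (tips × datasets) — the latter
    computes contrasts for every column at once, which is what the
    permutation test uses.  Zero-length sister branches (from polytomy
    resolution) receive a small jitter (1e-8 × tree depth by default) so
    contrast variances stay positive.
    """
    if not tree.is_binary():
        raise ValueError("pic requires a binary tree; resolve polytomies first")
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    if isinstance(y, Mapping):
        ymat = np.array([float(y[lab]) for lab in labels])[:, None]
        squeeze = True
    else:
        arr = np.asarray(y, dtype=float)
        squeeze = arr.ndim == 1
        ymat = arr[:, None] if squeeze else arr
    if ymat.shape[0] != len(labels):
        raise ValueError("trait array does not match tip count")
    if jitter is None:
        jitter = 1e-8 * max(tree.depths().values())

    value: Dict[str, np.ndarray] = {}
    vlen: Dict[str, float] = {}
    contrasts = []
    variances = []
    for node in tree.root.postorder():
        if node.is_leaf():
            value[node.label] = ymat[index[node.label]].astype(float)
            vlen[node.label] = node.length
            continue
        a, b = node.children
        va, vb = vlen[a.label], vlen[b.label]
        if va + vb <= 0:
            if jitter <= 0:
                raise ValueError(
                    f"zero combined branch variance at node {node.label!r}; "
                    "apply jitter"
                )
            va += jitter
            vb += jitter
        contrasts.append((value[a.label] - value[b.label]) / np.sqrt(va + vb))
        variances.append(va + vb)
        value[node.label] = (value[a.label] * vb + value[b.label] * va) / (va + vb)
        vlen[node.label] = node.length + va * vb / (va + vb)
    out = np.asarray(contrasts)
    if squeeze:
        out = out[:, 0]
    return ContrastSet(out, np.asarray(variances))


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


def blomberg_k(tree: CalibratedTree, y) -> float:
    """Blomberg's K: observed vs BM-expected variance ratio.

    K = (MSE0 / MSE) / [(tr C − n / (1ᵀ C⁻¹ 1)) / (n − 1)] with MSE0 the
    ordinary variance around the phylogenetic (GLS) mean and MSE the
    phylogenetically corrected mean square.
    """
    yv = _align(tree, y)
    n = yv.size
    C = vcv_matrix(tree).values
    from scipy.linalg import cho_solve

    cf = _chol_with_jitter(C)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    ahat = float(one @ cho_solve(cf, yv)) / float(one @ Ci1)
    r = yv - ahat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    if mse == 0:
        return 0.0
    expected = (np.trace(C) - n / float(one @ Ci1)) / (n - 1)
    return float((mse0 / mse) / expected)


def k_permutation_test(
    tree: CalibratedTree, y, n_perm: int = 1000, seed: int = 0
) -> Tuple[float, float]:
    """One-sided tip-shuffling test of phylogenetic signal.

    The statistic is the variance of standardized independent contrasts;
    under signal it is small relative to contrasts of tip-shuffled data.
    Returns (observed contrast variance, p) with
    p = (#{null ≤ observed} + 1) / (n_perm + 1).
    """
    yv = _align(tree, y)
    work = tree
    rng = np.random.default_rng(seed)
    obs = float(np.var(pic(work, yv).contrasts, ddof=1))
    perms = np.empty((yv.size, n_perm))
    for j in range(n_perm):
        perms[:, j] = yv[rng.permutation(yv.size)]
    null_contrasts = pic(work, perms).contrasts
    null = np.var(null_contrasts, axis=0, ddof=1)
    p = (int(np.sum(null <= obs)) + 1) / (n_perm + 1)
    return obs, float(p)


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _loglik_at_lambda(C: np.ndarray, yv: np.ndarray, lam: float) -> float:
    """Profile log-likelihood over (mu, sigma2) at fixed lambda."""
    n = yv.size
    V = _lambda_cov(C, lam)
    mu, quad, logdet = _mvn_profile(V, yv)
    sigma2 = quad / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(
    tree: CalibratedTree, y, lam_max: float = 1.0
) -> Tuple[float, float, float]:
    """ML estimate of lambda on [0, lam_max]; returns (lam, lnL(lam), lnL(1)).

    For each candidate lambda the mean and rate are profiled in closed form,
    so the search is 1-D.  lam_max defaults to 1 (the ultrametric-feasible
    range); values above 1 can be allowed where C(lambda) stays positive
    definite.
    """
    yv = _align(tree, y)
    C = vcv_matrix(tree).values

    def neg(lam: float) -> float:
        try:
            return -_loglik_at_lambda(C, yv, lam)
        except np.linalg.LinAlgError:
            return 1e10

    res = minimize_scalar(neg, bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-8})
    cands = [(float(res.x), -float(res.fun)), (0.0, -neg(0.0)),
             (lam_max, -neg(lam_max))]
    lam_hat, lnl_hat = max(cands, key=lambda c: c[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lnl_1 = _loglik_at_lambda(C, yv, 1.0) if lam_max >= 1.0 else -np.inf
    return lam_hat, lnl_hat, float(lnl_1)


def lambda_lrt(loglik_lam: float, loglik_lam1: float) -> Tuple[float, float]:
    """LRT of lambda-hat against lambda = 1; chisq clipped at 0, df 1."""
    stat = max(0.0, 2.0 * (loglik_lam - loglik_lam1))
    p = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
    return stat, p


def signal_summary(
    tree: CalibratedTree,
    y,
    trait: str = "",
    group: str = "",
    n_perm: int = 1000,
    seed: int = 0,
) -> SignalResult:
    """K with permutation p plus lambda with LRT p, on one pruned tree."""
    yv = _align(tree, y)
    k = blomberg_k(tree, yv)
    _, p_k = k_permutation_test(tree, yv, n_perm=n_perm, seed=seed)
    lam, lnl_lam, lnl_1 = pagel_lambda(tree, yv)
    _, p_lam = lambda_lrt(lnl_lam, lnl_1)
    boundary = lam <= 1e-8 or lam >= 1.0 - 1e-8
    return SignalResult(
        trait=trait, group=group, k=k, p_k=p_k, lam=lam,
        loglik_lam=lnl_lam, loglik_lam1=lnl_1, p_lam=p_lam,
        n=len(tree.tip_labels), n_perm=n_perm, seed=seed,
        lam_at_boundary=boundary,
    )
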