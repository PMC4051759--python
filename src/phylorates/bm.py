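"""Brownian-motion rate estimation: single-rate and state-dependent fits.

The single-rate model is the standard phylogenetic multivariate normal:
y ~ N(mu·1, sigma2·C) with C the shared-path-length covariance of the tree.
The state-dependent ("noncensored") model decomposes C along one stochastic
character map into per-state matrices C_k — shared path time spent in state k
— and fits y ~ N(mu·1, sum_k sigma2_k·C_k) jointly over the per-state rates.
A likelihood-ratio test with df = (#states − 1) contrasts the two, and
profile-likelihood intervals give 95% CIs on each rate.  Fits are averaged
over an ensemble of maps to integrate over ancestral-state uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from .mk import STATES, MapEnsemble, StochasticMap
from .tree import CalibratedTree, PhyloCovariance, vcv_matrix

__all__ = [
    "RateFit",
    "bm_loglik",
    "fit_single_rate",
    "fit_multi_rate",
    "regime_covariances",
    "lrt_single_vs_multi",
    "rate_ci",
    "pool_over_maps",
    "preprocess_trait",
]

_CHI2_95_DF1 = float(chi2.ppf(0.95, 1))  # 3.841...


@dataclass
class RateFit:
    """State-dependent rate fit summary (one trait / one species set)."""

    trait: str = ""
    group: str = ""
    sigma2_by_state: Dict[str, float] = field(default_factory=dict)
    sigma2_single: float = np.nan
    mu: float = np.nan
    loglik_single: float = np.nan
    loglik_multi: float = np.nan
    ci_by_state: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    chisq: float = np.nan
    p: float = np.nan
    n: int = 0
    n_maps: int = 1
    sigma2_sd_by_state: Dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core multivariate-normal machinery
# ---------------------------------------------------------------------------


def _chol_with_jitter(V: np.ndarray):
    """Cholesky factorization, escalating diagonal jitter when singular."""
    base = 1e-10 * float(np.mean(np.diag(V)))
    jitter = 0.0
    for _ in range(8):
        try:
            return cho_factor(V + jitter * np.eye(V.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = base if jitter == 0 else jitter * 10
            warnings.warn(
                f"covariance singular; adding jitter {jitter:.2e}",
                RuntimeWarning,
                stacklevel=3,
            )
    raise np.linalg.LinAlgError("covariance not positive definite after jitter")


def _mvn_profile(V: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """GLS mean, quadratic form and log|V| for covariance V and data y."""
    cf = _chol_with_jitter(V)
    one = np.ones_like(y)
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, one)
    mu = float(one @ Vi_y) / float(one @ Vi_1)
    r = y - mu
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return mu, quad, logdet


def bm_loglik(
    C,
    y: np.ndarray,
    sigma2,
    mu: float,
) -> float:
    """Log-density of y under N(mu·1, V).

    ``C`` is either a single covariance (PhyloCovariance or ndarray) with a
    scalar ``sigma2``, or a mapping state → C_k with ``sigma2`` a mapping
    state → rate (the state-dependent mixture V = sum_k sigma2_k C_k).
    """
    y = np.asarray(y, dtype=float)
    if isinstance(C, Mapping):
        V = sum(float(sigma2[k]) * _as_array(Ck) for k, Ck in C.items())
    else:
        V = float(sigma2) * _as_array(C)
    if V.shape != (y.size, y.size):
        raise ValueError("dimension mismatch between covariance and data")
    cf = _chol_with_jitter(V)
    r = y - mu
    quad = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n = y.size
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _as_array(C) -> np.ndarray:
    if isinstance(C, PhyloCovariance):
        return C.values
    return np.asarray(C, dtype=float)


# ---------------------------------------------------------------------------
# Single-rate fit
# ---------------------------------------------------------------------------


def fit_single_rate(tree_or_C, y) -> Tuple[float, float, float]:
    """ML single-rate BM fit: returns (sigma2_hat, mu_hat, loglik).

    mu_hat is the phylogenetic GLS mean; sigma2_hat uses the ML divisor n.
    A constant trait yields sigma2 = 0 (with a warning) and -inf likelihood
    is avoided by convention: the degenerate model assigns loglik = inf-free
    NaN only when n < 2.
    """
    C = _as_array(
        vcv_matrix(tree_or_C) if isinstance(tree_or_C, CalibratedTree) else tree_or_C
    )
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 taxa")
    mu, quad, logdet = _mvn_profile(C, y)
    sigma2 = quad / n
    if np.ptp(y) == 0 or sigma2 == 0:
        warnings.warn("zero trait variance: sigma2 = 0", RuntimeWarning)
        return 0.0, float(mu), np.nan
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(sigma2), float(mu), float(loglik)


# ---------------------------------------------------------------------------
# Regime covariances and the state-dependent fit
# ---------------------------------------------------------------------------


def regime_covariances(
    smap: StochasticMap, labels: Optional[Sequence[str]] = None
) -> Dict[str, np.ndarray]:
    """Per-state shared-path-time matrices C_k for one stochastic map.

    C_k[i, j] is the time spent in state k on the root→MRCA(i, j) path;
    summed over states the full Brownian covariance C is recovered exactly.
    """
    tree = smap.tree
    if labels is None:
        labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    # cumulative time-in-state from the root to each node
    cum: Dict[str, np.ndarray] = {}
    for node in tree.root.preorder():
        base = (
            np.zeros(len(STATES))
            if node.parent is None
            else cum[node.parent.label].copy()
        )
        for s, d in smap.segments[node.label]:
            base[STATES.index(s)] += d
        cum[node.label] = base

    Cs = {s: np.zeros((n, n)) for s in STATES}
    tipsets: Dict[int, List[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            tipsets[id(node)] = [node.label]
            if node.label in index:
                i = index[node.label]
                for k, s in enumerate(STATES):
                    Cs[s][i, i] = cum[node.label][k]
            continue
        kids = [tipsets[id(c)] for c in node.children]
        here = cum[node.label]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    if la not in index:
                        continue
                    ia = index[la]
                    for lb in kids[b]:
                        if lb not in index:
                            continue
                        ib = index[lb]
                        for k, s in enumerate(STATES):
                            Cs[s][ia, ib] = Cs[s][ib, ia] = here[k]
        tipsets[id(node)] = [t for kk in kids for t in kk]
    return Cs


def fit_multi_rate(
    smap: StochasticMap,
    y,
    labels: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, float], float, float]:
    """Joint ML fit of per-state rates on one map.

    Returns (sigma2 per state, mu_hat, loglik).  The GLS mean is profiled
    out at every rate evaluation; optimization is over log-rates with
    multiple starts around the single-rate estimate to avoid ridge optima.
    """
    tree = smap.tree
    if labels is None:
        labels = tree.tip_labels
    y = np.asarray(y, dtype=float)
    Cs = regime_covariances(smap, labels)
    present = [s for s in STATES if np.trace(Cs[s]) > 0]
    absent = [s for s in STATES if s not in present]
    Ctot = sum(Cs[s] for s in STATES)
    s2_single, mu_single, lnl_single = fit_single_rate(Ctot, y)
    if absent:
        raise ValueError(
            f"state(s) {absent} have zero mapped time on this tree; "
            "the state-dependent rate is not identifiable"
        )
    if s2_single == 0:
        return {s: 0.0 for s in STATES}, mu_single, np.nan

    n = y.size

    def nll(logs: np.ndarray) -> float:
        sig = np.exp(logs)
        V = sig[0] * Cs[STATES[0]] + sig[1] * Cs[STATES[1]]
        try:
            mu, quad, logdet = _mvn_profile(V, y)
        except np.linalg.LinAlgError:
            return 1e10
        return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

    best = None
    x_base = np.log([s2_single, s2_single])
    for factor in (1.0, 0.25, 4.0):
        x0 = x_base + np.log(factor) * np.array([1.0, -1.0])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    sig = np.exp(best.x)
    V = sig[0] * Cs[STATES[0]] + sig[1] * Cs[STATES[1]]
    mu, _, _ = _mvn_profile(V, y)
    loglik = -best.fun
    # numerical safety: the nested single-rate model can never beat us
    if loglik < lnl_single - 1e-6:
        sig = np.array([s2_single, s2_single])
        mu, loglik = mu_single, lnl_single
    return {STATES[0]: float(sig[0]), STATES[1]: float(sig[1])}, float(mu), float(loglik)


def lrt_single_vs_multi(loglik_multi: float, loglik_single: float,
                        df: int = 1) -> Tuple[float, float]:
    """LRT of the state-dependent vs single-rate model; chisq clipped at 0."""
    stat = max(0.0, 2.0 * (loglik_multi - loglik_single))
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, p


_lrt = lrt_single_vs_multi


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _profile_loglik_single(C: np.ndarray, y: np.ndarray, sigma2: float) -> float:
    """lnL at fixed sigma2, mu profiled (closed form for the single rate)."""
    n = y.size
    mu, quad, logdet = _mvn_profile(C, y)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + quad / sigma2)


def rate_ci(
    C_or_map,
    y,
    level: float = 0.95,
    state: Optional[str] = None,
) -> Tuple[float, float]:
    """Profile-likelihood CI for sigma2.

    For a single-rate fit pass a covariance (or tree); for a state-dependent
    fit pass the StochasticMap and the ``state`` whose rate is profiled (the
    other rate and the mean are re-optimized at each profile point).
    """
    y = np.asarray(y, dtype=float)
    crit = float(chi2.ppf(level, 1))
    if isinstance(C_or_map, StochasticMap):
        if state is None:
            raise ValueError("state required when profiling a map fit")
        Cs = regime_covariances(C_or_map)
        sig_hat, _, lmax = fit_multi_rate(C_or_map, y)
        center = sig_hat[state]
        other = [s for s in STATES if s != state][0]
        n = y.size

        def profile(s2: float) -> float:
            def nll(logo: float) -> float:
                V = s2 * Cs[state] + np.exp(logo) * Cs[other]
                try:
                    _, quad, logdet = _mvn_profile(V, y)
                except np.linalg.LinAlgError:
                    return 1e10
                return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

            from scipy.optimize import minimize_scalar

            res = minimize_scalar(
                nll,
                bounds=(np.log(sig_hat[other]) - 12, np.log(sig_hat[other]) + 12),
                method="bounded",
            )
            return -res.fun
    else:
        C = _as_array(
            vcv_matrix(C_or_map) if isinstance(C_or_map, CalibratedTree) else C_or_map
        )
        center, _, lmax = fit_single_rate(C, y)

        def profile(s2: float) -> float:
            return _profile_loglik_single(C, y, s2)

    if center <= 0:
        return (0.0, 0.0)

    def deficit(log_s2: float) -> float:
        return 2.0 * (lmax - profile(np.exp(log_s2))) - crit

    lo = _bracket_root(deficit, np.log(center), direction=-1)
    hi = _bracket_root(deficit, np.log(center), direction=+1)
    return (lo, hi)


def _bracket_root(deficit, log_center: float, direction: int) -> float:
    """Walk out from the optimum until the profile deficit changes sign."""
    step = 0.05 * direction
    x_prev = log_center
    for _ in range(400):
        x = x_prev + step
        if deficit(x) > 0:
            return float(np.exp(brentq(deficit, min(x_prev, x), max(x_prev, x),
                                       xtol=1e-10)))
        x_prev = x
        step *= 1.5
    return float("inf") if direction > 0 else 0.0


# ---------------------------------------------------------------------------
# Pooling across a map ensemble
# ---------------------------------------------------------------------------


def pool_over_maps(
    ensemble: MapEnsemble,
    y,
    labels: Optional[Sequence[str]] = None,
    trait: str = "",
    group: str = "",
    compute_ci: bool = True,
) -> RateFit:
    """Fit every map in the ensemble and average the estimates.

    Reports the across-map mean of per-state rates and log-likelihoods, the
    across-map SD of the rates, the single-rate fit (shared by all maps since
    the total covariance is map-invariant), the LRT on pooled likelihoods,
    and CIs from the pooled (mean-across-maps) profile log-likelihood.
    """
    if len(ensemble) == 0:
        raise ValueError("empty map ensemble")
    tree = ensemble.maps[0].tree
    if labels is None:
        labels = tree.tip_labels
    y = np.asarray(y, dtype=float)

    C = vcv_matrix(tree).values
    s2_single, mu_single, lnl_single = fit_single_rate(C, y)

    per_map: List[Dict[str, float]] = []
    lnls: List[float] = []
    mus: List[float] = []
    failed = 0
    for smap in ensemble.maps:
        try:
            sig, mu, lnl = fit_multi_rate(smap, y, labels)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"map fit failed and was excluded: {exc}", RuntimeWarning)
            failed += 1
            continue
        per_map.append(sig)
        lnls.append(lnl)
        mus.append(mu)
    if not per_map:
        raise RuntimeError("all map fits failed")

    mean_sig = {
        s: float(np.mean([m[s] for m in per_map])) for s in STATES
    }
    sd_sig = {
        s: float(np.std([m[s] for m in per_map], ddof=0)) for s in STATES
    }
    lnl_multi = float(np.mean(lnls))
    chisq, p = _lrt(lnl_multi, lnl_single)

    cis: Dict[str, Tuple[float, float]] = {}
    if compute_ci:
        for s in STATES:
            cis[s] = _pooled_ci(ensemble.maps[: len(per_map)], y, labels, s,
                                mean_sig, lnl_multi)

    return RateFit(
        trait=trait,
        group=group,
        sigma2_by_state=mean_sig,
        sigma2_single=s2_single,
        mu=float(np.mean(mus)),
        loglik_single=lnl_single,
        loglik_multi=lnl_multi,
        ci_by_state=cis,
        chisq=chisq,
        p=p,
        n=int(y.size),
        n_maps=len(per_map),
        sigma2_sd_by_state=sd_sig,
    )


def _pooled_ci(maps, y, labels, state, mean_sig, lnl_max) -> Tuple[float, float]:
    """CI from the across-map mean profile log-likelihood for one rate.

    To stay affordable on large ensembles the profile is averaged over at
    most 10 maps (evenly thinned), with the non-profiled rate re-optimized
    per map at each profile point by a bounded 1-D search.
    """
    from scipy.optimize import minimize_scalar

    thin = max(1, len(maps) // 10)
    use = maps[::thin][:10]
    other = [s for s in STATES if s != state][0]
    n = np.asarray(y).size
    y = np.asarray(y, dtype=float)
    regs = [regime_covariances(m, labels) for m in use]

    def mean_profile(s2: float) -> float:
        tot = 0.0
        for Cs in regs:
            def nll(logo: float) -> float:
                V = s2 * Cs[state] + np.exp(logo) * Cs[other]
                try:
                    _, quad, logdet = _mvn_profile(V, y)
                except np.linalg.LinAlgError:
                    return 1e10
                return 0.5 * (n * np.log(2 * np.pi) + logdet + quad)

            res = minimize_scalar(
                nll,
                bounds=(np.log(mean_sig[other]) - 10, np.log(mean_sig[other]) + 10),
                method="bounded",
                options={"xatol": 1e-6},
            )
            tot += -res.fun
        return tot / len(regs)

    center = mean_sig[state]
    if center <= 0:
        return (0.0, 0.0)
    # recompute the pooled maximum on the thinned profile for consistency
    res = minimize_scalar(
        lambda ls: -mean_profile(np.exp(ls)),
        bounds=(np.log(center) - 4, np.log(center) + 4),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lmax = -res.fun
    center = float(np.exp(res.x))

    def deficit(log_s2: float) -> float:
        return 2.0 * (lmax - mean_profile(np.exp(log_s2))) - _CHI2_95_DF1

    lo = _bracket_root(deficit, np.log(center), -1)
    hi = _bracket_root(deficit, np.log(center), +1)
    return (lo, hi)


# ---------------------------------------------------------------------------
# Trait preprocessing
# ---------------------------------------------------------------------------


def preprocess_trait(values: np.ndarray, transform: str = "auto") -> np.ndarray:
    """Natural-log transform (strictly positive traits) then z-score.

    ``transform``: "auto" logs only when all values are positive, "log"
    forces it (erroring on non-positive values), "none" skips it.  The
    z-score uses the analyzed species set.  Rates are therefore on a
    standardized-trait-variance-per-Myr scale.
    """
    v = np.asarray(values, dtype=float)
    if transform not in ("auto", "log", "none"):
        raise ValueError("transform must be auto|log|none")
    if transform == "log" and np.any(v <= 0):
        raise ValueError("log transform requires strictly positive values")
    if transform == "log" or (transform == "auto" and np.all(v > 0)):
        v = np.log(v)
    sd = v.std(ddof=0)
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd
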