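"""2-state Markov (Mk) fitting and stochastic character mapping.

A continuous-time 2-state Markov model is fitted to a binary character at the
tips (growth form: liana vs tree) by maximum likelihood over Felsenstein's
pruning recursion.  Stochastic character maps — fully timed state histories on
every branch, sampled from the joint posterior given the tips and the fitted
model — are drawn by backward filtering / forward sampling of node states
followed by endpoint-conditioned path sampling (rejection) within branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .tree import CalibratedTree

__all__ = [
    "MkModel",
    "StochasticMap",
    "MapEnsemble",
    "transition_matrix",
    "mk_loglik",
    "fit_mk",
    "sample_stochastic_maps",
    "state_times",
]

STATES = ("liana", "tree")


@dataclass
class MkModel:
    """Fitted 2-state Markov model: rate matrix, root prior, log-likelihood."""

    states: Tuple[str, str] = STATES
    Q: np.ndarray = field(default_factory=lambda: np.array([[-1.0, 1.0], [1.0, -1.0]]))
    prior: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.Q.shape != (2, 2):
            raise ValueError("Q must be 2x2")
        if np.any(self.Q[~np.eye(2, dtype=bool)] < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("Q rows must sum to 0")
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")

    @property
    def rates(self) -> Tuple[float, float]:
        return float(self.Q[0, 1]), float(self.Q[1, 0])


@dataclass
class StochasticMap:
    """One sampled, fully timed state history on a tree.

    ``segments`` maps each node label to the ordered (rootward→tipward) list
    of (state, duration) pieces of the branch above that node; the root entry
    is a single zero-length segment recording the sampled root state.
    """

    tree: CalibratedTree
    segments: Dict[str, List[Tuple[str, float]]]
    log_prob: float = np.nan

    def validate(self, atol: float = 1e-9) -> None:
        for node in self.tree.root.preorder():
            segs = self.segments[node.label]
            total = sum(d for _, d in segs)
            if abs(total - (node.length if node.parent is not None else 0.0)) > atol:
                raise ValueError(f"segments of {node.label!r} do not sum to length")
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                if s1 == s2:
                    raise ValueError(f"adjacent equal-state segments at {node.label!r}")

    def node_state(self, label: str) -> str:
        return self.segments[label][-1][0]


@dataclass
class MapEnsemble:
    """A set of stochastic maps drawn from one fitted model on one tree."""

    maps: List[StochasticMap]
    model: MkModel
    seed: int

    def __len__(self) -> int:
        return len(self.maps)

    def to_jsonl(self) -> str:
        lines = []
        for m in self.maps:
            lines.append(json.dumps({
                lab: [[s, d] for s, d in segs] for lab, segs in m.segments.items()
            }))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str, tree: CalibratedTree, model: MkModel,
                   seed: int = 0) -> "MapEnsemble":
        maps = []
        for line in text.strip().splitlines():
            raw = json.loads(line)
            segs = {lab: [(s, float(d)) for s, d in v] for lab, v in raw.items()}
            maps.append(StochasticMap(tree, segs))
        return cls(maps, model, seed)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) for a 2-state rate matrix, in closed form."""
    a, b = Q[0, 1], Q[1, 0]
    s = a + b
    if s == 0 or t == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array(
        [
            [(b + a * e) / s, (a - a * e) / s],
            [(b - b * e) / s, (a + b * e) / s],
        ]
    )


def _partials(tree: CalibratedTree, tip_states: Mapping[str, str],
              Q: np.ndarray) -> Tuple[Dict[str, np.ndarray], float]:
    """Post-order conditional likelihoods, rescaled; returns log scaler."""
    state_index = {s: i for i, s in enumerate(STATES)}
    partial: Dict[str, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.root.postorder():
        if node.is_leaf():
            if node.label not in tip_states:
                raise ValueError(f"no state for tip {node.label!r}")
            s = tip_states[node.label]
            if s not in state_index:
                raise ValueError(f"unknown state {s!r}")
            vec = np.zeros(2)
            vec[state_index[s]] = 1.0
        else:
            vec = np.ones(2)
            for child in node.children:
                P = transition_matrix(Q, child.length)
                vec = vec * (P @ partial[child.label])
            m = vec.max()
            if m > 0:
                vec = vec / m
                log_scale += np.log(m)
        partial[node.label] = vec
    return partial, log_scale


def mk_loglik(
    tree: CalibratedTree,
    tip_states: Mapping[str, str],
    Q: np.ndarray,
    prior: Optional[np.ndarray] = None,
) -> float:
    """Exact log-likelihood of tip states under the Mk model (pruning)."""
    if prior is None:
        prior = _stationary(Q)
    partial, log_scale = _partials(tree, tip_states, np.asarray(Q, float))
    lik = float(np.dot(prior, partial[tree.root.label]))
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def _stationary(Q: np.ndarray) -> np.ndarray:
    a, b = Q[0, 1], Q[1, 0]
    s = a + b
    if s == 0:
        return np.array([0.5, 0.5])
    return np.array([b / s, a / s])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_mk(
    tree: CalibratedTree,
    tip_states: Mapping[str, str],
    model_form: str = "ER",
) -> MkModel:
    """ML fit of the transition rates; ``model_form`` is "ER" or "ARD".

    The root prior is the stationary distribution of the fitted Q (uniform
    under equal rates).  Both character states must be present among the
    tips, otherwise the rate is not identifiable.
    """
    observed = set(tip_states[t.label] for t in tree.tips)
    if len(observed) < 2:
        raise ValueError(
            "rate not identifiable: only one state observed at the tips"
        )
    depth = max(tree.depths().values())
    lo, hi = 1e-6 / depth, 1e3 / depth

    def q_matrix(rates: Sequence[float]) -> np.ndarray:
        a, b = rates
        return np.array([[-a, a], [b, -b]])

    if model_form == "ER":
        def nll(logq: float) -> float:
            q = np.exp(logq)
            Q = q_matrix((q, q))
            return -mk_loglik(tree, tip_states, Q, _stationary(Q))

        res = minimize_scalar(
            nll, bounds=(np.log(lo), np.log(hi)), method="bounded",
            options={"xatol": 1e-10},
        )
        q = float(np.exp(res.x))
        Q = q_matrix((q, q))
        converged = bool(res.success)
    elif model_form == "ARD":
        # start from the ER optimum
        er = fit_mk(tree, tip_states, "ER")
        x0 = np.log([er.Q[0, 1], er.Q[1, 0]])

        def nll2(x: np.ndarray) -> float:
            Q = q_matrix(np.exp(x))
            return -mk_loglik(tree, tip_states, Q, _stationary(Q))

        res = minimize(
            nll2, x0, method="L-BFGS-B",
            bounds=[(np.log(lo), np.log(hi))] * 2,
        )
        Q = q_matrix(np.exp(res.x))
        converged = bool(res.success)
    else:
        raise ValueError("model_form must be 'ER' or 'ARD'")

    prior = _stationary(Q)
    return MkModel(STATES, Q, prior, mk_loglik(tree, tip_states, Q, prior),
                   converged)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------


def _sample_node_states(tree, tip_states, Q, prior, rng) -> Tuple[Dict[str, int], float]:
    """Joint draw of all node states given tips (backward filter, forward
    sample); returns state indices and the log-probability of the draw."""
    partial, _ = _partials(tree, tip_states, Q)
    state: Dict[str, int] = {}
    logp = 0.0
    for node in tree.root.preorder():
        if node.parent is None:
            w = prior * partial[node.label]
        else:
            P = transition_matrix(Q, node.length)
            w = P[state[node.parent.label]] * partial[node.label]
        w = w / w.sum()
        s = int(rng.random() < w[1])  # inverse-CDF draw on two states
        state[node.label] = s
        logp += np.log(w[s])
    return state, logp


def _sample_branch_path(start: int, end: int, t: float, Q: np.ndarray, rng,
                        max_tries: int = 10_000) -> List[Tuple[int, float]]:
    """Endpoint-conditioned CTMC path by rejection sampling.

    Simulates unconditional paths from ``start`` over duration ``t`` and
    accepts the first whose end state equals ``end``.
    """
    if t == 0:
        if start != end:
            raise RuntimeError("zero-length branch with unequal endpoint states")
        return [(start, 0.0)]
    rates = (Q[0, 1], Q[1, 0])
    for _ in range(max_tries):
        segs: List[Tuple[int, float]] = []
        cur, remaining = start, t
        while True:
            rate = rates[cur]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if wait >= remaining:
                segs.append((cur, remaining))
                break
            segs.append((cur, wait))
            remaining -= wait
            cur = 1 - cur
        if segs[-1][0] == end:
            return segs
    raise RuntimeError(
        "endpoint-conditioned path sampling failed after "
        f"{max_tries} attempts (branch length {t}, rates {rates}); "
        "a larger transition rate or shorter branches are needed"
    )


def sample_stochastic_maps(
    tree: CalibratedTree,
    model: MkModel,
    tip_states: Mapping[str, str],
    n_maps: int = 100,
    seed: int = 0,
) -> MapEnsemble:
    """Draw ``n_maps`` stochastic character maps from the posterior."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    maps: List[StochasticMap] = []
    for _ in range(n_maps):
        node_state, logp = _sample_node_states(
            tree, tip_states, model.Q, model.prior, rng
        )
        segments: Dict[str, List[Tuple[str, float]]] = {}
        for node in tree.root.preorder():
            if node.parent is None:
                segments[node.label] = [(STATES[node_state[node.label]], 0.0)]
                continue
            path = _sample_branch_path(
                node_state[node.parent.label],
                node_state[node.label],
                node.length,
                model.Q,
                rng,
            )
            segments[node.label] = [(STATES[s], d) for s, d in path]
        maps.append(StochasticMap(tree, segments, logp))
    return MapEnsemble(maps, model, seed)


def state_times(smap: StochasticMap) -> Dict[str, Dict[str, float]]:
    """Per-branch time spent in each state; durations sum to branch length."""
    out: Dict[str, Dict[str, float]] = {}
    for lab, segs in smap.segments.items():
        d = {s: 0.0 for s in STATES}
        for s, dur in segs:
            d[s] += dur
        out[lab] = d
    return out


def total_state_times(smap: StochasticMap) -> Dict[str, float]:
    """Whole-tree time in each state (sums branch shares)."""
    totals = {s: 0.0 for s in STATES}
    for shares in state_times(smap).values():
        for s, d in shares.items():
            totals[s] += d
    return totals
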