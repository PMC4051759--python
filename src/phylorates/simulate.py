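"""Synthetic calibrated trees, growth-form histories and trait tables.

The generator emulates the study design the analysis pipeline assumes: a
pooled set of liana and tree species on one ultrametric angiosperm-scale
phylogeny (134 tips, root age of order 10^2 Myr), a binary growth-form
character with phylogenetic structure (2-state Markov evolution), three
continuous ecophysiological traits (A_max, R_d, SLA) evolving by Brownian
motion whose diffusion rate depends on growth form, and per-trait, per-group
missingness so that available sample sizes span the 26–67 range seen in
literature compilations.

Everything is deterministic given (config, seed); the exact simulated state
history is returned alongside the data so downstream estimators can be tested
against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .tree import CalibratedTree, Node, read_newick, write_newick

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_tree",
    "simulate_discrete",
    "simulate_bm_multirate",
    "make_dataset",
    "load_dataset",
    "DEFAULT_RATES",
    "DEFAULT_MISSINGNESS",
]

STATES = ("liana", "tree")
TRAITS = ("Amax", "Rd", "SLA")
SITES = (
    "Gamboa", "SanLorenzo", "Riberalta", "Xishuangbanna",
    "Yakushidake", "Beltsville", "Puyehue",
)

# Per-trait (liana, tree) Brownian rates, trait variance per Myr on the
# standardized scale: R_d-like heterogeneity, SLA-like mild heterogeneity,
# A_max-like homogeneity.
DEFAULT_RATES: Dict[str, Tuple[float, float]] = {
    "Amax": (0.075, 0.075),
    "Rd": (0.148, 0.083),
    "SLA": (0.093, 0.103),
}

# Fractions of cells masked per (trait, group); chosen so the default
# 63-liana / 71-tree dataset yields per-trait group sizes from 26
# (Rd/lianas) to 67 (Amax/trees).
DEFAULT_MISSINGNESS: Dict[str, Dict[str, float]] = {
    "Amax": {"liana": 1 - 51 / 63, "tree": 1 - 67 / 71},
    "Rd": {"liana": 1 - 26 / 63, "tree": 1 - 49 / 71},
    "SLA": {"liana": 1 - 46 / 63, "tree": 1 - 60 / 71},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset generator.

    ``birth_rate`` only sets the pre-rescaling timescale of the pure-birth
    tree; after rescaling to ``root_age`` it has no effect on node depths.
    ``target_counts`` conditions the growth-form simulation on an exact
    (liana, tree) tip split by redrawing the Markov character with seeded
    sub-streams; set to None for unconditioned simulation.
    """

    n_tips: int = 134
    root_age: float = 150.0
    birth_rate: float = 1.0
    q: float = 0.02  # symmetric growth-form transition rate, per Myr
    rates: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_RATES.items()}
    )
    root_values: Dict[str, float] = field(
        default_factory=lambda: {t: 0.0 for t in TRAITS}
    )
    missingness: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            t: dict(g) for t, g in DEFAULT_MISSINGNESS.items()
        }
    )
    target_counts: Optional[Tuple[int, int]] = (63, 71)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.q <= 0 or self.root_age <= 0:
            raise ValueError("rates and root age must be positive")
        for trait, (a, b) in self.rates.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative BM rate for {trait}")
        for trait, groups in self.missingness.items():
            for g, f in groups.items():
                if not 0 <= f < 1:
                    raise ValueError(f"missingness for {trait}/{g} not in [0,1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rates"] = {k: list(v) for k, v in self.rates.items()}
        if self.target_counts is not None:
            d["target_counts"] = list(self.target_counts)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "rates" in d:
            d["rates"] = {k: tuple(v) for k, v in d["rates"].items()}
        if d.get("target_counts") is not None:
            d["target_counts"] = tuple(d["target_counts"])
        return cls(**d)


@dataclass
class SimDataset:
    """A simulated tree + growth forms + traits, with full ground truth."""

    tree: CalibratedTree
    tip_states: Dict[str, str]
    history: Dict[str, List[Tuple[str, float]]]  # node label -> segments
    table: pd.DataFrame
    config: SimConfig
    true_traits: pd.DataFrame  # complete (un-masked) trait values


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(config: SimConfig, rescale: bool = True) -> CalibratedTree:
    """Pure-birth (Yule) tree on ``n_tips``, rescaled so root age matches.

    Lineages split at rate ``birth_rate`` each; inter-event times are
    Exp(k·birth_rate) with k the current lineage count.  After ``n_tips``
    lineages exist, pendant branches are extended to the final time so the
    tree is ultrametric, then all depths are rescaled to ``root_age``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tips
    b = config.birth_rate

    root = Node("nd_root", 0.0)
    # active lineages as (node, birth_time)
    t = 0.0
    active: List[Tuple[Node, float]] = [(root, 0.0)]
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * b))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born if node.parent is not None else 0.0
        left, right = Node(None, 0.0), Node(None, 0.0)
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    # close pendant branches at the final event time + one more waiting time
    t_end = t + rng.exponential(1.0 / (n * b))
    for i, (node, born) in enumerate(active):
        node.length = t_end - born
        node.label = f"sp{i + 1:03d}"

    tree = CalibratedTree(root)
    if rescale:
        factor = config.root_age / tree.root_age
        for node in tree.root.preorder():
            node.length *= factor
    return tree


# ---------------------------------------------------------------------------
# Discrete (growth-form) simulation
# ---------------------------------------------------------------------------


def _evolve_branch(state: str, length: float, q: float, rng) -> List[Tuple[str, float]]:
    """Symmetric 2-state CTMC path along one branch; returns timed segments."""
    segments: List[Tuple[str, float]] = []
    remaining = length
    cur = state
    while True:
        wait = rng.exponential(1.0 / q) if q > 0 else np.inf
        if wait >= remaining:
            segments.append((cur, remaining))
            return segments
        segments.append((cur, wait))
        remaining -= wait
        cur = STATES[1 - STATES.index(cur)]


def simulate_discrete(
    tree: CalibratedTree, q: float, seed: int
) -> Tuple[Dict[str, str], Dict[str, List[Tuple[str, float]]]]:
    """Evolve a symmetric 2-state Markov character down the tree.

    Returns tip states and the exact per-branch segment history (segments
    ordered rootward to tipward; the root carries a single zero-length
    segment recording its state).  Root state is drawn uniformly.
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    rng = np.random.default_rng(seed)
    history: Dict[str, List[Tuple[str, float]]] = {}
    tip_states: Dict[str, str] = {}
    node_state: Dict[str, str] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            state = STATES[int(rng.integers(2))]
            history[node.label] = [(state, 0.0)]
            node_state[node.label] = state
        else:
            segs = _evolve_branch(node_state[node.parent.label], node.length, q, rng)
            history[node.label] = segs
            node_state[node.label] = segs[-1][0]
        if node.is_leaf():
            tip_states[node.label] = node_state[node.label]
    return tip_states, history


def _conditioned_discrete(tree, q, seed, target_counts, max_tries=5000):
    """Redraw the Mk simulation until the (liana, tree) tip split matches."""
    for k in range(max_tries):
        tip_states, history = simulate_discrete(tree, q, seed + 100_000 * (k + 1))
        n_liana = sum(1 for s in tip_states.values() if s == "liana")
        if (n_liana, len(tip_states) - n_liana) == tuple(target_counts):
            return tip_states, history
    raise RuntimeError(
        f"could not match target growth-form counts {target_counts} "
        f"in {max_tries} tries; relax target_counts or change q"
    )


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------


def simulate_bm_multirate(
    tree: CalibratedTree,
    history: Mapping[str, List[Tuple[str, float]]],
    rates: Mapping[str, float],
    root_value: float,
    seed: int,
) -> Dict[str, float]:
    """Brownian motion with state-dependent rate along a segment history.

    Each segment of duration ``d`` in state ``s`` contributes an independent
    Normal(0, rates[s]·d) increment; tip values are the root value plus the
    summed increments along the root-to-tip path.
    """
    rng = np.random.default_rng(seed)
    value: Dict[str, float] = {}
    for node in tree.root.preorder():
        base = root_value if node.parent is None else value[node.parent.label]
        inc = 0.0
        for state, dur in history[node.label]:
            if state not in rates:
                raise KeyError(f"no BM rate for state {state!r}")
            if dur > 0 and rates[state] > 0:
                inc += rng.normal(0.0, np.sqrt(rates[state] * dur))
        value[node.label] = base + inc
    return {t.label: value[t.label] for t in tree.tips}


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def make_dataset(config: SimConfig, outdir: Optional[Path] = None) -> SimDataset:
    """Generate a full synthetic dataset (tree + trait table + truth).

    Missingness masks an exact seeded count of cells per (trait, group):
    ``round(fraction * group size)`` species lose that trait value.  When
    ``outdir`` is given, writes ``tree.nwk``, ``traits.csv`` and
    ``config.yaml`` there.
    """
    tree = simulate_tree(config)
    if config.target_counts is not None:
        tip_states, history = _conditioned_discrete(
            tree, config.q, config.seed + 1, config.target_counts
        )
    else:
        tip_states, history = simulate_discrete(tree, config.q, config.seed + 1)

    species = tree.tip_labels
    true_vals = {}
    for i, trait in enumerate(TRAITS):
        sl, st = config.rates[trait]
        vals = simulate_bm_multirate(
            tree,
            history,
            {"liana": sl, "tree": st},
            config.root_values.get(trait, 0.0),
            config.seed + 10 + i,
        )
        true_vals[trait] = [vals[s] for s in species]
    true_traits = pd.DataFrame(true_vals, index=pd.Index(species, name="species"))

    rng = np.random.default_rng(config.seed + 99)
    sites = rng.choice(len(SITES), size=len(species))
    table = pd.DataFrame(
        {
            "species": species,
            "growth_form": [tip_states[s] for s in species],
            "site": [SITES[i] for i in sites],
        }
    )
    for trait in TRAITS:
        table[trait] = true_traits[trait].to_numpy()

    for trait in TRAITS:
        for group in STATES:
            frac = config.missingness.get(trait, {}).get(group, 0.0)
            idx = np.flatnonzero((table["growth_form"] == group).to_numpy())
            n_miss = int(round(frac * len(idx)))
            if n_miss > 0:
                drop = rng.choice(idx, size=n_miss, replace=False)
                table.loc[drop, trait] = np.nan

    dataset = SimDataset(tree, tip_states, history, table, config, true_traits)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(write_newick(tree) + "\n")
        table.to_csv(outdir / "traits.csv", index=False)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False)
        )
    return dataset


def load_dataset(outdir: Path) -> Tuple[CalibratedTree, pd.DataFrame, SimConfig]:
    """Read back the files written by :func:`make_dataset`."""
    outdir = Path(outdir)
    tree = read_newick((outdir / "tree.nwk").read_text())
    table = pd.read_csv(outdir / "traits.csv")
    config = SimConfig.from_dict(
        yaml.safe_load((outdir / "config.yaml").read_text())
    )
    return tree, table, config
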