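"""Mean pairwise distance and standardized effect sizes (SES_MPD / SES_MTD).

The observed mean pairwise distance of a species group is compared with a
null distribution built by drawing same-sized random groups from the species
pool (equivalent to shuffling species labels across the distance matrix).
z = (obs − null mean) / null SD; the quantile p is the rank of the observed
value in the null, so p > 0.95 indicates evenness (species less related, or
less similar, than chance) and p < 0.05 clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import DistanceMatrix

__all__ = [
    "SESResult",
    "TraitDistanceMatrix",
    "mpd",
    "n_pairs",
    "ses",
    "trait_distance",
]


@dataclass
class TraitDistanceMatrix:
    """Pairwise absolute trait differences (one trait, optionally z-scored)."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SESResult:
    """Observed MPD vs a random-group null: effect size and quantile p."""

    group: str
    metric: str
    obs: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_reps: int
    seed: int
    n_taxa: int
    degenerate: bool = False


def n_pairs(n: int) -> int:
    """Number of unordered species pairs, n(n−1)/2."""
    if n < 2:
        raise ValueError("need at least 2 species")
    return n * (n - 1) // 2


def _matrix_and_labels(dist) -> tuple:
    if isinstance(dist, (DistanceMatrix, TraitDistanceMatrix)):
        return dist.values, list(dist.labels)
    raise TypeError("expected a DistanceMatrix or TraitDistanceMatrix")


def mpd(dist, taxa: Sequence[str]) -> float:
    """Mean of the n(n−1)/2 pairwise distances among ``taxa``."""
    values, labels = _matrix_and_labels(dist)
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("mpd needs at least 2 taxa")
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [t for t in taxa if t not in index]
    if missing:
        raise KeyError(f"taxa not in distance matrix: {missing}")
    idx = np.array([index[t] for t in taxa])
    sub = values[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def ses(
    dist,
    group: Sequence[str],
    pool: Optional[Sequence[str]] = None,
    n_reps: int = 999,
    seed: int = 0,
    metric: str = "MPD",
    group_label: str = "",
) -> SESResult:
    """Standardized effect size of the group's MPD under a random-draw null.

    The null draws |group| labels without replacement from ``pool`` (default:
    all labels in the matrix) ``n_reps`` times and recomputes MPD.  The
    quantile p is (rank of obs among null, ties counted as ≤, + 1) /
    (n_reps + 1), so it can never be exactly 0 or 1.
    """
    values, labels = _matrix_and_labels(dist)
    if pool is None:
        pool = labels
    pool = list(pool)
    group = list(group)
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99 for a stable null")
    if not set(group) <= set(pool):
        raise ValueError("group must be a subset of the pool")
    if set(group) == set(pool):
        raise ValueError(
            "group equals the pool: the randomization null is degenerate"
        )
    index = {lab: i for i, lab in enumerate(labels)}
    pool_idx = np.array([index[t] for t in pool])
    g = len(group)
    obs = mpd(dist, group)

    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    denom = g * (g - 1)
    for r in range(n_reps):
        idx = rng.choice(pool_idx, size=g, replace=False)
        null[r] = values[np.ix_(idx, idx)].sum() / denom

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    degenerate = null_sd == 0
    z = float("nan") if degenerate else (obs - null_mean) / null_sd
    # (rank + 1)/(n_reps + 1), ties counted as <=, capped away from 0 and 1
    p = min(int(np.sum(null <= obs)) + 1, n_reps) / (n_reps + 1)
    return SESResult(
        group=group_label, metric=metric, obs=obs, null_mean=null_mean,
        null_sd=null_sd, z=z, p=float(p), n_reps=n_reps, seed=seed,
        n_taxa=g, degenerate=degenerate,
    )


def trait_distance(values, standardize: bool = True) -> TraitDistanceMatrix:
    """Pairwise absolute differences for one trait.

    ``values`` is a mapping or pandas Series, species → value; species with
    missing values are dropped.  With ``standardize`` (default) values are
    z-scored across the included species first, so the distances are
    invariant to affine rescaling of the raw trait.
    """
    if isinstance(values, pd.Series):
        series = values.astype(float)
    elif isinstance(values, Mapping):
        series = pd.Series({k: float(v) for k, v in values.items()})
    else:
        raise TypeError("values must be a Series or mapping species -> value")
    series = series.dropna()
    if len(series) < 2:
        raise ValueError("need at least 2 species with trait values")
    v = series.to_numpy()
    if standardize:
        sd = v.std(ddof=0)
        v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
    mat = np.abs(v[:, None] - v[None, :])
    return TraitDistanceMatrix(list(series.index), mat)
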