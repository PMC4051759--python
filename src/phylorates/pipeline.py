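"""End-to-end orchestration of the growth-form comparative analysis.

Given a calibrated tree and a species trait table (or a synthetic-data
configuration), the pipeline runs, per ecophysiological trait:

* an Mk fit + stochastic character maps of growth form on the tree pruned to
  species with that trait, then pooled single- vs state-dependent Brownian
  rate fits with profile CIs and a likelihood-ratio test;
* SES of mean pairwise phylogenetic distance for each growth form (on the
  full tree) and SES of mean pairwise trait distance per trait × group;
* Blomberg's K (tip-shuffling permutation test) and Pagel's lambda (LRT
  against lambda = 1) per trait × group on independently pruned trees.

Every statistic is computed by the module that owns it; the orchestrator only
routes data, derives per-stage seeds from the run seed, and writes the
report tables plus a JSON manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bm import pool_over_maps, preprocess_trait
from .community import ses, trait_distance
from .mk import STATES, fit_mk, sample_stochastic_maps
from .signal import signal_summary
from .simulate import SimConfig, make_dataset
from .tree import (
    CalibratedTree,
    bladj_smooth,
    cophenetic_matrix,
    prune_to,
    read_age_constraints,
    read_newick,
    resolve_polytomies,
)

__all__ = ["RunConfig", "AnalysisReport", "run_pipeline", "validate_inputs"]

TRAITS = ("Amax", "Rd", "SLA")


@dataclass
class RunConfig:
    """Inputs and settings for one pipeline run.

    Either the three input paths or ``sim`` must be given.  Defaults for the
    randomization sizes are 999 label-shuffling iterations for SES and 1000
    tip-shuffling permutations for the K test.
    """

    tree_path: Optional[str] = None
    ages_path: Optional[str] = None
    traits_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    n_maps: int = 100
    n_reps: int = 999
    n_perm: int = 1000
    seed: int = 0
    transform: str = "auto"
    outdir: Optional[str] = None
    traits: tuple = TRAITS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        d["traits"] = list(self.traits)
        return d


@dataclass
class AnalysisReport:
    """Tables + provenance from one run."""

    rates: pd.DataFrame
    ses: pd.DataFrame
    signal: pd.DataFrame
    manifest: dict
    log: List[str] = field(default_factory=list)
    failed_stages: List[str] = field(default_factory=list)


def validate_inputs(tree: CalibratedTree, table: pd.DataFrame) -> dict:
    """Cross-check tree tips against the trait table; summarize availability.

    Returns a report dict with species present on only one side, growth-form
    values outside {liana, tree}, and per-trait per-group available counts.
    """
    tips = set(tree.tip_labels)
    species = set(table["species"].astype(str))
    bad_forms = sorted(
        set(table["growth_form"].dropna().astype(str)) - set(STATES)
    )
    counts: Dict[str, Dict[str, int]] = {}
    for trait in (c for c in TRAITS if c in table.columns):
        counts[trait] = {}
        for group in STATES:
            sel = (table["growth_form"] == group) & table[trait].notna()
            counts[trait][group] = int(sel.sum())
    return {
        "tips_not_in_table": sorted(tips - species),
        "species_not_in_tree": sorted(species - tips),
        "bad_growth_forms": bad_forms,
        "n_species": {
            g: int((table["growth_form"] == g).sum()) for g in STATES
        },
        "trait_counts": counts,
    }


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        ds = make_dataset(config.sim)
        return ds.tree, ds.table
    if config.tree_path is None or config.traits_path is None:
        raise ValueError("provide tree_path and traits_path, or a sim config")
    tree = read_newick(Path(config.tree_path).read_text())
    if config.ages_path:
        constraints = read_age_constraints(config.ages_path)
        tree = bladj_smooth(tree, constraints)
    table = pd.read_csv(config.traits_path)
    return tree, table


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Run the full analysis; see the module docstring for the stages."""
    log: List[str] = []
    failed: List[str] = []
    tree, table = _load_inputs(config)
    table = table.copy()
    table["species"] = table["species"].astype(str)

    report = validate_inputs(tree, table)
    if report["tips_not_in_table"] or report["species_not_in_tree"]:
        raise ValueError(
            "species mismatch between tree and table: "
            f"{report['tips_not_in_table'][:5]} / "
            f"{report['species_not_in_tree'][:5]}"
        )
    if report["bad_growth_forms"]:
        raise ValueError(f"unknown growth forms: {report['bad_growth_forms']}")
    log.append(f"loaded {len(tree.tip_labels)} species; counts {report['n_species']}")

    tree = resolve_polytomies(tree, seed=config.seed)
    form = dict(zip(table["species"], table["growth_form"]))
    traits_avail = [t for t in config.traits if t in table.columns]

    # ---- rates (per trait, both groups on one trait-pruned tree) ----------
    rate_rows = []
    for i, trait in enumerate(traits_avail):
        try:
            have = table.loc[table[trait].notna(), "species"].tolist()
            sub = prune_to(tree, have)
            labels = sub.tip_labels
            states = {s: form[s] for s in labels}
            if len(set(states.values())) < 2:
                raise ValueError(f"only one growth form has {trait} values")
            raw = table.set_index("species").loc[labels, trait].to_numpy()
            yv = preprocess_trait(raw, config.transform)
            model = fit_mk(sub, states, "ER")
            ensemble = sample_stochastic_maps(
                sub, model, states, n_maps=config.n_maps,
                seed=config.seed + 1000 + i,
            )
            fit = pool_over_maps(ensemble, yv, labels, trait=trait)
            for group in STATES:
                n_group = sum(1 for s in labels if states[s] == group)
                rate_rows.append({
                    "trait": trait,
                    "group": group,
                    "sigma2": fit.sigma2_by_state[group],
                    "ci_lo": fit.ci_by_state[group][0],
                    "ci_hi": fit.ci_by_state[group][1],
                    "sigma2_single": fit.sigma2_single,
                    "chisq": fit.chisq,
                    "p": fit.p,
                    "n": n_group,
                    "n_total": fit.n,
                    "n_maps": fit.n_maps,
                    "seed": config.seed + 1000 + i,
                })
            log.append(f"rates[{trait}]: q={model.Q[0, 1]:.4g}, "
                       f"chisq={fit.chisq:.3f}, p={fit.p:.3f}")
        except Exception as exc:  # keep the partial report
            failed.append(f"rates:{trait}")
            log.append(f"rates[{trait}] FAILED: {exc}")

    # ---- SES_MPD on the full tree -----------------------------------------
    ses_rows = []
    dist = cophenetic_matrix(tree)
    for j, group in enumerate(STATES):
        try:
            members = [s for s in tree.tip_labels if form[s] == group]
            r = ses(dist, members, n_reps=config.n_reps,
                    seed=config.seed + 2000 + j, metric="MPD",
                    group_label=group)
            ses_rows.append(_ses_row(r))
            log.append(f"SES_MPD[{group}]: obs={r.obs:.1f}, z={r.z:.3f}, p={r.p:.3f}")
        except Exception as exc:
            failed.append(f"ses_mpd:{group}")
            log.append(f"SES_MPD[{group}] FAILED: {exc}")

    # ---- SES_MTD per trait x group ----------------------------------------
    for i, trait in enumerate(traits_avail):
        try:
            avail = table.loc[table[trait].notna()].set_index("species")[trait]
            prepped = pd.Series(
                preprocess_trait(avail.to_numpy(), config.transform),
                index=avail.index,
            )
            tdist = trait_distance(prepped, standardize=False)
            for j, group in enumerate(STATES):
                members = [s for s in tdist.labels if form[s] == group]
                r = ses(tdist, members, n_reps=config.n_reps,
                        seed=config.seed + 3000 + 10 * i + j,
                        metric=f"MTD:{trait}", group_label=group)
                ses_rows.append(_ses_row(r))
                log.append(
                    f"SES_MTD[{trait}/{group}]: z={r.z:.3f}, p={r.p:.3f}"
                )
        except Exception as exc:
            failed.append(f"ses_mtd:{trait}")
            log.append(f"SES_MTD[{trait}] FAILED: {exc}")

    # ---- signal per trait x group -----------------------------------------
    signal_rows = []
    for i, trait in enumerate(traits_avail):
        for j, group in enumerate(STATES):
            try:
                sel = (table["growth_form"] == group) & table[trait].notna()
                species = table.loc[sel, "species"].tolist()
                if len(species) < 4:
                    raise ValueError(f"too few species ({len(species)})")
                sub = prune_to(tree, species)
                raw = table.set_index("species").loc[sub.tip_labels, trait]
                yv = preprocess_trait(raw.to_numpy(), config.transform)
                res = signal_summary(
                    sub, yv, trait=trait, group=group,
                    n_perm=config.n_perm,
                    seed=config.seed + 4000 + 10 * i + j,
                )
                signal_rows.append({
                    "trait": trait, "group": group, "K": res.k,
                    "p_K": res.p_k, "lambda": res.lam, "p_lambda": res.p_lam,
                    "lambda_at_boundary": res.lam_at_boundary,
                    "n": res.n, "n_perm": res.n_perm, "seed": res.seed,
                })
                log.append(
                    f"signal[{trait}/{group}]: K={res.k:.3f} (p={res.p_k:.3f}), "
                    f"lambda={res.lam:.3f} (p={res.p_lam:.3f}), n={res.n}"
                )
            except Exception as exc:
                failed.append(f"signal:{trait}:{group}")
                log.append(f"signal[{trait}/{group}] FAILED: {exc}")

    rates_df = pd.DataFrame(rate_rows)
    ses_df = pd.DataFrame(ses_rows)
    signal_df = pd.DataFrame(signal_rows)
    manifest = {
        "package": "phylorates",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "n_species": report["n_species"],
        "trait_counts": report["trait_counts"],
        "failed_stages": failed,
    }
    out = AnalysisReport(rates_df, ses_df, signal_df, manifest, log, failed)
    if config.outdir:
        _write_report(out, Path(config.outdir))
    return out


def _ses_row(r) -> dict:
    return {
        "group": r.group, "metric": r.metric, "obs": r.obs,
        "null_mean": r.null_mean, "null_sd": r.null_sd, "z": r.z, "p": r.p,
        "n_taxa": r.n_taxa, "n_reps": r.n_reps, "seed": r.seed,
    }


def _write_report(report: AnalysisReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.rates.to_csv(outdir / "rates.csv", index=False)
    report.ses.to_csv(outdir / "ses.csv", index=False)
    report.signal.to_csv(outdir / "signal.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=_json_default) + "\n"
    )
    (outdir / "run.log").write_text("\n".join(report.log) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
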