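"""End-to-end per-clade and cross-clade workflows.

``run_clade`` takes one tree + karyotype table through the full protocol:
match → unit-depth rescale → MCMC under the exponential prior → sensitivity
MCMC under the uniform prior → ML fits of the full and dysploidy-only models →
ΔAIC classification → posterior predictive adequacy check. ``run_global``
aggregates per-clade medians into a rate table and runs the fold range,
geometric means, variance decomposition at both label levels, and optional
PGLS per covariate.

Stages are decoupled by files (CSV/JSON): each clade can run independently and
the global stage is re-runnable from the per-clade outputs alone. Every output
directory contains the fully resolved config and all seeds, so a rerun from
that directory reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adequacy import posterior_predictive_check
from .comparative import fold_range, geometric_means, pgls, variance_decomposition
from .likelihood import RootPolicy
from .mcmc import MCMCConfig, PosteriorSample, PriorSpec, dysploidy_rate_per_myr, run_mcmc
from .model import build_state_space
from .selection import DYSPLOIDY_ONLY, FULL, compare_polyploidy_support, fit_ml
from .trees import TimeTree, match_tree_data, read_karyotypes, read_tree, scale_to_unit_depth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_clade", "run_global"]


@dataclass
class RunConfig:
    """Resolved settings for one clade run; every field but the paths has a default."""

    tree_path: str = ""
    counts_path: str = ""
    out_dir: str = "karyotempo_out"
    clade_name: str = "clade"
    depth_myr: float | None = None  # override; default: depth read from the tree
    missing_policy: str = "drop"
    padding_factor: float = 2.0
    root_mode: str = "fitzjohn"
    prior_mean: float = 1.0
    uniform_hi: float = 100.0
    n_steps: int = 1000
    burn_in_frac: float = 0.25
    proposal_sd: float = 0.3
    ess_threshold: float = 200.0
    n_starts: int = 5
    delta_aic_threshold: float = 5.0
    n_ppc_replicates: int = 200
    seed: int = 0
    run_uniform_sensitivity: bool = True

    def to_yaml(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def run_clade(
    config: RunConfig,
    *,
    tree: TimeTree | None = None,
    karyotypes: pd.DataFrame | None = None,
) -> dict:
    """Full single-clade analysis; returns the report dict and writes outputs.

    ``tree``/``karyotypes`` may be passed in-memory (e.g. from the simulators);
    otherwise they are read from the configured paths. If ``tree_path`` is a
    directory, the analysis loops over every ``.nwk``/``.tre`` file in it
    (tree-set mode) and a pooled summary of the per-tree rate medians is added.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    if tree is None and Path(config.tree_path).is_dir():
        return _run_tree_set(config)

    t0 = time.time()
    if tree is None:
        tree = read_tree(config.tree_path)
    if karyotypes is None:
        karyotypes = read_karyotypes(config.counts_path)
    if config.depth_myr is not None:
        tree.depth_myr = float(config.depth_myr)

    matched_tree, matched_counts = match_tree_data(tree, karyotypes, config.missing_policy)
    unit_tree, depth_myr = scale_to_unit_depth(matched_tree)
    space = build_state_space(matched_counts, config.padding_factor)
    root = RootPolicy(mode=config.root_mode)
    cfg = MCMCConfig(
        n_steps=config.n_steps,
        burn_in_frac=config.burn_in_frac,
        proposal_sd=config.proposal_sd,
        seed=config.seed,
        ess_threshold=config.ess_threshold,
    )

    stage = "mcmc_exponential"
    try:
        post_exp = run_mcmc(
            unit_tree, matched_counts, FULL,
            PriorSpec.exponential(config.prior_mean), cfg, root=root, space=space,
        )
        post_exp.to_frame().to_csv(out / "posterior_exponential.csv", index=False)

        post_uni: PosteriorSample | None = None
        if config.run_uniform_sensitivity:
            stage = "mcmc_uniform"
            post_uni = run_mcmc(
                unit_tree, matched_counts, FULL,
                PriorSpec.uniform(0.0, config.uniform_hi), cfg, root=root, space=space,
            )
            post_uni.to_frame().to_csv(out / "posterior_uniform.csv", index=False)

        stage = "ml_fits"
        fit_full = fit_ml(unit_tree, matched_counts, FULL, config.n_starts, config.seed,
                          root=root, space=space)
        fit_red = fit_ml(unit_tree, matched_counts, DYSPLOIDY_ONLY, config.n_starts,
                         config.seed, root=root, space=space)
        comparison = compare_polyploidy_support(fit_full, fit_red, config.delta_aic_threshold)

        stage = "adequacy"
        adequacy = posterior_predictive_check(
            unit_tree, matched_counts, post_exp, root,
            n_replicates=min(config.n_ppc_replicates, post_exp.n_draws),
            seed=config.seed, space=space,
        )
    except Exception as exc:
        raise RuntimeError(f"clade {config.clade_name!r} failed at stage {stage}: {exc}") from exc

    _, rate_median = dysploidy_rate_per_myr(post_exp, depth_myr)
    report = {
        "clade": config.clade_name,
        "version": __version__,
        "seed": config.seed,
        "n_tips": unit_tree.n_tips,
        "depth_myr": depth_myr,
        "state_space": {"n_min": space.n_min, "n_max": space.n_max},
        "dysploidy_rate_myr_median": rate_median,
        "posterior_median_rates_unit_tree": post_exp.median_params().to_dict(),
        "acceptance_rate": post_exp.acceptance_rate,
        "ess": post_exp.ess,
        "ess_pass": post_exp.ess_pass,
        "uniform_prior_rate_myr_median": (
            dysploidy_rate_per_myr(post_uni, depth_myr)[1] if post_uni is not None else None
        ),
        "logL_full": fit_full.log_lik,
        "logL_reduced": fit_red.log_lik,
        "aic_full": fit_full.aic,
        "aic_reduced": fit_red.aic,
        "delta_aic": comparison["delta_aic"],
        "strong_support_polyploidy": comparison["strong_support"],
        "best_model": comparison["best_model"],
        "ppc": adequacy.to_dict(),
        "wall_time_s": round(time.time() - t0, 3),
    }
    _write_json(report, out / "report.json")
    pd.DataFrame(adequacy.predictive).to_csv(out / "ppc_replicates.csv", index=False)
    logger.info("clade %s done in %.1fs", config.clade_name, report["wall_time_s"])
    return report


def _run_tree_set(config: RunConfig) -> dict:
    """Repeat the clade analysis over a directory of trees; pool the medians."""
    tree_files = sorted(
        p for p in Path(config.tree_path).iterdir() if p.suffix in {".nwk", ".tre", ".newick"}
    )
    if not tree_files:
        raise FileNotFoundError(f"no newick files in {config.tree_path}")
    out = Path(config.out_dir)
    reports = []
    for i, tf in enumerate(tree_files):
        sub = dataclasses.replace(
            config,
            tree_path=str(tf),
            out_dir=str(out / f"tree_{i:03d}"),
            clade_name=f"{config.clade_name}[{tf.name}]",
        )
        reports.append(run_clade(sub))
    medians = [r["dysploidy_rate_myr_median"] for r in reports]
    pooled = {
        "clade": config.clade_name,
        "mode": "tree_set",
        "n_trees": len(reports),
        "per_tree_rate_myr_medians": medians,
        "pooled_median": float(np.median(medians)),
        "pooled_spread": float(np.ptp(medians)),
        "reports": reports,
    }
    _write_json(pooled, out / "tree_set_report.json")
    return pooled


def run_global(
    clade_table: pd.DataFrame,
    *,
    backbone_tree: TimeTree | None = None,
    covariates: list[str] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    out_dir: str | None = None,
) -> dict:
    """Cross-clade analysis of a per-clade rate table.

    The table needs columns ``clade, rate_myr, kingdom, higher_taxon`` and may
    carry covariate columns for PGLS (which also requires a backbone tree whose
    tips are the clade names). Variance decomposition runs at both label
    levels; a level with fewer than two distinct labels is reported as refused
    rather than failing the whole stage.
    """
    required = {"clade", "rate_myr", "kingdom", "higher_taxon"}
    missing = required - set(clade_table.columns)
    if missing:
        raise ValueError(f"clade table missing columns: {sorted(missing)}")
    unlabeled = clade_table.loc[
        clade_table["kingdom"].isna() | clade_table["higher_taxon"].isna(), "clade"
    ].tolist()
    if unlabeled:
        raise ValueError(f"clades without labels: {unlabeled[:5]}")
    if len(clade_table) < 2:
        raise ValueError("need >= 2 clades")

    report: dict = {
        "n_clades": int(len(clade_table)),
        "fold_range": fold_range(clade_table),
        "geometric_mean_rate_by_kingdom": geometric_means(clade_table, "kingdom").to_dict(),
        "decomposition": {},
        "pgls": {},
        "seed": seed,
    }
    for level in ("kingdom", "higher_taxon"):
        n_groups = clade_table[level].nunique()
        if n_groups < 2 or len(clade_table) - n_groups < 1:
            report["decomposition"][level] = {
                "refused": f"insufficient groups at level {level!r} "
                           "(need >= 2 groups and >= 1 residual df)"
            }
            continue
        vd = variance_decomposition(clade_table, level, n_perm=n_perm, seed=seed)
        report["decomposition"][level] = vd.to_dict()

    if covariates:
        if backbone_tree is None:
            raise ValueError("PGLS requires a backbone tree across clades")
        logged = clade_table.set_index("clade")
        y = np.log10(logged["rate_myr"])
        for cov in covariates:
            x = logged[cov]
            # genome size is a multiplicative quantity; log it like the rates
            if cov == "genome_size":
                x = np.log10(x)
            res = pgls(y, x, backbone_tree)
            report["pgls"][cov] = dataclasses.asdict(res)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(report, out / "global_report.json")
        clade_table.to_csv(out / "clade_rates.csv", index=False)
    return report
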