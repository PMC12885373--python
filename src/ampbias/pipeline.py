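"""End-to-end pipeline: simulate -> fit -> bias -> sweep -> optimize grouping.

Every stage writes its artifacts under the configured output directory and
registers them in a manifest (``manifest.json``) that records the seed, a
hash of the configuration and a hash of every artifact, so a rerun with the
same configuration is verifiably byte-identical.  A failure in any stage is
re-raised as :class:`StageError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import posterior_bias
from .compositions import phi_inverse
from .diversity import ALPHA_METRICS, BETA_METRICS, TreeIndex, alpha_diversity, distance_matrix, read_newick
from .grouping import optimize_grouping
from .inference import extract_alpha_beta, fit_mln, summarize_posterior
from .io import (
    design_from_metadata,
    read_count_table,
    read_metadata,
    write_count_table,
    write_metadata,
    write_posterior_archive,
    write_truth,
)
from .compositions import make_contrast_matrix
from .diversity import write_newick
from .sweep import sweep_alpha
from .synthetic import efficiencies_to_beta, mock_community_study

__all__ = ["RunConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run; unknown keys are rejected."""

    seed: int = 0
    n_taxa: int = 10
    n_communities: int = 10
    cycles: tuple[int, ...] = (20, 28, 35)
    depth: int = 10_000
    sigma_scale: float = 0.1
    efficiency_spread: float = 0.3
    alpha_scale: float = 1.5
    n_draws: int = 500
    x_eval: float = 35.0
    alpha_metrics: tuple[str, ...] = ALPHA_METRICS
    beta_metrics: tuple[str, ...] = BETA_METRICS
    grouping_metric: str = "shannon"
    grouping_beta_metric: str = "bray_curtis"
    grouping_method: str = "ga"
    min_group_size: int = 2
    sweep_step: float = 0.02
    sweep_floor: float = 1e-6
    outdir: str = "results"
    # optional external inputs: when set, the simulate stage is skipped
    counts_file: str | None = None
    metadata_file: str | None = None
    tree_file: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("cycles", "alpha_metrics", "beta_metrics"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict, verbose: bool = False) -> dict:
    """Run all stages; returns the artifact manifest (also written to disk)."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def log(msg: str) -> None:
        if verbose:
            print(msg)

    # ---- stage: simulate / load -----------------------------------------
    stage = "simulate" if config.counts_file is None else "load"
    try:
        if config.counts_file is None:
            study = mock_community_study(
                seed=config.seed,
                n_taxa=config.n_taxa,
                n_communities=config.n_communities,
                cycles=config.cycles,
                depth=config.depth,
                sigma_scale=config.sigma_scale,
                efficiency_spread=config.efficiency_spread,
                alpha_scale=config.alpha_scale,
            )
            write_count_table(study.counts, out / "counts.tsv")
            write_metadata(study.metadata, out / "metadata.tsv")
            write_newick(study.tree, out / "tree.nwk")
            write_truth(study.truth, out / "truth.json", covariate_names=study.design.covariate_names)
            artifacts += [out / "counts.tsv", out / "metadata.tsv", out / "tree.nwk", out / "truth.json"]
            counts, tree = study.counts, study.tree
            meta = study.metadata
        else:
            counts = read_count_table(config.counts_file)
            meta = read_metadata(config.metadata_file)
            tree = read_newick(config.tree_file) if config.tree_file else None
        design = design_from_metadata(meta, counts.sample_ids)
        log(f"{stage}: {counts.D} taxa x {counts.N} samples, {len(design.communities)} communities")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: fit ------------------------------------------------------
    try:
        psi = make_contrast_matrix("alr", counts.D)
        draws = fit_mln(counts, design, psi=psi, n_draws=config.n_draws, seed=config.seed)
        summary = summarize_posterior(draws)
        summary.to_csv(out / "posterior_summary.csv", index=False, float_format="%.10g")
        write_posterior_archive(draws, out / "posterior.npz")
        artifacts += [out / "posterior_summary.csv", out / "posterior.npz"]
        log(f"fit: {draws.S} joint posterior draws")
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc

    # ---- stage: bias -----------------------------------------------------
    try:
        tidy = []
        tree_index = TreeIndex(tree, counts.taxon_ids) if tree is not None else None
        for community in draws.communities:
            for metric in config.alpha_metrics:
                res = posterior_bias(draws, community, metric, x=config.x_eval)
                tidy.append(
                    {
                        "community": community,
                        "metric": metric,
                        "cycles": config.x_eval,
                        "median": res.median,
                        "lo95": res.lo95,
                        "hi95": res.hi95,
                    }
                )
        for c1, c2 in combinations(draws.communities, 2):
            for metric in config.beta_metrics:
                if metric == "weighted_unifrac" and tree_index is None:
                    continue
                res = posterior_bias(draws, (c1, c2), metric, x=config.x_eval, tree=tree_index)
                tidy.append(
                    {
                        "community": f"{c1}|{c2}",
                        "metric": metric,
                        "cycles": config.x_eval,
                        "median": res.median,
                        "lo95": res.lo95,
                        "hi95": res.hi95,
                    }
                )
        pd.DataFrame(tidy).to_csv(out / "bias_summary.csv", index=False, float_format="%.10g")
        artifacts.append(out / "bias_summary.csv")
        log(f"bias: {len(tidy)} estimand summaries")
    except Exception as exc:
        raise StageError("bias", str(exc)) from exc

    # ---- stage: sweep ----------------------------------------------------
    try:
        psi3 = make_contrast_matrix("alr", 3)
        scenarios = {
            # preferentially amplify taxon 1 vs the rest / the rest vs taxon 1
            "amplify_taxon1": efficiencies_to_beta(np.array([2.0, 1.8, 1.8]), psi3),
            "amplify_taxa23": efficiencies_to_beta(np.array([1.7, 2.0, 2.0]), psi3),
        }
        for name, beta3 in scenarios.items():
            surf = sweep_alpha(
                "shannon", beta3, x=config.x_eval, step=config.sweep_step, floor=config.sweep_floor
            )
            surf.to_csv(out / f"sweep_shannon_{name}.csv")
            artifacts.append(out / f"sweep_shannon_{name}.csv")
        log(f"sweep: {len(scenarios)} shannon surfaces at step {config.sweep_step}")
    except Exception as exc:
        raise StageError("sweep", str(exc)) from exc

    # ---- stage: grouping -------------------------------------------------
    try:
        communities = draws.communities
        a_draws = {c: extract_alpha_beta(draws, c) for c in communities}
        val0, val35 = [], []
        comp0, comp35 = [], []
        for c in communities:
            alpha_d, beta_d = a_draws[c]
            f0 = [alpha_diversity(phi_inverse(a, draws.psi), config.grouping_metric) for a in alpha_d]
            f35 = [
                alpha_diversity(phi_inverse(a + config.x_eval * b, draws.psi), config.grouping_metric)
                for a, b in zip(alpha_d, beta_d)
            ]
            val0.append(float(np.mean(f0)))
            val35.append(float(np.mean(f35)))
            mean_alpha = alpha_d.mean(axis=0)
            mean_beta = beta_d.mean(axis=0)
            comp0.append(phi_inverse(mean_alpha, draws.psi))
            comp35.append(phi_inverse(mean_alpha + config.x_eval * mean_beta, draws.psi))
        result = optimize_grouping(
            np.array(val0), np.array(val35), mode="anova",
            method=config.grouping_method, min_size=config.min_group_size, seed=config.seed,
        )
        dm0 = distance_matrix(comp0, config.grouping_beta_metric, tree=tree_index,
                              taxon_ids=counts.taxon_ids, sample_ids=communities)
        dm35 = distance_matrix(comp35, config.grouping_beta_metric, tree=tree_index,
                               taxon_ids=counts.taxon_ids, sample_ids=communities)
        result_b = optimize_grouping(
            dm0, dm35, mode="permanova",
            method=config.grouping_method, min_size=config.min_group_size, seed=config.seed,
        )
        payload = {
            "anova": {
                "metric": config.grouping_metric,
                "assignment": result.assignment.tolist(),
                "units": communities,
                "r2_cycle0": result.r2_cycle0,
                "r2_cycle35": result.r2_cycle35,
                "delta_r2": result.delta_r2,
                "method": result.method,
                "seed": result.seed,
            },
            "permanova": {
                "metric": config.grouping_beta_metric,
                "assignment": result_b.assignment.tolist(),
                "units": communities,
                "r2_cycle0": result_b.r2_cycle0,
                "r2_cycle35": result_b.r2_cycle35,
                "delta_r2": result_b.delta_r2,
                "method": result_b.method,
                "seed": result_b.seed,
            },
        }
        (out / "grouping.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        artifacts.append(out / "grouping.json")
        log(f"grouping: anova delta_r2={result.delta_r2:.3f}, permanova delta_r2={result_b.delta_r2:.3f}")
    except Exception as exc:
        raise StageError("grouping", str(exc)) from exc

    manifest = {
        "config": json.loads(config.canonical()),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
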