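"""Config-driven orchestration of the full two-stage analysis.

Chains imputation, GPA/LSR, PCA morphospaces, Procrustes ANOVA and
allometry, phylogenetic signal, phylomorphospaces, convergence
(single- and multi-tree), disparity-through-time, traitgrams, and the
decoupling battery, writing one JSON/CSV report per stage plus a run
manifest.  A single root seed is split deterministically into
per-stage seeds, so any stage rerun in isolation reproduces its
full-pipeline values.
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
from .decoupling import decoupling_summary
from .io import (
    match_species,
    read_factors,
    read_measurements,
    read_newick,
    read_newick_trees,
    read_tps,
    write_report,
)
from .morphospace import allometry_regression, pca, procrustes_anova
from .phylo import (
    blomberg_k,
    dtt_profile,
    multi_tree_convergence,
    phylomorphospace,
    stayton_convergence,
    traitgram,
)
from .shape import gpa, impute_pca, log_shape_ratios, species_mean_shapes

log = logging.getLogger(__name__)

STAGE_NAMES = (
    "impute",
    "shape",
    "pca",
    "anova",
    "allometry",
    "signal",
    "phylomorphospace",
    "convergence",
    "dtt",
    "traitgram",
    "decoupling",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable under stage reruns)."""
    idx = STAGE_NAMES.index(stage)
    return int(
        np.random.SeedSequence([int(root_seed), idx]).generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected up front."""

    tps: str
    measurements: str
    factors: str
    tree: str
    trees: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGE_NAMES))
    seed: int = 0
    nperm: int = 9999
    nsim: int = 1000
    n_iter: int = 1000
    n_components: int = 2
    n_bins: int = 10
    convergence_pcs: int = 2
    stage_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.convergence_pcs not in (1, 2):
            raise ValueError("convergence_pcs must be 1 or 2")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in order, writing reports to ``outdir``.

    Any stage failure halts the run with the stage name and cause;
    reports already written are retained.  Returns the in-memory result
    objects keyed by stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_NAMES},
        "config": dataclasses.asdict(config),
        "log": [],
    }

    def note(msg: str, *args) -> None:
        log.info(msg, *args)
        manifest["log"].append(msg % args if args else msg)

    # ---- inputs ----------------------------------------------------------
    configs = read_tps(config.tps)
    measurements = read_measurements(config.measurements)
    factors = read_factors(config.factors)
    tree = read_newick(config.tree)
    alt_trees = read_newick_trees(config.trees) if config.trees else []
    note(
        "inputs: %d landmark configurations, %d species measured, %d tips on tree",
        len(configs), len(measurements.species), tree.n_tips,
    )

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            results[name] = fn(stage_seed(config.seed, name))
        except Exception as exc:  # halt with stage name; keep partial output
            raise StageFailure(name, exc) from exc
        timings[name] = time.perf_counter() - t0

    # ---- impute ----------------------------------------------------------
    def do_impute(seed: int):
        imp = impute_pca(measurements, n_components=config.n_components)
        note("impute: %d cells filled in %d iterations", measurements.n_missing, imp.n_iter)
        from .io import write_measurements

        write_measurements(imp.table, outdir / "imputed_measurements.csv")
        write_report(
            {"n_missing": measurements.n_missing, "n_iter": imp.n_iter,
             "converged": imp.converged},
            outdir / "impute.json", seed=seed,
        )
        return imp

    run_stage("impute", do_impute)
    table = results["impute"].table if "impute" in results else measurements

    # ---- GPA + LSR -------------------------------------------------------
    def do_shape(seed: int):
        aligned = gpa(configs)
        species = pd.Series(
            {c.specimen_id: (c.species or c.specimen_id) for c in configs}
        )
        means = species_mean_shapes(aligned, species)
        lsr = log_shape_ratios(table)
        means.to_csv(outdir / "procrustes_coords.csv", index_label="species")
        lsr.values.to_csv(outdir / "log_shape_ratios.csv", index_label="species")
        aligned.centroid_sizes.to_csv(outdir / "centroid_sizes.csv", header=True)
        write_report(
            {"gpa_iterations": aligned.iterations, "n_specimens": len(aligned.coords),
             "n_species": len(means)},
            outdir / "shape.json", seed=seed,
        )
        return {"aligned": aligned, "species_means": means, "lsr": lsr,
                "species": species}

    run_stage("shape", do_shape)
    if "shape" not in results:
        raise StageFailure("shape", RuntimeError("shape stage is required"))
    means = results["shape"]["species_means"]
    lsr = results["shape"]["lsr"]
    aligned = results["shape"]["aligned"]
    species_of = results["shape"]["species"]

    fac = factors.reindex(means.index)

    # ---- PCA morphospaces ------------------------------------------------
    def do_pca(seed: int):
        larval = pca(means)
        adult = pca(lsr.values)
        larval.scores.to_csv(outdir / "larval_pc_scores.csv", index_label="species")
        adult.scores.to_csv(outdir / "adult_pc_scores.csv", index_label="species")
        adult.loadings.iloc[:, :2].to_csv(outdir / "adult_pc_loadings.csv")
        write_report(
            {
                "larval_var_explained": larval.var_explained,
                "adult_var_explained": adult.var_explained,
            },
            outdir / "pca.json", seed=seed,
        )
        return {"larval": larval, "adult": adult}

    run_stage("pca", do_pca)
    larval_pca = results["pca"]["larval"]
    adult_pca = results["pca"]["adult"]

    # ---- Procrustes ANOVA ------------------------------------------------
    def do_anova(seed: int):
        wanted = ["genus", "family", "larval_guild", "stage_class"]
        terms = [t for t in wanted if t in fac.columns and fac[t].notna().all()]
        if not terms:
            raise ValueError("no usable factor columns for the ANOVA")
        table_ = procrustes_anova(
            means.to_numpy(), fac, terms, nperm=config.nperm, seed=seed
        )
        if "stage_class" in terms:
            p_stage = table_["stage_class"]["p"]
            if p_stage > config.stage_p_threshold:
                note("anova: developmental stage non-significant (p=%.3f); "
                     "no stage correction applied", p_stage)
        table_.table.to_csv(outdir / "procrustes_anova.csv", index_label="term")
        write_report(table_, outdir / "anova.json", seed=seed)
        return table_

    run_stage("anova", do_anova)

    # ---- allometry -------------------------------------------------------
    def do_allometry(seed: int):
        out = {}
        # larval size: ln centroid size averaged per species
        cs = np.log(aligned.centroid_sizes.groupby(species_of).mean())
        out["larval"] = allometry_regression(
            means, cs.reindex(means.index), groups=fac["family"],
            nperm=config.nperm, seed=seed,
        )
        out["adult"] = allometry_regression(
            lsr.values, lsr.log_svl, groups=factors.reindex(lsr.values.index)["family"],
            nperm=config.nperm, seed=seed,
        )
        for stage_name, res in out.items():
            res.anova.table.to_csv(
                outdir / f"allometry_{stage_name}_anova.csv", index_label="term"
            )
            pd.DataFrame(
                {
                    "regression_score": res.regression_score,
                    "predicted_shape_pc1": res.predicted_shape_pc1,
                }
            ).to_csv(outdir / f"allometry_{stage_name}_scores.csv",
                     index_label="species")
            write_report(
                {"anova": res.anova, "group_stats": res.group_stats},
                outdir / f"allometry_{stage_name}.json", seed=seed,
            )
        return out

    run_stage("allometry", do_allometry)

    # ---- tree matching ---------------------------------------------------
    matched, dropped = match_species(list(means.index), tree.tip_labels)
    if dropped:
        note("tree matching: %d species not on tree dropped for tree-based stages",
             len(dropped))
    tree_pruned = tree.pruned(matched) if len(matched) < tree.n_tips else tree
    extra_tips = set(tree.tip_labels) - set(matched)
    if extra_tips:
        tree_pruned = tree.pruned(matched)
        note("tree matching: %d tree tips without data pruned", len(extra_tips))
    larval_scores = larval_pca.scores.loc[matched]
    adult_scores = adult_pca.scores.reindex(matched)

    # ---- phylogenetic signal --------------------------------------------
    def do_signal(seed: int):
        res = {
            "larval": blomberg_k(tree_pruned, larval_scores["PC1"],
                                 nperm=config.nperm, seed=seed),
            "adult": blomberg_k(tree_pruned, adult_scores["PC1"],
                                nperm=config.nperm, seed=seed),
        }
        write_report(res, outdir / "signal.json", seed=seed)
        return res

    run_stage("signal", do_signal)

    # ---- phylomorphospace ------------------------------------------------
    def do_pms(seed: int):
        out = {}
        for stage_name, scores in (("larval", larval_scores), ("adult", adult_scores)):
            pms = phylomorphospace(tree_pruned, scores.iloc[:, :2])
            pms.edges.to_csv(outdir / f"phylomorphospace_{stage_name}_edges.csv",
                             index=False)
            pms.node_coords.to_csv(
                outdir / f"phylomorphospace_{stage_name}_nodes.csv", index_label="node"
            )
            out[stage_name] = pms
        return out

    run_stage("phylomorphospace", do_pms)

    # ---- convergence -----------------------------------------------------
    def do_convergence(seed: int):
        npcs = config.convergence_pcs
        fac_tree = factors.reindex(matched)
        focal_sets: dict[str, dict[str, list[str]]] = {"larval": {}, "adult": {}}
        for stage_name, guild_col in (("larval", "larval_guild"),
                                      ("adult", "adult_guild")):
            for col in ("family", guild_col):
                if col not in fac_tree.columns:
                    continue
                for level, members in fac_tree.groupby(col).groups.items():
                    if len(members) >= 2:
                        focal_sets[stage_name][str(level)] = list(members)
        out: dict = {}
        for stage_name, scores in (("larval", larval_scores), ("adult", adult_scores)):
            X = scores.iloc[:, :npcs]
            reports = {}
            multi = {}
            for label, tips in focal_sets[stage_name].items():
                reports[label] = stayton_convergence(
                    tree_pruned, X, tips, nsim=config.nsim, seed=seed
                )
                if alt_trees:
                    multi[label] = multi_tree_convergence(
                        alt_trees, X, tips, nsim=0, seed=seed
                    )
            write_report(reports, outdir / f"convergence_{stage_name}.json", seed=seed)
            if multi:
                write_report(
                    {k: {"values": v.values, "n_used": v.n_used}
                     for k, v in multi.items()},
                    outdir / f"convergence_{stage_name}_trees.json", seed=seed,
                )
            out[stage_name] = {"single": reports, "multi": multi}
        return out

    run_stage("convergence", do_convergence)

    # ---- DTT -------------------------------------------------------------
    def do_dtt(seed: int):
        edges = np.linspace(tree_pruned.height, 0.0, config.n_bins + 1)
        out = {}
        for stage_name, scores in (("larval", larval_scores), ("adult", adult_scores)):
            prof = dtt_profile(tree_pruned, scores["PC1"], bin_edges=edges)
            out[stage_name] = prof
            pd.DataFrame(
                {
                    "midpoint_mya": prof.bin_midpoints,
                    "disparity": prof.disparity,
                    "n_lineages": prof.n_lineages,
                }
            ).to_csv(outdir / f"dtt_{stage_name}.csv", index=False)
        write_report(out, outdir / "dtt.json", seed=seed)
        return out

    run_stage("dtt", do_dtt)

    # ---- traitgram -------------------------------------------------------
    def do_traitgram(seed: int):
        out = {}
        for stage_name, scores in (("larval", larval_scores), ("adult", adult_scores)):
            tg = traitgram(tree_pruned, scores["PC1"])
            pd.DataFrame(
                {"time_mya": tg.times, "value": tg.values}
            ).to_csv(outdir / f"traitgram_{stage_name}.csv", index_label="node")
            out[stage_name] = tg
        return out

    run_stage("traitgram", do_traitgram)

    # ---- decoupling ------------------------------------------------------
    def do_decoupling(seed: int):
        common = [s for s in means.index if s in lsr.values.index]
        larval_mat = means.loc[common]
        adult_mat = lsr.values.loc[common]
        res = decoupling_summary(
            larval_mat, adult_mat,
            groups=factors.reindex(common)["family"],
            nperm=config.nperm, n_iter=config.n_iter, seed=seed,
        )
        res.paired_dissimilarities.to_csv(outdir / "paired_dissimilarities.csv",
                                          index=False)
        write_report(
            {
                "mantel": res.mantel,
                "disparity_r": res.disparity.r,
                "per_family_r": {g: v.r for g, v in res.disparity.per_group.items()},
                "n_iter": res.disparity.n_iter,
                "subset_size": res.disparity.subset_size,
            },
            outdir / "decoupling.json", seed=seed,
        )
        return res

    run_stage("decoupling", do_decoupling)

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return results
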