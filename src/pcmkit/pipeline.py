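"""Config-driven orchestration of the full comparative workflow.

``run_pipeline`` chains trait preparation, disparity-through-time, model
selection, group tests and phenotype-environment correlations, iterating
every statistic over a posterior tree sample, and writes the three summary
tables (model comparison, group tests, correlations) plus DTT curves and
plots into an output directory.  Per-tree records are persisted so every
summary cell can be recomputed from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .disparity import dtt_posterior, plot_dtt
from .models import compare_over_posterior
from .regression import correlate_over_posterior, group_test_over_posterior
from .traits import TraitMatrix, pca_reduce, read_trait_table, species_means
from .trees import TreeSet, read_tree, read_tree_set

log = logging.getLogger("pcmkit.pipeline")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated run configuration.

    Dataset roles: ``response_blocks`` name multivariate trait blocks
    (column-name prefixes in the trait tables), ``univariate`` names single
    columns.  ``n_sim`` controls DTT null simulations per tree, ``n_perm``
    MANOVA permutations, ``n_trees`` the posterior subsample size.
    """

    trees_path: str | None = None
    trees_format: str = "newick"
    traits_path: str | None = None
    env_path: str | None = None
    species_col: str = "species"
    pca_threshold: float = 0.99
    models: tuple = ("BM", "OU", "EB")
    n_sim: int = 200
    n_perm: int = 199
    n_trees: int | None = 100
    significance: float = 0.05
    seed: int = 0
    out_dir: str = "pcmkit_run"
    group_col: str | None = None
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.pca_threshold <= 1):
            raise ValueError("pca_threshold must be in (0, 1]")
        if self.n_sim < 2 or self.n_perm < 99:
            raise ValueError("n_sim >= 2 and n_perm >= 99 required")
        if not (0 < self.significance < 1):
            raise ValueError("significance must be in (0, 1)")


@dataclass
class ReportBundle:
    out_dir: Path
    model_table: pd.DataFrame           # Table-1 analogue
    group_table: pd.DataFrame | None    # Table-2 analogue
    corr_table: pd.DataFrame | None     # Table-3 analogue
    dtt_results: dict
    per_tree_records: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)


def _derive_seed(seed: int, tag: str) -> int:
    import zlib

    # stable across processes (unlike the builtin string hash)
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def run_pipeline(
    config: RunConfig,
    treeset: TreeSet | None = None,
    datasets: dict[str, object] | None = None,
    groups: pd.Series | None = None,
) -> ReportBundle:
    """Run prep -> DTT -> model fits -> group tests -> correlations.

    Inputs may be given in-memory (``treeset``, ``datasets`` mapping
    dataset name -> DataFrame/Series, ``groups``) or through file paths in
    the config.  ``datasets`` must contain at least one phenotype entry
    named ``'size'`` or ``'shape'``; remaining entries are treated as
    environmental predictors.  Stage failures are isolated: a failed stage
    is logged and recorded, and the partial bundle is still returned.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if treeset is None:
        if config.trees_path is None:
            raise FileNotFoundError("no trees: set trees_path or pass a TreeSet")
        treeset = read_tree_set(config.trees_path, config.trees_format,
                                max_trees=config.n_trees, seed=config.seed)
    elif config.n_trees is not None and config.n_trees < len(treeset):
        rng = np.random.default_rng(config.seed)
        keep = np.sort(rng.choice(len(treeset), size=config.n_trees, replace=False))
        treeset = TreeSet([treeset[i] for i in keep], treeset.median_tree,
                          treeset.source)
    tips = treeset.tip_labels

    if datasets is None:
        datasets = _load_datasets(config, tips)
    datasets = {k: (v.data if isinstance(v, TraitMatrix) else v) for k, v in datasets.items()}
    datasets = {k: (v.to_frame() if isinstance(v, pd.Series) else v).loc[tips]
                for k, v in datasets.items()}

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh)
    run_log = {"version": __version__, "seed": config.seed,
               "n_trees": len(treeset), "datasets": {k: list(v.columns) for k, v in datasets.items()}}

    failures: dict[str, str] = {}
    per_tree: dict[str, pd.DataFrame] = {}

    # ---- stage 1: disparity through time ---------------------------------
    dtt_results = {}
    for name, data in datasets.items():
        try:
            res = dtt_posterior(treeset, data, n_sim=config.n_sim,
                                seed=_derive_seed(config.seed, f"dtt:{name}"))
            dtt_results[name] = res
            pd.DataFrame({"rel_time": res.grid, "observed_mean": res.mean_curve,
                          "null_mean": res.null_mean_curve}).to_csv(
                out / f"dtt_{name}.csv", index=False)
            pd.DataFrame({"tree": np.arange(len(res.mdi_values)),
                          "mdi": res.mdi_values}).to_csv(
                out / f"dtt_{name}_per_tree.csv", index=False)
            if config.make_plots:
                plot_dtt(res, out / f"dtt_{name}.svg", title=name)
        except Exception as exc:  # isolate stage failures per dataset
            log.warning("DTT failed for %s: %s", name, exc)
            failures[f"dtt:{name}"] = str(exc)

    # ---- stage 2: trait-evolution model comparison ------------------------
    model_rows = []
    for name, data in datasets.items():
        try:
            summ = compare_over_posterior(treeset, data, config.models)
            recs = []
            for i, c in enumerate(summ.per_tree):
                for m in config.models:
                    recs.append({"tree": i, "dataset": name, "model": m,
                                 "weight": c.weights[m], "aicc": c.fits[m].aicc,
                                 "delta_aicc": c.delta_aicc[m],
                                 "alpha": c.fits[m].alpha, "r": c.fits[m].r})
            per_tree[f"models:{name}"] = pd.DataFrame(recs)
            for m in config.models:
                w = summ.weight_mean_ci.loc[m]
                a = summ.aicc_mean_sd.loc[m]
                row = {"dataset": name, "model": m,
                       "weight_mean": w["mean"], "weight_lo": w["lo"], "weight_hi": w["hi"],
                       "aicc_mean": a["mean"], "aicc_sd": a["sd"],
                       "best": m == summ.consensus_best,
                       "support_fraction": summ.support_fraction[m]}
                if m == "OU" and "alpha" in summ.param_mean_sd.index:
                    row["param_mean"] = summ.param_mean_sd.loc["alpha", "mean"]
                    row["param_sd"] = summ.param_mean_sd.loc["alpha", "sd"]
                if m == "EB" and "r" in summ.param_mean_sd.index:
                    row["param_mean"] = summ.param_mean_sd.loc["r", "mean"]
                    row["param_sd"] = summ.param_mean_sd.loc["r", "sd"]
                model_rows.append(row)
        except Exception as exc:
            log.warning("model comparison failed for %s: %s", name, exc)
            failures[f"models:{name}"] = str(exc)
    model_table = pd.DataFrame(model_rows)
    model_table.to_csv(out / "table1_models.csv", index=False)

    best_model = {r["dataset"]: r["model"] for r in model_rows if r.get("best")}

    # ---- stage 3: group tests (Table-2 analogue) --------------------------
    group_table = None
    if groups is not None or config.group_col:
        if groups is None:
            raise FileNotFoundError("group_col set but no group labels found")
        rows = []
        for name, data in datasets.items():
            try:
                gt = group_test_over_posterior(
                    treeset, data, groups, corr_model=best_model.get(name, "BM"),
                    n_perm=config.n_perm,
                    seed=_derive_seed(config.seed, f"group:{name}"),
                    threshold=config.significance)
                per_tree[f"group:{name}"] = gt.per_tree.reset_index()
                rows.append({"dataset": name, "statistic": gt.statistic_name,
                             "stat_mean": gt.stat_mean_sd[0], "stat_sd": gt.stat_mean_sd[1],
                             "stat_lo": gt.stat_ci95[0], "stat_hi": gt.stat_ci95[1],
                             "p_mean": gt.p_mean_sd[0], "p_sd": gt.p_mean_sd[1],
                             "p_lo": gt.p_ci95[0], "p_hi": gt.p_ci95[1],
                             "prop_nonsignificant": 1.0 - gt.prop_significant,
                             "corr_model": gt.corr_model})
            except Exception as exc:
                log.warning("group test failed for %s: %s", name, exc)
                failures[f"group:{name}"] = str(exc)
        group_table = pd.DataFrame(rows)
        group_table.to_csv(out / "table2_groups.csv", index=False)

    # ---- stage 4: phenotype-environment correlations ----------------------
    corr_table = None
    pheno_names = [k for k in ("shape", "size") if k in datasets]
    env_names = [k for k in datasets if k not in ("shape", "size")]
    if pheno_names and env_names:
        rows = []
        for ph in pheno_names:
            for en in env_names:
                try:
                    summ = correlate_over_posterior(
                        treeset, datasets[ph], datasets[en],
                        threshold=config.significance, n_perm=config.n_perm,
                        seed=_derive_seed(config.seed, f"corr:{ph}:{en}"))
                    per_tree[f"corr:{ph}:{en}"] = summ.records
                    t = summ.table.reset_index()
                    t.insert(0, "phenotype", ph)
                    t.insert(1, "environment", en)
                    t["corr_model"] = summ.corr_model
                    rows.append(t)
                except Exception as exc:
                    log.warning("correlation failed for %s ~ %s: %s", ph, en, exc)
                    failures[f"corr:{ph}:{en}"] = str(exc)
        if rows:
            corr_table = pd.concat(rows, ignore_index=True)
            corr_table.to_csv(out / "table3_correlations.csv", index=False)

    for key, df in per_tree.items():
        safe = key.replace(":", "_")
        df.to_csv(out / f"per_tree_{safe}.csv", index=False)
    run_log["failures"] = failures
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)

    return ReportBundle(out_dir=out, model_table=model_table,
                        group_table=group_table, corr_table=corr_table,
                        dtt_results=dtt_results, per_tree_records=per_tree,
                        failures=failures)


def _load_datasets(config: RunConfig, tips) -> dict:
    """Assemble datasets from trait/environment CSVs named in the config."""
    if config.traits_path is None:
        raise FileNotFoundError("no trait data: set traits_path or pass datasets")
    from .traits import size_correct

    morph = read_trait_table(config.traits_path, config.species_col)
    morph = species_means(morph)
    corrected = size_correct(morph)
    shape_cols = [c for c in corrected.data.columns if c != "SVL"]
    datasets: dict[str, object] = {
        "size": corrected.data[["SVL"]],
        "shape": corrected.data[shape_cols],
    }
    if config.env_path:
        env = species_means(read_trait_table(config.env_path, config.species_col))
        blocks: dict[str, list] = {}
        for c in env.data.columns:
            blocks.setdefault(c.split("_")[0], []).append(c)
        for block, cols in blocks.items():
            if len(cols) == 1:
                datasets[block] = env.data[cols]
            else:
                pca = pca_reduce(TraitMatrix(env.data[cols]), config.pca_threshold)
                datasets[block] = pca.scores
    return datasets
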