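"""End-to-end orchestration: filter -> weights -> replicates -> enrichment -> regression.

A single :class:`RunConfig` (loadable from YAML) drives the whole analysis;
:func:`run_analysis` writes weight tables, replicate draws, enrichment rows,
null-distribution p-values and histograms, the regression table, and a
manifest recording every count, seed, and bandwidth of the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import enrichment as enr
from . import regression as reg
from . import sampling as smp
from .universe import (
    GeneSet,
    GeneUniverse,
    filter_universe,
    read_gene_set,
    read_gene_table,
    write_gene_table,
)

logger = logging.getLogger(__name__)

VARIANTS = ("include_all", "exclude_target", "top_excluded")


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    gene_table: str
    target_set: str
    candidate_sets: list[str]
    out_dir: str
    column_map: dict[str, str] = field(default_factory=dict)
    log_transform_lengths: bool = False
    min_log_expr: float | None = 2.0
    require_cds_len: bool = True
    require_tx_len: bool = True
    modes: list[str] = field(default_factory=lambda: ["expression"])
    variants: list[str] = field(default_factory=lambda: ["include_all"])
    n_replicates: int = 1000
    n_per_set: int | None = None  # default: number of in-universe target genes
    genome_size: int | None = None  # target-vs-candidate N; default |universe|
    clip_filters: list[int] = field(default_factory=lambda: [1, 17])
    run_regression: bool = True
    make_plots: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.candidate_sets:
            raise ValueError("at least one candidate set is required")
        for m in self.modes:
            if m not in smp.MODE_COVARIATES:
                raise ValueError(f"unknown sampling mode {m!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.gene_table, self.target_set, *self.candidate_sets]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class RunReport:
    manifest: dict[str, Any]
    out_dir: Path

    def manifest_path(self) -> Path:
        return self.out_dir / "manifest.json"


def _stage_seed(seed: int, *key: int) -> int:
    """Derive a stage seed from the run seed via a splittable construction."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, np.uint64)[0])


def _histogram_tsv(p_values: Sequence[float], path: Path) -> None:
    counts, edges = np.histogram(np.asarray(p_values), bins=20, range=(0.0, 1.0))
    with open(path, "w") as fh:
        fh.write("bin_left\tbin_right\tcount\n")
        for i, c in enumerate(counts):
            fh.write(f"{edges[i]:.2f}\t{edges[i + 1]:.2f}\t{int(c)}\n")


def _histogram_png(p_values: Sequence[float], target_p: float, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(p_values, bins=20, range=(0, 1), color="steelblue")
    ax.axvline(0.05, color="blue", linestyle="--", label="p = 0.05")
    ax.axvline(target_p, color="red", label="target set p")
    ax.set_xlabel("right-tail p")
    ax.set_ylabel("replicates")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _load_inputs(cfg: RunConfig) -> tuple[GeneUniverse, GeneSet, list[GeneSet]]:
    universe = read_gene_table(
        cfg.gene_table, column_map=cfg.column_map or None,
        log_transform_lengths=cfg.log_transform_lengths,
    )
    target = read_gene_set(cfg.target_set, name="target")
    candidates = [read_gene_set(p) for p in cfg.candidate_sets]
    return universe, target, candidates


def run_analysis(cfg: RunConfig) -> RunReport:
    """Run every stage of the analysis and write its outputs to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        cfg.validate_paths()
        raw_universe, target, candidates = _load_inputs(cfg)

        stage = "filter universe"
        universe = filter_universe(
            raw_universe,
            min_log_expr=cfg.min_log_expr,
            require_cds_len=cfg.require_cds_len,
            require_tx_len=cfg.require_tx_len,
        )
        write_gene_table(universe, out / "universe_filtered.tsv")
        target_in = GeneSet("target_in_universe", target.intersect(universe.symbols))
        n_per_set = cfg.n_per_set if cfg.n_per_set is not None else len(target_in)
        genome_size = cfg.genome_size  # None -> use the filtered universe

        manifest: dict[str, Any] = {
            "seed": cfg.seed,
            "counts": {
                "universe_input": len(raw_universe),
                "universe_filtered": len(universe),
                "target_total": len(target),
                "target_in_universe": len(target_in),
                "n_per_set": n_per_set,
            },
            "filters": {
                "min_log_expr": cfg.min_log_expr,
                "require_cds_len": cfg.require_cds_len,
                "require_tx_len": cfg.require_tx_len,
            },
            "bandwidths": {},
            "pool_sizes": {},
            "stage_seeds": {},
            "outputs": ["universe_filtered.tsv"],
        }

        stage = "target enrichment"
        enrich_rows: list[tuple[str, str, enr.EnrichmentResult]] = []
        target_results: dict[str, enr.EnrichmentResult] = {}
        for cand in candidates:
            res = enr.overlap_enrichment(
                target_in, cand,
                universe_size=genome_size, universe=None if genome_size else universe,
            )
            target_results[cand.name] = res
            enrich_rows.append(("target", cand.name, res))

        stage = "matched sampling"
        summary_rows: list[dict[str, Any]] = []
        for mi, mode in enumerate(cfg.modes):
            weights = smp.density_ratio_weights(universe, target_in, mode=mode)
            weights.write_tsv(out / f"weights_{mode}.tsv")
            manifest["bandwidths"][mode] = {
                k: list(v) for k, v in weights.bandwidths.items()
            }
            manifest["outputs"].append(f"weights_{mode}.tsv")

            for vi, variant in enumerate(cfg.variants):
                exclude = target_in if variant in ("exclude_target", "top_excluded") else None
                pool = len(universe) - (len(target_in) if exclude else 0)
                manifest["pool_sizes"][f"{mode}/{variant}"] = pool
                plan_seed = _stage_seed(cfg.seed, mi, vi)
                manifest["stage_seeds"][f"{mode}/{variant}"] = plan_seed

                if variant == "top_excluded":
                    top = smp.top_weighted_set(
                        universe, weights, n_per_set, exclude=exclude,
                        name=f"top_{mode}",
                    )
                    for cand in candidates:
                        res = enr.overlap_enrichment(top, cand, universe=universe)
                        enrich_rows.append((f"top_{mode}", cand.name, res))
                    continue

                plan = smp.SamplingPlan(
                    mode=mode, n_per_set=n_per_set, n_replicates=cfg.n_replicates,
                    exclude=exclude, seed=plan_seed,
                )
                replicates = smp.sample_replicates(universe, weights, plan)
                rep_file = f"replicates_{mode}_{variant}.tsv"
                smp.write_replicates_tsv(replicates, out / rep_file)
                manifest["outputs"].append(rep_file)

                for cand in candidates:
                    summary = enr.null_summary(
                        replicates, cand, universe, target_results[cand.name]
                    )
                    label = f"{mode}_{variant}_{cand.name}"
                    enr.write_pvalues_tsv(summary, out / f"null_pvalues_{label}.tsv", label)
                    _histogram_tsv(summary.p_values, out / f"hist_{label}.tsv")
                    if cfg.make_plots:
                        _histogram_png(
                            summary.p_values, summary.target_p,
                            out / f"hist_{label}.png", label,
                        )
                    manifest["outputs"] += [f"null_pvalues_{label}.tsv", f"hist_{label}.tsv"]
                    summary_rows.append(
                        {
                            "mode": mode,
                            "variant": variant,
                            "candidate": cand.name,
                            "n_replicates": cfg.n_replicates,
                            "target_p": summary.target_p,
                            "frac_nominal": summary.frac_nominal,
                            "frac_beats_target": summary.frac_beats_target,
                        }
                    )

        stage = "write enrichment tables"
        enr.results_frame(enrich_rows).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.17g"
        )
        manifest["outputs"].append("enrichment.tsv")
        if summary_rows:
            import pandas as pd

            pd.DataFrame(summary_rows).to_csv(
                out / "null_summary.tsv", sep="\t", index=False, float_format="%.17g"
            )
            manifest["outputs"].append("null_summary.tsv")

        stage = "regression"
        if cfg.run_regression:
            try:
                table = reg.table1(universe, clip_filters=cfg.clip_filters)
            except ValueError as exc:
                logger.warning("regression skipped: %s", exc)
            else:
                table.write_tsv(out / "table1.tsv")
                manifest["outputs"].append("table1.tsv")

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return RunReport(manifest=manifest, out_dir=out)
    except Exception as exc:
        raise RuntimeError(f"analysis failed in stage {stage!r}: {exc}") from exc
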