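"""End-to-end orchestration: one input table + one config -> output bundle.

Stages: per-environment genetic parameters, pooled and per-environment
trait correlations, per-environment yield regression, divergence
clustering, adaptability ranking/selection, and the combined
genotype x year ANOVA.  Outputs are deterministic CSVs plus a manifest
with the config echo and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import associations, clustering, gai, genparams, regression
from .anova import combined_gxy_anova
from .io import TraitTable, read_trait_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_path: str | None = None
    out_dir: str = "metbiom_out"
    traits: list[str] | None = None
    response: str = "FY"
    k: float = genparams.DEFAULT_K
    cluster_method: str = "tocher"
    cluster_k: int | None = 5
    min_occurrence: int = 5
    round_decimals: int | None = None     # None = full precision
    seed: int | None = None               # echoed in the manifest
    column_names: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path, decimals: int | None) -> None:
    if decimals is not None:
        df = df.round(decimals)
    df.to_csv(path, index=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, table: TraitTable | None = None) -> dict:
    """Run every stage and write the output bundle; returns the manifest."""
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = read_trait_table(config.input_path, columns=config.column_names)
    traits = config.traits or table.traits
    unknown = [t for t in traits if t not in table.traits]
    if unknown:
        raise PipelineError("preflight", ValueError(f"unknown trait(s): {unknown}"))
    table.validate_balance()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    dec = config.round_decimals

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            fn()
        except Exception as exc:  # abort and remove partial outputs
            for p in written:
                p.unlink(missing_ok=True)
            shutil.rmtree(out / "clusters", ignore_errors=True)
            raise PipelineError(name, exc) from exc

    def emit(df, relpath):
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        _write(df, path, dec)
        written.append(path)

    def do_params():
        emit(genparams.build_table1(table, k=config.k, traits=traits), "table1.csv")

    def do_corr():
        pooled = associations.correlation_matrices(table, traits)
        emit(associations.correlation_long(pooled), "corr_pooled.csv")
        for env in table.environments:
            res = associations.correlation_matrices(table, traits, environment=env)
            emit(associations.correlation_long(res), f"corr_{env}.csv")

    def do_regress():
        preds = [t for t in traits if t != config.response]
        for env in table.environments:
            res = regression.fit_fy_regression(
                table, environment=env, response=config.response, predictors=preds
            )
            frame = pd.DataFrame(
                {
                    "predictor": res.predictors,
                    "b": res.slopes.to_numpy(),
                    "p_value": res.p_values.to_numpy(),
                }
            )
            frame["r2_percent"] = res.r2_percent
            frame["model_p"] = res.model_p
            emit(frame, f"regress_{env}.csv")

    def do_cluster():
        means = clustering.trait_mean_matrix(table, traits)
        cov = clustering.pooled_within_covariance(table, traits)
        dm = clustering.mahalanobis_d2(means, cov)
        sol = clustering.cluster_genotypes(
            dm, method=config.cluster_method, k=config.cluster_k
        )
        summary = clustering.cluster_summary(sol, dm, means)
        emit(summary["membership"], "clusters/membership.csv")
        emit(
            summary["distances"].reset_index(names="cluster"),
            "clusters/distances.csv",
        )
        emit(
            summary["cluster_means"].reset_index(names="cluster"),
            "clusters/means.csv",
        )
        if config.cluster_method in ("ward", "average"):
            z = clustering.linkage_tree(dm, method=config.cluster_method)
            nwk = clustering.dendrogram_newick(z, dm.labels)
            path = out / "clusters" / "dendrogram.nwk"
            path.write_text(nwk + "\n")
            written.append(path)

    def do_gai():
        mat = gai.gai_from_table(table, traits)
        report = gai.consolidate_ranks(gai.rank_by_gai(mat))
        emit(report.as_frame().reset_index(names="genotype"), "gai_table7.csv")
        emit(mat.gai.reset_index(names="genotype"), "gai_values.csv")
        emit(gai.select_superior(report, config.min_occurrence), "gai_selected.csv")

    def do_gxy():
        if table.n_environments >= 2:
            anova = combined_gxy_anova(table, config.response)
            emit(anova.with_percent_total(), "gxy_anova.csv")

    stage("genetic_parameters", do_params)
    stage("trait_associations", do_corr)
    stage("yield_regression", do_regress)
    stage("divergence_clustering", do_cluster)
    stage("adaptability_ranking", do_gai)
    stage("combined_gxy_anova", do_gxy)

    manifest = {
        "seed": config.seed,
        "config": {
            k: v for k, v in config.__dict__.items() if k != "column_names"
        },
        "files": {str(p.relative_to(out)): _checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
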