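"""Configuration-driven orchestration of the analysis workflows.

A YAML config lists stages (``process``, ``stats``, ``network``,
``enrich``) with per-stage parameter blocks.  Stage outputs flow into the
next stage in memory and are also written as TSV artifacts, so every
stage can equally be run standalone from files.  A pre-flight pass
verifies that each stage's required input is produced by an earlier
stage or supplied as a file before any computation starts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_data import Dataset, read_dataset, read_gmt, write_dataset, write_table
from .processing import NormalizationSpec, apply_pipeline, pca_overview
from .stats import DesignSpec, test_features
from .networks import (
    correlation_network,
    fit_bum,
    max_scoring_subnetwork,
    partial_correlation_network,
    score_nodes,
)
from .enrichment import fcs_enrich, ora_hypergeometric

__all__ = ["run_config", "PipelineError"]

log = logging.getLogger("metabolokit")

#: what each stage consumes and produces
_STAGE_IO = {
    "process": ("dataset", "dataset"),
    "stats": ("dataset", "stats"),
    "network": ("dataset", "network"),
    "enrich": ("stats", "enrichment"),
}


class PipelineError(ValueError):
    pass


def _preflight(stages: list[dict]) -> None:
    available: set[str] = set()
    for i, st in enumerate(stages):
        name = st.get("stage")
        if name not in _STAGE_IO:
            raise PipelineError(f"unknown stage {name!r} at position {i}")
        needs, makes = _STAGE_IO[name]
        if needs not in available and "input" not in st:
            raise PipelineError(
                f"stage {name!r} (position {i}) needs a {needs!r} input, but no "
                f"earlier stage produces one and no 'input' file is given"
            )
        available.add(makes)


def _load_input(st: dict, kind: str):
    path = st["input"]
    if kind == "dataset":
        return read_dataset(path, sample_meta_path=st.get("sample_meta"))
    if kind == "stats":
        from .core_data import read_stats_table

        return read_stats_table(path)
    raise PipelineError(f"cannot load stage input of kind {kind!r}")


def run_config(config_path, out_dir=None, seed: int | None = None) -> dict:
    """Execute the stages of a YAML config; returns the artifact dict.

    Artifacts (``dataset``, ``stats``, ``network``, ``enrichment``) are
    written as TSVs under ``out_dir`` and a run log records versions,
    parameters, seeds and warnings.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    stages = cfg.get("stages", [])
    if not stages:
        raise PipelineError("config has no stages")
    out_dir = Path(out_dir or cfg.get("out_dir", config_path.parent / "results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else cfg.get("seed")

    _preflight(stages)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("metabolokit %s", __version__)
    log.info("config: %s, seed: %s", config_path, seed)

    artifacts: dict = {}
    try:
        for st in stages:
            name = st["stage"]
            needs, _makes = _STAGE_IO[name]
            log.info("stage %s params=%s", name, {k: v for k, v in st.items() if k != "stage"})
            source = _load_input(st, needs) if "input" in st else artifacts[needs]

            if name == "process":
                spec = NormalizationSpec(
                    transform=st.get("transform", "none"),
                    power_exponent=st.get("power_exponent", 0.5),
                    sample_method=st.get("sample_norm", "none"),
                    sample_params=st.get("sample_params", {}),
                    feature_method=st.get("feature_norm", "none"),
                )
                processed, report = apply_pipeline(source, spec)
                artifacts["dataset"] = processed
                write_dataset(processed, out_dir / "normalized.tsv",
                              out_dir / "sample_meta.tsv")
                if "loess_spans" in report:
                    report["loess_spans"].to_csv(out_dir / "loess_spans.tsv", sep="\t")
                    for feat, row in report["loess_spans"].iterrows():
                        log.info("loess spans %s: %s", feat, row.to_dict())
                if st.get("pca", True):
                    complete = processed.intensities.dropna(axis=0)
                    if len(complete):
                        scores, _loadings, evr = pca_overview(
                            Dataset(complete, processed.sample_meta), st.get("pca_components", 2)
                        )
                        scores["explained"] = ""
                        scores.to_csv(out_dir / "pca_scores.tsv", sep="\t")
                        log.info("pca explained variance: %s", evr.to_dict())
            elif name == "stats":
                design = DesignSpec(
                    design=st["design"],
                    factors=tuple(st.get("factors", [st.get("group", "group")])),
                    subject=st.get("subject"),
                )
                table = test_features(
                    source, design, method=st.get("method"), fdr=st.get("fdr", 0.05)
                )
                artifacts["stats"] = table
                write_table(table, out_dir / "stats.tsv")
                ph = table.attrs.get("post_hoc")
                if ph is not None and len(ph):
                    write_table(ph, out_dir / "post_hoc.tsv")
            elif name == "network":
                method = st.get("method", "pearson")
                threshold = st.get("threshold", 0.7)
                if method == "partial":
                    net = partial_correlation_network(source, threshold=threshold)
                else:
                    net = correlation_network(source, method=method, threshold=threshold)
                artifacts["network"] = net
                net.write(out_dir / "network_edges.tsv")
                if st.get("subnetwork") and "stats" in artifacts:
                    stats_table = artifacts["stats"].dropna(subset=["p"])
                    fit = fit_bum(stats_table["p"].to_numpy(), fdr=st.get("bum_fdr", 0.05))
                    scores = score_nodes(
                        fit, dict(zip(stats_table["entity_id"], stats_table["p"]))
                    )
                    scores = {n: scores.get(n, -1.0) for n in net.graph.nodes}
                    sub, total = max_scoring_subnetwork(net, scores)
                    sub.write(out_dir / "subnetwork_edges.tsv")
                    log.info("subnetwork: %d nodes, score %.3f (lambda=%.3f a=%.3f tau=%.3g)",
                             sub.n_nodes, total, fit.lam, fit.a, fit.tau)
                    artifacts["subnetwork"] = sub
            elif name == "enrich":
                sets = read_gmt(st["gmt"])
                if st.get("method", "fisher") == "ora":
                    fdr = st.get("fdr", 0.05)
                    sel = source.loc[source["pFDR"] < fdr, "entity_id"]
                    res = ora_hypergeometric(sel, source["entity_id"], sets)
                else:
                    res = fcs_enrich(
                        source.dropna(subset=["p"]), sets,
                        method=st.get("method", "fisher"),
                        n_perm=st.get("n_perm", 1000), seed=seed,
                    )
                artifacts["enrichment"] = res
                write_table(res, out_dir / "enrichment.tsv")
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts
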