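"""End-to-end pipeline: simulate/load → normalize → DEG → logic → network
→ enrichment → CK response, with TSV/JSON outputs and a machine-readable
run report.

One top-level seed fans out deterministically to per-stage child seeds via
``numpy.random.SeedSequence``, so any stage can be re-run in isolation with
its recorded seed and reproduce its output byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ck as ck_mod
from . import enrich, io, logic, network, report
from .model import KnockoutLogicModel

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "deg", "network", "enrich", "ck")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run (TOML-loadable)."""

    # inputs; matrix/sample_sheet empty → simulate with package defaults
    matrix: str = ""
    sample_sheet: str = ""
    network: str = ""
    annotations: str = ""
    hormone_lists: str = ""
    # deg parameters
    alpha: float = 0.05
    fc_quantile: float = 0.95
    max_perms: int = 1000
    # logic parameters
    mode: str = "closure"
    percentile: float = 50.0
    report_18: bool = False
    # network parameters
    network_mode: str = "exact"
    n_samples: int = 100_000
    # enrichment parameters
    enrich_variant: str = "fisher"
    enrich_threshold: float = 0.1
    # run control
    seed: int = 0
    outdir: str = "arrlogic_out"
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.fc_quantile < 1:
            raise ValueError("alpha and fc_quantile must lie in (0, 1)")
        if self.mode not in ("strict", "closure"):
            raise ValueError(f"unknown logic mode {self.mode!r}")
        if self.network_mode not in ("exact", "sampled"):
            raise ValueError(f"unknown network mode {self.network_mode!r}")
        for attr in ("matrix", "sample_sheet", "network", "annotations",
                     "hormone_lists"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


def load_config(path) -> PipelineConfig:
    """Read a TOML config; unknown keys are rejected."""
    import tomllib
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def stage_seeds(seed: int | None) -> dict[str, int]:
    """Deterministic per-stage child seeds from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(_STAGES, children)}


def _fingerprint(df: pd.DataFrame) -> str:
    h = pd.util.hash_pandas_object(df, index=True).sum()
    return f"{df.shape[0]}x{df.shape[1]}:{int(h) % 10**10:010d}"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input shape."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``outdir/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    t0 = time.time()
    rep: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "params": {k: v for k, v in asdict(config).items()
                   if k not in ("simulate",)},
        "outputs": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t")
        rep["outputs"].append(name)

    # --- input stage: load or simulate -----------------------------------
    truth = None
    stage = "simulate"
    try:
        if config.matrix:
            study = io.read_expression_study(config.matrix,
                                             config.sample_sheet)
            logger.info("loaded study %s", _fingerprint(study.matrix))
        else:
            from .simulate import SimConfig, generate_expression_study
            sim = SimConfig(**{**config.simulate, "seed": seeds["simulate"]})
            study, truth = generate_expression_study(sim)
            io.write_expression_study(study, outdir / "matrix.tsv",
                                      outdir / "samples.tsv")
            rep["outputs"] += ["matrix.tsv", "samples.tsv"]
            _write(truth, "truth.tsv")
            logger.info("simulated study %s", _fingerprint(study.matrix))
    except Exception as err:
        raise StageError(f"stage {stage!r} failed: {err}") from err

    # --- DEG + logic -------------------------------------------------------
    stage = "deg"
    try:
        model = KnockoutLogicModel(study)
        results = model.fit(alpha=config.alpha,
                            fc_quantile=config.fc_quantile,
                            max_perms=config.max_perms,
                            mode=config.mode,
                            percentile=config.percentile,
                            n_catalogue=18 if config.report_18 else 15,
                            seed=seeds["deg"])
        _write(results.matrix.rename_axis("gene_id"), "normalized.tsv")
        for label, t in results.deg_tables.items():
            _write(t, f"deg_{label.replace('/', '_')}.tsv")
        if results.ck_table is not None:
            _write(results.ck_table, "deg_WT_CK.tsv")
        _write(results.patterns.rename_axis("gene_id"), "patterns.tsv")
        _write(results.cluster_table, "clusters.tsv")
        cat = logic.structure_catalogue_frame()
        if not config.report_18:
            cat = cat[cat.index <= 15]
        (outdir / "structures.json").write_text(
            cat.reset_index().to_json(orient="records", force_ascii=False,
                                      indent=1))
        rep["outputs"].append("structures.json")
        rep["deg_counts"] = {
            k: v for k, v in
            results.deg_counts.to_dict(orient="index").items()}
        rep["fc_cutoffs"] = results.fc_cutoffs.round(6).to_dict()
        sizes = results.cluster_sizes
        rep["cluster_sizes"] = sizes.to_dict(orient="records")
        rep["selected_clusters"] = sorted(
            sizes.loc[sizes["selected"], "cluster"].unique().tolist())
        rep["n_structures_mapped"] = len(results.mapped_structures)
        if truth is not None:
            rep["recovery"] = results.recovery_against(truth)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {stage!r} failed "
                         f"(input {_fingerprint(study.matrix)}): {err}"
                         ) from err

    # --- network -----------------------------------------------------------
    stage = "network"
    try:
        if config.network:
            import networkx as nx
            edges = io.read_edge_list(config.network)
            g = nx.from_pandas_edgelist(edges, "source", "target")
            g.remove_edges_from(nx.selfloop_edges(g))
            stats = network.node_stats(g, mode=config.network_mode,
                                       n_samples=config.n_samples,
                                       seed=seeds["network"])
            _write(stats, "node_stats.tsv")
            directions = results.cluster_table["direction"].where(
                results.cluster_table["cluster"] > 0)
            rep["hub_counts"] = report.directional_node_counts(
                stats["hub"], directions)
            rep["high_cc_counts"] = report.directional_node_counts(
                stats["high_cc"], directions)
            if config.hormone_lists:
                hormones = pd.read_csv(config.hormone_lists, sep="\t")
                classes = results.cluster_table["group"].where(
                    results.cluster_table["group"] != "none")
                targets = {h: sub for h, sub in hormones.groupby("hormone")}
                frac = network.group_fraction_table(classes.dropna(), targets)
                _write(frac.set_index("set"), "hormone_fractions.tsv")
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {stage!r} failed: {err}") from err

    # --- enrichment ----------------------------------------------------------
    stage = "enrich"
    try:
        if config.annotations:
            annotation = io.read_gmt(config.annotations)
            universe = set(results.matrix.index)
            groups = results.cluster_table
            enr_all = []
            for grp, sub in groups[groups["group"] != "none"].groupby("group"):
                res = enrich.fisher_enrichment(
                    set(sub.index), annotation, universe,
                    variant=config.enrich_variant,
                    threshold=config.enrich_threshold)
                res = res.assign(group=grp)
                enr_all.append(res)
            if enr_all:
                _write(pd.concat(enr_all), "enrichment.tsv")
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {stage!r} failed: {err}") from err

    # --- CK response --------------------------------------------------------
    stage = "ck"
    try:
        if results.ck_table is not None:
            overlap = results.ck_overlap()
            _write(overlap, "ck_overlap.tsv")
            _write(ck_mod.summarize_overlap(overlap).set_index("class"),
                   "ck_summary.tsv")
            rep["ck_class_counts"] = ck_mod.class_counts(overlap)
    except StageError:
        raise
    except Exception as err:
        raise StageError(f"stage {stage!r} failed: {err}") from err

    rep["runtime_s"] = round(time.time() - t0, 2)
    for name in rep["outputs"]:
        if not (outdir / name).exists():
            raise StageError(f"declared output missing: {name}")
    (outdir / "report.json").write_text(json.dumps(rep, indent=1,
                                                   default=str))
    rep["outputs"].append("report.json")
    return rep
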