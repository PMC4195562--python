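"""End-to-end orchestration: coupling -> networks -> DE -> motifs -> enrichment.

A single YAML (or dict) config names the inputs — two expression TSVs plus
sample metadata, or a ``synthetic`` block generating them — the scenario,
and the statistical parameters.  Every stage writes its TSV outputs into
the run directory and the run is summarized in a JSON manifest holding the
config snapshot, seed, per-stage timings, input checksums and output file
list.  A master seed deterministically derives per-stage substream seeds,
so an individual stage rerun from intermediate files matches the full run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .celltype_de import run_celltype_de
from .core_io import (
    PipelineConfig,
    intersect_genes,
    load_expression_matrix,
    load_sample_map,
)
from .coupling import run_coupling
from .enrichment import enrich
from .motifs import MotifSpace, permutation_motif_test
from .netcons import coexpression_adjacency, node_properties, run_netcons, threshold_graph, write_edge_list
from .synthetic_data import (
    SyntheticConfig,
    generate_annotation,
    generate_paired_dataset,
    write_dataset,
)

log = logging.getLogger("coupletrans")


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


CONFIG_SCHEMA = {
    "scenario": "identical | common (default common)",
    "inputs": {
        "transcriptome": "path to genes x samples TSV",
        "translatome": "path to genes x samples TSV",
        "metadata": "path to sample map TSV "
                    "(sample_id, level, promoter, cell_type, replicate)",
        "annotation": "optional path to gene_id/term_id TSV",
    },
    "synthetic": "alternative to inputs: SyntheticConfig fields "
                 f"({[f.name for f in fields(SyntheticConfig)]}) plus an "
                 "optional 'annotation' sub-block "
                 "{n_terms, background_prob, planted_prob}",
    "params": f"PipelineConfig fields ({[f.name for f in fields(PipelineConfig)]})",
}


def print_schema() -> str:
    return json.dumps(CONFIG_SCHEMA, indent=2)


def load_config(source) -> dict:
    """Accept a dict, a YAML string path, or a Path; validate the skeleton."""
    if isinstance(source, dict):
        cfg = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError(f"config {path} is not a mapping")
    if ("inputs" in cfg) == ("synthetic" in cfg):
        raise ConfigError(
            "config must contain exactly one of 'inputs' or 'synthetic'; "
            f"schema:\n{print_schema()}")
    scenario = cfg.get("scenario", "common")
    if scenario not in ("identical", "common"):
        raise ConfigError(f"unknown scenario {scenario!r}")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("transcriptome", "translatome", "metadata"):
            if key not in inputs:
                raise ConfigError(f"inputs block missing {key!r}")
            if not Path(inputs[key]).exists():
                raise ConfigError(f"input file not found: {inputs[key]}")
        if "annotation" in inputs and not Path(inputs["annotation"]).exists():
            raise ConfigError(f"input file not found: {inputs['annotation']}")
    bad = set(cfg) - {"scenario", "inputs", "synthetic", "params"}
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    return cfg


def _pipeline_config(cfg: dict, seed: int | None) -> PipelineConfig:
    params = dict(cfg.get("params", {}) or {})
    known = {f.name for f in fields(PipelineConfig)}
    bad = set(params) - known
    if bad:
        raise ConfigError(f"unknown params: {sorted(bad)}; known: {sorted(known)}")
    try:
        pc = PipelineConfig(**params)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid params: {exc}") from exc
    if seed is not None:
        pc = pc.with_overrides(seed=int(seed))
    return pc


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, outdir, seed: int | None = None) -> dict:
    """Run every stage on one scenario; returns the manifest (also on disk).

    ``config`` is a dict or a YAML path following :data:`CONFIG_SCHEMA`.
    ``seed`` overrides ``params.seed``.
    """
    cfg = load_config(config)
    pc = _pipeline_config(cfg, seed)
    scenario = cfg.get("scenario", "common")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "scenario": scenario,
        "seed": pc.seed,
        "config": {k: (v if k != "params" else dict(v or {}))
                   for k, v in cfg.items()},
        "params": asdict(pc),
        "stages": {},
        "inputs": {},
        "outputs": [],
        "status": "running",
    }
    outputs: list[Path] = []

    def _finish_stage(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s finished in %.2fs", name, manifest["stages"][name]["seconds"])

    def _write(df: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        outputs.append(path)
        return path

    try:
        t0 = time.perf_counter()
        annotation = None
        truth = None
        if "synthetic" in cfg:
            syn = dict(cfg["synthetic"] or {})
            ann_cfg = syn.pop("annotation", None)
            known = {f.name for f in fields(SyntheticConfig)}
            bad = set(syn) - known
            if bad:
                raise ConfigError(f"unknown synthetic keys: {sorted(bad)}")
            syn.setdefault("seed", stage_seed(pc.seed, "synthetic"))
            for key in ("cell_types", "unshared_cell_types", "replicates",
                        "baseline_range"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            try:
                scfg = SyntheticConfig(**syn)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid synthetic block: {exc}") from exc
            em_tr, em_tl, smap, truth = generate_paired_dataset(scfg)
            if ann_cfg:
                annotation = generate_annotation(
                    truth,
                    n_terms=int(ann_cfg.get("n_terms", 20)),
                    background_prob=float(ann_cfg.get("background_prob", 0.05)),
                    planted_prob=float(ann_cfg.get("planted_prob", 0.6)),
                    seed=stage_seed(pc.seed, "annotation"),
                )
            paths = write_dataset(outdir / "inputs", scfg, em_tr, em_tl, smap,
                                  truth, annotation)
            manifest["inputs"] = {k: _sha256(Path(v)) for k, v in paths.items()}
            outputs.extend(Path(v) for v in paths.values())
        else:
            inputs = cfg["inputs"]
            em_tr = load_expression_matrix(inputs["transcriptome"])
            em_tl = load_expression_matrix(inputs["translatome"])
            smap = load_sample_map(inputs["metadata"])
            if "annotation" in inputs:
                annotation = pd.read_csv(inputs["annotation"], sep="\t")
            manifest["inputs"] = {k: _sha256(Path(v)) for k, v in inputs.items()}
        _finish_stage("load", t0)

        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(pc.seed, "coupling"))
        coupling = run_coupling(em_tr, em_tl, smap, scenario, pc, rng=rng)
        _write(coupling, "coupling.tsv")
        _finish_stage("coupling", t0)

        t0 = time.perf_counter()
        rng = np.random.default_rng(stage_seed(pc.seed, "netcons"))
        ec_table, net_summary = run_netcons(em_tr, em_tl, smap, scenario, pc,
                                            rng=rng)
        _write(ec_table, "ec_scores.tsv")
        _write(pd.DataFrame([net_summary]), "network_summary.tsv", index=False)
        from .core_io import aggregate_to_cell_types  # local to avoid cycle noise
        paired = aggregate_to_cell_types(em_tr, em_tl, smap, scenario=scenario,
                                         pooling=pc.pooling)
        gene_sel = list(ec_table.index)
        pos = {g: i for i, g in enumerate(paired.gene_ids)}
        sel = [pos[g] for g in gene_sel]
        for level, X in (("transcriptome", paired.X_tr[sel]),
                         ("translatome", paired.X_tl[sel])):
            A = coexpression_adjacency(X, gene_sel)
            graph = threshold_graph(A, pc.t_edge)
            nodes, edges, transitivity = node_properties(
                graph, alpha_scale=pc.alpha_centrality_scale)
            nodes["graph_transitivity"] = transitivity
            _write(nodes, f"node_properties_{level}.tsv")
            edge_path = outdir / f"edges_{level}.tsv"
            write_edge_list(A, edge_path, t=pc.t_edge)
            outputs.append(edge_path)
        _finish_stage("netcons", t0)

        t0 = time.perf_counter()
        de_table, similarity, cell_types = run_celltype_de(
            em_tr, em_tl, smap, scenario, pc)
        _write(de_table, "de_anova.tsv", index=False)
        _write(similarity, "similarity_vectors.tsv", index=False)
        _finish_stage("celltype_de", t0)

        t0 = time.perf_counter()
        space = MotifSpace(len(cell_types))
        rng = np.random.default_rng(stage_seed(pc.seed, "motifs"))
        motif_table = permutation_motif_test(similarity, space, pc, rng=rng)
        _write(motif_table, "motif_table.tsv", index=False)
        manifest["motif_space_size"] = space.size
        _finish_stage("motifs", t0)

        if annotation is not None:
            t0 = time.perf_counter()
            population = intersect_genes(em_tr, em_tl)
            for cls in ("coupled", "uncoupled"):
                study = list(coupling.index[coupling["coupling_class"] == cls])
                table = enrich(study, annotation, population, q=pc.fdr_q)
                _write(table, f"enrichment_{cls}.tsv", index=False)
            _finish_stage("enrichment", t0)
        else:
            manifest["stages"]["enrichment"] = {"skipped": "no annotation input"}

        manifest["status"] = "complete"
    except Exception:
        manifest["status"] = "failed"
        manifest["outputs"] = sorted(str(p) for p in outputs)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    manifest["outputs"] = sorted(str(p) for p in outputs)
    manifest["checksums"] = {Path(p).name: _sha256(Path(p))
                             for p in manifest["outputs"]}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


DEMO_CONFIG: dict = {
    "scenario": "common",
    "synthetic": {
        "n_genes": 400,
        "annotation": {"n_terms": 20, "background_prob": 0.05,
                       "planted_prob": 0.6},
    },
    "params": {"n_boot": 200, "n_perm": 500},
}
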