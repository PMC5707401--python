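"""End-to-end orchestration: ingest -> calls -> similarity -> benchmark.

A run is described by a small config mapping (usually loaded from YAML):

    bait: BAIT                     # bait gene name
    protocol: adapted              # adapted | conventional
    replicates: [rep1.tsv, ...]    # proteinGroups-dialect tables
    column_map: {}                 # optional header rebinding
    ontology: ontology.obo         # needed for similarity scoring
    annotations: annotations.tsv
    network: network.tsv           # reference network for the null
    categories: categories.yaml    # optional curated scheme
    reference_list: known.txt      # optional known-interactor list
    z_cut: 2.0
    min_reps: 2
    fdr_alpha: 0.10
    namespace: biological_process

Artifacts written to the output directory: the ranked interactome TSV,
normalization metadata YAML, a ratio-intensity plot-data CSV, the
coherence benchmark JSON, the PR-curve CSV, the category tally CSV and
an optional overlap JSON.  Any stage failure is re-raised with the stage
name and partial outputs are removed.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import yaml

from . import benchmark as bm
from . import quant, report, wang, zscore

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir, *, seed: int = 0) -> dict:
    """Execute the full workflow; returns a manifest of written artifacts."""
    cfg = _load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def out(name: str) -> str:
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    try:
        return _run(cfg, out, out_dir, seed)
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.unlink(p)
        raise


def _require(cfg: dict, key: str, stage: str):
    if not cfg.get(key):
        raise PipelineError(stage, f"config is missing required input {key!r}")
    return cfg[key]


def _run(cfg: dict, out, out_dir: str, seed: int) -> dict:
    z_cut = float(cfg.get("z_cut", 2.0))
    min_reps = int(cfg.get("min_reps", 2))
    alpha = float(cfg.get("fdr_alpha", 0.10))
    namespace = cfg.get("namespace", "biological_process")
    bait = cfg.get("bait", "BAIT")
    protocol = cfg.get("protocol", "adapted")
    column_map = cfg.get("column_map") or None

    # --- ingest ------------------------------------------------------
    try:
        paths = _require(cfg, "replicates", "ingest")
        tables, reports = [], {}
        for i, path in enumerate(paths):
            t = quant.read_protein_groups(
                path, column_map, replicate_id=f"rep{i + 1}",
                protocol=protocol)
            ft, rep = quant.apply_quant_filters(t)
            tables.append(ft)
            reports[ft.replicate_id] = rep.__dict__ | {
                "n_survivors": rep.n_survivors}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc

    # --- interactor statistics ---------------------------------------
    try:
        calls, params = zscore.call_interactors(
            tables, z_cut=z_cut, min_reps=min_reps,
            scheme=cfg.get("scheme", "iqr"),
            center_stat=cfg.get("center_stat", "mean"))
        if protocol == "conventional":
            rnase = zscore.rnase_z_scores(tables,
                                          scheme=cfg.get("scheme", "iqr"),
                                          center_stat=cfg.get("center_stat",
                                                              "mean"))
            calls = zscore.classify_rnase(calls, rnase)
        else:
            calls["rna_class"] = "not_applicable"
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    # --- GO similarity ------------------------------------------------
    want_benchmark = bool(cfg.get("network"))
    ontology = annotations = None
    if cfg.get("ontology") or want_benchmark:
        try:
            obo = _require(cfg, "ontology", "gosim")
            ann_path = _require(cfg, "annotations", "gosim")
            ontology = wang.parse_obo(obo)
            annotations = wang.read_annotations(ann_path)
            bait_terms = annotations.get(bait, set())
            calls["wi"] = [
                wang.gene_similarity(
                    bait_terms, annotations.get(g, set()), ontology,
                    namespace=namespace).wi
                for g in calls["gene_name"]]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("gosim", str(exc)) from exc

    # --- coherence benchmark + PR curve ------------------------------
    bench = curve = None
    if want_benchmark:
        try:
            network = bm.read_edge_list(cfg["network"])

            def similarity(u, v):
                return wang.gene_similarity(
                    annotations.get(u, set()), annotations.get(v, set()),
                    ontology, namespace=namespace).wi

            bench = bm.build_null(network, similarity, seed=seed,
                                  mode=cfg.get("null_mode", "auto"),
                                  n_samples=int(cfg.get("null_samples",
                                                        100_000)))
            threshold = bm.empirical_fdr_threshold(bench, alpha)
            bm.compare_distributions(bench)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("benchmark", str(exc)) from exc

        try:
            ranked = list(zip(calls["protein_group_id"], calls["mean_z"]))
            wi_by_id = dict(zip(calls["protein_group_id"], calls["wi"]))
            cutoff_rank = int((calls["mean_z"] >= z_cut).sum())
            curve = bm.precision_recall_curve(
                ranked,
                lambda pid: wi_by_id[pid] >= threshold and wi_by_id[pid] != -1,
                cutoff_rank=cutoff_rank)
        except Exception as exc:
            raise PipelineError("pr", str(exc)) from exc

    # --- categorization and overlap ----------------------------------
    called = calls[calls["is_interactor"]]
    per_gene = tally = None
    if ontology is not None:
        try:
            scheme = (report.load_category_scheme(cfg["categories"])
                      if cfg.get("categories")
                      else report.default_category_scheme())
            per_gene, tally = report.categorize(
                called["gene_name"], annotations, ontology, scheme)
        except Exception as exc:
            raise PipelineError("categorize", str(exc)) from exc

    overlap = None
    if cfg.get("reference_list"):
        try:
            with open(cfg["reference_list"]) as fh:
                ref_ids = [ln.strip() for ln in fh if ln.strip()
                           and not ln.startswith("#")]
            id_map = cfg.get("id_map") or None
            overlap = report.overlap_with_reference(
                called["gene_name"], ref_ids,
                reference_name=os.path.basename(str(cfg["reference_list"])),
                id_map=id_map)
        except Exception as exc:
            raise PipelineError("overlap", str(exc)) from exc

    # --- write artifacts ---------------------------------------------
    manifest = {"out_dir": str(out_dir), "seed": seed, "bait": bait,
                "protocol": protocol, "z_cut": z_cut, "min_reps": min_reps,
                "filter_reports": reports,
                "n_quantified": int(len(calls)),
                "n_interactors": int(called.shape[0])}

    calls.to_csv(out("interactome.tsv"), sep="\t", index=False)
    with open(out("normalization.yaml"), "w") as fh:
        yaml.safe_dump({rid: p.as_dict() for rid, p in params.items()}, fh,
                       sort_keys=True)
    calls[["protein_group_id", "gene_name", "mean_z",
           "mean_log10_intensity"]].to_csv(
        out("ratio_intensity.csv"), index=False)

    if bench is not None:
        with open(out("benchmark.json"), "w") as fh:
            json.dump(bench.summary(), fh, indent=2, sort_keys=True)
        curve.points.to_csv(out("pr_curve.csv"), index=False)
        manifest["wi_threshold"] = bench.wi_threshold
        manifest["mwu_p"] = bench.mwu_p
        manifest["pr_area"] = curve.area()
    if tally is not None:
        cat = pd.DataFrame({"gene_name": per_gene.index,
                            "category": per_gene.values})
        cat.to_csv(out("categories.csv"), index=False)
        manifest["category_tally"] = {k: int(v) for k, v in tally.items()}
    if overlap is not None:
        with open(out("overlap.json"), "w") as fh:
            json.dump(overlap.as_dict(), fh, indent=2, sort_keys=True)
        manifest["overlap"] = overlap.as_dict()
    if protocol == "conventional":
        n_dep = int((called["rna_class"] == "rna_dependent").sum())
        manifest["rna_dependent"] = {"n_dependent": n_dep,
                                     "n_called": int(called.shape[0])}

    with open(out("run_manifest.yaml"), "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
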