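"""Configuration-driven end-to-end runs on synthetic data.

``run_pipeline`` executes the enabled stages in dependency order —
``simulate -> specificity -> annotate -> network -> drugassoc -> axes`` —
inside an output directory, writing each stage's tables as TSV plus a
``manifest.json`` recording the package version, seeds, parameter values
and per-stage row counts. Identical config + seed reproduces identical
outputs byte for byte.

Stage seeds are derived deterministically from the single top-level seed
(fixed offsets), so individual stages are reproducible in isolation too.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    assign_names,
    classify_against_reference,
    detect_readthrough,
    tss_evidence,
    write_bed,
    write_gtf,
)
from .atlas import (
    ExpressionAtlas,
    aggregate_by_lineage,
    call_lineage_specific,
    load_expression,
    prevalence_filter,
    specificity_scores,
    write_expression,
)
from .axes import build_axes, summarize_axes
from .drugs import (
    ElasticNetConfig,
    bootstrap_predictive_scores,
    build_prediction_matrix,
    call_associations,
    spearman_prefilter,
    tune_elastic_net,
)
from .errors import ConfigurationError, DataError
from .network import build_network, summarize_network
from .simulate import (
    AtlasSimConfig,
    DrugSimConfig,
    RegulomeSimConfig,
    make_transcript_models,
    simulate_annotation,
    simulate_drug_response,
    simulate_expression_atlas,
    simulate_regulome,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "specificity", "annotate", "network", "drugassoc", "axes")

DEFAULT_THRESHOLDS = {
    "min_tpm": 0.1,
    "prevalence_fraction": 0.2,
    "fc": 1.5,
    "fdr": 0.05,
    "rho_min": 0.2,
    "rho_fdr_max": 0.05,
    "bootstrap_B": 1000,
    "score_threshold": 0.7,
    "tss_window": 500,
    "specificity_score_min": 1.0,
    "ratio_factor": 2.0,
}


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config (YAML path or dict)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_dict)
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(ALL_STAGES))
    unknown = set(cfg["stages"]) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}")
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for key in ("fdr", "rho_fdr_max", "prevalence_fraction"):
        if not 0 <= thresholds[key] <= 1:
            raise ConfigurationError(f"threshold {key} must lie in [0, 1]")
    if thresholds["bootstrap_B"] < 1:
        raise ConfigurationError("bootstrap_B must be >= 1")
    cfg["thresholds"] = thresholds
    cfg.setdefault("atlas", {})
    cfg.setdefault("drugs", {})
    cfg.setdefault("regulome", {})
    return cfg


def _write(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    return len(df)


def run_pipeline(config, output_dir=None) -> dict:
    """Run the enabled stages; returns the manifest dict (also written to
    ``<output_dir>/manifest.json``)."""
    cfg = load_config(config)
    out = Path(output_dir or cfg.get("output_dir", "txaxes_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    stages = cfg["stages"]
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
        "thresholds": th,
        "counts": {},
        "timings_s": {},
    }
    state: dict = {}

    def tick(stage):
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

    # ---- simulate -------------------------------------------------------
    if "simulate" in stages:
        t0 = time.time()
        atlas_cfg = AtlasSimConfig(**{"seed": seed, **cfg["atlas"]})
        atlas, truth = simulate_expression_atlas(atlas_cfg)
        state["atlas"], state["atlas_truth"] = atlas, truth
        write_expression(atlas, out / "atlas.tsv", out / "lineages.tsv")

        rng = np.random.default_rng(seed + 5)
        labels = pd.DataFrame({
            "transcript_id": atlas.transcript_ids,
            "annotated": rng.random(len(atlas.transcript_ids)) < 0.5,
        })
        state["labels"] = labels
        _write(labels, out / "transcript_labels.tsv")

        drug_cfg = DrugSimConfig(**{"seed": seed + 1, **cfg["drugs"]})
        auc, drug_truth = simulate_drug_response(atlas, drug_cfg)
        state["auc"], state["drug_truth"] = auc, drug_truth
        auc.rename_axis("cell_line").to_csv(out / "drug_auc.tsv", sep="\t")

        models = make_transcript_models(atlas.transcript_ids, seed=seed + 2)
        state["models"] = models
        write_gtf(models.values(), out / "transcript_models.gtf")
        reg_cfg = RegulomeSimConfig(**{"seed": seed + 3, **cfg["regulome"]})
        de_set, peak_set, reg_truth = simulate_regulome(
            atlas.transcript_ids, reg_cfg, models
        )
        state["de_set"], state["peak_set"], state["reg_truth"] = (
            de_set, peak_set, reg_truth,
        )
        de_dir = out / "de_tables"
        peak_dir = out / "peaks"
        de_dir.mkdir(exist_ok=True)
        peak_dir.mkdir(exist_ok=True)
        for rbp, de in de_set.items():
            _write(de, de_dir / f"{rbp}.tsv")
            write_bed(peak_set[rbp], peak_dir / f"{rbp}.bed")
        truth_all = {
            "specific_transcripts": truth.specific_transcripts,
            "drug_drivers": drug_truth.to_dict()["drug_drivers"],
            "regulated": reg_truth.to_dict()["regulated"],
            "bound": reg_truth.bound,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_all, indent=1))
        manifest["counts"]["simulate"] = {
            "transcripts": int(atlas.values.shape[0]),
            "cell_lines": int(atlas.values.shape[1]),
            "drugs": int(auc.shape[1]),
            "rbps": len(de_set),
        }
        manifest["sim_params"] = {
            "atlas": vars(atlas_cfg), "drugs": vars(drug_cfg),
            "regulome": vars(reg_cfg),
        }
        tick("simulate")

    def need(key, stage, loader=None):
        if key in state:
            return state[key]
        if loader is not None:
            value = loader()
            if value is not None:
                state[key] = value
                return value
        raise DataError(
            f"stage '{stage}' needs '{key}' from an upstream stage; enable "
            "'simulate' or point the config at an existing run directory"
        )

    def _load_atlas():
        if (out / "atlas.tsv").exists():
            return load_expression(out / "atlas.tsv", out / "lineages.tsv")
        return None

    # ---- specificity ----------------------------------------------------
    if "specificity" in stages:
        t0 = time.time()
        atlas = need("atlas", "specificity", _load_atlas)
        kept = prevalence_filter(atlas, th["min_tpm"], min_cells=1,
                                 mode="inclusive")
        profile = aggregate_by_lineage(kept)
        scored = call_lineage_specific(
            specificity_scores(profile),
            score_min=th["specificity_score_min"],
            ratio_factor=th["ratio_factor"],
        )
        state["specificity"] = scored
        n = _write(scored.rename_axis("transcript_id"), out / "specificity.tsv",
                   index=True)
        manifest["counts"]["specificity"] = {
            "scored": n,
            "prevalence_removed": int(atlas.values.shape[0] - kept.values.shape[0]),
            "specific": int(scored["is_specific"].sum()),
        }
        tick("specificity")

    # ---- annotate -------------------------------------------------------
    if "annotate" in stages:
        t0 = time.time()
        reference, queries, cage, chromatin, ann_truth = simulate_annotation()
        results = {q.id: classify_against_reference(q, reference) for q in queries}
        for q in queries:
            results[q.id].is_readthrough = detect_readthrough(q, reference)
        assign_names(queries, results, reference)
        cls = pd.DataFrame(
            [
                {
                    "transcript_id": r.transcript_id,
                    "category": r.category,
                    "is_readthrough": r.is_readthrough,
                    "assigned_name": r.assigned_name,
                }
                for r in results.values()
            ]
        )
        calls = tss_evidence(queries, cage, chromatin, window=th["tss_window"])
        ev = pd.DataFrame(
            [
                {"transcript_id": c.transcript_id, "has_cage": c.has_cage,
                 "has_chromatin": c.has_chromatin, "label": c.label}
                for c in calls
            ]
        )
        state["annotation_truth"] = ann_truth
        manifest["counts"]["annotate"] = {
            "classified": _write(cls, out / "classification.tsv"),
            "evidence_calls": _write(ev, out / "evidence.tsv"),
        }
        tick("annotate")

    def _load_de_set():
        de_dir = out / "de_tables"
        if de_dir.is_dir():
            return {
                p.stem: pd.read_csv(p, sep="\t")
                for p in sorted(de_dir.glob("*.tsv"))
            }
        return None

    def _load_peak_set():
        from .annotation import read_bed

        peak_dir = out / "peaks"
        if peak_dir.is_dir():
            return {p.stem: read_bed(p) for p in sorted(peak_dir.glob("*.bed"))}
        return None

    def _load_models():
        from .annotation import parse_gtf

        path = out / "transcript_models.gtf"
        if path.exists():
            return {m.id: m for m in parse_gtf(path)}
        return None

    # ---- network --------------------------------------------------------
    if "network" in stages:
        t0 = time.time()
        de_set = need("de_set", "network", _load_de_set)
        peak_set = need("peak_set", "network", _load_peak_set)
        models = need("models", "network", _load_models)
        edges = build_network(de_set, peak_set, models,
                              fc_threshold=th["fc"], fdr_threshold=th["fdr"])
        state["edges"] = edges
        summaries = summarize_network(edges)
        n = _write(edges, out / "edges.tsv")
        _write(summaries["per_rbp"], out / "network_per_rbp.tsv")
        manifest["counts"]["network"] = {"edges": n}
        tick("network")

    # ---- drugassoc ------------------------------------------------------
    if "drugassoc" in stages:
        t0 = time.time()
        atlas = need("atlas", "drugassoc", _load_atlas)
        auc = need("auc", "drugassoc", lambda: (
            pd.read_csv(out / "drug_auc.tsv", sep="\t", index_col=0)
            if (out / "drug_auc.tsv").exists() else None
        ))
        kept = prevalence_filter(
            atlas, th["min_tpm"], min_fraction=th["prevalence_fraction"],
            mode="strict",
        )
        prefilter = spearman_prefilter(
            kept, auc, rho_min=th["rho_min"], fdr_max=th["rho_fdr_max"]
        )
        _write(prefilter, out / "prefilter.tsv")
        assoc_rows = []
        encfg = ElasticNetConfig(search_seed=seed + 10)
        for j, drug in enumerate(auc.columns):
            passing = prefilter.query("drug_id == @drug and passes")
            if passing.empty:
                continue
            cells = atlas.cell_line_ids.intersection(auc.index)
            y_all = auc.loc[cells, drug]
            cells = y_all.dropna().index
            X = build_prediction_matrix(kept, passing["transcript_id"], cells)
            if X.shape[1] == 0:
                continue
            y = y_all.loc[cells].to_numpy()
            encfg.search_seed = seed + 10 + j
            alpha, lam, _ = tune_elastic_net(X, y, encfg)
            scores = bootstrap_predictive_scores(
                X, y, alpha, lam, B=th["bootstrap_B"], seed=seed + 100 + j
            )
            scores = scores.join(
                passing.set_index("transcript_id")[["rho", "fdr"]], how="left"
            )
            scores["drug_id"] = drug
            scores["alpha"] = alpha
            scores["lambda"] = lam
            assoc_rows.append(scores.reset_index())
        columns = ["transcript_id", "drug_id", "rho", "fdr", "f_pos", "f_neg",
                   "B", "score", "direction", "alpha", "lambda"]
        all_scores = (
            pd.concat(assoc_rows, ignore_index=True)[columns]
            if assoc_rows else pd.DataFrame(columns=columns)
        )
        associations = call_associations(all_scores,
                                         threshold=th["score_threshold"])
        state["associations"] = associations
        _write(all_scores, out / "bootstrap_scores.tsv")
        n = _write(associations, out / "associations.tsv")
        manifest["counts"]["drugassoc"] = {
            "pairs_evaluated": int(len(prefilter)),
            "pairs_passing_prefilter": int(prefilter["passes"].sum()),
            "associations": n,
        }
        tick("drugassoc")

    # ---- axes -----------------------------------------------------------
    if "axes" in stages:
        t0 = time.time()
        edges = need("edges", "axes", lambda: (
            pd.read_csv(out / "edges.tsv", sep="\t")
            if (out / "edges.tsv").exists() else None
        ))
        associations = need("associations", "axes", lambda: (
            pd.read_csv(out / "associations.tsv", sep="\t")
            if (out / "associations.tsv").exists() else None
        ))
        axes = build_axes(edges, associations)
        labels = state.get("labels")
        annotated_of = (
            labels.set_index("transcript_id")["annotated"]
            if labels is not None else None
        )
        summary = summarize_axes(axes, annotated_of)
        n = _write(axes, out / "axes.tsv")
        (out / "axes_summary.json").write_text(json.dumps(summary, indent=1))
        manifest["counts"]["axes"] = {"axes": n, **summary}
        tick("axes")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline finished: %s", out)
    return manifest
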