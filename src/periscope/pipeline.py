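"""End-to-end orchestration from a single YAML config to a result bundle.

Stage order: inputs (read or simulate) → preprocess → enrichment /
deconvolution / TCR diversity → PICS clustering / composite scores →
response model per arm → survival stratification.  Every run writes a
manifest recording the config, seeds and content hashes of the inputs
and outputs; a rerun with an identical config and seed reproduces
byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import (
    add_monocyte_aggregate,
    build_reference,
    estimate_fractions,
    reference_from_marker_sets,
)
from .enrichment import ssgsea_scores
from .io_formats import (
    SampleTable,
    ValidationError,
    read_clonotypes,
    read_count_matrix,
    read_gmt,
    read_sample_table,
    summarize_response_rates,
    write_clonotypes,
    write_count_matrix,
    write_gmt,
    write_sample_table,
)
from .model import build_features, cross_validate, fit_model, predict_prob, roc_auc
from .pics import annotate_clusters, assign_pics, composition_change, fit_pics
from .preprocess import batch_center, filter_genes, normalize_transform
from .scores import chemotaxis_score, composite_score, score_delta
from .survival import km_fit, stratify_by_score
from .synthetic import CHEMOTAXIS_SET, SUPERTYPE_MAP, SimulationConfig, simulate_cohort
from .tcr import diversity_delta, diversity_records, records_frame

__all__ = ["run_pipeline", "write_simulation"]

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write every fixture file plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, samples, clonotypes, sets, truth = simulate_cohort(config)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_count_matrix(counts, paths["counts"])
    write_sample_table(samples, paths["samples"])
    write_gmt(sets, paths["gene_sets"])
    clone_dir = out / "clonotypes"
    clone_dir.mkdir(exist_ok=True)
    for sid, table in clonotypes.items():
        write_clonotypes(table, clone_dir / f"{sid}.tsv")
    truth_payload = {
        "fractions": truth.fractions.round(10).to_dict(orient="index"),
        "gene_celltype": truth.gene_celltype.to_dict(),
        "effector_panel": truth.effector_panel,
        "patient_effects": truth.patient_effects.round(10).to_dict(orient="records"),
        "config": truth.config,
    }
    paths["truth"].write_text(json.dumps(_to_plain(truth_payload), sort_keys=True, indent=1))
    paths["clonotype_dir"] = clone_dir
    return paths


def _load_inputs(cfg: dict, seed: int):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        for key in ("timepoints", "arms"):
            if key in sim:
                sim[key] = tuple(sim[key])
        counts, samples, clonotypes, sets, truth = simulate_cohort(SimulationConfig(**sim))
        panel = truth.effector_panel
        return counts, samples, clonotypes, sets, panel, truth
    if "inputs" not in cfg:
        raise ValidationError("config must provide either 'simulate' or 'inputs'")
    inp = cfg["inputs"]
    counts = read_count_matrix(inp["counts"], inp.get("counts_format", "tsv"))
    samples = read_sample_table(inp["samples"])
    sets = read_gmt(inp["gene_sets"])
    clonotypes = {}
    if inp.get("clonotype_dir"):
        for path in sorted(Path(inp["clonotype_dir"]).glob("*.tsv")):
            table = read_clonotypes(path)
            clonotypes[table.sample_id] = table
    panel = cfg.get("scores", {}).get("panel")
    if panel is None:
        raise ValidationError("scores.panel (the composite gene panel) is required for file inputs")
    return counts, samples, clonotypes, sets, panel, None


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Run every stage from a config path (YAML) or dict; returns a summary.

    Result tables, model JSONs and a reproducibility manifest are
    written under ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text())
        config_path: Path | None = Path(config)
    else:
        cfg = dict(config)
        config_path = None
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts, samples, clonotypes, sets, panel, truth = _load_inputs(cfg, seed)
    log.info("inputs: %d genes x %d samples, %d gene sets", *counts.shape, len(sets))

    # ---- preprocess
    pp = cfg.get("preprocess", {})
    filtered = filter_genes(counts, pp.get("min_expressed_fraction", 0.5))
    values = normalize_transform(filtered, pp.get("transform", "vst_like"))
    if pp.get("batch_center") and "batch" in samples.frame.columns:
        batches = samples.frame.set_index("sample_id")["batch"]
        protected = samples.frame.set_index("sample_id")["clinical_subtype"]
        values = batch_center(values, batches, protected)

    # ---- enrichment scores on immune-cell sets
    en = cfg.get("enrichment", {})
    chemo_set = cfg.get("scores", {}).get("chemotaxis_set", CHEMOTAXIS_SET)
    immune_sets = sets.subset([n for n in sets if n != chemo_set])
    scores = ssgsea_scores(
        values,
        immune_sets,
        weight=en.get("weight", 0.25),
        min_set_size=en.get("min_set_size", 5),
    )
    scores.to_frame().to_csv(out / "enrichment_scores.tsv", sep="\t")

    # ---- deconvolution
    dc = cfg.get("deconvolution", {})
    if truth is not None:
        ref = build_reference(truth.profiles, immune_sets)
    else:
        ref = reference_from_marker_sets(immune_sets, fold=dc.get("marker_fold", 6.0))
    fractions = estimate_fractions(values, ref, mode=dc.get("mode", "absolute"))
    try:
        frac_table = add_monocyte_aggregate(fractions)
    except ValidationError:
        frac_table = fractions.to_frame()
    frac_table.to_csv(out / "cell_fractions.tsv", sep="\t")

    # ---- TCR diversity
    records = diversity_records(clonotypes.values()) if clonotypes else []
    if records:
        records_frame(records).to_csv(out / "tcr_diversity.tsv", sep="\t", index=False)
        diversity_delta(records, samples).to_csv(out / "tcr_diversity_delta.tsv", sep="\t", index=False)

    # ---- PICS clustering on Baseline + EarlyTreatment samples
    pc = cfg.get("pics", {})
    cluster_samples = list(
        samples.select(timepoint=["Baseline", "EarlyTreatment"])["sample_id"]
    )
    pics_scores = ssgsea_scores(
        values.subset_samples(cluster_samples),
        immune_sets,
        weight=en.get("weight", 0.25),
        min_set_size=en.get("min_set_size", 5),
    )
    pics_model = fit_pics(
        pics_scores, k=pc.get("k", 7), linkage_method=pc.get("linkage", "complete")
    )
    supertype_map = pc.get("supertype_map", SUPERTYPE_MAP)
    supertype_map = {
        k: [m for m in v if m in pics_model.set_names] for k, v in supertype_map.items()
    }
    supertype_map = {k: v for k, v in supertype_map.items() if v}
    if supertype_map:
        annotate_clusters(pics_model, supertype_map)
    labels = assign_pics(pics_model, pics_scores)
    labels_df = labels.rename_axis("sample_id").reset_index()
    labels_df["annotation"] = labels_df["pics_cluster"].map(pics_model.annotations)
    labels_df.to_csv(out / "pics_labels.tsv", sep="\t", index=False)
    composition_change(labels, samples).to_csv(
        out / "pics_composition_change.tsv", sep="\t", index=False
    )

    # ---- composite scores
    tcell = composite_score(values, panel)
    chemo = chemotaxis_score(values, sets, chemo_set)
    pd.DataFrame(
        {"tcell_composite": tcell.scores, "leukocyte_chemotaxis": chemo.scores}
    ).rename_axis("sample_id").to_csv(out / "composite_scores.tsv", sep="\t")
    score_delta(tcell, samples).to_csv(out / "tcell_composite_delta.tsv", sep="\t", index=False)

    # ---- response model per arm
    if not records:
        raise ValidationError(
            "response model needs the baseline TCR Shannon feature; "
            "no clonotype tables were provided"
        )
    md = cfg.get("model", {})
    arms = md.get("arms", ["ChemoPembro", "Chemo"])
    summary: dict[str, Any] = {
        "seed": seed,
        "n_genes_input": counts.shape[0],
        "n_genes_filtered": filtered.shape[0],
        "n_samples": counts.shape[1],
        "response_rates": summarize_response_rates(samples).to_dict(orient="records"),
        "arms": {},
    }
    for arm in arms:
        arm_meta = SampleTable(samples.select(arm=arm))
        if not len(arm_meta):
            log.warning("arm %s: no samples; skipped", arm)
            continue
        features = build_features(tcell, chemo, records, arm_meta)
        model = fit_model(features, cohort_id=arm)
        probs = predict_prob(model, features)
        roc = roc_auc(features.frame["response"].to_numpy(), probs.to_numpy())
        cv = cross_validate(
            features,
            n_folds=md.get("n_folds", 10),
            threshold=md.get("threshold", 0.5),
            seed=seed,
        )
        arm_out: dict[str, Any] = {
            "n_patients": len(features),
            "coefficients": model.coefficients.round(10).to_dict(),
            "separable": model.separable,
            "auc": roc.auc,
            "auc_ci": [roc.ci_low, roc.ci_high],
            "auc_p_vs_half": roc.p_vs_half,
            "optimal_cutoff": roc.optimal_cutoff,
            "youden_j": roc.youden_j,
            "cv_kappa": cv.kappa,
            "cv_kappa_youden_cutoff": cv.kappa_youden,
        }
        roc.roc_points.to_csv(out / f"roc_{arm}.tsv", sep="\t", index=False)
        # ---- survival stratification at the optimal cutoff
        pats = arm_meta.patients().set_index("patient_id")
        if "drfs_time" in pats.columns and pats["drfs_time"].notna().any():
            common = [p for p in features.frame.index if p in pats.index]
            surv = pats.loc[common].dropna(subset=["drfs_time", "drfs_event"])
            groups = stratify_by_score(probs[surv.index].to_numpy(), roc.optimal_cutoff)
            if len(set(groups)) == 2:
                fit = km_fit(
                    surv["drfs_time"].to_numpy(), surv["drfs_event"].to_numpy(int), groups
                )
                arm_out["drfs_logrank_chi2"] = fit.chi_square
                arm_out["drfs_logrank_p"] = fit.p_value
                arm_out["drfs_group_sizes"] = fit.group_sizes
        summary["arms"][arm] = arm_out
        (out / f"model_{arm}.json").write_text(
            json.dumps(_to_plain(arm_out), sort_keys=True, indent=1)
        )

    # ---- manifest
    outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "periscope_version": __version__,
        "seed": seed,
        "config": _to_plain(cfg),
        "config_file": str(config_path) if config_path else None,
        "input_hashes": {
            k: _sha256(Path(v))
            for k, v in (cfg.get("inputs", {}) or {}).items()
            if isinstance(v, str) and Path(v).is_file()
        },
        "output_hashes": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(_to_plain(manifest), sort_keys=True, indent=1))
    summary["outputs"] = [p.name for p in outputs]
    return summary
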