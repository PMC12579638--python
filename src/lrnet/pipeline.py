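"""Stage orchestration: each stage reads upstream artifacts plus the config
and writes its own outputs, recording provenance in a manifest.

Stages and their artifacts (all under ``config.output_dir``):

========== ==============================================================
simulate    interactions.tsv, metadata.tsv, ground_truth.json,
            survival_cohort.tsv
frequencies frequencies.tsv, frequency_tests.tsv, frequency_log2fc.tsv
impute      rank_matrix.tsv, imputation_report.json, imputed_matrix.tsv
select      selection.tsv, pruning.json
oplsda      oplsda_model.json, oplsda_scores.tsv
network     conetwork.graphml, conetwork.edges.tsv
survival    lr_scores.tsv, survival_results.json, km_curves.tsv
========== ==============================================================
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import frequency as freq_mod
from . import imputation as imp_mod
from . import io as io_mod
from . import network as net_mod
from . import oplsda as opls_mod
from . import stability as stab_mod
from . import survival as surv_mod
from . import synthetic as syn_mod
from .config import PipelineConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "frequencies",
    "impute",
    "select",
    "oplsda",
    "network",
    "survival",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _record_manifest(
    outdir: Path, stage: str, inputs: list[Path], outputs: list[Path], seed: int, settings: dict
) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[stage] = {
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
        "seed": seed,
        "settings": settings,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _interactions_path(config: PipelineConfig, outdir: Path) -> Path:
    path = Path(config.interactions) if config.interactions else outdir / "interactions.tsv"
    if not path.exists():
        raise FileNotFoundError(
            f"interaction table {path} not found; run `simulate` or point "
            "`interactions` at your data"
        )
    return path


def _metadata_path(config: PipelineConfig, outdir: Path) -> Path:
    path = Path(config.metadata) if config.metadata else outdir / "metadata.tsv"
    if not path.exists():
        raise FileNotFoundError(f"metadata table {path} not found")
    return path


def _two_group_labels(
    annotations: dict[str, io_mod.SampleAnnotation], group_by: str
) -> pd.Series:
    values = {
        s: getattr(a, group_by) for s, a in annotations.items()
    }
    labels = pd.Series(values, name=group_by)
    labels = labels[labels != "unknown"]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(
            f"grouping column {group_by!r} must yield exactly two groups, got {groups}"
        )
    return labels


def run_simulate(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    seed = config.seed_for("simulate")
    sim = syn_mod.SimulationConfig(
        n_samples_per_group=config.sim_samples_per_group,
        n_cell_types=config.sim_cell_types,
        n_lr_pairs=config.sim_lr_pairs,
        n_discriminative=config.sim_discriminative,
        rank_shift=config.sim_rank_shift,
        missing_rate=config.sim_missing_rate,
        seed=seed,
    )
    records, annotations, truth = syn_mod.simulate_interaction_cohort(sim)
    interactions = outdir / "interactions.tsv"
    metadata = outdir / "metadata.tsv"
    io_mod.write_interaction_table(records, interactions)
    io_mod.write_metadata(annotations, metadata)

    # survival cohort over the genes of the planted discriminative features
    genes = sorted(
        {g for key in truth.discriminative_keys for g in (*key.ligand, *key.receptor)}
    ) or [f"GENE{i:02d}" for i in range(10)]
    cohort, surv_truth = syn_mod.simulate_survival_cohort(
        n_patients=config.sim_survival_patients,
        genes=genes,
        hazard_ratio=config.sim_hazard_ratio,
        censor_rate=config.sim_censor_rate,
        seed=config.seed_for("simulate_survival"),
    )
    survival_path = outdir / "survival_cohort.tsv"
    surv_mod.write_survival_cohort(cohort, survival_path)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "discriminative_features": sorted(
                    io_mod.key_to_label(k) for k in truth.discriminative_keys
                ),
                "group_of_sample": truth.group_of_sample,
                "survival_cluster_of_patient": surv_truth.survival_cluster_of_patient,
                "true_hazard_ratio": surv_truth.true_hazard_ratio,
            },
            indent=2,
            sort_keys=True,
        )
    )
    outputs = [interactions, metadata, survival_path, truth_path]
    _record_manifest(outdir, "simulate", [], outputs, seed, {"sim": asdict(sim)})
    return outputs


def run_frequencies(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    interactions = _interactions_path(config, outdir)
    metadata = _metadata_path(config, outdir)
    records = io_mod.read_interaction_tables([interactions])
    annotations = io_mod.read_metadata(metadata)
    filtered = {
        s: freq_mod.filter_significant(recs, config.aggregate_rank_cutoff)
        for s, recs in records.items()
    }
    cell_types = sorted(
        {r.key.sender for recs in records.values() for r in recs}
        | {r.key.receiver for recs in records.values() for r in recs}
    )
    matrix = freq_mod.pair_frequencies(filtered, cell_types)
    freq_path = outdir / "frequencies.tsv"
    matrix.to_csv(freq_path, sep="\t")

    labels = _two_group_labels(annotations, config.group_by)
    common = matrix.index.intersection(labels.index)
    tests = freq_mod.compare_pair_frequencies(matrix.loc[common], labels.loc[common])
    tests_path = outdir / "frequency_tests.tsv"
    tests.to_csv(tests_path, sep="\t")

    a, b = sorted(labels.unique())
    fc = freq_mod.median_log2_fc(
        matrix.loc[labels[labels == a].index.intersection(matrix.index)],
        matrix.loc[labels[labels == b].index.intersection(matrix.index)],
        pseudocount=config.fc_pseudocount,
    )
    fc_path = outdir / "frequency_log2fc.tsv"
    freq_mod.long_format(fc).to_csv(fc_path, sep="\t", index=False)
    outputs = [freq_path, tests_path, fc_path]
    _record_manifest(
        outdir,
        "frequencies",
        [interactions, metadata],
        outputs,
        config.seed,
        {"cutoff": config.aggregate_rank_cutoff, "groups": [a, b]},
    )
    return outputs


def run_impute(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    interactions = _interactions_path(config, outdir)
    metadata = _metadata_path(config, outdir)
    records = io_mod.read_interaction_tables([interactions])
    annotations = io_mod.read_metadata(metadata)
    matrix = io_mod.build_rank_matrix(records, annotations)
    matrix_path = outdir / "rank_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")

    params = {
        "n_trees": config.rf_trees,
        "max_iter": config.rf_max_iter,
        "k": config.knn_k,
        "seed": config.imputation_seed,
    }
    if matrix.isna().any().any():
        report = imp_mod.threshold_sweep(
            matrix, config.imputer, seed=config.imputation_seed, imputer_params=params
        )
        filtered = imp_mod.missingness_filter(matrix, report.chosen_threshold)
        imputed = imp_mod.impute(filtered, report.chosen_imputer, **params)
        threshold = report.chosen_threshold
    else:
        logger.info("matrix already complete; skipping sweep")
        report = None
        imputed = matrix.copy()
        threshold = 0.0
    report_path = outdir / "imputation_report.json"
    if report is not None:
        report.to_json(report_path)
    else:
        report_path.write_text(json.dumps({"note": "matrix complete; no imputation"}))
    imputed_path = outdir / "imputed_matrix.tsv"
    imputed.to_csv(imputed_path, sep="\t")
    outputs = [matrix_path, report_path, imputed_path]
    _record_manifest(
        outdir,
        "impute",
        [interactions, metadata],
        outputs,
        config.imputation_seed,
        {"imputer": config.imputer, "chosen_threshold": threshold},
    )
    return outputs


def run_select(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    imputed_path = outdir / "imputed_matrix.tsv"
    if not imputed_path.exists():
        raise FileNotFoundError(f"{imputed_path} missing; run the impute stage first")
    metadata = _metadata_path(config, outdir)
    matrix = pd.read_csv(imputed_path, sep="\t", index_col=0)
    annotations = io_mod.read_metadata(metadata)
    labels = _two_group_labels(annotations, config.group_by)
    common = matrix.index.intersection(labels.index)
    X = stab_mod.log10_transform(matrix.loc[common])
    y = labels.loc[common]

    exclusion: dict[str, str] = {}
    if config.exclusion_list:
        exclusion = stab_mod.read_exclusion_list(config.exclusion_list)
    seed = config.seed_for("select")
    selection, pruning = stab_mod.prune_and_rerun(
        X,
        y,
        exclusion,
        alpha=config.alpha,
        n_repeats=config.n_repeats,
        retention=config.retention,
        seed=seed,
    )
    selection_path = outdir / "selection.tsv"
    selection.to_frame().to_csv(selection_path, sep="\t", index=False)
    pruning_path = outdir / "pruning.json"
    pruning_path.write_text(
        json.dumps(
            [
                {
                    "iteration": r.iteration,
                    "excluded": [list(t) for t in r.excluded_features],
                    "retained_after": sorted(r.retained_after),
                }
                for r in pruning
            ],
            indent=2,
        )
    )
    outputs = [selection_path, pruning_path]
    _record_manifest(
        outdir,
        "select",
        [imputed_path, metadata],
        outputs,
        seed,
        {"alpha": config.alpha, "n_repeats": config.n_repeats, "retention": config.retention},
    )
    return outputs


def _retained_features(outdir: Path) -> list[str]:
    selection_path = outdir / "selection.tsv"
    if not selection_path.exists():
        raise FileNotFoundError(f"{selection_path} missing; run the select stage first")
    frame = pd.read_csv(selection_path, sep="\t")
    retained = frame.loc[frame["retained"], "feature"].tolist()
    if not retained:
        raise ValueError("no retained features; nothing to model")
    return retained


def run_oplsda(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    retained = _retained_features(outdir)
    imputed_path = outdir / "imputed_matrix.tsv"
    metadata = _metadata_path(config, outdir)
    matrix = pd.read_csv(imputed_path, sep="\t", index_col=0)
    annotations = io_mod.read_metadata(metadata)
    labels = _two_group_labels(annotations, config.group_by)
    common = matrix.index.intersection(labels.index)
    X = stab_mod.log10_transform(matrix.loc[common, retained])
    y = labels.loc[common]
    seed = config.seed_for("oplsda")
    try:
        stage1, stage2, final_features = opls_mod.two_stage_fit(
            X,
            y,
            k=config.cv_folds,
            n_permutations=config.n_permutations,
            seed=seed,
            n_orthogonal=config.n_orthogonal,
            vip_cutoff=config.vip_cutoff,
        )
    except ValueError as exc:
        if "VIP" not in str(exc):
            raise
        # degenerate stage 1 (e.g. a single retained feature has VIP exactly
        # 1): fall back to a single-stage model on all retained columns
        logger.warning("VIP filter left no features (%s); using a single-stage model", exc)
        stage1 = opls_mod.fit_oplsda(X, y, n_orthogonal=config.n_orthogonal)
        stage2 = opls_mod.fit_oplsda(X, y, n_orthogonal=config.n_orthogonal)
        stage2.cv_accuracy = opls_mod.cross_validate(
            X, y, k=config.cv_folds, seed=seed, n_orthogonal=config.n_orthogonal
        )
        stage2.permutation = opls_mod.permutation_test(
            X, y, k=config.cv_folds, n_permutations=config.n_permutations,
            seed=seed, n_orthogonal=config.n_orthogonal,
        )
        final_features = list(X.columns)
    model_path = outdir / "oplsda_model.json"
    model_path.write_text(
        json.dumps(
            {
                "stage1_vip": stage1.vip.round(10).to_dict(),
                "stage2_vip": stage2.vip.round(10).to_dict(),
                "final_features": final_features,
                "cv_accuracy": stage2.cv_accuracy,
                "permutation": {
                    "n_permutations": stage2.permutation.n_permutations,
                    "observed_metric": stage2.permutation.observed_metric,
                    "k_at_least": stage2.permutation.k_at_least,
                    "p_value": stage2.permutation.p_value,
                },
            },
            indent=2,
            sort_keys=True,
        )
    )
    scores_path = outdir / "oplsda_scores.tsv"
    scores = pd.DataFrame(
        {
            "sample_id": list(common),
            "label": y.to_numpy(),
            "predictive_score": stage2.predictive_scores,
        }
    )
    if stage2.orthogonal_scores.shape[1]:
        scores["orthogonal_score_1"] = stage2.orthogonal_scores[:, 0]
    scores.to_csv(scores_path, sep="\t", index=False)
    outputs = [model_path, scores_path]
    _record_manifest(
        outdir,
        "oplsda",
        [imputed_path, metadata],
        outputs,
        seed,
        {"cv_folds": config.cv_folds, "n_permutations": config.n_permutations},
    )
    return outputs


def run_network(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    retained = _retained_features(outdir)
    matrix_path = outdir / "rank_matrix.tsv"
    if not matrix_path.exists():
        raise FileNotFoundError(f"{matrix_path} missing; run the impute stage first")
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    edges = net_mod.pairwise_pearson(retained, matrix, min_overlap=config.min_overlap)
    per_center = net_mod.top_k_edges(edges, k=config.top_k_correlates)
    for center in retained:  # centers with no valid partner remain isolated
        per_center.setdefault(center, [])
    graphml, tsv = net_mod.export_network(per_center, outdir / "conetwork")
    outputs = [graphml, tsv]
    _record_manifest(
        outdir,
        "network",
        [matrix_path],
        outputs,
        config.seed,
        {"top_k": config.top_k_correlates, "min_overlap": config.min_overlap},
    )
    return outputs


def run_survival(config: PipelineConfig) -> list[Path]:
    outdir = _outdir(config)
    cohort_path = (
        Path(config.survival_cohort)
        if config.survival_cohort
        else outdir / "survival_cohort.tsv"
    )
    if not cohort_path.exists():
        raise FileNotFoundError(f"survival cohort {cohort_path} not found")
    cohort = surv_mod.read_survival_cohort(cohort_path)

    retained = _retained_features(outdir)
    pairs = []
    seen = set()
    table_genes = {str(c).upper() for c in cohort.z.columns}
    for label in retained:
        key = io_mod.label_to_key(label)
        pair = (key.ligand, key.receptor)  # cell type deliberately dropped
        if pair in seen:
            continue
        seen.add(pair)
        if any(g.upper() in table_genes for g in (*key.ligand, *key.receptor)):
            pairs.append(pair)
        else:
            logger.warning("pair %s has no measurable gene; skipped", label)
    if not pairs:
        raise ValueError("no retained pair has measurable genes in the cohort")

    scores = surv_mod.lr_scores(cohort, pairs)
    scores_path = outdir / "lr_scores.tsv"
    scores.to_csv(scores_path, sep="\t")

    k = min(config.clusters_k, len(scores))
    cohort.cluster = surv_mod.ward_cluster(scores, k=k)
    high, low = 1, k  # clusters renumbered by descending mean score
    if k == 1:
        raise ValueError("clusters_k must be >= 2 for a survival comparison")
    curves, chi2, logrank_p = surv_mod.km_logrank(cohort, (high, low))
    hr, (lo, hi) = surv_mod.cox_hr_5yr(cohort, reference=high, comparison=low)

    km_path = outdir / "km_curves.tsv"
    km_frames = []
    for label, curve in curves.items():
        curve = curve.copy()
        curve.insert(0, "cluster", label)
        km_frames.append(curve)
    pd.concat(km_frames).to_csv(km_path, sep="\t", index=False)

    results_path = outdir / "survival_results.json"
    results_path.write_text(
        json.dumps(
            {
                "cluster_sizes": cohort.cluster.value_counts().sort_index().to_dict(),
                "comparison": {"high_cluster": high, "low_cluster": low},
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
                "hazard_ratio_low_vs_high": hr,
                "hr_ci95": [lo, hi],
            },
            indent=2,
            sort_keys=True,
            default=int,
        )
    )
    outputs = [scores_path, km_path, results_path]
    _record_manifest(
        outdir,
        "survival",
        [cohort_path],
        outputs,
        config.seed,
        {"clusters_k": k},
    )
    return outputs


def run_all(config: PipelineConfig) -> list[Path]:
    """Chain frequencies -> impute -> select -> oplsda -> network, plus
    survival when a cohort is available."""
    outputs: list[Path] = []
    outputs += run_frequencies(config)
    outputs += run_impute(config)
    outputs += run_select(config)
    outputs += run_oplsda(config)
    outputs += run_network(config)
    outdir = _outdir(config)
    cohort_path = (
        Path(config.survival_cohort)
        if config.survival_cohort
        else outdir / "survival_cohort.tsv"
    )
    if cohort_path.exists():
        outputs += run_survival(config)
    return outputs
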