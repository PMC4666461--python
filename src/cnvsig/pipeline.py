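"""End-to-end pipeline: segment -> associate -> target genes -> classify -> evaluate.

`run_study` executes the whole method on one synthetic study: CBS calls on
the training copy-number profiles, per-endpoint Fisher scans and region
aggregation, per-region SAM screens with directional fold filters, the union
of the two endpoints' target-gene sets, a shrunken-centroid model trained on
the five-year endpoint, median-match normalization of the second validation
batch, validation predictions, and survival/recovery evaluation against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import association as assoc
from . import classifier as clf
from . import cna, cohort, survival as surv
from . import targets as tg


@dataclass
class PipelineParams:
    """Analysis-stage parameters (the generator's knobs live in StudyConfig)."""

    cbs_alpha: float = 0.01
    cbs_n_perm: int = 200
    cbs_min_width: int = 2
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    assoc_alpha: float = 0.05
    max_gap_mb: float = 11.5
    min_clones: int = 1
    sam_n_perm: int = 200
    fdr_target: float = 0.10
    two_x: float = 2.0
    three_x: float = 3.0
    delta_grid: int = 20
    cv_folds: int = 10


@dataclass
class StudyResult:
    study: cohort.Study
    params: PipelineParams
    calls: pd.DataFrame
    associations: dict[str, pd.DataFrame]
    regions: dict[str, list[assoc.GenomicRegion]]
    target_sets: dict[str, list[tg.TargetGeneSet]]
    gene_sets: dict[str, dict[str, set[str]]]
    combined_set: dict[str, set[str]]
    model: clf.CentroidModel | None
    predictions: pd.Series | None
    report: surv.EvaluationReport
    multivariate: pd.DataFrame | None = None
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def _region_targets(
    study: cohort.Study,
    calls: pd.DataFrame,
    regions: list[assoc.GenomicRegion],
    endpoint: str,
    params: PipelineParams,
    seed: int,
) -> list[tg.TargetGeneSet]:
    """SAM screen + fold filters for every region with enough samples/probes."""
    sets: list[tg.TargetGeneSet] = []
    normals = list(study.normal_expr.columns)
    expr = study.train_expr
    for r_idx, region in enumerate(regions):
        probes = tg.map_probes_to_region(study.probe_annotation, region)
        if not probes:
            continue
        rep_calls = calls.loc[region.representative_clone]
        altered = list(rep_calls.index[rep_calls == region.alteration_type])
        neutral = list(rep_calls.index[rep_calls == cohort.NORMAL])
        if len(altered) < 2 or len(neutral) < 2:
            continue
        sub = expr.loc[probes, altered + neutral]
        sam = tg.sam_screen(sub, altered, n_perm=params.sam_n_perm,
                            fdr_target=params.fdr_target,
                            seed=seed + 31 * r_idx)
        if not sam.selected:
            continue
        expr_all = pd.concat([expr, study.normal_expr], axis=1)
        folds = tg.fold_changes(expr_all.loc[probes], altered, neutral, normals,
                                region.alteration_type)
        sets.append(tg.select_targets(sam, folds, region, endpoint,
                                      params.two_x, params.three_x))
    return sets


def run_study(
    config: cohort.StudyConfig | None = None,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> StudyResult:
    """Simulate one study and run the full analysis on it."""
    params = PipelineParams() if params is None else params
    study = cohort.simulate_study(config, seed)
    return analyze_study(study, params)


def analyze_study(study: cohort.Study, params: PipelineParams | None = None
                  ) -> StudyResult:
    params = PipelineParams() if params is None else params
    seed = study.seed

    segments = cna.segment_matrix(study.train_cn, study.clone_map,
                                  alpha=params.cbs_alpha,
                                  n_perm=params.cbs_n_perm,
                                  min_width=params.cbs_min_width,
                                  seed=seed)
    calls = cna.call_alterations(study.train_cn, study.clone_map, segments,
                                 params.gain_threshold, params.loss_threshold)

    associations: dict[str, pd.DataFrame] = {}
    regions: dict[str, list[assoc.GenomicRegion]] = {}
    target_sets: dict[str, list[tg.TargetGeneSet]] = {}
    gene_sets: dict[str, dict[str, set[str]]] = {}
    for endpoint in (assoc.ENDPOINT_2YDFS, assoc.ENDPOINT_5YDSS):
        labels = assoc.derive_endpoint_labels(study.train_outcomes, endpoint)
        scan = assoc.associate_all(calls, labels, study.clone_map)
        found = assoc.build_regions(scan, study.clone_map,
                                    alpha=params.assoc_alpha,
                                    max_gap_mb=params.max_gap_mb,
                                    min_clones=params.min_clones)
        associations[endpoint] = scan
        regions[endpoint] = found
        target_sets[endpoint] = _region_targets(study, calls, found, endpoint,
                                                params, seed)
        gene_sets[endpoint] = tg.endpoint_gene_set(target_sets[endpoint], endpoint)

    combined = tg.combine_gene_sets(gene_sets[assoc.ENDPOINT_2YDFS],
                                    gene_sets[assoc.ENDPOINT_5YDSS])

    # train on the five-year endpoint with the combined gene set
    train_labels = assoc.derive_endpoint_labels(study.train_outcomes,
                                                assoc.ENDPOINT_5YDSS)
    eligible = train_labels[train_labels.isin([assoc.GOOD, assoc.POOR])]
    model, predictions = None, None
    multivariate = None
    km_curves: dict[str, pd.DataFrame] = {}
    probe_list = sorted(combined)
    if probe_list and eligible.nunique() == 2:
        model = clf.nsc_train(study.train_expr.loc[probe_list, eligible.index],
                              eligible, delta_grid=params.delta_grid,
                              cv_folds=params.cv_folds, seed=seed)
        # validation: normalize batch 2 onto batch 1 before predicting
        batches = study.val_batches
        val1 = list(batches.index[batches == "val1"])
        val2 = list(batches.index[batches == "val2"])
        val_expr = study.val_expr.loc[probe_list]
        if val2:
            matched = clf.median_match_normalize(val_expr[val2], val_expr[val1])
            val_expr = pd.concat([val_expr[val1], matched], axis=1)
        predictions = clf.nsc_predict(model, val_expr).predicted

    val_labels = assoc.derive_endpoint_labels(study.val_outcomes,
                                              assoc.ENDPOINT_5YDSS)
    val_eligible = val_labels[val_labels.isin([assoc.GOOD, assoc.POOR])]

    survival_df = None
    if predictions is not None:
        survival_df = pd.DataFrame({
            "time": study.val_outcomes["followup_months"],
            "event": study.val_outcomes["death_from_disease_flag"].astype(int),
            "group": predictions.reindex(study.val_outcomes.index),
        })
        if survival_df["group"].nunique() == 2:
            km_curves = surv.km_estimate(survival_df)
        risk = study.val_outcomes["igcccg_risk"]
        outcome01 = (val_eligible == assoc.POOR).astype(int)
        pred01 = (predictions.reindex(val_eligible.index) == assoc.POOR).astype(int)
        multivariate = surv.multivariate_model(outcome01, pred01,
                                               risk.reindex(val_eligible.index))

    found_union = {r.label: r for eps in regions.values() for r in eps}
    report = surv.evaluate_pipeline(
        truth_regions=study.regions,
        found_regions=list(found_union.values()),
        dosage_probe_ids=study.dosage_probe_ids,
        selected_probes=probe_list,
        predicted=(None if predictions is None
                   else predictions.reindex(val_eligible.index)),
        actual=val_eligible if len(val_eligible) else None,
        survival=survival_df,
        seed=seed,
        config=study.config.to_dict())

    return StudyResult(study=study, params=params, calls=calls,
                       associations=associations, regions=regions,
                       target_sets=target_sets, gene_sets=gene_sets,
                       combined_set=combined, model=model,
                       predictions=predictions, report=report,
                       multivariate=multivariate, km_curves=km_curves)
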