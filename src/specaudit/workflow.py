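"""End-to-end drivers chaining the pipeline stages.

Simulation -> hard filtering -> site matrix -> off-target prediction ->
attribution -> per-plant counts.  Used by the analysis scripts, the CLI
and the acceptance checks; each stage remains individually importable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import (
    ClassifiedVariant,
    attribution_summary,
    classify_variants,
    count_table,
    on_target_windows,
)
from .io import calls_from_records, site_depths_from_records
from .offtargets import (
    OffTargetSite,
    predict_crispr_offtargets,
    predict_talen_offtargets,
)
from .pipeline import VariantMatrix, build_site_matrix, filter_calls
from .simulate import (
    ExperimentResult,
    SimulationConfig,
    simulate_experiment,
    simulate_reference,
)


@dataclass
class AuditResult:
    """Everything one audit run produces."""

    experiment: ExperimentResult
    matrix: VariantMatrix
    predicted_sites: list[OffTargetSite]
    classified: list[ClassifiedVariant]
    counts: pd.DataFrame
    summary: dict


def predict_all_offtargets(genome, specs) -> list[OffTargetSite]:
    sites: list[OffTargetSite] = []
    for spec in specs:
        if spec.kind == "crispr":
            sites.extend(predict_crispr_offtargets(genome, spec))
        else:
            sites.extend(predict_talen_offtargets(genome, spec))
    return sites


def audit_experiment(
    experiment: ExperimentResult,
    specs,
    window_bp: int = 50,
) -> AuditResult:
    """Run filtering, matrix assembly and attribution on one experiment."""
    active = [s for s in experiment.samples if not s.excluded]
    sample_ids = [s.sample_id for s in active]
    calls = calls_from_records(experiment.records, sample_ids)
    filtered = filter_calls(calls)
    depths = site_depths_from_records(experiment.records)
    matrix = build_site_matrix(filtered, experiment.samples, depths)
    predicted = predict_all_offtargets(experiment.genome, specs)
    windows = on_target_windows(specs)
    classified = classify_variants(
        matrix, experiment.samples, windows, predicted, window_bp=window_bp
    )
    kinds = {spec.nuclease_id: spec.kind for spec in specs}
    counts = count_table(classified, experiment.samples, kinds)
    return AuditResult(
        experiment=experiment,
        matrix=matrix,
        predicted_sites=predicted,
        classified=classified,
        counts=counts,
        summary=attribution_summary(classified),
    )


def run_synthetic_audit(config: SimulationConfig) -> AuditResult:
    """Simulate one experiment under ``config`` and audit it."""
    genome = simulate_reference(config)
    experiment = simulate_experiment(config, genome)
    return audit_experiment(experiment, config.nuclease_specs)


def truth_recovery_metrics(result: AuditResult) -> dict:
    """Score the classifier's output against the simulator's truth labels.

    On-target and polymorphism recovery are measured over all truth sites
    (a site lost to the coverage-in-all-samples rule counts as missed).
    ``planted_offtarget_as_polymorphism`` counts the worst possible
    confusion: a true nuclease off-target mutation attributed to standing
    variation.
    """
    from .simulate import site_truth_labels

    truth_sites = site_truth_labels(result.experiment.truth)
    classified = {v.site_id: v.category for v in result.classified}
    poly = {"ref_polymorphism", "lineage_polymorphism"}

    def recovery(label_set: set[str]) -> tuple[int, int]:
        sub = truth_sites[truth_sites.category.isin(label_set)]
        hit = sum(classified.get(sid) == cat
                  for sid, cat in zip(sub.site_id, sub.category))
        return hit, len(sub)

    on_hit, on_total = recovery({"on_target"})
    on_classified = sum(
        sid in classified
        for sid in truth_sites[truth_sites.category == "on_target"].site_id
    )
    poly_hit, poly_total = recovery(poly)
    planted = truth_sites[truth_sites.category == "planted_off_target"]
    planted_as_poly = sum(classified.get(sid) in poly for sid in planted.site_id)
    planted_as_offtarget = sum(
        classified.get(sid) == "predicted_off_target_hit" for sid in planted.site_id
    )
    return {
        "on_target_total": on_total,
        "on_target_classified": on_classified,
        "on_target_recovered": on_hit,
        "on_target_recovery_pct": 100.0 * on_hit / on_total if on_total else None,
        "polymorphism_total": poly_total,
        "polymorphism_recovered": poly_hit,
        "polymorphism_recovery_pct": (
            100.0 * poly_hit / poly_total if poly_total else None
        ),
        "planted_offtarget_total": len(planted),
        "planted_offtarget_as_polymorphism": planted_as_poly,
        "planted_offtarget_recovered": planted_as_offtarget,
    }
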