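"""End-to-end orchestration: gate -> cluster -> metacluster -> stratify.

`analyze_cohort` wires the stages together with the study defaults
(27 clusters per sample, 19 metaclusters, rare filter at 3 member
clusters, 0.5% population cutoff, 3 patient groups) and returns every
intermediate product for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_gating import (
    DEFAULT_PANEL, EventMatrix, MarkerPanel, apply_gate, auto_thresholds, gate_nk,
)
from .mixture import MixtureOptions, cluster_cohort
from .metacluster import (
    AnnotationRule, DEFAULT_ANNOTATION_RULES, Dendrogram, Metacluster,
    RescaledCenters, annotate, build_metaclusters, cut_dendrogram, filter_rare,
    hcl, rescale_centers,
)
from .cohort import (
    DEFAULT_CATEGORY_MAP, FrequencyMatrix, PatientGrouping,
    exclude_rare_populations, maturation_summary, population_frequencies,
    stratify_patients,
)
from .stats import group_report

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    n_clusters: int = 27
    n_metaclusters: int = 19
    min_metacluster_members: int = 3
    rare_population_threshold: float = 0.5  # % of NK, cohort-wide mean
    n_patient_groups: int = 3
    mixture: MixtureOptions = field(default_factory=MixtureOptions)
    panel: MarkerPanel = DEFAULT_PANEL
    annotation_rules: Sequence[AnnotationRule] = field(
        default_factory=lambda: list(DEFAULT_ANNOTATION_RULES)
    )
    category_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MAP)
    )


@dataclass
class PipelineResult:
    gate_thresholds: dict[str, float]
    cluster_table: pd.DataFrame
    failed_samples: list[str]
    rescaled: RescaledCenters
    dendrogram: Dendrogram
    metaclusters: list[Metacluster]
    frequencies_all: FrequencyMatrix  # every named population
    frequencies: FrequencyMatrix  # after the rare-population exclusion
    grouping: PatientGrouping | None
    maturation: pd.DataFrame
    report: pd.DataFrame | None


def analyze_cohort(
    samples: Sequence[EventMatrix],
    metadata: pd.DataFrame | None = None,
    gate_thresholds: Mapping[str, float] | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full unsupervised NK profiling pipeline on a cohort.

    When ``gate_thresholds`` is None, cutoffs are derived per channel from
    the first sample with the midpoint-between-modes rule. Patients are
    stratified on T0 rows only; healthy-donor samples (metadata
    ``subject_type`` != 'patient') are excluded from stratification but
    processed through clustering like any other sample.
    """
    params = params or PipelineParams()
    panel = params.panel
    if gate_thresholds is None:
        channels = list(panel.dump_markers) + [
            panel.viability_marker, panel.nk_markers[0], panel.nk_markers[1]
        ]
        gate_thresholds = auto_thresholds(samples[0], channels)
    thresholds = dict(gate_thresholds)

    gated = [apply_gate(s, gate_nk(s, thresholds, panel)) for s in samples]
    cluster_table, failed = cluster_cohort(
        gated, params.n_clusters, params.mixture, channels=panel.nk_markers
    )

    rescaled = rescale_centers(cluster_table, markers=panel.nk_markers)
    dend = hcl(rescaled)
    labels = cut_dendrogram(dend, params.n_metaclusters)
    metas = annotate(
        filter_rare(
            build_metaclusters(rescaled, labels), params.min_metacluster_members
        ),
        params.annotation_rules,
    )

    freq_all = population_frequencies(cluster_table, metas)
    freq = exclude_rare_populations(freq_all, params.rare_population_threshold)

    t0 = freq.timepoint_view("T0")
    if metadata is not None and "subject_type" in metadata.columns:
        patients = set(
            metadata.loc[metadata["subject_type"] == "patient", "patient_id"]
        )
        t0 = t0.loc[[p for p in t0.index if p in patients]]
    grouping = None
    if len(t0) >= params.n_patient_groups:
        grouping = stratify_patients(t0, params.n_patient_groups)

    maturation = maturation_summary(freq.frequencies, params.category_map)

    report = None
    if metadata is not None and grouping is not None:
        report = group_report(t0, metadata, grouping.assignments)

    return PipelineResult(
        gate_thresholds=thresholds,
        cluster_table=cluster_table,
        failed_samples=failed,
        rescaled=rescaled,
        dendrogram=dend,
        metaclusters=metas,
        frequencies_all=freq_all,
        frequencies=freq,
        grouping=grouping,
        maturation=maturation,
        report=report,
    )


__all__ = ["PipelineParams", "PipelineResult", "analyze_cohort"]
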