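"""Patient-level analysis: population frequencies, stratification, kinetics.

Event counts per (sample, cluster) are converted into a patients x
populations matrix of percentages of total gated NK events; populations
whose cohort-wide mean frequency falls below 0.5% are excluded; patients
are stratified at T0 by hierarchical clustering of their frequency
vectors, and the resulting groups are named X/Y/Z by matching group
medians to the signature populations (X: CD56dim NKG2A+ high;
Y: CD56dim CD57+ high; Z: CD56dim triple-negative high). Maturation
summaries aggregate populations into the Progenitors / Effectors /
Intermediate / Mature / Dysfunctional categories and sum all CD57+ cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic as _syn
from .metacluster import Dendrogram, Metacluster, UNCLASSIFIED, cut_dendrogram, hcl

logger = logging.getLogger(__name__)

RARE_POPULATION_THRESHOLD = 0.5  # % of total NK, cohort-wide mean

#: reconstruction of the maturation categories (fully overridable):
#: Progenitors = CD56bright variants; Effectors = CD56dim NKG2A+ (+-NKG2C);
#: Intermediate = CD56dim triple-negative and NKG2C+ CD57-; Mature = all
#: CD56dim CD57+ variants; Dysfunctional = CD56neg / CD16low variants.
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    _syn.P_BRIGHT: "Progenitors",
    _syn.P_BRIGHT_LOW: "Progenitors",
    _syn.P_A: "Effectors",
    _syn.P_AC: "Effectors",
    _syn.P_TN: "Intermediate",
    _syn.P_C: "Intermediate",
    _syn.P_57: "Mature",
    _syn.P_C57: "Mature",
    _syn.P_A57: "Mature",
    _syn.P_NEG_A: "Dysfunctional",
    _syn.P_NEG_57: "Dysfunctional",
    _syn.P_NEG: "Dysfunctional",
    _syn.P_DIM_LOW: "Dysfunctional",
}

CATEGORY_ORDER = (
    "Progenitors", "Effectors", "Intermediate", "Mature", "Dysfunctional"
)

#: populations whose group medians identify the X/Y/Z maturation profiles
GROUP_SIGNATURE_POPULATIONS = {
    "X": _syn.P_A,
    "Y": _syn.P_57,
    "Z": _syn.P_TN,
}


def split_sample_id(sample_id: str) -> tuple[str, str]:
    """'P01_T0' -> ('P01', 'T0')."""
    patient, _, timepoint = sample_id.rpartition("_")
    if not patient:
        raise ValueError(f"sample id {sample_id!r} is not '<patient>_<timepoint>'")
    return patient, timepoint


@dataclass
class FrequencyMatrix:
    """Samples x named populations, as % of total gated NK events.

    Row sums can be below 100 when unclassified or rare-metacluster mass
    is present; that mass stays in the denominator. Empty samples carry
    NaN rows and are listed in ``empty_samples``.
    """

    frequencies: pd.DataFrame  # index: sample_id, columns: population names
    total_events: pd.Series  # gated NK events per sample
    empty_samples: list[str]

    @property
    def populations(self) -> list[str]:
        return list(self.frequencies.columns)

    def unassigned_pct(self) -> pd.Series:
        """Mass per sample not carried by any named population."""
        return 100.0 - self.frequencies.sum(axis=1)

    def timepoint_view(self, timepoint: str) -> pd.DataFrame:
        """Rows of one timepoint, re-indexed by patient id."""
        rows = [
            sid for sid in self.frequencies.index
            if split_sample_id(sid)[1] == timepoint
        ]
        out = self.frequencies.loc[rows].copy()
        out.index = [split_sample_id(sid)[0] for sid in rows]
        return out

    def save(self, path) -> None:
        self.frequencies.to_csv(path, sep="\t", float_format="%.6g")


def population_frequencies(
    cluster_table: pd.DataFrame, metaclusters: Sequence[Metacluster]
) -> FrequencyMatrix:
    """Pivot pooled cluster records into the frequency matrix.

    Each (sample, cluster) maps through its metacluster to a population
    name; metaclusters sharing a name are pooled; unretained or
    unclassified metaclusters contribute to the denominator only.
    """
    key_to_name: dict[tuple, str] = {}
    names: set[str] = set()
    for m in metaclusters:
        name = m.name if m.retained else UNCLASSIFIED
        if name != UNCLASSIFIED:
            names.add(name)
        for key in m.members:
            key_to_name[key] = name
    missing = [
        key for key in zip(cluster_table["sample_id"], cluster_table["cluster_id"])
        if key not in key_to_name
    ]
    if missing:
        raise ValueError(f"clusters not covered by any metacluster: {missing[:5]}")

    columns = sorted(names)
    sample_ids = list(dict.fromkeys(cluster_table["sample_id"]))
    counts = pd.DataFrame(0.0, index=sample_ids, columns=columns)
    totals = pd.Series(0.0, index=sample_ids)
    for sid, cid, count in zip(
        cluster_table["sample_id"], cluster_table["cluster_id"],
        cluster_table["event_count"],
    ):
        totals[sid] += count
        name = key_to_name[(sid, cid)]
        if name != UNCLASSIFIED:
            counts.loc[sid, name] += count

    empty = [sid for sid in sample_ids if totals[sid] == 0]
    if empty:
        logger.warning("samples with zero gated events: %s", empty)
    freq = 100.0 * counts.div(totals.replace(0.0, np.nan), axis=0)
    return FrequencyMatrix(
        frequencies=freq, total_events=totals.astype(int), empty_samples=empty
    )


def exclude_rare_populations(
    matrix: FrequencyMatrix, threshold: float = RARE_POPULATION_THRESHOLD
) -> FrequencyMatrix:
    """Drop populations whose cohort-wide mean frequency is strictly below
    ``threshold`` percent of total NK cells."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = matrix.frequencies.mean(axis=0, skipna=True)
    keep = [p for p in matrix.populations if not means[p] < threshold]
    if not keep:
        raise ValueError("the rare-population filter removed every population")
    dropped = sorted(set(matrix.populations) - set(keep))
    if dropped:
        logger.info("excluded rare populations (<%.2f%%): %s", threshold, dropped)
    return FrequencyMatrix(
        frequencies=matrix.frequencies[keep].copy(),
        total_events=matrix.total_events,
        empty_samples=list(matrix.empty_samples),
    )


@dataclass
class PatientGrouping:
    """T0 patient stratification with post-hoc X/Y/Z naming."""

    assignments: dict[str, str]  # patient -> group label
    n_groups: int
    patient_dendrogram: Dendrogram
    population_dendrogram: Dendrogram | None
    labels_named: bool  # False when X/Y/Z matching was ambiguous

    def group_of(self, patient: str) -> str:
        return self.assignments[patient]

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def members(self, label: str) -> list[str]:
        return [p for p, g in self.assignments.items() if g == label]

    def save(self, path) -> None:
        pd.Series(self.assignments, name="group").rename_axis("patient_id").to_csv(
            path, sep="\t"
        )


def stratify_patients(
    frequencies: pd.DataFrame,
    n_groups: int = 3,
    metric: str = "euclidean",
    method: str = "average",
    signature_populations: Mapping[str, str] = GROUP_SIGNATURE_POPULATIONS,
) -> PatientGrouping:
    """Hierarchically cluster patient frequency vectors into ``n_groups``.

    ``frequencies`` is the T0 patients x populations table (raw
    percentages; no re-standardisation). Groups are named by matching each
    target label's signature population to the group with the highest
    median; if two labels pick the same group, the generic G1..Gn labels
    are kept and a warning logged. A population dendrogram (for the
    two-way heatmap display) is computed alongside.
    """
    if len(frequencies) < n_groups:
        raise ValueError("fewer patients than groups")
    dend = hcl(frequencies, metric=metric, method=method)
    raw = cut_dendrogram(dend, n_groups)
    patients = list(frequencies.index)
    col_dend = (
        hcl(frequencies.T, metric=metric, method=method)
        if frequencies.shape[1] >= 2
        else None
    )

    label_map: dict[int, str] = {}
    named = True
    if signature_populations and set(signature_populations.values()) <= set(
        frequencies.columns
    ) and len(signature_populations) == n_groups:
        claimed: dict[int, str] = {}
        for label, pop in signature_populations.items():
            medians = {
                g: float(np.median(frequencies[pop].to_numpy()[raw == g]))
                for g in range(n_groups)
            }
            winner = max(medians, key=medians.get)
            if winner in claimed:
                logger.warning(
                    "group naming ambiguous: %s and %s both match cluster %d",
                    claimed[winner], label, winner,
                )
                named = False
                break
            claimed[winner] = label
        if named:
            label_map = claimed
    else:
        named = False
    if not named:
        label_map = {g: f"G{g + 1}" for g in range(n_groups)}

    assignments = {p: label_map[int(g)] for p, g in zip(patients, raw)}
    return PatientGrouping(
        assignments=assignments,
        n_groups=n_groups,
        patient_dendrogram=dend,
        population_dendrogram=col_dend,
        labels_named=named,
    )


def maturation_summary(
    frequencies: pd.DataFrame,
    category_map: Mapping[str, str] = DEFAULT_CATEGORY_MAP,
) -> pd.DataFrame:
    """Per-sample maturation aggregates (% of NK).

    Columns: the five maturation categories plus ``cd57_total``, the sum
    over all populations whose name contains 'CD57+'. Every population in
    the matrix must be covered by ``category_map``.
    """
    unmapped = [p for p in frequencies.columns if p not in category_map]
    if unmapped:
        raise ValueError(f"populations missing from category_map: {unmapped}")
    out = pd.DataFrame(index=frequencies.index)
    for cat in CATEGORY_ORDER:
        cols = [p for p in frequencies.columns if category_map[p] == cat]
        out[cat] = frequencies[cols].sum(axis=1) if cols else 0.0
    cd57_cols = [p for p in frequencies.columns if "CD57+" in p]
    out["cd57_total"] = frequencies[cd57_cols].sum(axis=1) if cd57_cols else 0.0
    return out


def group_median_summary(
    per_sample: pd.DataFrame, grouping: PatientGrouping
) -> pd.DataFrame:
    """Group medians of any per-patient table (rows indexed by patient)."""
    rows = {}
    for label in grouping.groups:
        members = [p for p in grouping.members(label) if p in per_sample.index]
        rows[label] = per_sample.loc[members].median(axis=0)
    return pd.DataFrame(rows).T


def suppression_table(
    metadata: pd.DataFrame,
    grouping: PatientGrouping | Mapping[str, str],
    threshold_copies: float = _syn.SUPPRESSION_THRESHOLD_COPIES,
    combine: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-group viral suppression at M3: counts and percentage of patients
    with HIV-RNA below ``threshold_copies`` copies/mL. ``combine`` adds rows
    pooling several groups (e.g. {'X+Z': ['X', 'Z']}). Percentages are exact
    arithmetic (100*k/n)."""
    assign = grouping.assignments if isinstance(grouping, PatientGrouping) else dict(grouping)
    m3 = metadata[metadata["timepoint"] == "M3"]
    cut = float(np.log10(threshold_copies))
    by_group: dict[str, tuple[int, int]] = {}
    for label in sorted(set(assign.values())):
        patients = [p for p, g in assign.items() if g == label]
        rows = m3[m3["patient_id"].isin(patients)]
        n = len(rows)
        k = int((rows["hiv_rna"] < cut).sum())
        by_group[label] = (k, n)
    records = [
        {"group": g, "n_suppressed": k, "n": n,
         "pct": 100.0 * k / n if n else float("nan")}
        for g, (k, n) in by_group.items()
    ]
    for name, members in (combine or {}).items():
        k = sum(by_group.get(m, (0, 0))[0] for m in members)
        n = sum(by_group.get(m, (0, 0))[1] for m in members)
        records.append(
            {"group": name, "n_suppressed": k, "n": n,
             "pct": 100.0 * k / n if n else float("nan")}
        )
    return pd.DataFrame(records)


__all__ = [
    "FrequencyMatrix", "PatientGrouping",
    "population_frequencies", "exclude_rare_populations", "stratify_patients",
    "maturation_summary", "group_median_summary", "suppression_table",
    "split_sample_id", "DEFAULT_CATEGORY_MAP", "CATEGORY_ORDER",
    "GROUP_SIGNATURE_POPULATIONS", "RARE_POPULATION_THRESHOLD",
]
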