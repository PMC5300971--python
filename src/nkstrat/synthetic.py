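"""Synthetic primary-HIV cohort generator.

Emulates the data structure the downstream analysis assumes: ~30 patients
sampled before cART (T0) and at month 3 (M3) plus a healthy donor, each
sample a 9-channel NK-panel event table (CD56/CD16/NKG2A/NKG2C/CD57 +
CD3/CD14/CD19 dump + viability), drawn from a mixture of 13 NK maturation
phenotypes whose per-group frequency centers reproduce the published
group medians:

* group X (n=14) dominated by CD56dim NKG2A+ cells (34% of NK),
* group Y (n=10) dominated by mature CD57+ cells (Mature aggregate 39%),
* group Z (n=4) dominated by CD56dim NKG2A-NKG2C-CD57- cells (42.6%).

Event-level intensities are diagonal Gaussians on a transformed scale with
level grid neg=0, low=1, dim=2.5, bright/high=4. Patient-level frequency
noise is logistic-normal (multiplicative log-normal jitter, renormalised
to the simplex). Clinical metadata are drawn from group-specific ranges
with assay detection-limit behaviour: HIV-RNA floored at 20 copies/mL and
undetectable IL-6 imputed at 0.46 pg/mL (half the detection limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_gating import DEFAULT_PANEL, EventMatrix, MarkerPanel, write_events

# ---------------------------------------------------------------------------
# phenotype definitions

LEVEL_GRID = {"neg": 0.0, "low": 1.0, "dim": 2.5, "bright": 4.0, "high": 4.0}
DEFAULT_EVENT_SD = 0.30

P_BRIGHT = "CD56bright"
P_BRIGHT_LOW = "CD56bright CD16low"
P_A = "CD56dim NKG2A+"
P_AC = "CD56dim NKG2A+NKG2C+"
P_A57 = "CD56dim NKG2A+CD57+"
P_C = "CD56dim NKG2C+"
P_C57 = "CD56dim NKG2C+CD57+"
P_57 = "CD56dim CD57+"
P_TN = "CD56dim NKG2A-NKG2C-CD57-"
P_NEG_A = "CD56neg CD16+ NKG2A+"
P_NEG_57 = "CD56neg CD16+ CD57+"
P_NEG = "CD56neg CD16+"
P_DIM_LOW = "CD56dim CD16low"

#: fixed order used for frequency vectors everywhere
DEFAULT_PHENOTYPE_NAMES = (
    P_BRIGHT, P_BRIGHT_LOW,
    P_A, P_AC, P_A57, P_C, P_C57, P_57, P_TN,
    P_NEG_A, P_NEG_57, P_NEG, P_DIM_LOW,
)

CONTAMINANT_LABEL = "contaminant"

# marker level per phenotype, in panel order CD56/CD16/NKG2A/NKG2C/CD57
_PHENOTYPE_LEVELS: dict[str, tuple[str, str, str, str, str]] = {
    P_BRIGHT:    ("bright", "neg", "high", "neg", "neg"),
    P_BRIGHT_LOW: ("bright", "low", "high", "neg", "neg"),
    P_A:         ("dim", "high", "high", "neg", "neg"),
    P_AC:        ("dim", "high", "high", "high", "neg"),
    P_A57:       ("dim", "high", "high", "neg", "high"),
    P_C:         ("dim", "high", "neg", "high", "neg"),
    P_C57:       ("dim", "high", "neg", "high", "high"),
    P_57:        ("dim", "high", "neg", "neg", "high"),
    P_TN:        ("dim", "high", "neg", "neg", "neg"),
    P_NEG_A:     ("neg", "high", "high", "neg", "neg"),
    P_NEG_57:    ("neg", "high", "neg", "neg", "high"),
    P_NEG:       ("neg", "high", "neg", "neg", "neg"),
    P_DIM_LOW:   ("dim", "low", "neg", "neg", "neg"),
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """A named NK phenotype: marker levels and the Gaussian they generate."""

    name: str
    levels: dict[str, str]
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        for marker in DEFAULT_PANEL.nk_markers:
            if marker not in self.levels or marker not in self.means:
                raise ValueError(f"{self.name}: missing level/mean for {marker}")
            if self.sds[marker] <= 0:
                raise ValueError(f"{self.name}: sd must be > 0 for {marker}")


def build_default_phenotypes(event_sd: float = DEFAULT_EVENT_SD) -> list[PhenotypeSpec]:
    """The 13 NK maturation phenotypes: 2 CD56bright, 7 CD56dim variants
    (NKG2A/NKG2C/CD57 combinations) and 4 CD56neg/CD16low dysfunctional
    variants. Any two specs differ by >= 3 sd on at least one marker."""
    specs = []
    for name, levels in _PHENOTYPE_LEVELS.items():
        level_map = dict(zip(DEFAULT_PANEL.nk_markers, levels))
        specs.append(
            PhenotypeSpec(
                name=name,
                levels=level_map,
                means={m: LEVEL_GRID[lv] for m, lv in level_map.items()},
                sds={m: event_sd for m in DEFAULT_PANEL.nk_markers},
            )
        )
    return specs


# ---------------------------------------------------------------------------
# group profiles

@dataclass
class GroupProfile:
    """Per-group frequency centers (% of NK) and metadata distributions."""

    label: str
    n_patients: int
    freq_center: dict[str, float]
    freq_spread: float = 0.15  # sd of the log-normal jitter on the simplex
    metadata_centers: dict[str, tuple[float, float, float] | None] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if any(v < 0 for v in self.freq_center.values()):
            raise ValueError("frequency centers must be >= 0")
        if sum(self.freq_center.values()) > 100 + 1e-9:
            raise ValueError("frequency centers must sum to <= 100")


# Frequency centers (% of NK). The four signature populations carry the
# published group medians (CD56dim NKG2A+ 34/13.8/14.3; CD56dim CD57+
# 21 in Y; CD56dim NKG2C+CD57+ 17.8 in Y; triple-negative 42.6 in Z);
# category totals follow the published group table where compatible; the
# CD56neg CD16+ CD57+ population is planted below the 0.5% analysis cutoff.
_FREQ_X = {
    P_BRIGHT: 5.7, P_BRIGHT_LOW: 2.0,
    P_A: 34.0, P_AC: 15.2, P_A57: 1.0, P_C: 3.0, P_C57: 2.9, P_57: 2.9, P_TN: 17.5,
    P_NEG_A: 8.7, P_NEG_57: 0.3, P_NEG: 4.0, P_DIM_LOW: 2.8,
}
_FREQ_Y = {
    P_BRIGHT: 3.0, P_BRIGHT_LOW: 1.0,
    P_A: 13.8, P_AC: 7.0, P_A57: 0.2, P_C: 6.7, P_C57: 17.8, P_57: 21.0, P_TN: 16.0,
    P_NEG_A: 5.5, P_NEG_57: 0.3, P_NEG: 4.0, P_DIM_LOW: 3.7,
}
_FREQ_Z = {
    P_BRIGHT: 4.3, P_BRIGHT_LOW: 2.0,
    P_A: 14.3, P_AC: 1.0, P_A57: 0.1, P_C: 5.3, P_C57: 0.9, P_57: 7.2, P_TN: 42.6,
    P_NEG_A: 10.0, P_NEG_57: 0.3, P_NEG: 6.0, P_DIM_LOW: 6.0,
}
_FREQ_HEALTHY = {
    P_BRIGHT: 5.0, P_BRIGHT_LOW: 1.0,
    P_A: 18.0, P_AC: 2.0, P_A57: 2.0, P_C: 2.0, P_C57: 5.0, P_57: 25.0, P_TN: 30.0,
    P_NEG_A: 2.0, P_NEG_57: 0.3, P_NEG: 3.0, P_DIM_LOW: 4.7,
}

# metadata field -> (median, low, high); virology is None for healthy donors
_META_X = {
    "cd4": (549, 323, 1012), "cd8": (2148, 502, 8157),
    "hiv_rna": (5.77, 4.6, 7.0), "hiv_dna": (3.8, 3.2, 4.7),
    "il6": (3.5, 0.2, 15.0), "ip10": (800, 150, 2500),
    "pdc_pct": (0.15, 0.02, 0.35), "mdc_pct": (0.15, 0.02, 0.35),
    "cd38_mfi": (5.0, 2.0, 9.0), "cd86_mfi": (4.0, 1.5, 8.0), "pdl1_mfi": (3.5, 1.5, 7.0),
}
_META_Y = {
    "cd4": (584, 368, 864), "cd8": (1308, 417, 2716),
    "hiv_rna": (4.88, 3.2, 5.7), "hiv_dna": (3.5, 2.8, 4.3),
    "il6": (1.2, 0.2, 4.0), "ip10": (300, 80, 900),
    "pdc_pct": (0.30, 0.10, 0.55), "mdc_pct": (0.30, 0.10, 0.50),
    "cd38_mfi": (3.0, 1.5, 6.0), "cd86_mfi": (2.0, 1.0, 4.0), "pdl1_mfi": (1.5, 0.8, 3.0),
}
_META_Z = {
    "cd4": (430, 341, 513), "cd8": (1415, 1140, 1966),
    "hiv_rna": (6.05, 5.6, 7.0), "hiv_dna": (3.9, 3.2, 4.5),
    "il6": (3.0, 0.2, 12.0), "ip10": (700, 150, 2000),
    "pdc_pct": (0.15, 0.02, 0.30), "mdc_pct": (0.15, 0.02, 0.30),
    "cd38_mfi": (4.5, 2.0, 8.0), "cd86_mfi": (3.5, 1.5, 7.0), "pdl1_mfi": (3.0, 1.2, 6.0),
}
_META_HEALTHY = {
    "cd4": (900, 500, 1400), "cd8": (600, 300, 900),
    "hiv_rna": None, "hiv_dna": None,
    "il6": (0.8, 0.2, 2.0), "ip10": (100, 40, 250),
    "pdc_pct": (0.45, 0.25, 0.70), "mdc_pct": (0.33, 0.15, 0.55),
    "cd38_mfi": (1.0, 0.5, 2.0), "cd86_mfi": (1.0, 0.5, 2.0), "pdl1_mfi": (1.0, 0.5, 2.0),
}

METADATA_FIELDS = tuple(_META_X)

#: assay floors: HIV-RNA quantification limit (copies/mL, stored as log10)
#: and the IL-6 imputation value for undetectable samples (pg/mL)
HIV_RNA_FLOOR_COPIES = 20.0
HIV_RNA_FLOOR_LOG10 = float(np.log10(HIV_RNA_FLOOR_COPIES))
IL6_DETECTION_LIMIT = 0.92
IL6_IMPUTED = 0.46
SUPPRESSION_THRESHOLD_COPIES = 50.0


def default_group_profiles() -> list[GroupProfile]:
    return [
        GroupProfile("X", 14, dict(_FREQ_X), metadata_centers=dict(_META_X)),
        GroupProfile("Y", 10, dict(_FREQ_Y), metadata_centers=dict(_META_Y)),
        GroupProfile("Z", 4, dict(_FREQ_Z), metadata_centers=dict(_META_Z)),
    ]


def healthy_profile() -> GroupProfile:
    return GroupProfile(
        "H", 1, dict(_FREQ_HEALTHY), metadata_centers=dict(_META_HEALTHY)
    )


#: gate cutoffs implied by the generator's level grid (used by tests and the
#: default pipeline on synthetic data; real data go through auto_thresholds)
TRUTH_GATE_THRESHOLDS = {
    "CD3": 2.0, "CD14": 2.0, "CD19": 2.0, "LiveDead": 2.0,
    "CD56": 1.25, "CD16": 0.5,
}


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort; seed fixes all draws."""

    group_profiles: list[GroupProfile] = field(default_factory=default_group_profiles)
    events_per_sample: int = 2000
    contaminant_fraction: float = 0.05
    healthy_donors: int = 1
    # additive T0->M3 change in summed CD57+ frequency, per group
    m3_shift: dict[str, float] = field(
        default_factory=lambda: {"X": 6.6, "Y": 1.4, "Z": 7.7}
    )
    # planted number of patients per group with viral load < 50 copies/mL at M3
    suppressed_m3_counts: dict[str, int] = field(
        default_factory=lambda: {"X": 6, "Y": 7, "Z": 1}
    )
    # extra patients whose T0 acquisition is degenerate (too few events for
    # the clustering stage to fit): they complete the 30-patient cohort but
    # drop out of stratification, mirroring samples that fail to compute
    n_failing_patients: int = 2
    failing_events: int = 20
    event_sd: float = DEFAULT_EVENT_SD
    seed: int = 0
    file_format: str = "csv"  # or "fcs"

    def __post_init__(self) -> None:
        if self.events_per_sample < 0:
            raise ValueError("events_per_sample must be >= 0")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must be in [0, 1)")

    # -- round-trip to a structured key-value file -------------------------
    def to_dict(self) -> dict:
        return {
            "events_per_sample": self.events_per_sample,
            "contaminant_fraction": self.contaminant_fraction,
            "healthy_donors": self.healthy_donors,
            "m3_shift": dict(self.m3_shift),
            "suppressed_m3_counts": dict(self.suppressed_m3_counts),
            "event_sd": self.event_sd,
            "seed": self.seed,
            "file_format": self.file_format,
            "group_profiles": [
                {
                    "label": g.label,
                    "n_patients": g.n_patients,
                    "freq_center": dict(g.freq_center),
                    "freq_spread": g.freq_spread,
                    "metadata_centers": {
                        k: (list(v) if v is not None else None)
                        for k, v in g.metadata_centers.items()
                    },
                }
                for g in self.group_profiles
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        profiles = [
            GroupProfile(
                label=g["label"],
                n_patients=g["n_patients"],
                freq_center=dict(g["freq_center"]),
                freq_spread=g.get("freq_spread", 0.15),
                metadata_centers={
                    k: (tuple(v) if v is not None else None)
                    for k, v in g.get("metadata_centers", {}).items()
                },
            )
            for g in d.pop("group_profiles", [])
        ]
        if profiles:
            d["group_profiles"] = profiles
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# sampling

def sample_patient_frequencies(
    profile: GroupProfile,
    rng: np.random.Generator,
    phenotype_names: Sequence[str] = DEFAULT_PHENOTYPE_NAMES,
) -> dict[str, float]:
    """Draw one patient's phenotype frequency vector (% of NK, sums to 100).

    Logistic-normal around the group centers: each positive center is
    multiplied by exp(spread * N(0,1)) and the vector renormalised; zero
    centers stay exactly zero. spread=0 returns the renormalised centers.
    """
    centers = np.array([profile.freq_center.get(p, 0.0) for p in phenotype_names])
    if centers.sum() <= 0:
        raise ValueError(f"group {profile.label}: all frequency centers are zero")
    noise = rng.standard_normal(len(centers))
    jittered = np.where(
        centers > 0, centers * np.exp(profile.freq_spread * noise), 0.0
    )
    freqs = 100.0 * jittered / jittered.sum()
    return dict(zip(phenotype_names, freqs))


def _shifted_centers(
    center: Mapping[str, float], shift: float
) -> dict[str, float]:
    """Move `shift` percentage points into the CD57+ CD56dim pools, taken
    from the triple-negative and NKG2A+ pools (maturation kinetics on cART)."""
    out = dict(center)
    targets = [p for p in (P_57, P_C57, P_A57) if out.get(p, 0) > 0]
    sources = [p for p in (P_TN, P_A) if out.get(p, 0) > 0]
    if not targets or not sources:
        return out
    avail = sum(out[p] - 0.5 for p in sources if out[p] > 0.5)
    shift = max(0.0, min(shift, avail))
    tmass = sum(out[p] for p in targets)
    smass = sum(out[p] for p in sources)
    for p in targets:
        out[p] += shift * out[p] / tmass
    for p in sources:
        out[p] -= shift * out[p] / smass
    return out


def simulate_sample(
    frequencies: Mapping[str, float],
    phenotypes: Sequence[PhenotypeSpec],
    panel: MarkerPanel,
    n_events: int,
    contaminant_fraction: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
    return_truth: bool = False,
):
    """Simulate one event table.

    NK events are diagonal Gaussians around their phenotype means, dump-
    negative and viable; a ``contaminant_fraction`` of events is dump-
    positive (CD14-high, CD16+ non-classical-monocyte-like). Phenotype
    counts are multinomial in the given frequencies.
    """
    by_name = {p.name: p for p in phenotypes}
    names = [n for n in frequencies if frequencies[n] > 0 or n in by_name]
    fvec = np.array([frequencies[n] for n in names])
    if n_events > 0 and abs(fvec.sum() - 100.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 100 (got {fvec.sum():.6f})")
    unknown = [n for n in names if n not in by_name and frequencies[n] > 0]
    if unknown:
        raise ValueError(f"no phenotype spec for: {unknown}")

    nk = list(panel.nk_markers)
    dump = list(panel.dump_markers)
    columns = nk + dump + [panel.viability_marker]
    if n_events == 0:
        mat = EventMatrix(pd.DataFrame(columns=columns, dtype=float), sample_id)
        return (mat, np.empty(0, dtype=object)) if return_truth else mat

    probs = np.append(fvec / 100.0 * (1 - contaminant_fraction), contaminant_fraction)
    counts = rng.multinomial(n_events, probs)
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for name, k in zip(names, counts[:-1]):
        if k == 0:
            continue
        spec = by_name[name]
        mu = np.array([spec.means[m] for m in nk])
        sd = np.array([spec.sds[m] for m in nk])
        block = np.empty((k, len(columns)))
        block[:, : len(nk)] = rng.normal(mu, sd, size=(k, len(nk)))
        block[:, len(nk) : len(nk) + 3] = rng.normal(0.2, 0.3, size=(k, 3))
        block[:, -1] = rng.normal(0.3, 0.3, size=k)
        blocks.append(block)
        labels.append(np.full(k, name, dtype=object))
    n_cont = counts[-1]
    if n_cont:
        block = np.empty((n_cont, len(columns)))
        block[:, 0] = rng.normal(0.3, 0.3, size=n_cont)   # CD56
        block[:, 1] = rng.normal(2.0, 0.8, size=n_cont)   # CD16 (monocyte-like)
        block[:, 2:5] = rng.normal(0.2, 0.3, size=(n_cont, 3))
        block[:, len(nk)] = rng.normal(0.2, 0.3, size=n_cont)      # CD3
        block[:, len(nk) + 1] = rng.normal(4.0, 0.5, size=n_cont)  # CD14 high
        block[:, len(nk) + 2] = rng.normal(0.2, 0.3, size=n_cont)  # CD19
        block[:, -1] = rng.normal(0.3, 0.3, size=n_cont)
        blocks.append(block)
        labels.append(np.full(n_cont, CONTAMINANT_LABEL, dtype=object))

    events = np.concatenate(blocks, axis=0)
    truth = np.concatenate(labels)
    order = rng.permutation(len(events))
    mat = EventMatrix(
        pd.DataFrame(events[order], columns=columns), sample_id=sample_id
    )
    return (mat, truth[order]) if return_truth else mat


@dataclass
class SyntheticCohort:
    """In-memory result of :func:`simulate_cohort`."""

    samples: list[EventMatrix]
    truth_labels: dict[str, np.ndarray]
    truth_frequencies: pd.DataFrame  # planted % per sample, + group/timepoint
    metadata: pd.DataFrame
    gate_thresholds: dict[str, float]
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def _draw_meta(
    center: tuple[float, float, float] | None, rng: np.random.Generator
) -> float:
    if center is None:
        return float("nan")
    med, lo, hi = center
    return float(np.clip(rng.normal(med, (hi - lo) / 4.0), lo, hi))


def simulate_cohort(
    config: CohortConfig | None = None, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate the full cohort: one event table per patient-timepoint plus
    healthy donors, clinical metadata, and the planted truth tables.

    Identical configs (including the seed) give bit-identical outputs.
    """
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.seed)
    phenotypes = build_default_phenotypes(config.event_sd)
    panel = DEFAULT_PANEL

    samples: list[EventMatrix] = []
    truth_labels: dict[str, np.ndarray] = {}
    freq_rows: list[dict] = []
    meta_rows: list[dict] = []

    pid = 0
    for profile in config.group_profiles:
        shift = config.m3_shift.get(profile.label, 0.0)
        m3_profile = GroupProfile(
            label=profile.label,
            n_patients=profile.n_patients,
            freq_center=_shifted_centers(profile.freq_center, shift),
            freq_spread=profile.freq_spread,
            metadata_centers=profile.metadata_centers,
        )
        n_supp = config.suppressed_m3_counts.get(profile.label, 0)
        suppressed = np.zeros(profile.n_patients, dtype=bool)
        suppressed[rng.choice(profile.n_patients, size=n_supp, replace=False)] = True

        for i in range(profile.n_patients):
            pid += 1
            patient = f"P{pid:02d}"
            meta_t0 = {f: _draw_meta(profile.metadata_centers.get(f), rng)
                       for f in METADATA_FIELDS}
            meta_m3 = dict(meta_t0)
            # month-3 kinetics: ~3 log viral decay, partial immune restoration
            meta_m3["cd4"] = meta_t0["cd4"] + float(np.clip(rng.normal(100, 50), -50, 300))
            meta_m3["cd8"] = _draw_meta((705, 371, 1282), rng)
            if suppressed[i]:
                copies = rng.uniform(5.0, SUPPRESSION_THRESHOLD_COPIES - 5.0)
                meta_m3["hiv_rna"] = float(
                    np.log10(max(copies, HIV_RNA_FLOOR_COPIES))
                )
            else:
                meta_m3["hiv_rna"] = float(rng.uniform(1.80, 3.42))
            meta_m3["hiv_dna"] = max(2.0, meta_t0["hiv_dna"] - rng.uniform(0.6, 1.0))
            meta_m3["il6"] = meta_t0["il6"] * rng.uniform(0.4, 0.8)
            meta_m3["ip10"] = meta_t0["ip10"] * rng.uniform(0.3, 0.7)
            meta_m3["cd38_mfi"] = meta_t0["cd38_mfi"] * rng.uniform(0.4, 0.8)

            for timepoint, tp_profile, meta in (
                ("T0", profile, meta_t0),
                ("M3", m3_profile, meta_m3),
            ):
                sid = f"{patient}_{timepoint}"
                freqs = sample_patient_frequencies(tp_profile, rng)
                mat, truth = simulate_sample(
                    freqs, phenotypes, panel, config.events_per_sample,
                    config.contaminant_fraction, rng, sample_id=sid,
                    return_truth=True,
                )
                samples.append(mat)
                truth_labels[sid] = truth
                freq_rows.append(
                    {"sample_id": sid, "patient_id": patient,
                     "group_label": profile.label, "timepoint": timepoint, **freqs}
                )
                # assay floors
                meta = dict(meta)
                if not np.isnan(meta["hiv_rna"]):
                    meta["hiv_rna"] = max(meta["hiv_rna"], HIV_RNA_FLOOR_LOG10)
                if meta["il6"] < IL6_DETECTION_LIMIT:
                    meta["il6"] = IL6_IMPUTED
                meta_rows.append(
                    {"patient_id": patient, "timepoint": timepoint,
                     "subject_type": "patient", **meta,
                     "suppressed_m3": bool(suppressed[i])}
                )

    # patients with a degenerate T0 acquisition (group membership unknowable)
    fail_profile = config.group_profiles[0]
    for _ in range(config.n_failing_patients):
        pid += 1
        patient = f"P{pid:02d}"
        meta = {f: _draw_meta(fail_profile.metadata_centers.get(f), rng)
                for f in METADATA_FIELDS}
        for timepoint, n_ev in (("T0", config.failing_events),
                                ("M3", config.events_per_sample)):
            sid = f"{patient}_{timepoint}"
            freqs = sample_patient_frequencies(fail_profile, rng)
            mat, truth = simulate_sample(
                freqs, phenotypes, panel, n_ev, config.contaminant_fraction,
                rng, sample_id=sid, return_truth=True,
            )
            samples.append(mat)
            truth_labels[sid] = truth
            freq_rows.append(
                {"sample_id": sid, "patient_id": patient, "group_label": "F",
                 "timepoint": timepoint, **freqs}
            )
            row = dict(meta)
            if not np.isnan(row["hiv_rna"]):
                row["hiv_rna"] = max(row["hiv_rna"], HIV_RNA_FLOOR_LOG10)
            if row["il6"] < IL6_DETECTION_LIMIT:
                row["il6"] = IL6_IMPUTED
            meta_rows.append(
                {"patient_id": patient, "timepoint": timepoint,
                 "subject_type": "patient", **row, "suppressed_m3": False}
            )

    hprofile = healthy_profile()
    for j in range(config.healthy_donors):
        patient = f"HD{j + 1:02d}"
        sid = f"{patient}_T0"
        freqs = sample_patient_frequencies(hprofile, rng)
        mat, truth = simulate_sample(
            freqs, phenotypes, panel, config.events_per_sample,
            config.contaminant_fraction, rng, sample_id=sid, return_truth=True,
        )
        samples.append(mat)
        truth_labels[sid] = truth
        freq_rows.append(
            {"sample_id": sid, "patient_id": patient, "group_label": "H",
             "timepoint": "T0", **freqs}
        )
        meta = {f: _draw_meta(hprofile.metadata_centers.get(f), rng)
                for f in METADATA_FIELDS}
        if meta["il6"] < IL6_DETECTION_LIMIT:
            meta["il6"] = IL6_IMPUTED
        meta_rows.append(
            {"patient_id": patient, "timepoint": "T0",
             "subject_type": "healthy", **meta, "suppressed_m3": False}
        )

    cohort = SyntheticCohort(
        samples=samples,
        truth_labels=truth_labels,
        truth_frequencies=pd.DataFrame(freq_rows).set_index("sample_id"),
        metadata=pd.DataFrame(meta_rows),
        gate_thresholds=dict(TRUTH_GATE_THRESHOLDS),
        config=config,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "fcs" if cohort.config.file_format == "fcs" else "csv"
    for sample in cohort.samples:
        write_events(sample, out_dir / f"{sample.sample_id}.{ext}")
    cohort.metadata.to_csv(
        out_dir / "metadata.tsv", sep="\t", index=False, float_format="%.6g"
    )
    cohort.truth_frequencies.to_csv(
        out_dir / "truth_frequencies.tsv", sep="\t", float_format="%.6g"
    )
    cohort.config.save(out_dir / "config.yaml")


__all__ = [
    "PhenotypeSpec", "GroupProfile", "CohortConfig", "SyntheticCohort",
    "build_default_phenotypes", "default_group_profiles", "healthy_profile",
    "sample_patient_frequencies", "simulate_sample", "simulate_cohort",
    "DEFAULT_PHENOTYPE_NAMES", "LEVEL_GRID", "DEFAULT_EVENT_SD",
    "TRUTH_GATE_THRESHOLDS", "CONTAMINANT_LABEL",
    "HIV_RNA_FLOOR_LOG10", "IL6_IMPUTED", "SUPPRESSION_THRESHOLD_COPIES",
    "METADATA_FIELDS",
    "P_BRIGHT", "P_BRIGHT_LOW", "P_A", "P_AC", "P_A57", "P_C", "P_C57",
    "P_57", "P_TN", "P_NEG_A", "P_NEG_57", "P_NEG", "P_DIM_LOW",
]
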