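"""Longitudinal cohort simulator.

Generates a hierarchical cohort mirroring the study design: three groups
(stable MS, active MS, healthy volunteers), two corpus-callosum VOIs per
subject (a few subjects contribute only one), MS timepoints at month 0 and
month 6 (month 3 for most active cases), and HV repeat scans within two
weeks. Draws are hierarchical per measure:

    subject effect ~ Normal(group baseline mean, between-subject SD)
    observation    = subject effect + timepoint effect + Normal(0, within SD)

Default group sizes (6 stable, 13 active, 6 HV), baseline means, and
six-month changes follow the study's reported group statistics for NAA
D_cytosol and the water-DTI/volumetric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import CohortRecord

__all__ = ["MeasureTruth", "CohortGroundTruth", "simulate_cohort"]

GROUPS = ("stable", "active", "HV")


@dataclass
class MeasureTruth:
    """Hierarchical ground truth for one measure."""

    baseline_mean: dict[str, float]  # per group
    delta_6mo: dict[str, float]  # per group mean change over 6 months
    between_sd: float
    within_sd: float

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be nonnegative")


def _default_measures() -> dict[str, MeasureTruth]:
    # Baseline means follow the reported month-0 group statistics; the printed
    # group SDs (~0.05-0.07 for D_cytosol) are split into between-subject and
    # within-subject (VOI/replicate) components.
    return {
        "d_cytosol": MeasureTruth(
            baseline_mean={"stable": 0.45, "active": 0.50, "HV": 0.52},
            delta_6mo={"stable": 0.03, "active": -0.04, "HV": 0.0},
            between_sd=0.06, within_sd=0.035,
        ),
        "md": MeasureTruth(
            baseline_mean={"stable": 1.21, "active": 1.24, "HV": 1.10},
            delta_6mo={"stable": 0.05, "active": -0.03, "HV": 0.0},
            between_sd=0.13, within_sd=0.06,
        ),
        "fa": MeasureTruth(
            baseline_mean={"stable": 0.55, "active": 0.53, "HV": 0.57},
            delta_6mo={"stable": -0.01, "active": 0.0, "HV": 0.0},
            between_sd=0.05, within_sd=0.02,
        ),
        "lambda_par": MeasureTruth(
            baseline_mean={"stable": 1.98, "active": 1.99, "HV": 1.85},
            delta_6mo={"stable": 0.06, "active": -0.03, "HV": 0.0},
            between_sd=0.12, within_sd=0.06,
        ),
        "lambda_perp": MeasureTruth(
            baseline_mean={"stable": 0.81, "active": 0.87, "HV": 0.73},
            delta_6mo={"stable": 0.08, "active": -0.02, "HV": 0.0},
            between_sd=0.14, within_sd=0.06,
        ),
        "pct_icv": MeasureTruth(
            baseline_mean={"stable": 79.2, "active": 79.9, "HV": 82.0},
            delta_6mo={"stable": -0.01, "active": -0.13, "HV": 0.0},
            between_sd=2.2, within_sd=0.3,
        ),
    }


@dataclass
class CohortGroundTruth:
    """Design and distributional truth of the simulated cohort."""

    measures: dict[str, MeasureTruth] = field(default_factory=_default_measures)
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"stable": 6, "active": 13, "HV": 6}
    )
    vois_per_subject: int = 2
    #: number of subjects per group contributing only one VOI (intolerance)
    single_voi_subjects: dict[str, int] = field(
        default_factory=lambda: {"stable": 1, "active": 1, "HV": 0}
    )
    #: VOIs per group missing the second timepoint (dropout / unusable scans)
    missing_followup_vois: dict[str, int] = field(
        default_factory=lambda: {"stable": 1, "active": 3, "HV": 2}
    )
    #: active subjects with an additional month-3 scan
    month3_subjects: int = 11
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"stable": (48, 13), "active": (41, 12), "HV": (48, 9)}
    )
    n_women: dict[str, int] = field(
        default_factory=lambda: {"stable": 4, "active": 6, "HV": 1}
    )

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")

    def to_dict(self) -> dict:
        return {
            "group_sizes": dict(self.group_sizes),
            "measures": {
                k: {
                    "baseline_mean": m.baseline_mean,
                    "delta_6mo": m.delta_6mo,
                    "between_sd": m.between_sd,
                    "within_sd": m.within_sd,
                }
                for k, m in self.measures.items()
            },
        }


def _timepoints_for(group: str, subject_pos: int, truth: CohortGroundTruth) -> list[tuple[str, float]]:
    """(timepoint label, months) pairs for one subject."""
    if group == "HV":
        # repeat scans <= 14 days apart; treated as zero elapsed time
        return [("scan1", 0.0), ("scan2", 0.0)]
    tps = [("mo0", 0.0), ("mo6", 6.0)]
    if group == "active" and subject_pos < truth.month3_subjects:
        tps.insert(1, ("mo3", 3.0))
    return tps


def simulate_cohort(
    truth: CohortGroundTruth | None = None, seed: int = 0
) -> tuple[list[CohortRecord], dict]:
    """Draw one cohort; deterministic given `seed`. Returns (records, truth dict)."""
    if truth is None:
        truth = CohortGroundTruth()
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []

    for group in GROUPS:
        n_sub = truth.group_sizes[group]
        n_single = truth.single_voi_subjects.get(group, 0)
        n_missing = truth.missing_followup_vois.get(group, 0)
        age_mu, age_sd = truth.age_mean_sd.get(group, (45, 10))
        n_women = truth.n_women.get(group, n_sub // 2)

        # Enumerate (subject, voi) pairs so follow-up dropout can be assigned
        # deterministically to the last VOIs of the group.
        voi_slots = []
        for s in range(n_sub):
            n_voi = 1 if s >= n_sub - n_single else truth.vois_per_subject
            for v in range(n_voi):
                voi_slots.append((s, v))
        drop = {slot for slot in voi_slots[len(voi_slots) - n_missing:]} if n_missing else set()

        subj_effects = {
            name: rng.normal(m.baseline_mean[group], m.between_sd, size=n_sub)
            for name, m in truth.measures.items()
        }
        ages = rng.normal(age_mu, age_sd, size=n_sub)
        sexes = ["F" if s < n_women else "M" for s in range(n_sub)]
        edss = np.round(np.clip(rng.normal(1.5, 1.0, size=n_sub), 0, 6.5) * 2) / 2

        for s, v in voi_slots:
            sid = f"{group}{s + 1:02d}"
            vid = "anterior" if v == 0 else "posterior"
            for tp, months in _timepoints_for(group, s, truth):
                # Dropout: MS VOIs lose the follow-up scan; HV VOIs whose
                # repeat scan is unusable are excluded entirely (they carry
                # no longitudinal information and the study counted only
                # twice-scanned HV volumes).
                if (s, v) in drop and (group == "HV" or tp != "mo0"):
                    continue
                vals = {}
                for name, m in truth.measures.items():
                    tp_effect = m.delta_6mo[group] * months / 6.0
                    vals[name] = float(
                        subj_effects[name][s] + tp_effect + rng.normal(0.0, m.within_sd)
                    )
                records.append(
                    CohortRecord(
                        subject_id=sid, group=group, voi_id=vid, timepoint=tp,
                        sex=sexes[s], age=float(np.round(ages[s], 1)),
                        edss=float(edss[s]) if group != "HV" else None,
                        lesion_load_pct_wm=(
                            float(np.abs(rng.normal(1.6, 0.8))) if group != "HV" else 0.0
                        ),
                        voi_lesion_mm3=(
                            float(np.abs(rng.normal(40, 40))) if group != "HV" else 0.0
                        ),
                        **vals,
                    )
                )
    return records, truth.to_dict()
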