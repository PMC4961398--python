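"""Per-time-point tumor-burden quantification and relapse flagging.

The burden estimate at a plasma time point is the mean VAF over the
patient's tracked marker panel. Two averaging modes exist because they
answer different questions:

* ``union_imputed`` (default): arithmetic mean over the *whole* panel,
  counting undetected markers as 0 — comparable across time points
  because the denominator never changes;
* ``detected_only``: mean over the markers detected at that time point —
  the typical VAF of what is actually visible, biased high when few
  markers rise above background.

Absolute ctDNA concentration (ng per mL plasma) is the mean fraction
times the total cfDNA concentration. Relapse is flagged when a
post-operative point rises at least ``fold_threshold`` times above the
post-operative nadir seen so far *and* clears an absolute floor that
keeps error-level loads from ever flagging; a zero nadir makes the fold
infinite and leaves the decision to the absolute arm alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_formats import SampleRecord
from .marker_tracking import MarkerVafMatrix

__all__ = [
    "TumorLoadPoint",
    "MonitoringReport",
    "mean_vaf",
    "absolute_ctdna",
    "build_series",
    "flag_relapse",
    "compare_biomarkers",
]

DEFAULT_FOLD_THRESHOLD = 5.0
DEFAULT_MIN_ABS_LEVEL = 0.02  # ng/mL, above simulated error-floor loads
DEFAULT_CEA_CUTOFF = 5.0  # μg/L, standard clinical reference limit
DEFAULT_CA199_CUTOFF = 37.0  # kU/L, standard clinical reference limit

MEAN_VAF_MODES = ("union_imputed", "detected_only")


def mean_vaf(
    vafs: Sequence[float],
    mode: str = "union_imputed",
    imputed: Sequence[bool] | None = None,
) -> float:
    """Summarise one time point's marker VAFs into a single fraction.

    ``union_imputed`` averages over every marker (imputed zeros
    included); ``detected_only`` averages over the non-imputed entries
    and requires at least one. ``imputed`` flags which entries are
    imputed zeros; without it, zeros are assumed imputed.
    """
    if mode not in MEAN_VAF_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    values = [float(v) for v in vafs]
    if mode == "union_imputed":
        if not values:
            raise ValueError("mean VAF undefined for an empty marker panel")
        return sum(values) / len(values)
    if imputed is None:
        detected = [v for v in values if v > 0]
    else:
        detected = [v for v, imp in zip(values, imputed) if not imp]
    if not detected:
        raise ValueError("detected_only mean undefined: no detected marker")
    return sum(detected) / len(detected)


def absolute_ctdna(mean_vaf_fraction: float, cfdna_conc: float) -> float:
    """ctDNA ng per mL plasma: mean fraction x total cfDNA concentration."""
    if not 0.0 <= mean_vaf_fraction <= 1.0:
        raise ValueError(f"mean VAF out of [0,1]: {mean_vaf_fraction}")
    if cfdna_conc < 0:
        raise ValueError(f"cfdna_conc must be >= 0, got {cfdna_conc}")
    return mean_vaf_fraction * cfdna_conc


@dataclass
class TumorLoadPoint:
    """Tumor burden at one plasma time point."""

    patient_id: str
    time_days: float
    mean_vaf: float
    cfdna_conc: float
    ctdna_ng_per_ml: float = field(default=None)  # type: ignore[assignment]
    cea: float | None = None
    ca199: float | None = None
    relapse_flag: bool = False

    def __post_init__(self) -> None:
        expected = absolute_ctdna(self.mean_vaf, self.cfdna_conc)
        if self.ctdna_ng_per_ml is None:
            self.ctdna_ng_per_ml = expected
        elif not math.isclose(self.ctdna_ng_per_ml, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(
                "ctdna_ng_per_ml inconsistent with mean_vaf x cfdna_conc: "
                f"{self.ctdna_ng_per_ml} != {expected}"
            )


@dataclass
class MonitoringReport:
    """A patient's longitudinal series plus the relapse-call summary.

    ``baseline`` is the post-operative nadir in force at the first
    flagged point (or the overall post-op nadir among non-final points
    when nothing flags); fold fields are None when fewer than two
    post-operative points exist, and ``max_fold`` is ``inf`` when the
    nadir is exactly zero.
    """

    patient_id: str
    points: list[TumorLoadPoint]
    baseline: float | None
    max_fold: float | None
    first_flagged_time: float | None
    flagged_times: list[float] = field(default_factory=list)
    confirmed_relapse_time: float | None = None

    @property
    def relapse_detected(self) -> bool:
        return self.first_flagged_time is not None

    @property
    def relapse_confirmed(self) -> bool:
        """Patient-level call: molecular relapse confirmed on the next draw.

        A real recurrence grows, so once it clears the flagging rule it
        stays flagged at every later draw; an isolated error-driven flag
        does not. Requiring two consecutive flagged points is the usual
        clinical confirmation rule and is what the per-patient operating
        characteristics are quoted on.
        """
        return self.confirmed_relapse_time is not None

    def to_json(self) -> str:
        payload = {
            "patient_id": self.patient_id,
            "baseline_ng_per_ml": self.baseline,
            "max_fold": (
                None
                if self.max_fold is None
                else ("inf" if math.isinf(self.max_fold) else self.max_fold)
            ),
            "first_flagged_time": self.first_flagged_time,
            "flagged_times": self.flagged_times,
            "confirmed_relapse_time": self.confirmed_relapse_time,
            "points": [
                {
                    "time_days": p.time_days,
                    "mean_vaf": p.mean_vaf,
                    "ctdna_ng_per_ml": p.ctdna_ng_per_ml,
                    "cfdna_conc": p.cfdna_conc,
                    "cea": p.cea,
                    "ca199": p.ca199,
                    "relapse_flag": p.relapse_flag,
                }
                for p in self.points
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def build_series(
    patient_id: str,
    matrix: MarkerVafMatrix,
    sample_sheet: Sequence[SampleRecord],
    mode: str = "union_imputed",
) -> list[TumorLoadPoint]:
    """One TumorLoadPoint per plasma sample, strictly time-ordered.

    Every matrix column must appear in the sample sheet (with cfDNA
    concentration and any serum-marker values). In ``detected_only``
    mode a time point with no detected marker contributes 0 — nothing
    visible means no measurable ctDNA, not an undefined burden.
    """
    records = {r.sample_id: r for r in sample_sheet}
    points: list[TumorLoadPoint] = []
    for sid in matrix.sample_ids:
        rec = records.get(sid)
        if rec is None:
            raise ValueError(f"plasma sample {sid} missing from sample sheet")
        column = matrix.vaf[sid]
        imput = matrix.imputed[sid]
        try:
            mv = mean_vaf(column.tolist(), mode=mode, imputed=imput.tolist())
        except ValueError:
            if mode == "detected_only":
                mv = 0.0
            else:
                raise
        points.append(
            TumorLoadPoint(
                patient_id=patient_id,
                time_days=rec.time_days,
                mean_vaf=mv,
                cfdna_conc=rec.cfdna_conc,
                cea=rec.cea,
                ca199=rec.ca199,
            )
        )
    points.sort(key=lambda p: p.time_days)
    return points


def flag_relapse(
    series: Sequence[TumorLoadPoint],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_abs_level: float = DEFAULT_MIN_ABS_LEVEL,
) -> MonitoringReport:
    """Flag molecular relapse by fold change over the post-operative nadir.

    For each post-operative point after the first, the baseline is the
    minimum post-operative load among strictly earlier points (the nadir
    so far — robust to transient fluctuation during adjuvant therapy). A
    point is flagged iff its load reaches ``fold_threshold`` times that
    baseline *and* ``min_abs_level`` ng/mL; a zero baseline yields an
    infinite fold and is gated by the absolute arm alone. With fewer
    than two post-operative points no fold is defined and nothing flags.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    points = sorted(series, key=lambda p: p.time_days)
    if not points:
        raise ValueError("empty series")
    patient_id = points[0].patient_id
    postop = [p for p in points if p.time_days > 0]
    if len(postop) < 2:
        return MonitoringReport(
            patient_id=patient_id,
            points=points,
            baseline=None,
            max_fold=None,
            first_flagged_time=None,
        )

    flagged_times: list[float] = []
    first_flag_baseline: float | None = None
    max_fold = 0.0
    for i in range(1, len(postop)):
        candidate = postop[i]
        baseline = min(p.ctdna_ng_per_ml for p in postop[:i])
        if baseline == 0.0:
            fold = math.inf if candidate.ctdna_ng_per_ml > 0 else 0.0
            passes_fold = candidate.ctdna_ng_per_ml > 0
        else:
            fold = candidate.ctdna_ng_per_ml / baseline
            passes_fold = fold >= fold_threshold
        max_fold = max(max_fold, fold)
        if passes_fold and candidate.ctdna_ng_per_ml >= min_abs_level:
            candidate.relapse_flag = True
            flagged_times.append(candidate.time_days)
            if first_flag_baseline is None:
                first_flag_baseline = baseline
    if first_flag_baseline is None:
        # nadir among candidates' baselines (all but the last post-op point)
        report_baseline = min(p.ctdna_ng_per_ml for p in postop[:-1])
    else:
        report_baseline = first_flag_baseline
    confirmed_time = None
    for earlier, later in zip(postop, postop[1:]):
        if earlier.relapse_flag and later.relapse_flag:
            confirmed_time = earlier.time_days
            break
    return MonitoringReport(
        patient_id=patient_id,
        points=points,
        baseline=report_baseline,
        max_fold=max_fold,
        first_flagged_time=flagged_times[0] if flagged_times else None,
        flagged_times=flagged_times,
        confirmed_relapse_time=confirmed_time,
    )


def compare_biomarkers(
    series: Sequence[TumorLoadPoint],
    cea_cutoff: float = DEFAULT_CEA_CUTOFF,
    ca199_cutoff: float = DEFAULT_CA199_CUTOFF,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cross-tabulate ctDNA relapse flags against serum-marker positivity.

    A point is biomarker-positive when CEA exceeds ``cea_cutoff`` (μg/L)
    or CA 19-9 exceeds ``ca199_cutoff`` (kU/L); missing measurements
    count as negative. Returns a per-time-point table and summary counts
    of ctDNA-only, biomarker-only, concordant-positive and
    concordant-negative calls.
    """
    if cea_cutoff <= 0 or ca199_cutoff <= 0:
        raise ValueError("biomarker cutoffs must be positive")
    rows = []
    summary = {
        "ctdna_only": 0,
        "biomarker_only": 0,
        "concordant_positive": 0,
        "concordant_negative": 0,
    }
    for p in sorted(series, key=lambda q: q.time_days):
        cea_pos = p.cea is not None and p.cea > cea_cutoff
        ca_pos = p.ca199 is not None and p.ca199 > ca199_cutoff
        bio_pos = cea_pos or ca_pos
        rows.append(
            {
                "time_days": p.time_days,
                "ctdna_flag": p.relapse_flag,
                "cea_positive": cea_pos,
                "ca199_positive": ca_pos,
                "biomarker_positive": bio_pos,
            }
        )
        if p.relapse_flag and not bio_pos:
            summary["ctdna_only"] += 1
        elif bio_pos and not p.relapse_flag:
            summary["biomarker_only"] += 1
        elif p.relapse_flag and bio_pos:
            summary["concordant_positive"] += 1
        else:
            summary["concordant_negative"] += 1
    return pd.DataFrame(rows), summary
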