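"""End-to-end per-patient analysis: files in, monitoring report out.

Ties the stages together in the order a tumor-informed MRD workflow
runs them: germline subtraction and nonsynonymous filtering of the
tissue calls, binomial detection of every plasma observation, marker-set
construction (tissue-derived plus de novo plasma), VAF-matrix assembly
with zero imputation, tumor-load series, relapse flagging, and the
serum-biomarker comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import somatic_filtering as sf
from .io_formats import SampleRecord, Variant, VariantCalls, read_sample_sheet, read_variants
from .marker_tracking import MarkerSet, MarkerVafMatrix, build_marker_set, fill_vaf_matrix
from .spectrum_summary import SpectrumCounts, spectrum
from .tumor_load import (
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_MIN_ABS_LEVEL,
    MonitoringReport,
    TumorLoadPoint,
    build_series,
    compare_biomarkers,
    flag_relapse,
)

__all__ = ["PatientAnalysis", "analyze_patient", "analyze_patient_dir"]


@dataclass
class PatientAnalysis:
    """Every intermediate and final product of one patient's analysis."""

    patient_id: str
    somatic_tissue: list[Variant]
    detections: pd.DataFrame
    marker_set: MarkerSet
    matrix: MarkerVafMatrix
    series: list[TumorLoadPoint]
    report: MonitoringReport
    biomarker_table: pd.DataFrame
    biomarker_summary: dict
    tissue_spectrum: SpectrumCounts


def analyze_patient(
    patient_id: str,
    tissue_calls: VariantCalls,
    pbl_calls: VariantCalls,
    plasma_observations: pd.DataFrame,
    sample_sheet: Sequence[SampleRecord],
    error_rate: float = sf.DEFAULT_ERROR_RATE,
    alpha: float = sf.DEFAULT_ALPHA,
    min_alt_reads: int = sf.DEFAULT_MIN_ALT_READS,
    mode: str = "union_imputed",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    min_abs_level: float = DEFAULT_MIN_ABS_LEVEL,
) -> PatientAnalysis:
    """Run the whole monitoring analysis for one patient (in-memory inputs)."""
    plasma_samples = [
        r
        for r in sample_sheet
        if r.patient_id == patient_id and r.compartment == "plasma"
    ]
    if not plasma_samples:
        raise ValueError(f"no plasma samples for patient {patient_id}")

    somatic = sf.subtract_germline(tissue_calls.variants, pbl_calls.variants)
    somatic = sf.filter_nonsynonymous(somatic)

    detections = sf.call_plasma_table(
        plasma_observations,
        error_rate=error_rate,
        alpha=alpha,
        min_alt_reads=min_alt_reads,
    )
    plasma_ids = {r.sample_id for r in plasma_samples}
    det = detections[detections["detected"] & detections["sample_id"].isin(plasma_ids)]
    per_sample: dict[str, list[tuple]] = {sid: [] for sid in sorted(plasma_ids)}
    for rec in det.itertuples(index=False):
        per_sample[rec.sample_id].append((rec.chrom, rec.pos, rec.ref, rec.alt))

    marker_set = build_marker_set(
        patient_id, somatic, per_sample, sample_sheet=sample_sheet
    )
    matrix = fill_vaf_matrix(
        marker_set,
        plasma_observations,
        plasma_samples,
        error_rate=error_rate,
        alpha=alpha,
        min_alt_reads=min_alt_reads,
    )
    series = build_series(patient_id, matrix, plasma_samples, mode=mode)
    report = flag_relapse(
        series, fold_threshold=fold_threshold, min_abs_level=min_abs_level
    )
    bio_table, bio_summary = compare_biomarkers(report.points)
    return PatientAnalysis(
        patient_id=patient_id,
        somatic_tissue=somatic,
        detections=detections,
        marker_set=marker_set,
        matrix=matrix,
        series=report.points,
        report=report,
        biomarker_table=bio_table,
        biomarker_summary=bio_summary,
        tissue_spectrum=spectrum(somatic),
    )


def analyze_patient_dir(
    cohort_dir: str | Path, patient_id: str, **kwargs
) -> PatientAnalysis:
    """Analyze one patient from a cohort directory laid out as written by
    :func:`ctdnatrack.synthetic_data.generate_cohort`."""
    cohort_dir = Path(cohort_dir)
    tissue = read_variants(cohort_dir / f"{patient_id}.tissue.vcf", fmt="vcf")
    pbl = read_variants(cohort_dir / f"{patient_id}.pbl.vcf", fmt="vcf")
    plasma = read_variants(cohort_dir / f"{patient_id}.plasma_counts.tsv", fmt="tsv")
    sheet = read_sample_sheet(cohort_dir / "sample_sheet.tsv")
    return analyze_patient(
        patient_id, tissue, pbl, plasma.observations, sheet, **kwargs
    )
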