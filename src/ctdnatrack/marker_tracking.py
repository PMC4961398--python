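"""Per-patient marker panels and their VAF matrix across plasma samples.

The tracked panel is tumor-informed but heterogeneity-aware: it is the
union of the somatic nonsynonymous variants found in the resected tissue
and every variant independently detected in any plasma sample (de novo
plasma mutations, attributed to spatial tumor heterogeneity). The panel
is built once per patient and applied retrospectively to every time
point; a marker absent or not detected in a sample contributes VAF = 0
(imputed) so that each time point is summarised over the same
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SampleRecord, Variant
from .somatic_filtering import (
    DEFAULT_ALPHA,
    DEFAULT_ERROR_RATE,
    DEFAULT_MIN_ALT_READS,
    call_plasma_table,
)

__all__ = [
    "MarkerSet",
    "MarkerVafMatrix",
    "ReappearanceReport",
    "build_marker_set",
    "fill_vaf_matrix",
    "tissue_validated_proportion",
    "relapse_reappearance",
]

PROVENANCES = ("tissue_derived", "de_novo_plasma", "both")

VariantKey = tuple[str, int, str, str]


def _as_key(item) -> VariantKey:
    if isinstance(item, Variant):
        return item.key
    key = tuple(item)
    if len(key) != 4:
        raise ValueError(f"not a variant key: {item!r}")
    return key  # type: ignore[return-value]


@dataclass
class MarkerSet:
    """A patient's tracked mutation panel with per-marker provenance."""

    patient_id: str
    provenance: dict[VariantKey, str]
    genes: dict[VariantKey, str] = field(default_factory=dict)
    built_from: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key, prov in self.provenance.items():
            if prov not in PROVENANCES:
                raise ValueError(f"unknown provenance {prov!r} for {key}")

    @property
    def keys(self) -> list[VariantKey]:
        return list(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "chrom": [k[0] for k in self.keys],
                "pos": [k[1] for k in self.keys],
                "ref": [k[2] for k in self.keys],
                "alt": [k[3] for k in self.keys],
                "gene": [self.genes.get(k, "") for k in self.keys],
                "provenance": [self.provenance[k] for k in self.keys],
            }
        )


@dataclass
class MarkerVafMatrix:
    """Rectangular markers x plasma-samples VAF matrix.

    ``vaf`` rows are marker keys, columns are plasma sample ids in
    strictly increasing time order; ``imputed`` flags entries set to 0
    because the marker was absent from (or not detected in) that
    sample's count table. ``times`` maps each column to its
    ``time_days``.
    """

    vaf: pd.DataFrame
    imputed: pd.DataFrame
    times: dict[str, float]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.vaf.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.vaf[sample_id]


def build_marker_set(
    patient_id: str,
    tissue_somatic: Iterable[Variant],
    plasma_detections: Mapping[str, Iterable],
    sample_sheet: Sequence[SampleRecord] | None = None,
) -> MarkerSet:
    """Union the tissue somatic panel with all plasma-detected variants.

    ``plasma_detections`` maps plasma sample_id -> detected variants (or
    keys). Provenance is ``both`` iff a variant was found in tissue and
    independently detected in at least one plasma sample. If a
    ``sample_sheet`` is given, every referenced sample must belong to
    ``patient_id`` (mixing patients is an error).
    """
    if sample_sheet is not None:
        owner = {r.sample_id: r.patient_id for r in sample_sheet}
        for sid in plasma_detections:
            if owner.get(sid, patient_id) != patient_id:
                raise ValueError(
                    f"sample {sid} belongs to patient {owner[sid]}, "
                    f"not {patient_id}"
                )
    tissue = list(tissue_somatic)
    tissue_keys = {v.key for v in tissue}
    genes: dict[VariantKey, str] = {v.key: v.gene for v in tissue}

    plasma_keys: list[VariantKey] = []
    seen_plasma: set[VariantKey] = set()
    for sid in plasma_detections:
        for item in plasma_detections[sid]:
            key = _as_key(item)
            if isinstance(item, Variant) and key not in genes:
                genes[key] = item.gene
            if key not in seen_plasma:
                seen_plasma.add(key)
                plasma_keys.append(key)

    provenance: dict[VariantKey, str] = {}
    for v in tissue:
        provenance[v.key] = "both" if v.key in seen_plasma else "tissue_derived"
    for key in plasma_keys:
        if key not in tissue_keys:
            provenance[key] = "de_novo_plasma"
    return MarkerSet(
        patient_id=patient_id,
        provenance=provenance,
        genes={k: genes.get(k, "") for k in provenance},
        built_from=sorted(plasma_detections),
    )


def fill_vaf_matrix(
    marker_set: MarkerSet,
    plasma_observations: pd.DataFrame,
    plasma_samples: Sequence[SampleRecord],
    require_detection: bool = True,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> MarkerVafMatrix:
    """Assemble the rectangular marker x time-point VAF matrix.

    An entry is the observed VAF when the marker is detected in that
    sample; 0 with the imputed flag set when the marker is absent from
    the sample's count table or fails the detection rule. With
    ``require_detection=False`` any nonzero alt count yields its raw VAF
    (sensitivity-analysis mode).
    """
    plasma = [r for r in plasma_samples if r.compartment == "plasma"]
    plasma = sorted(plasma, key=lambda r: r.time_days)
    sample_ids = [r.sample_id for r in plasma]
    times = {r.sample_id: r.time_days for r in plasma}

    called = call_plasma_table(
        plasma_observations,
        error_rate=error_rate,
        alpha=alpha,
        min_alt_reads=min_alt_reads,
    )
    if require_detection:
        usable = called[called["detected"]]
    else:
        usable = called[called["alt_count"] > 0]
    lookup: dict[tuple[str, VariantKey], float] = {}
    for rec in usable.itertuples(index=False):
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        lookup[(rec.sample_id, key)] = rec.alt_count / rec.depth

    markers = marker_set.keys
    # object index of key tuples (tupleize_cols=False prevents a MultiIndex)
    idx = pd.Index(markers, tupleize_cols=False)
    vaf = pd.DataFrame(0.0, index=idx, columns=sample_ids)
    imputed = pd.DataFrame(True, index=idx, columns=sample_ids)
    for sid in sample_ids:
        for key in markers:
            value = lookup.get((sid, key))
            if value is not None:
                vaf.loc[[key], sid] = value
                imputed.loc[[key], sid] = False
    return MarkerVafMatrix(vaf=vaf, imputed=imputed, times=times)


def tissue_validated_proportion(
    plasma_detected: Iterable, tissue_somatic: Iterable
) -> float:
    """Fraction of plasma-detected variants also present in tissue.

    The denominator is the plasma-detected set; the complement of the
    result is the de novo share attributable to spatial heterogeneity.
    """
    plasma = {_as_key(v) for v in plasma_detected}
    if not plasma:
        raise ValueError("tissue-validated proportion undefined: empty plasma set")
    tissue = {_as_key(v) for v in tissue_somatic}
    return len(plasma & tissue) / len(plasma)


@dataclass
class ReappearanceReport:
    """Concordance of relapse-plasma mutations with the preoperative set."""

    shared: list[VariantKey]
    shared_fraction: float
    vaf_delta: dict[VariantKey, float]
    n_increased: int

    @property
    def shared_count(self) -> int:
        return len(self.shared)


def relapse_reappearance(
    preop_detected: Iterable,
    relapse_detected: Iterable,
    preop_vafs: Mapping,
    relapse_vafs: Mapping,
) -> ReappearanceReport:
    """Compare relapse-time plasma mutations against the preoperative set.

    Reports the shared markers, the shared fraction (denominator =
    preoperative set), per-marker VAF change on shared markers, and how
    many increased strictly above their preoperative VAF.
    """
    preop = {_as_key(v) for v in preop_detected}
    if not preop:
        raise ValueError("reappearance undefined: empty preoperative detection set")
    relapse = {_as_key(v) for v in relapse_detected}
    shared = sorted(preop & relapse)
    preop_v = {_as_key(k): v for k, v in preop_vafs.items()}
    relapse_v = {_as_key(k): v for k, v in relapse_vafs.items()}
    delta = {k: relapse_v[k] - preop_v[k] for k in shared}
    return ReappearanceReport(
        shared=shared,
        shared_fraction=len(shared) / len(preop),
        vaf_delta=delta,
        n_increased=sum(1 for d in delta.values() if d > 0),
    )
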