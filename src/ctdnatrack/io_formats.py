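"""Readers and writers for the tables the monitoring pipeline exchanges.

Three input dialects are supported:

* VCF v4.2 with per-sample ``AD`` (allelic depth) and ``DP`` fields — the
  shape of caller output after somatic discovery;
* an mpileup-style allele-count TSV with columns
  ``sample_id chrom pos ref alt ref_count alt_count depth`` (optionally
  ``gene`` and ``consequence``) — the shape of per-site read support used
  for plasma tracking;
* a sample-sheet TSV describing each biospecimen (patient, compartment,
  collection time relative to surgery, cfDNA concentration and the serum
  protein markers CEA / CA 19-9).

Conventions used throughout the package:

* coordinates are 1-based inclusive (VCF convention); indels are
  left-aligned, minimal, anchored-base VCF style;
* VAF is ``alt_count / depth`` (mpileup-style), not ``alt/(alt+ref)``;
* a variant's identity key is ``(chrom, pos, ref, alt)`` — gene and
  consequence annotations ride along but do not participate in identity;
* missing biomarker measurements are empty fields, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CONSEQUENCES",
    "NONSYNONYMOUS_CONSEQUENCES",
    "COMPARTMENTS",
    "Variant",
    "Observation",
    "SampleRecord",
    "VariantCalls",
    "read_variants",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_counts_tsv",
    "write_variants_vcf",
    "write_results",
    "read_results",
]

CONSEQUENCES = frozenset(
    {
        "nonsynonymous_snv",
        "synonymous_snv",
        "frameshift_indel",
        "inframe_indel",
        "other",
    }
)
#: consequence classes usable as tumor-burden markers
NONSYNONYMOUS_CONSEQUENCES = frozenset(
    {"nonsynonymous_snv", "frameshift_indel", "inframe_indel"}
)

COMPARTMENTS = ("tissue", "plasma", "PBL")

_BASES = frozenset("ACGT")

#: columns of the allele-count TSV dialect
COUNT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "depth",
]

SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "compartment",
    "time_days",
    "cfdna_conc",
    "cea",
    "ca199",
]

RESULT_COLUMNS = [
    "patient_id",
    "time_days",
    "mean_vaf",
    "ctdna_ng_per_ml",
    "cfdna_conc",
    "cea",
    "ca199",
    "relapse_flag",
]


@dataclass(frozen=True)
class Variant:
    """A genomic change; identity is ``(chrom, pos, ref, alt)``."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)
    consequence: str = field(default="other", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _BASES.issuperset(allele):
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence label {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        """``SNV`` iff both alleles are single bases, else ``INDEL``."""
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"


@dataclass(frozen=True)
class Observation:
    """Read support for one variant in one sample."""

    variant: Variant
    sample_id: str
    alt_count: int
    ref_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.alt_count + self.ref_count > self.depth:
            raise ValueError(
                f"alt_count + ref_count exceeds depth for {self.variant.key} "
                f"in {self.sample_id}: {self.alt_count}+{self.ref_count} > {self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class SampleRecord:
    """One biospecimen: compartment, timing and accompanying measurements.

    ``time_days`` is signed days relative to surgery (negative =
    preoperative). ``cfdna_conc`` (ng cfDNA per mL plasma) is required for
    plasma samples and must be absent for tissue/PBL. CEA (μg/L) and
    CA 19-9 (kU/L) are optional serum markers.
    """

    sample_id: str
    patient_id: str
    compartment: str
    time_days: float
    cfdna_conc: float | None = None
    cea: float | None = None
    ca199: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.compartment == "plasma":
            if self.cfdna_conc is None:
                raise ValueError(f"plasma sample {self.sample_id} lacks cfdna_conc")
            if self.cfdna_conc < 0:
                raise ValueError("cfdna_conc must be >= 0")
        elif self.cfdna_conc is not None:
            raise ValueError(
                f"cfdna_conc given for non-plasma sample {self.sample_id}"
            )


@dataclass
class VariantCalls:
    """Variants plus their per-sample read support.

    ``observations`` has one row per (sample, variant) with the
    allele-count TSV columns plus ``vaf``; ``n_rejected`` counts
    zero-depth rows that were dropped on read.
    """

    variants: list[Variant]
    observations: pd.DataFrame
    n_rejected: int = 0

    def variant_index(self) -> dict[tuple[str, int, str, str], Variant]:
        return {v.key: v for v in self.variants}

    @property
    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


def _empty_observations() -> pd.DataFrame:
    return pd.DataFrame(columns=COUNT_COLUMNS + ["vaf"])


def _calls_from_rows(rows: list[dict], variants: dict, n_rejected: int) -> VariantCalls:
    obs = pd.DataFrame(rows, columns=COUNT_COLUMNS) if rows else _empty_observations()
    if rows:
        obs["vaf"] = obs["alt_count"] / obs["depth"]
    return VariantCalls(
        variants=list(variants.values()), observations=obs, n_rejected=n_rejected
    )


def read_variants(path: str | Path, fmt: str = "tsv") -> VariantCalls:
    """Read a variant-call file into validated variants + observations.

    Parameters
    ----------
    path
        Input file.
    fmt
        ``"tsv"`` for the allele-count dialect, ``"vcf"`` for VCF v4.2
        with per-sample AD/DP. Multi-allelic VCF records are split into
        one variant per alternate allele.

    Zero-depth rows are rejected (counted in the returned envelope's
    ``n_rejected``); any other invariant violation raises ``ValueError``
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        return _read_variants_tsv(path)
    if fmt == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'vcf'")


def _read_variants_tsv(path: Path) -> VariantCalls:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_gene = "gene" in df.columns
    has_csq = "consequence" in df.columns

    rows: list[dict] = []
    variants: dict[tuple, Variant] = {}
    n_rejected = 0
    for i, rec in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            depth = int(getattr(rec, "depth"))
            if depth == 0:
                n_rejected += 1
                continue
            variant = Variant(
                chrom=str(rec.chrom),
                pos=int(rec.pos),
                ref=str(rec.ref),
                alt=str(rec.alt),
                gene=str(getattr(rec, "gene", "") or "") if has_gene else "",
                consequence=(str(rec.consequence) if has_csq and rec.consequence else "other"),
            )
            obs = Observation(
                variant=variant,
                sample_id=str(rec.sample_id),
                alt_count=int(rec.alt_count),
                ref_count=int(rec.ref_count),
                depth=depth,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        variants.setdefault(variant.key, variant)
        rows.append(
            {
                "sample_id": obs.sample_id,
                "chrom": variant.chrom,
                "pos": variant.pos,
                "ref": variant.ref,
                "alt": variant.alt,
                "ref_count": obs.ref_count,
                "alt_count": obs.alt_count,
                "depth": obs.depth,
            }
        )
    return _calls_from_rows(rows, variants, n_rejected)


def _read_variants_vcf(path: Path) -> VariantCalls:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    variants: dict[tuple, Variant] = {}
    n_rejected = 0
    for rec in vcf:
        gene = rec.INFO.get("GENE") or ""
        consequence = rec.INFO.get("CSQ") or "other"
        ad = rec.format("AD")  # shape (n_samples, 1 + n_alts)
        if ad is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD")
        dp = rec.format("DP")
        for ai, alt in enumerate(rec.ALT):
            variant = Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                gene=gene,
                consequence=consequence,
            )
            variants.setdefault(variant.key, variant)
            for si, sample in enumerate(samples):
                ref_count = int(ad[si, 0])
                alt_count = int(ad[si, ai + 1])
                depth = (
                    int(dp[si].ravel()[0]) if dp is not None else ref_count + alt_count
                )
                if depth <= 0:
                    n_rejected += 1
                    continue
                obs = Observation(  # validates invariants
                    variant=variant,
                    sample_id=sample,
                    alt_count=alt_count,
                    ref_count=ref_count,
                    depth=depth,
                )
                rows.append(
                    {
                        "sample_id": sample,
                        "chrom": variant.chrom,
                        "pos": variant.pos,
                        "ref": variant.ref,
                        "alt": variant.alt,
                        "ref_count": obs.ref_count,
                        "alt_count": obs.alt_count,
                        "depth": obs.depth,
                    }
                )
    return _calls_from_rows(rows, variants, n_rejected)


def _opt_float(value: str) -> float | None:
    value = value.strip()
    return None if value == "" else float(value)


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read the sample sheet; enforces compartment-conditional fields.

    Errors on duplicate sample ids, on plasma rows lacking a cfDNA
    concentration, and on duplicate plasma collection times within a
    patient.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[SampleRecord] = []
    seen_ids: set[str] = set()
    plasma_times: set[tuple[str, float]] = set()
    for i, rec in enumerate(df.itertuples(index=False)):
        lineno = i + 2
        sample_id = str(rec.sample_id)
        if sample_id in seen_ids:
            raise ValueError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
        seen_ids.add(sample_id)
        try:
            record = SampleRecord(
                sample_id=sample_id,
                patient_id=str(rec.patient_id),
                compartment=str(rec.compartment),
                time_days=float(rec.time_days),
                cfdna_conc=_opt_float(str(rec.cfdna_conc)),
                cea=_opt_float(str(rec.cea)),
                ca199=_opt_float(str(rec.ca199)),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if record.compartment == "plasma":
            tkey = (record.patient_id, record.time_days)
            if tkey in plasma_times:
                raise ValueError(
                    f"{path}:{lineno}: duplicate plasma time {record.time_days} "
                    f"for patient {record.patient_id}"
                )
            plasma_times.add(tkey)
        records.append(record)
    return records


def _fmt_opt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.6g}"


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    lines = ["\t".join(SHEET_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.sample_id,
                    r.patient_id,
                    r.compartment,
                    f"{r.time_days:.6g}",
                    _fmt_opt(r.cfdna_conc),
                    _fmt_opt(r.cea),
                    _fmt_opt(r.ca199),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_counts_tsv(
    observations: pd.DataFrame,
    path: str | Path,
    variant_annotations: Mapping[tuple, Variant] | None = None,
) -> None:
    """Write an allele-count table in the TSV dialect.

    When ``variant_annotations`` is given, ``gene`` and ``consequence``
    columns are appended from it.
    """
    df = observations.loc[:, COUNT_COLUMNS].copy()
    if variant_annotations is not None:
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        df["gene"] = [variant_annotations[k].gene for k in keys]
        df["consequence"] = [variant_annotations[k].consequence for k in keys]
    df.to_csv(path, sep="\t", index=False)


def write_variants_vcf(
    variants: Sequence[Variant],
    observations: pd.DataFrame,
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Write a minimal valid VCF v4.2 with per-sample GT/AD/DP.

    Variants with no observation in a sample get ``./.`` with zero
    counts. Output is deterministic: records sorted by (chrom, pos, ref,
    alt), samples in the order given (or sorted).
    """
    if sample_ids is None:
        sample_ids = sorted(observations["sample_id"].unique())
    by_key: dict[tuple, dict[str, tuple[int, int, int]]] = {}
    for rec in observations.itertuples(index=False):
        key = (rec.chrom, rec.pos, rec.ref, rec.alt)
        by_key.setdefault(key, {})[rec.sample_id] = (
            int(rec.ref_count),
            int(rec.alt_count),
            int(rec.depth),
        )
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    contigs = sorted({v.chrom for v in ordered})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    for v in ordered:
        info_parts = []
        if v.gene:
            info_parts.append(f"GENE={v.gene}")
        info_parts.append(f"CSQ={v.consequence}")
        cols = [
            v.chrom,
            str(v.pos),
            ".",
            v.ref,
            v.alt,
            ".",
            "PASS",
            ";".join(info_parts),
            "GT:AD:DP",
        ]
        support = by_key.get(v.key, {})
        for sample in sample_ids:
            if sample in support:
                ref_c, alt_c, depth = support[sample]
                cols.append(f"0/1:{ref_c},{alt_c}:{depth}")
            else:
                cols.append("./.:0,0:0")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_results(series: Sequence, path: str | Path) -> None:
    """Write one row per (patient, time point) of a tumor-load series.

    ``series`` is any sequence of objects carrying the TumorLoadPoint
    attributes (patient_id, time_days, mean_vaf, ctdna_ng_per_ml,
    cfdna_conc, cea, ca199, relapse_flag). Values round-trip through
    :func:`read_results` to 6 significant digits.
    """
    if len(series) == 0:
        raise ValueError("refusing to write an empty results series")
    lines = ["\t".join(RESULT_COLUMNS)]
    for p in series:
        lines.append(
            "\t".join(
                [
                    str(p.patient_id),
                    f"{p.time_days:.6g}",
                    f"{p.mean_vaf:.6g}",
                    f"{p.ctdna_ng_per_ml:.6g}",
                    f"{p.cfdna_conc:.6g}",
                    _fmt_opt(p.cea),
                    _fmt_opt(p.ca199),
                    str(int(bool(p.relapse_flag))),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (inverse of write_results)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing results columns {missing}")
    df["relapse_flag"] = df["relapse_flag"].astype(bool)
    return df
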