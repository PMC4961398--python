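"""Synthetic ctDNA monitoring cohorts with known ground truth.

Emulates a small surgical colorectal-cancer cohort profiled by deep
targeted sequencing: per patient a resected-tumor mutation catalog
(6-45 nonsynonymous mutations, ~89% SNV / ~11% indel, C>A/G>T-dominant
substitution spectrum), matched germline (PBL) calls, and serial plasma
samples collected one week before surgery, one month after, and at
3-month follow-up intervals. The latent tumor-fraction trajectory is
piecewise: a preoperative plateau, a sharp post-surgical drop to a
residual level, and — for relapsing patients — exponential regrowth
from a relapse onset time. Plasma read counts are binomial draws at
realistic panel depths with a flat per-base background error rate;
spatial heterogeneity is modelled by shedding only a random subset of
tissue markers into plasma and by injecting de novo plasma-only
mutations. Serum CEA / CA 19-9 are simulated as insensitive biomarkers:
only a Bernoulli-selected subset of patients secrete them in proportion
to tumor fraction, so relapse with normal serum markers is common.

What this generator does *not* model: trinucleotide-specific error,
fragment-size signal, clonal evolution between tissue and relapse, and
depth variation across panel sites beyond a uniform draw per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    SampleRecord,
    Variant,
    write_counts_tsv,
    write_sample_sheet,
    write_variants_vcf,
)
from .spectrum_summary import CATEGORIES

__all__ = [
    "DEFAULT_SPECTRUM_WEIGHTS",
    "SimulationConfig",
    "SimulatedMutation",
    "PatientTruth",
    "simulate_tumor_profile",
    "simulate_trajectory",
    "simulate_plasma_sample",
    "simulate_biomarkers",
    "simulate_patient",
    "generate_cohort",
]

#: default collapsed-spectrum weights; C>A/G>T transversions dominate
#: (0.47) with C>T/G>A transitions the runner-up, as in colorectal
#: tumor panels.
DEFAULT_SPECTRUM_WEIGHTS = {
    "C>A/G>T": 0.47,
    "C>G/G>C": 0.08,
    "C>T/G>A": 0.30,
    "T>A/A>T": 0.05,
    "T>C/A>G": 0.07,
    "T>G/A>C": 0.03,
}

#: recurrently mutated colorectal driver genes; one per simulated tumor
DRIVER_GENES = ("APC", "KRAS", "TP53")

#: passenger symbols drawn from a broad solid-tumor panel
PANEL_GENES = (
    "PIK3CA", "SMAD4", "FBXW7", "TCF7L2", "BRAF", "NRAS", "FAT4", "ARID1A",
    "SOX9", "ATM", "PTEN", "CTNNB1", "KMT2D", "RNF43", "AMER1", "GNAS",
    "BCL9", "ERBB3", "CASP8", "EP300", "LRP1B", "PREX2", "SPEN", "TGFBR2",
)

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: default collection schedule (days vs surgery): 1 week before, 1 month
#: after, then every 3 months out to 2 years of follow-up.
DEFAULT_SAMPLING_TIMES = (-7, 30, 120, 210, 300, 390, 480, 570, 660, 750)


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults."""

    n_patients: int = 6
    n_mutations_range: tuple[int, int] = (6, 45)
    indel_fraction: float = 0.11
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS)
    )
    preop_tumor_fraction_range: tuple[float, float] = (0.004, 0.02)
    postop_residual_fraction: float = 5e-4
    relapse_fraction: float = 1 / 6
    relapse_growth_fold_per_month: float = 2.0
    relapse_onset_range_days: tuple[float, float] = (180.0, 540.0)
    plasma_depth_range: tuple[int, int] = (308, 1436)
    tissue_depth: int = 500
    error_rate: float = 1e-3
    tissue_plasma_overlap: tuple[float, float] = (0.5, 0.9)
    de_novo_plasma_rate: float = 1.0
    cfdna_conc_median: float = 25.0
    cfdna_conc_sigma: float = 0.5
    biomarker_sensitivity: float = 0.3
    biomarker_noise_sd: float = 0.1
    cea_baseline_median: float = 2.0
    ca199_baseline_median: float = 10.0
    cea_gain: float = 400.0  # μg/L per unit tumor fraction
    ca199_gain: float = 2000.0  # kU/L per unit tumor fraction
    purity_range: tuple[float, float] = (0.3, 0.7)
    clonal_fraction_range: tuple[float, float] = (0.2, 1.0)
    n_germline: int = 30
    n_synonymous_mean: float = 4.0
    n_decoy_sites: int = 50
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_mutations_range",
            "sampling_times",
            "preop_tumor_fraction_range",
            "plasma_depth_range",
            "tissue_plasma_overlap",
            "relapse_onset_range_days",
            "purity_range",
            "clonal_fraction_range",
        ):
            setattr(self, name, tuple(getattr(self, name)))
        for name in (
            "indel_fraction",
            "postop_residual_fraction",
            "relapse_fraction",
            "error_rate",
            "biomarker_sensitivity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        for name in (
            "n_mutations_range",
            "preop_tumor_fraction_range",
            "plasma_depth_range",
            "tissue_plasma_overlap",
            "relapse_onset_range_days",
            "purity_range",
            "clonal_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min {lo} exceeds max {hi}")
        if self.plasma_depth_range[0] <= 0:
            raise ValueError("plasma depths must be positive")
        if set(self.spectrum_weights) != set(CATEGORIES):
            raise ValueError("spectrum_weights must cover the 6 categories")
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"spectrum_weights must sum to 1, got {total}")
        if self.relapse_growth_fold_per_month <= 1:
            raise ValueError("relapse growth fold per month must exceed 1")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise ValueError("sampling_times must be sorted")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["n_mutations_range"] = list(self.n_mutations_range)
        data["sampling_times"] = list(self.sampling_times)
        for key in (
            "preop_tumor_fraction_range",
            "plasma_depth_range",
            "tissue_plasma_overlap",
            "relapse_onset_range_days",
            "purity_range",
            "clonal_fraction_range",
        ):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class SimulatedMutation:
    """One true tumor mutation with its cellular prevalence."""

    variant: Variant
    clonal_fraction: float
    origin: str  # "tissue" or "de_novo"
    shed: bool  # whether plasma ever carries it (spatial heterogeneity)


@dataclass
class PatientTruth:
    """Everything the generator knows about one simulated patient."""

    patient_id: str
    purity: float
    preop_fraction: float
    relapse: bool
    relapse_time_days: float | None
    overlap: float
    mutations: list[SimulatedMutation]
    trajectory: dict[float, float]
    cea_responder: bool
    ca199_responder: bool

    @property
    def marker_mutations(self) -> list[SimulatedMutation]:
        """Trackable truth: nonsynonymous somatic mutations (any origin)."""
        return [
            m
            for m in self.mutations
            if m.variant.consequence != "synonymous_snv"
        ]


def patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    """Independent substream per patient: adding patients never perturbs
    earlier patients' draws."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(patient_index,))
    )


def _draw_snv_alleles(rng: np.random.Generator, weights: dict[str, float]) -> tuple[str, str]:
    probs = np.array([weights[c] for c in CATEGORIES])
    cat = CATEGORIES[rng.choice(len(CATEGORIES), p=probs)]
    pyr = cat.split("/")[0]
    ref, alt = pyr[0], pyr[2]
    if rng.random() < 0.5:  # emit the purine-strand presentation
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _draw_indel_alleles(rng: np.random.Generator) -> tuple[str, str, str]:
    """Anchored-base VCF indel; returns (ref, alt, consequence)."""
    anchor = "ACGT"[rng.integers(4)]
    length = int(rng.integers(1, 7))
    inserted = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if rng.random() < 0.5:  # insertion
        ref, alt = anchor, anchor + inserted
    else:  # deletion
        ref, alt = anchor + inserted, anchor
    consequence = "inframe_indel" if length % 3 == 0 else "frameshift_indel"
    return ref, alt, consequence


def _draw_site(rng: np.random.Generator, used: set) -> tuple[str, int]:
    while True:
        chrom = _CHROMS[rng.integers(len(_CHROMS))]
        pos = int(rng.integers(1_000_000, 120_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _draw_variant(
    rng: np.random.Generator,
    used_sites: set,
    weights: dict[str, float],
    indel_fraction: float,
    gene: str,
    synonymous: bool = False,
) -> Variant:
    chrom, pos = _draw_site(rng, used_sites)
    if not synonymous and rng.random() < indel_fraction:
        ref, alt, consequence = _draw_indel_alleles(rng)
    else:
        ref, alt = _draw_snv_alleles(rng, weights)
        consequence = "synonymous_snv" if synonymous else "nonsynonymous_snv"
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                   consequence=consequence)


def simulate_tumor_profile(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "P1",
    used_sites: set | None = None,
) -> tuple[list[SimulatedMutation], pd.DataFrame, float]:
    """Draw a tumor's somatic mutation catalog and its tissue read support.

    The mutation count is uniform over ``n_mutations_range``; alleles
    follow ``spectrum_weights`` with random strand presentation for SNVs
    and ``indel_fraction`` of anchored indels. One mutation is a fully
    clonal known driver (APC/KRAS/TP53 pool); the rest take passenger
    symbols and clonal fractions from ``clonal_fraction_range``. Tissue
    VAF is clonal_fraction x purity / 2 (heterozygous diploid), sampled
    binomially at ``tissue_depth``. Returns (mutations, tissue
    observations, purity).
    """
    lo, hi = config.n_mutations_range
    if lo > hi:
        raise ValueError("degenerate n_mutations_range")
    if used_sites is None:
        used_sites = set()
    n_mut = int(rng.integers(lo, hi + 1))
    purity = float(rng.uniform(*config.purity_range))

    mutations: list[SimulatedMutation] = []
    driver_gene = DRIVER_GENES[rng.integers(len(DRIVER_GENES))]
    for i in range(n_mut):
        if i == 0:
            gene, cf = driver_gene, 1.0
        else:
            gene = PANEL_GENES[rng.integers(len(PANEL_GENES))]
            cf = float(rng.uniform(*config.clonal_fraction_range))
        variant = _draw_variant(
            rng, used_sites, config.spectrum_weights, config.indel_fraction, gene
        )
        mutations.append(
            SimulatedMutation(variant=variant, clonal_fraction=cf,
                              origin="tissue", shed=True)
        )

    sample_id = f"{patient_id}_T"
    rows = []
    for m in mutations:
        vaf = m.clonal_fraction * purity / 2.0
        depth = config.tissue_depth
        alt = int(rng.binomial(depth, vaf))
        rows.append(
            {
                "sample_id": sample_id,
                "chrom": m.variant.chrom,
                "pos": m.variant.pos,
                "ref": m.variant.ref,
                "alt": m.variant.alt,
                "ref_count": depth - alt,
                "alt_count": alt,
                "depth": depth,
            }
        )
    tissue_obs = pd.DataFrame(rows)
    return mutations, tissue_obs, purity


def tumor_fraction_at(
    t: float,
    preop_fraction: float,
    residual_fraction: float,
    relapse_time: float | None,
    growth_fold_per_month: float,
) -> float:
    """Piecewise latent trajectory: plateau, post-surgical drop, regrowth."""
    if t < 0:
        return preop_fraction
    if relapse_time is not None and t >= relapse_time:
        months = (t - relapse_time) / 30.0
        return min(1.0, residual_fraction * growth_fold_per_month**months)
    return residual_fraction


def simulate_trajectory(
    config: SimulationConfig,
    relapse: bool,
    times: Sequence[float],
    rng: np.random.Generator | None = None,
    preop_fraction: float | None = None,
    relapse_time: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Evaluate the latent tumor fraction at the given (sorted) times.

    Preoperative level and relapse onset are drawn from the config
    ranges unless supplied explicitly (then the function is fully
    deterministic). Returns (fractions, parameter dict).
    """
    if list(times) != sorted(times):
        raise ValueError("times must be sorted")
    if preop_fraction is None:
        if rng is None:
            raise ValueError("need an rng to draw preop_fraction")
        preop_fraction = float(rng.uniform(*config.preop_tumor_fraction_range))
    if relapse and relapse_time is None:
        if rng is None:
            raise ValueError("need an rng to draw relapse_time")
        relapse_time = float(rng.uniform(*config.relapse_onset_range_days))
    if not relapse:
        relapse_time = None
    f = np.array(
        [
            tumor_fraction_at(
                t,
                preop_fraction,
                config.postop_residual_fraction,
                relapse_time,
                config.relapse_growth_fold_per_month,
            )
            for t in times
        ]
    )
    return f, {"preop_fraction": preop_fraction, "relapse_time": relapse_time}


def simulate_plasma_sample(
    markers: Sequence[SimulatedMutation],
    f_t: float,
    depth_range: tuple[int, int],
    error_rate: float,
    rng: np.random.Generator,
    sample_id: str = "S",
    decoy_sites: Sequence[Variant] = (),
) -> pd.DataFrame:
    """Binomial read counts for every tracked marker (plus decoy sites).

    A shed marker's expected VAF is f_t x clonal_fraction / 2 plus the
    background error rate; an unshed marker and every decoy site see
    error only. Depth is uniform over ``depth_range`` per site.
    """
    if not 0.0 <= f_t <= 1.0:
        raise ValueError(f"tumor fraction out of [0,1]: {f_t}")
    lo, hi = depth_range
    rows = []
    for m in markers:
        depth = int(rng.integers(lo, hi + 1))
        expected = (f_t * m.clonal_fraction / 2.0 if m.shed else 0.0) + error_rate
        alt = int(rng.binomial(depth, min(1.0, expected)))
        rows.append(
            {
                "sample_id": sample_id,
                "chrom": m.variant.chrom,
                "pos": m.variant.pos,
                "ref": m.variant.ref,
                "alt": m.variant.alt,
                "ref_count": depth - alt,
                "alt_count": alt,
                "depth": depth,
            }
        )
    for v in decoy_sites:
        depth = int(rng.integers(lo, hi + 1))
        alt = int(rng.binomial(depth, error_rate))
        rows.append(
            {
                "sample_id": sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "ref_count": depth - alt,
                "alt_count": alt,
                "depth": depth,
            }
        )
    return pd.DataFrame(rows)


def simulate_biomarkers(
    f_t: float | np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    responders: tuple[bool, bool],
    baselines: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Serum CEA (μg/L) and CA 19-9 (kU/L) at the given tumor fractions.

    Each marker responds to tumor fraction only in "responder" patients
    (drawn Bernoulli(biomarker_sensitivity) upstream); non-responders
    fluctuate around their baseline regardless of burden, which is how a
    relapse can present with normal serum markers.
    """
    f = np.atleast_1d(np.asarray(f_t, dtype=float))
    if baselines is None:
        baselines = (config.cea_baseline_median, config.ca199_baseline_median)
    cea_resp, ca_resp = responders
    noise_cea = rng.normal(0.0, config.biomarker_noise_sd, size=f.shape)
    noise_ca = rng.normal(0.0, config.biomarker_noise_sd, size=f.shape)
    cea = baselines[0] * np.exp(noise_cea) + (config.cea_gain * f if cea_resp else 0.0)
    ca199 = baselines[1] * np.exp(noise_ca) + (
        config.ca199_gain * f if ca_resp else 0.0
    )
    return cea, ca199


@dataclass
class SimulatedPatient:
    """In-memory bundle for one patient: truth + every generated table."""

    truth: PatientTruth
    tissue_calls: list[Variant]  # somatic + germline + synonymous, as a caller emits
    tissue_obs: pd.DataFrame
    pbl_calls: list[Variant]
    pbl_obs: pd.DataFrame
    plasma_obs: pd.DataFrame  # all time points stacked
    samples: list[SampleRecord]
    decoy_sites: list[Variant]


def simulate_patient(
    config: SimulationConfig, patient_index: int
) -> SimulatedPatient:
    """Simulate one patient end to end on their own RNG substream."""
    rng = patient_rng(config.seed, patient_index)
    patient_id = f"P{patient_index + 1}"
    used_sites: set = set()

    mutations, tissue_obs, purity = simulate_tumor_profile(
        config, rng, patient_id=patient_id, used_sites=used_sites
    )

    # spatial heterogeneity: only a theta-fraction of tissue markers shed
    overlap = float(rng.uniform(*config.tissue_plasma_overlap))
    for m in mutations:
        m.shed = bool(rng.random() < overlap)

    # somatic synonymous calls ride along in tissue output but are not markers
    n_syn = int(rng.poisson(config.n_synonymous_mean))
    synonymous: list[Variant] = []
    for _ in range(n_syn):
        gene = PANEL_GENES[rng.integers(len(PANEL_GENES))]
        synonymous.append(
            _draw_variant(rng, used_sites, config.spectrum_weights, 0.0, gene,
                          synonymous=True)
        )

    # germline variants appear in both tissue and PBL calls at het/hom VAF
    germline: list[Variant] = []
    pbl_rows = []
    tissue_germ_rows = []
    for _ in range(config.n_germline):
        gene = PANEL_GENES[rng.integers(len(PANEL_GENES))]
        v = _draw_variant(
            rng, used_sites, config.spectrum_weights, config.indel_fraction, gene
        )
        germline.append(v)
        g_vaf = 0.5 if rng.random() < 0.8 else 1.0
        for rows, sid in ((pbl_rows, f"{patient_id}_PBL"),
                          (tissue_germ_rows, f"{patient_id}_T")):
            depth = config.tissue_depth
            alt = int(rng.binomial(depth, g_vaf))
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "depth": depth,
                }
            )

    # de novo plasma-only mutations (heterogeneity the biopsy missed)
    n_denovo = int(rng.poisson(config.de_novo_plasma_rate))
    for _ in range(n_denovo):
        gene = PANEL_GENES[rng.integers(len(PANEL_GENES))]
        v = _draw_variant(
            rng, used_sites, config.spectrum_weights, config.indel_fraction, gene
        )
        mutations.append(
            SimulatedMutation(
                variant=v,
                clonal_fraction=float(rng.uniform(*config.clonal_fraction_range)),
                origin="de_novo",
                shed=True,
            )
        )

    decoys = [
        _draw_variant(rng, used_sites, config.spectrum_weights, 0.0, "")
        for _ in range(config.n_decoy_sites)
    ]

    # latent trajectory and relapse assignment happen in generate-cohort
    # order for reproducibility; relapse status is passed in via index
    relapse = _relapse_assignment(config)[patient_index]
    times = list(config.sampling_times)
    f, params = simulate_trajectory(config, relapse, times, rng=rng)

    responders = (
        bool(rng.random() < config.biomarker_sensitivity),
        bool(rng.random() < config.biomarker_sensitivity),
    )
    cea_base = float(config.cea_baseline_median * rng.lognormal(0.0, 0.3))
    ca_base = float(config.ca199_baseline_median * rng.lognormal(0.0, 0.3))
    cea, ca199 = simulate_biomarkers(
        f, config, rng, responders, baselines=(cea_base, ca_base)
    )

    samples: list[SampleRecord] = [
        SampleRecord(
            sample_id=f"{patient_id}_T",
            patient_id=patient_id,
            compartment="tissue",
            time_days=0.0,
        ),
        SampleRecord(
            sample_id=f"{patient_id}_PBL",
            patient_id=patient_id,
            compartment="PBL",
            time_days=0.0,
        ),
    ]
    trackable = [m for m in mutations if m.variant.consequence != "synonymous_snv"]
    plasma_frames = []
    for i, t in enumerate(times):
        sid = f"{patient_id}_d{int(t)}"
        cfdna = float(
            config.cfdna_conc_median * rng.lognormal(0.0, config.cfdna_conc_sigma)
        )
        samples.append(
            SampleRecord(
                sample_id=sid,
                patient_id=patient_id,
                compartment="plasma",
                time_days=float(t),
                cfdna_conc=round(cfdna, 4),
                cea=round(float(cea[i]), 4),
                ca199=round(float(ca199[i]), 4),
            )
        )
        plasma_frames.append(
            simulate_plasma_sample(
                trackable,
                float(f[i]),
                config.plasma_depth_range,
                config.error_rate,
                rng,
                sample_id=sid,
                decoy_sites=decoys,
            )
        )

    truth = PatientTruth(
        patient_id=patient_id,
        purity=purity,
        preop_fraction=params["preop_fraction"],
        relapse=relapse,
        relapse_time_days=params["relapse_time"],
        overlap=overlap,
        mutations=mutations,
        trajectory={float(t): float(f[i]) for i, t in enumerate(times)},
        cea_responder=responders[0],
        ca199_responder=responders[1],
    )
    tissue_calls = [m.variant for m in mutations if m.origin == "tissue"]
    tissue_calls = tissue_calls + synonymous + germline
    tissue_all_obs = pd.concat(
        [tissue_obs, pd.DataFrame(tissue_germ_rows)], ignore_index=True
    )
    return SimulatedPatient(
        truth=truth,
        tissue_calls=tissue_calls,
        tissue_obs=tissue_all_obs,
        pbl_calls=list(germline),
        pbl_obs=pd.DataFrame(pbl_rows),
        plasma_obs=pd.concat(plasma_frames, ignore_index=True),
        samples=samples,
        decoy_sites=decoys,
    )


def _relapse_assignment(config: SimulationConfig) -> list[bool]:
    """Deterministic relapse flags by stride: patient i relapses iff the
    running count floor((i+1) x fraction) increments at i. Keeps the
    relapse share at the configured fraction while guaranteeing that
    growing the cohort never changes earlier patients (no shared RNG)."""
    fr = config.relapse_fraction
    return [
        int((i + 1) * fr + 1e-9) > int(i * fr + 1e-9)
        for i in range(config.n_patients)
    ]


def _truth_to_dict(truth: PatientTruth) -> dict:
    return {
        "patient_id": truth.patient_id,
        "purity": truth.purity,
        "preop_fraction": truth.preop_fraction,
        "relapse": truth.relapse,
        "relapse_time_days": truth.relapse_time_days,
        "overlap": truth.overlap,
        "cea_responder": truth.cea_responder,
        "ca199_responder": truth.ca199_responder,
        "trajectory": {str(t): f for t, f in truth.trajectory.items()},
        "mutations": [
            {
                "chrom": m.variant.chrom,
                "pos": m.variant.pos,
                "ref": m.variant.ref,
                "alt": m.variant.alt,
                "gene": m.variant.gene,
                "consequence": m.variant.consequence,
                "clonal_fraction": m.clonal_fraction,
                "origin": m.origin,
                "shed": m.shed,
            }
            for m in truth.mutations
        ],
    }


def generate_cohort(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete synthetic cohort to ``out_dir``.

    Per patient: ``<P>.tissue.vcf`` and ``<P>.pbl.vcf`` (caller-style
    output, germline included in the tissue calls), and
    ``<P>.plasma_counts.tsv`` (all time points stacked). Cohort-wide:
    ``sample_sheet.tsv``, ``ground_truth.json`` and ``config.yaml``.
    Deterministic for a given seed (byte-identical re-runs). Returns a
    manifest of the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"patients": {}, "out_dir": str(out)}
    all_samples: list[SampleRecord] = []
    truths: dict[str, dict] = {}
    for i in range(config.n_patients):
        sp = simulate_patient(config, i)
        pid = sp.truth.patient_id
        tissue_vcf = out / f"{pid}.tissue.vcf"
        pbl_vcf = out / f"{pid}.pbl.vcf"
        plasma_tsv = out / f"{pid}.plasma_counts.tsv"
        annotations = {v.key: v for v in sp.tissue_calls}
        write_variants_vcf(sp.tissue_calls, sp.tissue_obs, tissue_vcf,
                           sample_ids=[f"{pid}_T"])
        write_variants_vcf(sp.pbl_calls, sp.pbl_obs, pbl_vcf,
                           sample_ids=[f"{pid}_PBL"])
        write_counts_tsv(sp.plasma_obs, plasma_tsv)
        manifest["patients"][pid] = {
            "tissue_vcf": str(tissue_vcf),
            "pbl_vcf": str(pbl_vcf),
            "plasma_counts": str(plasma_tsv),
        }
        all_samples.extend(sp.samples)
        truths[pid] = _truth_to_dict(sp.truth)
    sheet_path = out / "sample_sheet.tsv"
    write_sample_sheet(all_samples, sheet_path)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truths, indent=2, sort_keys=True))
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    manifest["sample_sheet"] = str(sheet_path)
    manifest["ground_truth"] = str(truth_path)
    manifest["config"] = str(config_path)
    return manifest
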