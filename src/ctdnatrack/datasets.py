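"""Small built-in example datasets, constructed programmatically.

``relapse_example`` is a synthetic worked case modelled on a relapsing
colorectal-cancer patient: six plasma markers (five tumor-derived, one
de novo), three plasma time points (one week pre-op, one month post-op,
relapse at month 18), a 13-fold rise in absolute ctDNA at relapse with
five of the six marker VAFs above their preoperative values, and serum
CEA / CA 19-9 that stay within their reference ranges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import SampleRecord, Variant, VariantCalls

__all__ = ["RelapseExample", "relapse_example"]

# (gene, chrom, pos, ref, alt, tissue_derived, preop_alt, postop_alt, relapse_alt)
_MARKERS = [
    ("APC", "chr5", 112175240, "G", "T", True, 9, 6, 15),
    ("KRAS", "chr12", 25398284, "C", "A", True, 12, 0, 18),
    ("TP53", "chr17", 7578406, "C", "T", True, 20, 0, 12),
    ("SMAD4", "chr18", 48591918, "C", "A", True, 8, 0, 11),
    ("FBXW7", "chr4", 153249385, "G", "T", True, 10, 0, 13),
    ("PIK3CA", "chr3", 178936091, "G", "A", False, 7, 0, 9),
]

_DEPTH = 1000

_SAMPLES = [
    # sample_id, time_days, cfdna ng/mL, CEA μg/L, CA19-9 kU/L
    ("P4_preop", -7.0, 30.0, 3.72, 16.0),
    ("P4_postop", 30.0, 20.0, 2.5, 12.0),
    ("P4_relapse", 540.0, 20.0, 3.8, 18.7),
]


@dataclass
class RelapseExample:
    """In-memory inputs for the worked relapse case."""

    patient_id: str
    tissue_calls: VariantCalls
    pbl_calls: VariantCalls
    plasma_observations: pd.DataFrame
    sample_sheet: list[SampleRecord]


def relapse_example() -> RelapseExample:
    """Build the synthetic relapsing-patient example.

    All read counts are at depth 1000, so VAFs are exact: the
    preoperative panel mean VAF is 1.1% (0.33 ng/mL at 30 ng/mL cfDNA),
    the post-operative nadir 0.1% (0.02 ng/mL), and the relapse point
    1.3% (0.26 ng/mL) — a 13-fold rise over the nadir. All six
    preoperative mutations reappear at relapse; every VAF rises except
    TP53.
    """
    patient_id = "P4"
    variants = [
        Variant(chrom=c, pos=p, ref=r, alt=a, gene=g,
                consequence="nonsynonymous_snv")
        for g, c, p, r, a, _, _, _, _ in _MARKERS
    ]
    tissue_variants = [
        v for v, m in zip(variants, _MARKERS) if m[5]
    ]
    tissue_rows = []
    for v in tissue_variants:
        alt = 200  # clonal at ~40% in tissue
        tissue_rows.append(
            {
                "sample_id": f"{patient_id}_T",
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "ref_count": 500 - alt,
                "alt_count": alt,
                "depth": 500,
            }
        )
    tissue_obs = pd.DataFrame(tissue_rows)
    tissue_obs["vaf"] = tissue_obs["alt_count"] / tissue_obs["depth"]
    tissue_calls = VariantCalls(variants=tissue_variants, observations=tissue_obs)
    pbl_calls = VariantCalls(
        variants=[],
        observations=pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt",
                     "ref_count", "alt_count", "depth", "vaf"]
        ),
    )

    plasma_rows = []
    for (g, c, p, r, a, _tissue, pre, post, rel), v in zip(_MARKERS, variants):
        for (sid, _t, _cf, _cea, _ca), alt in zip(
            _SAMPLES, (pre, post, rel)
        ):
            if alt == 0:
                continue  # marker absent from that sample's count table
            plasma_rows.append(
                {
                    "sample_id": sid,
                    "chrom": c,
                    "pos": p,
                    "ref": r,
                    "alt": a,
                    "ref_count": _DEPTH - alt,
                    "alt_count": alt,
                    "depth": _DEPTH,
                }
            )
    plasma_obs = pd.DataFrame(plasma_rows)

    sheet = [
        SampleRecord(
            sample_id=f"{patient_id}_T",
            patient_id=patient_id,
            compartment="tissue",
            time_days=0.0,
        )
    ] + [
        SampleRecord(
            sample_id=sid,
            patient_id=patient_id,
            compartment="plasma",
            time_days=t,
            cfdna_conc=cf,
            cea=cea,
            ca199=ca,
        )
        for sid, t, cf, cea, ca in _SAMPLES
    ]
    return RelapseExample(
        patient_id=patient_id,
        tissue_calls=tissue_calls,
        pbl_calls=pbl_calls,
        plasma_observations=plasma_obs,
        sample_sheet=sheet,
    )
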