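"""Somatic marker derivation and plasma detection calls.

Somatic candidates come from subtracting matched germline (PBL) calls
from the tumor-tissue calls and keeping protein-altering events
(nonsynonymous SNVs, frameshift and in-frame indels). Whether a tracked
marker is *detected* in a plasma sample is decided by an exact binomial
test of its alt-read count against a per-base background error rate,
with a minimum alt-read floor — the standard call/no-call rule for
low-frequency variant tracking in deep targeted sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_formats import NONSYNONYMOUS_CONSEQUENCES, CONSEQUENCES, Observation, Variant

__all__ = [
    "DetectionDecision",
    "subtract_germline",
    "filter_nonsynonymous",
    "call_plasma_mutation",
    "call_plasma_table",
    "classify_variant_type",
]

DEFAULT_ERROR_RATE = 1e-3
DEFAULT_ALPHA = 0.01
DEFAULT_MIN_ALT_READS = 3


@dataclass(frozen=True)
class DetectionDecision:
    """Outcome of testing one plasma observation against background error."""

    variant: Variant
    sample_id: str
    alt_count: int
    depth: int
    p_value: float
    detected: bool

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


def subtract_germline(
    tumor_variants: Iterable[Variant], pbl_variants: Iterable[Variant]
) -> list[Variant]:
    """Return tumor variants whose (chrom, pos, ref, alt) key is absent
    from the matched-germline set. Order-preserving and idempotent.

    Matching is by exact allele key, not position: distinct alternate
    alleles at one site are distinct events.
    """
    germline_keys = {v.key for v in pbl_variants}
    return [v for v in tumor_variants if v.key not in germline_keys]


def filter_nonsynonymous(variants: Iterable[Variant]) -> list[Variant]:
    """Keep protein-altering variants (the tumor-burden marker classes).

    Retains nonsynonymous SNVs and frameshift/in-frame indels,
    preserving input order. Unknown consequence labels raise.
    """
    kept: list[Variant] = []
    for v in variants:
        if v.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence label {v.consequence!r}")
        if v.consequence in NONSYNONYMOUS_CONSEQUENCES:
            kept.append(v)
    return kept


def classify_variant_type(variant: Variant) -> str:
    """``SNV`` iff ref and alt are both single bases, else ``INDEL``."""
    return variant.vtype


def binomial_tail_pvalue(alt_count: int, depth: int, error_rate: float) -> float:
    """P[Binomial(depth, error_rate) >= alt_count], the exact upper tail."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if alt_count <= 0:
        return 1.0
    # survival function at alt_count - 1 is the inclusive upper tail
    return float(binom.sf(alt_count - 1, depth, error_rate))


def call_plasma_mutation(
    obs: Observation,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> DetectionDecision:
    """Decide whether one plasma observation is a real mutation signal.

    Detected iff the exact binomial upper-tail p-value against
    ``error_rate`` is <= ``alpha`` *and* the alt-read count reaches
    ``min_alt_reads`` (a floor guarding against isolated error reads at
    low depth, where a tiny count can already be nominally significant).
    """
    p = binomial_tail_pvalue(obs.alt_count, obs.depth, error_rate)
    detected = (obs.alt_count >= min_alt_reads) and (p <= alpha)
    return DetectionDecision(
        variant=obs.variant,
        sample_id=obs.sample_id,
        alt_count=obs.alt_count,
        depth=obs.depth,
        p_value=p,
        detected=detected,
    )


def call_plasma_table(
    observations: pd.DataFrame,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> pd.DataFrame:
    """Vectorised detection over an allele-count table.

    Returns a copy of ``observations`` with ``vaf``, ``p_value`` and
    ``detected`` columns (the detections-TSV layout).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    df = observations.copy()
    if (df["depth"] <= 0).any():
        raise ValueError("zero-depth rows must be rejected before calling")
    alt = df["alt_count"].to_numpy()
    depth = df["depth"].to_numpy()
    p = binom.sf(alt - 1, depth, error_rate)
    p = np.where(alt <= 0, 1.0, p)
    df["vaf"] = alt / depth
    df["p_value"] = p
    df["detected"] = (alt >= min_alt_reads) & (p <= alpha)
    return df
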