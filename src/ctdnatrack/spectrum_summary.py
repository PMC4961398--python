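"""Mutation-catalog summaries: SNV/indel split and substitution spectrum.

Single-base substitutions are collapsed into the six strand-symmetric
categories conventional in cancer genomics (pyrimidine-reference
notation): a G>T on the sequenced strand is the same biological event as
a C>A on the opposite strand, so both pool into C>A/G>T. No
trinucleotide context is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io_formats import Variant

__all__ = ["CATEGORIES", "SpectrumCounts", "classify_substitution", "spectrum"]

#: the six collapsed substitution categories, pyrimidine reference first
CATEGORIES = (
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYR_TO_CATEGORY = {cat.split("/")[0]: cat for cat in CATEGORIES}


def classify_substitution(ref: str, alt: str) -> str:
    """Map a single-base substitution to its collapsed category.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine-reference strand first (G>T -> C>A/G>T, A>G -> T>C/A>G).
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"invalid base in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt bases must differ")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return _PYR_TO_CATEGORY[f"{ref}>{alt}"]


@dataclass
class SpectrumCounts:
    """Counts over the six substitution categories plus the indel tally."""

    counts: dict[str, int]
    total_snvs: int
    total_indels: int

    @property
    def proportions(self) -> dict[str, float] | None:
        """Per-category SNV proportions; None when no SNVs (undefined)."""
        if self.total_snvs == 0:
            return None
        return {c: self.counts[c] / self.total_snvs for c in CATEGORIES}

    @property
    def snv_fraction(self) -> float | None:
        total = self.total_snvs + self.total_indels
        return None if total == 0 else self.total_snvs / total

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            {
                "category": CATEGORIES,
                "count": [self.counts[c] for c in CATEGORIES],
                "proportion": [
                    props[c] if props is not None else float("nan")
                    for c in CATEGORIES
                ],
            }
        )


def spectrum(variants: Iterable[Variant]) -> SpectrumCounts:
    """Tally a variant catalog into SpectrumCounts.

    SNVs are routed through :func:`classify_substitution`; anything with
    a multi-base allele counts as an indel.
    """
    counts = {c: 0 for c in CATEGORIES}
    n_snv = 0
    n_indel = 0
    for v in variants:
        if v.vtype == "SNV":
            counts[classify_substitution(v.ref, v.alt)] += 1
            n_snv += 1
        else:
            n_indel += 1
    return SpectrumCounts(counts=counts, total_snvs=n_snv, total_indels=n_indel)
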