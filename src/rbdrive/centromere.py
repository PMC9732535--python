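"""Pericentromeric-region morphometry for Rb metacentric chromosomes.

Chromosome preparations differ in compaction from plate to plate, so raw
pixel lengths of the DAPI-bright pericentromeric block are not comparable
across cells.  The compaction-robust statistic is the pericentromeric
length (CL) normalized by the chromosome's total length (TL), expressed as
a percentage: ``CL / TL * 100`` with TL the mean of the two measured sister
chromatid lengths.  Because compaction rescales CL and TL jointly, the
ratio is invariant to it.

Per-animal summaries (mean and sd of the ratio over all measured
chromosomes) are compared against a parental reference ratio; whether
more than half of the offspring exceed the reference is tested with a
one-sided binomial proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .drive import ProportionResult, proportion_test

__all__ = [
    "ChromosomeMeasurement",
    "AnimalCentromereSummary",
    "normalized_ratio",
    "summarize_animal",
    "count_exceeding",
    "exceedance_test",
]


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """Lengths (pixels) of one Rb chromosome in one metaphase plate."""

    animal_id: str
    plate_id: str
    chromosome_id: str
    chromatid_len_1: float
    chromatid_len_2: float
    pericentromeric_len: float

    def __post_init__(self) -> None:
        for name in ("chromatid_len_1", "chromatid_len_2", "pericentromeric_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pericentromeric_len > max(self.chromatid_len_1, self.chromatid_len_2):
            raise ValueError(
                "pericentromeric_len exceeds the longer chromatid; "
                "measurement is inconsistent"
            )


@dataclass
class AnimalCentromereSummary:
    """Per-animal mean and sd of the normalized pericentromeric ratio (%)."""

    animal_id: str
    n_measurements: int
    mean_ratio_pct: float
    sd_ratio_pct: float


def normalized_ratio(m: ChromosomeMeasurement) -> float:
    """Pericentromeric length as percent of chromosome total length.

    TL is the mean of the two chromatid lengths; the result is
    ``100 * CL / TL``, invariant to uniform compaction rescaling of all
    three lengths.
    """
    tl = (m.chromatid_len_1 + m.chromatid_len_2) / 2.0
    return 100.0 * m.pericentromeric_len / tl


def summarize_animal(
    measurements: Iterable[ChromosomeMeasurement], animal_id: str
) -> AnimalCentromereSummary:
    """Mean and sd of the normalized ratio over one animal's measurements."""
    ratios = [normalized_ratio(m) for m in measurements if m.animal_id == animal_id]
    if not ratios:
        raise ValueError(f"no measurements for animal {animal_id!r}")
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return AnimalCentromereSummary(animal_id, len(arr), float(arr.mean()), sd)


def count_exceeding(
    summaries: Sequence[AnimalCentromereSummary], reference_pct: float
) -> int:
    """Number of animals whose mean ratio strictly exceeds the reference."""
    if not summaries:
        raise ValueError("at least one summary is required")
    return sum(1 for s in summaries if s.mean_ratio_pct > reference_pct)


def exceedance_test(
    summaries: Sequence[AnimalCentromereSummary],
    reference_pct: float,
    method: str = "normal_approx",
) -> ProportionResult:
    """Test whether more than half the offspring exceed the parental ratio.

    One-sided (greater) binomial proportion test of
    ``count_exceeding / n_summaries`` against 0.5: under chance inheritance
    an offspring's mean pericentromeric ratio is equally likely to fall on
    either side of the parental average.
    """
    k = count_exceeding(summaries, reference_pct)
    return proportion_test(k, len(summaries), 0.5, "greater", method)
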