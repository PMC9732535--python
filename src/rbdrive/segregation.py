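"""Segregation models for multiple Robertsonian (Rb) heterozygotes.

An Rb heterozygote carrying ``n`` metacentric fusion chromosomes forms ``n``
trivalents at meiosis I.  Under alternate segregation each trivalent
independently transmits either the metacentric (probability ``p_i``) or the
two homologous telocentrics to a gamete.  The number of Rb metacentrics an
offspring inherits from the heterozygous parent is therefore the sum of
``n`` independent Bernoulli trials — Binomial(n, 0.5) under the Mendelian
null, and Poisson-binomial when per-trivalent transmission probabilities
differ (meiotic drive).

This module houses the null/drive model, the observed offspring count
distribution, and karyotype consistency rules (in this cross design an
offspring's diploid number is ``telocentric_base - rb_count``, because each
inherited metacentric replaces two telocentrics).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SegregationModel",
    "CountDistribution",
    "OffspringRecord",
    "ValidationReport",
    "AmbiguousKaryotypeError",
    "transmission_pmf",
    "expected_counts",
    "observed_distribution",
    "total_rb",
    "mean_rb",
    "fraction_of_max",
    "consensus_rb_count",
    "validate_record",
]


class AmbiguousKaryotypeError(ValueError):
    """Raised when metaphase-plate counts do not yield a unique modal value."""


@dataclass(frozen=True)
class SegregationModel:
    """Per-trivalent transmission model.

    Parameters
    ----------
    n_trivalents:
        Number of trivalents formed by the heterozygous parent (8 in the
        CD1 x Milano II cross design).
    p:
        Per-trivalent probability that the metacentric is transmitted.
        All 0.5 is the Mendelian null; heterogeneous values model
        chromosome-specific drive.
    """

    n_trivalents: int
    p: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_trivalents < 1:
            raise ValueError("n_trivalents must be a positive integer")
        if len(self.p) != self.n_trivalents:
            raise ValueError(
                f"p has length {len(self.p)}, expected {self.n_trivalents}"
            )
        for pi in self.p:
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"transmission probability {pi} outside [0, 1]")

    @classmethod
    def mendelian(cls, n_trivalents: int = 8) -> "SegregationModel":
        """The null model: every trivalent transmits the metacentric at 0.5."""
        return cls.homogeneous(n_trivalents, 0.5)

    @classmethod
    def homogeneous(cls, n_trivalents: int, p: float) -> "SegregationModel":
        return cls(n_trivalents, (float(p),) * n_trivalents)


@dataclass
class CountDistribution:
    """Offspring counts indexed by number of inherited Rb chromosomes.

    ``counts[k]`` is the number of offspring that inherited exactly ``k``
    metacentrics, ``k = 0..n_trivalents``.
    """

    n_trivalents: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_trivalents + 1,):
            raise ValueError(
                f"counts must have length n_trivalents + 1 = {self.n_trivalents + 1}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        """Total number of offspring."""
        return int(self.counts.sum())


@dataclass
class OffspringRecord:
    """One karyotyped offspring of a heterozygous x homozygous cross."""

    animal_id: str
    het_parent_sex: str
    rb_count: int
    diploid_n: int
    plate_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.het_parent_sex not in ("female", "male"):
            raise ValueError(
                f"het_parent_sex must be 'female' or 'male', got {self.het_parent_sex!r}"
            )
        if self.rb_count < 0:
            raise ValueError("rb_count must be non-negative")
        if self.plate_counts is not None:
            self.plate_counts = tuple(int(c) for c in self.plate_counts)


@dataclass
class ValidationReport:
    """Outcome of the karyotype consistency checks for one record."""

    animal_id: str
    passed: bool
    messages: tuple[str, ...] = field(default_factory=tuple)


def transmission_pmf(model: SegregationModel) -> np.ndarray:
    """Exact pmf of the number of metacentrics transmitted across trivalents.

    Computed by iterative convolution of the per-trivalent Bernoulli pmfs
    (the Poisson-binomial distribution, O(n^2) and exact).  When all ``p_i``
    are equal this reduces to Binomial(n, p).

    Returns
    -------
    numpy.ndarray
        Probabilities over ``k = 0..n_trivalents``; sums to 1 to within
        1e-12.
    """
    pmf = np.zeros(model.n_trivalents + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(model.p):
        # after trivalent i the support is 0..i+1
        new = np.zeros_like(pmf)
        new[: i + 2] = pmf[: i + 2] * (1.0 - pi)
        new[1 : i + 2] += pmf[: i + 1] * pi
        pmf = new
    return pmf


def expected_counts(model: SegregationModel, n_offspring: int) -> np.ndarray:
    """Expected offspring frequencies for each inherited-Rb class.

    Simply ``n_offspring * transmission_pmf(model)``; linear in the total
    and summing to ``n_offspring`` to within 1e-9.
    """
    if n_offspring < 0:
        raise ValueError("n_offspring must be non-negative")
    return n_offspring * transmission_pmf(model)


def observed_distribution(
    records: Iterable[OffspringRecord],
    sex_filter: str | None = None,
    n_trivalents: int = 8,
) -> CountDistribution:
    """Tabulate offspring by inherited Rb count.

    Parameters
    ----------
    sex_filter:
        Keep only records whose heterozygous parent has this sex
        (``"female"`` or ``"male"``); ``None`` keeps all.
    """
    counts = np.zeros(n_trivalents + 1, dtype=np.int64)
    for rec in records:
        if sex_filter is not None and rec.het_parent_sex != sex_filter:
            continue
        if not 0 <= rec.rb_count <= n_trivalents:
            raise ValueError(
                f"record {rec.animal_id!r}: rb_count {rec.rb_count} outside "
                f"0..{n_trivalents}"
            )
        counts[rec.rb_count] += 1
    return CountDistribution(n_trivalents, counts, label=sex_filter or "all")


def total_rb(dist: CountDistribution) -> int:
    """Total Rb chromosomes carried by the offspring cohort, sum k * counts[k]."""
    k = np.arange(dist.n_trivalents + 1)
    return int((k * dist.counts).sum())


def mean_rb(dist: CountDistribution) -> float:
    """Mean inherited Rb count per offspring."""
    if dist.n == 0:
        raise ValueError("mean_rb undefined for an empty distribution")
    return total_rb(dist) / dist.n


def fraction_of_max(dist: CountDistribution) -> float:
    """Inherited Rb chromosomes as a fraction of the maximum possible (n * N)."""
    if dist.n == 0:
        raise ValueError("fraction_of_max undefined for an empty distribution")
    return total_rb(dist) / (dist.n_trivalents * dist.n)


def consensus_rb_count(plate_counts: Sequence[int]) -> int:
    """Reduce per-metaphase-plate Rb counts to one karyotype call.

    Returns the modal value.  A tie for the mode raises
    :class:`AmbiguousKaryotypeError` rather than silently picking a value:
    an ambiguous set of plates means the animal must be re-examined.
    """
    if len(plate_counts) == 0:
        raise ValueError("at least one plate count is required")
    tally = Counter(int(c) for c in plate_counts)
    ranked = tally.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        tied = sorted(v for v, c in ranked if c == ranked[0][1])
        raise AmbiguousKaryotypeError(
            f"plate counts are tied between {tied}; karyotype is ambiguous"
        )
    return ranked[0][0]


def validate_record(
    record: OffspringRecord,
    telocentric_base: int = 40,
    n_trivalents: int = 8,
) -> ValidationReport:
    """Check a record against the cross design's karyotype arithmetic.

    Each inherited metacentric replaces two telocentrics, so the diploid
    number must equal ``telocentric_base - rb_count`` (40 - rb for the
    CD1 x Milano II design: 3 Rb <-> 2n = 37).  Also checks the admissible
    range of ``rb_count`` and, when plate counts are present, that their
    modal value agrees with the recorded count.
    """
    messages: list[str] = []
    if not 0 <= record.rb_count <= n_trivalents:
        messages.append(
            f"rb_count {record.rb_count} outside 0..{n_trivalents}"
        )
    expected_2n = telocentric_base - record.rb_count
    if record.diploid_n != expected_2n:
        messages.append(
            f"diploid number {record.diploid_n} != "
            f"{telocentric_base} - {record.rb_count} = {expected_2n}"
        )
    if record.plate_counts:
        try:
            modal = consensus_rb_count(record.plate_counts)
        except AmbiguousKaryotypeError:
            messages.append("plate counts have no unique mode")
        else:
            if modal != record.rb_count:
                messages.append(
                    f"modal plate count {modal} != recorded rb_count {record.rb_count}"
                )
    return ValidationReport(record.animal_id, passed=not messages, messages=tuple(messages))
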