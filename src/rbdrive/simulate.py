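"""Synthetic offspring karyotypes and chromosome measurements with known truth.

The generator emulates the statistical structure the inference modules
assume: per-trivalent Bernoulli transmission (optionally with drive, i.e.
per-trivalent probabilities away from 0.5), optional genotype-class
viability selection acting on the number of inherited metacentrics,
Poisson litter structure, replicated metaphase-plate counts, and
length measurements with plate-level compaction and measurement noise.

All randomness goes through :func:`numpy.random.default_rng` (the PCG64
bit generator), so a given seed reproduces the same dataset on any
platform.  Seeds are part of the public contract of every function here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centromere import ChromosomeMeasurement
from .drive import estimate_transmission
from .segregation import (
    CountDistribution,
    OffspringRecord,
    SegregationModel,
    transmission_pmf,
)

__all__ = [
    "SimConfig",
    "RecoveryReport",
    "simulate_offspring",
    "simulate_measurements",
    "parameter_recovery",
]


@dataclass
class SimConfig:
    """Configuration of one simulated offspring cohort.

    Parameters
    ----------
    drive:
        Per-trivalent metacentric transmission probabilities.  All 0.5 is
        Mendelian segregation; a scalar is broadcast to all trivalents.
    viability:
        Optional relative survival weights over the inherited-Rb classes
        ``k = 0..n_trivalents``.  Selection acts on the offspring genotype
        class (the count of metacentrics), the minimal mechanism that
        distorts the shape of the offspring distribution while leaving a
        near-Mendelian mean possible.  ``None`` means uniform viability.
    mean_litter_size:
        Mean of the (>= 1 truncated) Poisson litter sizes; 4.4 matches the
        maternal crosses of the study design this package reanalyses.
    telocentric_base:
        Diploid number of the all-telocentric karyotype; an offspring with
        ``k`` metacentrics has ``2n = telocentric_base - k``.
    miscount_rate:
        Probability that any single metaphase-plate count is off by one
        (clipped to the valid range), emulating occasional scoring error.
    """

    n_trivalents: int = 8
    drive: tuple[float, ...] | float = 0.5
    viability: tuple[float, ...] | None = None
    n_offspring: int = 100
    mean_litter_size: float = 4.4
    het_parent_sex: str = "female"
    telocentric_base: int = 40
    n_plates: int = 10
    miscount_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.drive, (int, float)):
            self.drive = (float(self.drive),) * self.n_trivalents
        else:
            self.drive = tuple(float(d) for d in self.drive)
        if len(self.drive) != self.n_trivalents:
            raise ValueError("drive must have one probability per trivalent")
        if self.viability is not None:
            self.viability = tuple(float(v) for v in self.viability)
            if len(self.viability) != self.n_trivalents + 1:
                raise ValueError("viability needs one weight per class k = 0..n")
            if any(v < 0 for v in self.viability):
                raise ValueError("viability weights must be non-negative")
            if not any(v > 0 for v in self.viability):
                raise ValueError("viability weights must not all be zero")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")

    @property
    def model(self) -> SegregationModel:
        return SegregationModel(self.n_trivalents, tuple(self.drive))

    def offspring_pmf(self) -> np.ndarray:
        """Distribution of inherited Rb counts after viability selection.

        Proportional to ``PoissonBinomial(k; drive) * viability[k]``.
        """
        pmf = transmission_pmf(self.model)
        if self.viability is not None:
            pmf = pmf * np.asarray(self.viability)
            total = pmf.sum()
            if total <= 0:
                raise ValueError(
                    "viability weights eliminate every class with non-zero "
                    "transmission probability"
                )
            pmf = pmf / total
        return pmf


def simulate_offspring(config: SimConfig) -> list[OffspringRecord]:
    """Draw a reproducible offspring cohort under the configured mechanism.

    Each offspring's Rb count is drawn from :meth:`SimConfig.offspring_pmf`;
    its diploid number follows the karyotype arithmetic of the cross; plate
    counts replicate the true count across ``n_plates`` plates with an
    optional per-plate miscount.  Offspring are grouped into litters of
    truncated-Poisson size (litter membership is encoded in the animal id,
    e.g. ``simF-L03-2``); litter structure is generated but deliberately not
    used by the inference modules, which pool littermates.
    """
    rng = np.random.default_rng(config.seed)
    pmf = config.offspring_pmf()
    ks = rng.choice(config.n_trivalents + 1, size=config.n_offspring, p=pmf)

    # assign litters: draw sizes until the cohort is covered
    litter_sizes: list[int] = []
    assigned = 0
    while assigned < config.n_offspring:
        size = max(1, int(rng.poisson(config.mean_litter_size)))
        size = min(size, config.n_offspring - assigned)
        litter_sizes.append(size)
        assigned += size

    prefix = "simF" if config.het_parent_sex == "female" else "simM"
    records: list[OffspringRecord] = []
    idx = 0
    for litter_no, size in enumerate(litter_sizes, start=1):
        for within in range(1, size + 1):
            k = int(ks[idx])
            plates = np.full(config.n_plates, k)
            if config.miscount_rate > 0:
                miss = rng.random(config.n_plates) < config.miscount_rate
                shift = rng.choice((-1, 1), size=config.n_plates)
                plates = np.where(miss, plates + shift, plates)
                plates = np.clip(plates, 0, config.n_trivalents)
            records.append(
                OffspringRecord(
                    animal_id=f"{prefix}-L{litter_no:02d}-{within}",
                    het_parent_sex=config.het_parent_sex,
                    rb_count=k,
                    diploid_n=config.telocentric_base - k,
                    plate_counts=tuple(int(c) for c in plates),
                )
            )
            idx += 1
    return records


def simulate_measurements(
    true_ratio_pct: float,
    n_plates: int = 20,
    chromosomes_per_plate: int = 8,
    compaction_cv: float = 0.3,
    measurement_cv: float = 0.05,
    seed: int | None = None,
    animal_id: str = "sim",
    base_chromatid_px: float = 120.0,
) -> list[ChromosomeMeasurement]:
    """Simulate pixel-length measurements with a known true CL/TL ratio.

    Per plate, one lognormal compaction factor (coefficient of variation
    ``compaction_cv``, unit mean) rescales every length jointly — this is
    the nuisance the CL/TL normalization removes exactly.  Each chromatid
    and the pericentromeric block then receive independent multiplicative
    lognormal measurement noise (cv ``measurement_cv``).  With zero
    measurement noise every normalized ratio equals ``true_ratio_pct``
    exactly; with noise the ratio's mean acquires a small positive bias of
    order ``0.5 * measurement_cv**2 * true_ratio_pct``.
    """
    if not 0.0 < true_ratio_pct <= 100.0:
        raise ValueError("true_ratio_pct must lie in (0, 100]")
    if compaction_cv < 0 or measurement_cv < 0:
        raise ValueError("cv parameters must be non-negative")
    if n_plates < 1 or chromosomes_per_plate < 1:
        raise ValueError("need at least one plate and one chromosome per plate")

    rng = np.random.default_rng(seed)

    def _lognormal_unit_mean(cv: float, size) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    measurements: list[ChromosomeMeasurement] = []
    for plate in range(1, n_plates + 1):
        compaction = float(_lognormal_unit_mean(compaction_cv, None))
        noise = _lognormal_unit_mean(measurement_cv, (chromosomes_per_plate, 3))
        for chrom in range(1, chromosomes_per_plate + 1):
            c1 = base_chromatid_px * compaction * noise[chrom - 1, 0]
            c2 = base_chromatid_px * compaction * noise[chrom - 1, 1]
            cl = (
                base_chromatid_px * (true_ratio_pct / 100.0)
                * compaction * noise[chrom - 1, 2]
            )
            measurements.append(
                ChromosomeMeasurement(
                    animal_id=animal_id,
                    plate_id=f"P{plate:02d}",
                    chromosome_id=f"Rb{chrom}",
                    chromatid_len_1=float(c1),
                    chromatid_len_2=float(c2),
                    pericentromeric_len=float(cl),
                )
            )
    return measurements


@dataclass
class RecoveryReport:
    """Bias and interval coverage of the transmission estimator."""

    drive_true: float
    n_offspring: int
    replicates: int
    mean_estimate: float
    bias: float
    ci_coverage: float
    estimates: np.ndarray = field(repr=False)


def parameter_recovery(
    drive_true: float,
    n_offspring: int,
    replicates: int,
    seed: int | None = None,
    n_trivalents: int = 8,
) -> RecoveryReport:
    """Self-validation of the transmission estimator on simulated cohorts.

    Simulates ``replicates`` cohorts under homogeneous drive, estimates the
    transmission proportion in each, and reports the mean estimate, bias
    and the fraction of 95% Wilson intervals covering the truth.
    """
    if not 0.0 < drive_true < 1.0:
        raise ValueError("drive_true must be strictly inside (0, 1)")
    root = np.random.default_rng(seed)
    estimates = np.empty(replicates)
    covered = 0
    for r in range(replicates):
        cfg = SimConfig(
            n_trivalents=n_trivalents,
            drive=drive_true,
            n_offspring=n_offspring,
            seed=int(root.integers(2**31)),
        )
        records = simulate_offspring(cfg)
        counts = np.bincount(
            [rec.rb_count for rec in records], minlength=n_trivalents + 1
        )
        dist = CountDistribution(n_trivalents, counts)
        res = estimate_transmission(dist)
        estimates[r] = res.estimate
        lo, hi = res.conf_int
        if lo <= drive_true <= hi:
            covered += 1
    mean_est = float(estimates.mean())
    return RecoveryReport(
        drive_true=drive_true,
        n_offspring=n_offspring,
        replicates=replicates,
        mean_estimate=mean_est,
        bias=mean_est - drive_true,
        ci_coverage=covered / replicates,
        estimates=estimates,
    )
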