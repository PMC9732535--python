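"""Tabular IO, bundled reference fixtures, and the end-to-end analysis report.

File formats (all tab-separated text, one header line):

* offspring table — ``animal_id  het_parent_sex  rb_count  diploid_n
  plate_counts`` with ``plate_counts`` a semicolon-joined integer list or
  empty;
* measurement table — ``animal_id  plate_id  chromosome_id
  chromatid_len_1  chromatid_len_2  pericentromeric_len`` (pixels);
* centromere summary table — ``animal_id  role  diploid_n  rb_count
  mean_ratio_pct`` (role is ``parent`` or ``descendant``).

The bundled fixtures reproduce the offspring karyotype counts and the
per-animal pericentromeric summaries of the published reference dataset
this package reanalyses; they are data files, not constants in code, so
they can be inspected and replaced.
"""

from __future__ import annotations

import csv
import datetime
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np

from .centromere import (
    AnimalCentromereSummary,
    ChromosomeMeasurement,
    count_exceeding,
    exceedance_test,
    summarize_animal,
)
from .drive import GofResult, ProportionResult, compare_transmission, gof_test
from .segregation import (
    CountDistribution,
    OffspringRecord,
    SegregationModel,
    fraction_of_max,
    mean_rb,
    observed_distribution,
    total_rb,
    validate_record,
)

__all__ = [
    "OFFSPRING_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "TableFormatError",
    "FixtureProvenanceWarning",
    "fmt",
    "read_offspring_table",
    "write_offspring_table",
    "read_measurement_table",
    "write_measurement_table",
    "read_centromere_summary",
    "load_offspring_fixture",
    "load_centromere_fixture",
    "CohortSummary",
    "CentromereSection",
    "AnalysisReport",
    "run_full_analysis",
]

OFFSPRING_COLUMNS = ["animal_id", "het_parent_sex", "rb_count", "diploid_n", "plate_counts"]
MEASUREMENT_COLUMNS = [
    "animal_id", "plate_id", "chromosome_id",
    "chromatid_len_1", "chromatid_len_2", "pericentromeric_len",
]
SUMMARY_COLUMNS = ["animal_id", "role", "diploid_n", "rb_count", "mean_ratio_pct"]


class TableFormatError(ValueError):
    """Raised for malformed input tables; message lists per-row problems."""


class FixtureProvenanceWarning(UserWarning):
    """Emitted when a bundled fixture with known source inconsistencies loads."""


def fmt(x: float, dp: int) -> str:
    """Shared rounding policy: fixed decimals, half-up (so 3.125 -> '3.13')."""
    q = Decimal(1).scaleb(-dp)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_header(row: list[str], expected: list[str], path: str) -> None:
    if [c.strip() for c in row] != expected:
        raise TableFormatError(
            f"{path}: malformed header {row!r}; expected columns {expected}"
        )


def read_offspring_table(
    path: str | Path,
    n_trivalents: int = 8,
    telocentric_base: int = 40,
    strict: bool = True,
) -> list[OffspringRecord]:
    """Read an offspring karyotype table.

    Every row is validated against the cross design's karyotype arithmetic
    (``diploid_n = telocentric_base - rb_count`` and ``0 <= rb_count <=
    n_trivalents``).  With ``strict=True`` any problem raises
    :class:`TableFormatError` listing each offending line number; otherwise
    inconsistent rows produce warnings and are kept.
    """
    path = Path(path)
    records: list[OffspringRecord] = []
    problems: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise TableFormatError(f"{path}: empty file")
        _check_header(header, OFFSPRING_COLUMNS, str(path))
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                animal_id, sex, rb_s, dip_s, plates_s = row
                rb = int(rb_s)
                dip = int(dip_s)
                plates = (
                    tuple(int(c) for c in plates_s.split(";")) if plates_s.strip() else None
                )
                rec = OffspringRecord(animal_id, sex.strip(), rb, dip, plates)
            except (ValueError, TypeError) as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            report = validate_record(rec, telocentric_base, n_trivalents)
            if not report.passed:
                problems.append(f"line {lineno}: {'; '.join(report.messages)}")
                if not strict:
                    records.append(rec)
                continue
            records.append(rec)
    if problems:
        msg = f"{path}: {len(problems)} problem row(s):\n  " + "\n  ".join(problems)
        if strict:
            raise TableFormatError(msg)
        warnings.warn(msg, stacklevel=2)
    return records


def write_offspring_table(records: list[OffspringRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(OFFSPRING_COLUMNS)
        for rec in records:
            plates = ";".join(str(c) for c in rec.plate_counts) if rec.plate_counts else ""
            writer.writerow(
                [rec.animal_id, rec.het_parent_sex, rec.rb_count, rec.diploid_n, plates]
            )


def read_measurement_table(path: str | Path) -> list[ChromosomeMeasurement]:
    path = Path(path)
    measurements: list[ChromosomeMeasurement] = []
    problems: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise TableFormatError(f"{path}: empty file")
        _check_header(header, MEASUREMENT_COLUMNS, str(path))
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                aid, pid, cid, c1, c2, cl = row
                measurements.append(
                    ChromosomeMeasurement(aid, pid, cid, float(c1), float(c2), float(cl))
                )
            except (ValueError, TypeError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise TableFormatError(
            f"{path}: {len(problems)} problem row(s):\n  " + "\n  ".join(problems)
        )
    return measurements


def write_measurement_table(
    measurements: list[ChromosomeMeasurement], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MEASUREMENT_COLUMNS)
        for m in measurements:
            writer.writerow(
                [m.animal_id, m.plate_id, m.chromosome_id,
                 repr(m.chromatid_len_1), repr(m.chromatid_len_2),
                 repr(m.pericentromeric_len)]
            )


def read_centromere_summary(
    path: str | Path, plates_per_animal: int = 20
) -> tuple[list[AnimalCentromereSummary], AnimalCentromereSummary]:
    """Read a per-animal centromere summary table.

    Returns ``(descendant_summaries, parent_summary)``.  ``n_measurements``
    is reconstructed as ``plates_per_animal * rb_count`` (one measurement
    per Rb chromosome per plate); the per-animal sd is not part of the
    summary format and is stored as NaN.
    """
    path = Path(path)
    descendants: list[AnimalCentromereSummary] = []
    parent: AnimalCentromereSummary | None = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise TableFormatError(f"{path}: empty file")
        _check_header(header, SUMMARY_COLUMNS, str(path))
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            aid, role, _dip, rb_s, pct_s = row
            summary = AnimalCentromereSummary(
                animal_id=aid,
                n_measurements=plates_per_animal * max(1, int(rb_s)),
                mean_ratio_pct=float(pct_s),
                sd_ratio_pct=float("nan"),
            )
            if role.strip() == "parent":
                parent = summary
            else:
                descendants.append(summary)
    if parent is None:
        raise TableFormatError(f"{path}: no row with role 'parent'")
    return descendants, parent


def _fixture_path(name: str):
    return resources.files("rbdrive.data").joinpath(name)


def load_offspring_fixture() -> list[OffspringRecord]:
    """Bundled offspring karyotype dataset: 139 offspring of Rb heterozygotes.

    83 offspring of heterozygous mothers and 56 of heterozygous fathers,
    each scored for the number of inherited Rb metacentrics (0-8).
    """
    with resources.as_file(_fixture_path("offspring_karyotypes.tsv")) as p:
        records = read_offspring_table(p)
    warnings.warn(
        "the source of the bundled offspring dataset prints a maternal "
        "expected-frequency column consistent with N = 84 although the "
        "maternal cohort size is 83; this package computes expectations "
        "from the actual N = 83",
        FixtureProvenanceWarning,
        stacklevel=2,
    )
    return records


def load_centromere_fixture() -> tuple[list[AnimalCentromereSummary], AnimalCentromereSummary]:
    """Bundled pericentromeric summary: one heterozygous father, six sons."""
    with resources.as_file(_fixture_path("centromere_summaries.tsv")) as p:
        descendants, parent = read_centromere_summary(p)
    warnings.warn(
        "one descendant's mean pericentromeric ratio is printed as 25.61 "
        "and 26.61 in different places of the source; the fixture uses "
        "25.61 (the exceedance count is unaffected either way)",
        FixtureProvenanceWarning,
        stacklevel=2,
    )
    return descendants, parent


# ---------------------------------------------------------------------------
# end-to-end report

@dataclass
class CohortSummary:
    """Aggregates and goodness-of-fit for one parent-sex cohort."""

    label: str
    n: int
    counts: np.ndarray
    total_rb: int
    mean_rb: float
    fraction_of_max: float
    gof: GofResult


@dataclass
class CentromereSection:
    summaries: list[AnimalCentromereSummary]
    reference_animal: str
    reference_pct: float
    n_exceeding: int
    test: ProportionResult


@dataclass
class AnalysisReport:
    """Full analysis output with provenance.

    ``to_tsv`` is the machine-readable form and is deterministic given the
    same inputs and seeds (the timestamp lives only in ``provenance`` /
    the human-readable text).
    """

    cohorts: list[CohortSummary]
    comparison: ProportionResult | None
    centromere: CentromereSection | None
    provenance: dict = field(default_factory=dict)

    @property
    def pooled_total_rb(self) -> int:
        return sum(c.total_rb for c in self.cohorts)

    @property
    def pooled_max_rb(self) -> int:
        return sum(len(c.counts[1:]) * c.n for c in self.cohorts)

    def to_tsv(self) -> str:
        rows = [["section", "quantity", "value", "method", "seed"]]

        def add(section, quantity, value, method="", seed=""):
            rows.append([section, quantity, str(value), method, str(seed)])

        for c in self.cohorts:
            sec = f"cohort_{c.label}"
            add(sec, "n_offspring", c.n)
            add(sec, "counts", ",".join(str(x) for x in c.counts))
            add(sec, "total_rb", c.total_rb)
            add(sec, "mean_rb", fmt(c.mean_rb, 2))
            add(sec, "fraction_of_max_pct", fmt(100 * c.fraction_of_max, 2))
            add(sec, "gof_statistic", fmt(c.gof.statistic, 4), c.gof.method,
                c.gof.seed if c.gof.seed is not None else "")
            add(sec, "gof_df", c.gof.df, c.gof.method)
            add(sec, "gof_p_value", fmt(c.gof.p_value, 4), c.gof.method,
                c.gof.seed if c.gof.seed is not None else "")
        if len(self.cohorts) > 1:
            add("pooled", "total_rb", self.pooled_total_rb)
            add("pooled", "max_rb", self.pooled_max_rb)
            add("pooled", "fraction_of_max_pct",
                fmt(100 * self.pooled_total_rb / self.pooled_max_rb, 2))
        if self.comparison is not None:
            add("comparison", "z", fmt(self.comparison.z, 4), self.comparison.method)
            add("comparison", "p_value", fmt(self.comparison.p_value, 4),
                self.comparison.method)
        if self.centromere is not None:
            ce = self.centromere
            add("centromere", "reference_pct", fmt(ce.reference_pct, 2))
            add("centromere", "n_descendants", len(ce.summaries))
            add("centromere", "n_exceeding", ce.n_exceeding)
            add("centromere", "exceedance_p_value", fmt(ce.test.p_value, 4),
                ce.test.method)
        return "\n".join("\t".join(r) for r in rows) + "\n"

    def to_text(self) -> str:
        lines = ["Rb transmission analysis", "=" * 24, ""]
        for c in self.cohorts:
            lines += [
                f"Heterozygous-{c.label} cohort: N = {c.n}",
                f"  offspring per inherited-Rb class 0..{len(c.counts) - 1}: "
                + " ".join(str(x) for x in c.counts),
                f"  total Rb inherited: {c.total_rb}"
                f"  (mean {fmt(c.mean_rb, 2)} per offspring, "
                f"{fmt(100 * c.fraction_of_max, 2)}% of maximum)",
                f"  goodness of fit vs Mendelian binomial: "
                f"chi2 = {fmt(c.gof.statistic, 2)}, df = {c.gof.df}, "
                f"p = {fmt(c.gof.p_value, 4)} [{c.gof.method}"
                + (f", seed={c.gof.seed}" if c.gof.method == "monte_carlo" else "")
                + "]",
                "",
            ]
        if len(self.cohorts) > 1:
            lines.append(
                f"Pooled: {self.pooled_total_rb} of a maximum {self.pooled_max_rb} "
                f"Rb chromosomes inherited "
                f"({fmt(100 * self.pooled_total_rb / self.pooled_max_rb, 2)}%)"
            )
        if self.comparison is not None:
            lines.append(
                f"Maternal vs paternal transmission: z = {fmt(self.comparison.z, 2)}, "
                f"p = {fmt(self.comparison.p_value, 4)} [{self.comparison.method}]"
            )
        if self.centromere is not None:
            ce = self.centromere
            lines += [
                "",
                f"Pericentromeric exceedance vs {ce.reference_animal} "
                f"({fmt(ce.reference_pct, 2)}%): "
                f"{ce.n_exceeding} of {len(ce.summaries)} descendants greater, "
                f"one-sided p = {fmt(ce.test.p_value, 4)} [{ce.test.method}]",
            ]
        if self.provenance:
            lines += ["", "Provenance:"]
            lines += [f"  {k}: {v}" for k, v in self.provenance.items()]
        return "\n".join(lines) + "\n"


def run_full_analysis(
    offspring_path: str | Path,
    measurements_path: str | Path | None = None,
    centromere_summary_path: str | Path | None = None,
    reference_animal: str | None = None,
    reference_pct: float | None = None,
    n_trivalents: int = 8,
    telocentric_base: int = 40,
    gof_method: str = "asymptotic",
    pool_below: float | None = None,
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the complete pipeline: aggregation, drive tests, morphometry.

    The centromere section is produced when either raw measurements or a
    summary table is supplied; the reference ratio comes from
    ``reference_pct``, or from ``reference_animal``'s summary, or from the
    summary table's ``parent`` row.  Without centromere input the section
    is simply omitted.
    """
    records = read_offspring_table(offspring_path, n_trivalents, telocentric_base)
    model = SegregationModel.mendelian(n_trivalents)

    cohorts: list[CohortSummary] = []
    dists: dict[str, CountDistribution] = {}
    for sex in ("female", "male"):
        dist = observed_distribution(records, sex, n_trivalents)
        if dist.n == 0:
            continue
        dists[sex] = dist
        gof = gof_test(dist, model, method=gof_method, pool_below=pool_below,
                       n_resamples=n_resamples, seed=seed)
        cohorts.append(
            CohortSummary(sex, dist.n, dist.counts, total_rb(dist),
                          mean_rb(dist), fraction_of_max(dist), gof)
        )

    comparison = None
    if len(dists) == 2:
        comparison = compare_transmission(dists["female"], dists["male"])

    centromere = None
    summaries: list[AnimalCentromereSummary] = []
    parent_summary: AnimalCentromereSummary | None = None
    if centromere_summary_path is not None:
        summaries, parent_summary = read_centromere_summary(centromere_summary_path)
    elif measurements_path is not None:
        measurements = read_measurement_table(measurements_path)
        for aid in sorted({m.animal_id for m in measurements}):
            s = summarize_animal(measurements, aid)
            if aid == reference_animal:
                parent_summary = s
            else:
                summaries.append(s)
    if summaries:
        if reference_pct is not None:
            ref_pct, ref_name = float(reference_pct), "reference"
        elif parent_summary is not None:
            ref_pct, ref_name = parent_summary.mean_ratio_pct, parent_summary.animal_id
        else:
            raise ValueError(
                "centromere analysis needs reference_pct, reference_animal, "
                "or a 'parent' row in the summary table"
            )
        n_exc = count_exceeding(summaries, ref_pct)
        test = exceedance_test(summaries, ref_pct)
        centromere = CentromereSection(summaries, ref_name, ref_pct, n_exc, test)

    provenance = {
        "offspring_path": str(offspring_path),
        "measurements_path": str(measurements_path) if measurements_path else "",
        "centromere_summary_path": (
            str(centromere_summary_path) if centromere_summary_path else ""
        ),
        "gof_method": gof_method,
        "seed": seed if seed is not None else "",
        "package_version": _package_version(),
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    return AnalysisReport(cohorts, comparison, centromere, provenance)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("rbdrive")
    except PackageNotFoundError:
        return "unknown"
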