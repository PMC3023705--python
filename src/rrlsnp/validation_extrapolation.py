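"""Stratified SNP validation bookkeeping and extrapolation.

Putative pooled SNPs are binned into discovery strata by depth of coverage
and minor allele count.  A sample from each stratum is genotyped with an
allele-specific assay; assays with poor genotype clustering fail QC and are
dropped from the denominator.  Each stratum's empirical validation rate
(validated / passing QC) is then multiplied by the stratum's putative count
to predict how many of its SNPs are real, with round-half-up to an integer.
Summing the per-stratum predictions gives the nuclear total; validated
organellar SNPs are added for a genome-wide figure.

The module ships the validation tallies of the white-tailed deer pooled
RRL+RSL discovery panel (six low-coverage strata, 78 assays, plus a 38-assay
mitochondrial panel) as a regression fixture: feeding them through the
engine reproduces the published-style totals (10,739 putative; 10,448
nuclear predicted; 89.8% mean class rate; +28 mitochondrial = 10,476).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationClass",
    "ValidationSummary",
    "round_half_up",
    "extrapolate_class",
    "summarize_validation",
    "record_assay_outcomes",
    "select_candidates",
    "load_reference_classes",
    "MITO_TESTED",
    "MITO_VALIDATED",
]

# Mitochondrial validation panel: every putative organellar SNP was assayed.
MITO_TESTED = 38
MITO_VALIDATED = 28


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (never banker's)."""
    return int(math.floor(x + 0.5))


@dataclass
class ValidationClass:
    """One discovery stratum with its assay tallies and extrapolation."""

    coverage: int
    minor_allele_count: int
    total_putative: int
    n_tested: int = 0
    n_passing_qc: int = 0
    n_validated: int = 0
    percent_of_all: float | None = None

    def __post_init__(self) -> None:
        if not self.n_validated <= self.n_passing_qc <= self.n_tested:
            raise ValueError("require n_validated <= n_passing_qc <= n_tested")

    @property
    def validation_rate(self) -> float | None:
        """validated / passing QC, or None when no assay passed QC."""
        if self.n_passing_qc == 0:
            return None
        return self.n_validated / self.n_passing_qc

    @property
    def predicted_valid(self) -> int | None:
        rate = self.validation_rate
        if rate is None:
            return None
        return round_half_up(self.total_putative * rate)


def extrapolate_class(cls: ValidationClass) -> int:
    """Predicted valid SNPs in a stratum: putative x validation rate, rounded."""
    pred = cls.predicted_valid
    if pred is None:
        raise ValueError(
            f"class {cls.coverage}X/{cls.minor_allele_count} has no QC-passing assays"
        )
    return pred


@dataclass
class ValidationSummary:
    classes: list
    total_putative_in_classes: int
    mean_class_validation_rate: float  # unweighted mean of class % rates
    pooled_validation_rate: float  # sum validated / sum passing, for reference
    predicted_nuclear_total: int
    validated_mito: int

    @property
    def predicted_genomewide_total(self) -> int:
        return self.predicted_nuclear_total + self.validated_mito

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classes:
            rate = c.validation_rate
            rows.append(
                {
                    "coverage": f"{c.coverage}X",
                    "minor_allele_count": c.minor_allele_count,
                    "total_putative": c.total_putative,
                    "percent_of_all": c.percent_of_all,
                    "n_tested": c.n_tested,
                    "n_passing_qc": c.n_passing_qc,
                    "n_validated": c.n_validated,
                    "validation_rate_pct": None if rate is None else round(100 * rate, 1),
                    "predicted_valid": c.predicted_valid,
                }
            )
        rows.append(
            {
                "coverage": "Totals/Avg",
                "minor_allele_count": "",
                "total_putative": self.total_putative_in_classes,
                "percent_of_all": None,
                "n_tested": sum(c.n_tested for c in self.classes),
                "n_passing_qc": sum(c.n_passing_qc for c in self.classes),
                "n_validated": sum(c.n_validated for c in self.classes),
                "validation_rate_pct": self.mean_class_validation_rate,
                "predicted_valid": self.predicted_nuclear_total,
            }
        )
        return pd.DataFrame(rows)


def summarize_validation(
    classes: Sequence[ValidationClass], validated_mito: int = 0
) -> ValidationSummary:
    """Totals and the headline extrapolations over the assayed strata.

    The headline mean rate is the unweighted arithmetic mean of the per-class
    percentage rates (1 decimal); the pooled rate (all validated / all
    passing) is also computed for reference.  Classes without QC-passing
    assays contribute no prediction and no rate.
    """
    with_rate = [c for c in classes if c.n_passing_qc >= 1]
    if not with_rate:
        raise ValueError("no class has QC-passing assays")
    rates = [round(100 * c.validation_rate, 1) for c in with_rate]
    predicted = sum(extrapolate_class(c) for c in with_rate)
    pooled = 100.0 * sum(c.n_validated for c in with_rate) / sum(
        c.n_passing_qc for c in with_rate
    )
    return ValidationSummary(
        classes=list(classes),
        total_putative_in_classes=sum(c.total_putative for c in classes),
        mean_class_validation_rate=round(float(np.mean(rates)), 1),
        pooled_validation_rate=round(pooled, 1),
        predicted_nuclear_total=predicted,
        validated_mito=validated_mito,
    )


def record_assay_outcomes(
    candidates: pd.DataFrame,
    outcomes: pd.DataFrame,
    totals: dict,
) -> list:
    """Fold per-candidate assay outcomes into per-stratum tallies.

    ``candidates`` needs ``snp_id``, ``coverage``, ``minor_allele_count``;
    ``outcomes`` needs ``snp_id``, ``pass_qc``, ``validated``.  ``totals``
    maps (coverage, minor allele count) to the stratum's putative SNP count.
    A validated outcome that failed QC is a bookkeeping error and raises.
    """
    merged = candidates.merge(outcomes, on="snp_id", how="left")
    if merged[["pass_qc", "validated"]].isna().any().any():
        missing = merged.loc[merged["pass_qc"].isna(), "snp_id"].tolist()
        raise ValueError(f"candidates without outcomes: {missing[:5]}")
    if (merged["validated"] & ~merged["pass_qc"]).any():
        raise ValueError("validated outcome recorded for a QC-failing assay")
    classes = []
    for (cov, mac), total in sorted(totals.items()):
        sub = merged[
            (merged["coverage"] == cov) & (merged["minor_allele_count"] == mac)
        ]
        classes.append(
            ValidationClass(
                coverage=cov,
                minor_allele_count=mac,
                total_putative=total,
                n_tested=len(sub),
                n_passing_qc=int(sub["pass_qc"].sum()),
                n_validated=int(sub["validated"].sum()),
            )
        )
    return classes


def select_candidates(
    calls: pd.DataFrame, per_class_n: int, seed: int = 0
) -> pd.DataFrame:
    """Pick assay candidates per stratum, spread across chromosomes.

    ``calls`` needs columns ``snp_id``, ``contig_id``, ``coverage``,
    ``minor_allele_count``, ``chromosome``, ``placement_status``,
    ``homopolymer_proximal``, ``clustered``.  Eligible calls sit on uniquely
    placed contigs and carry neither flag; at most one candidate is taken per
    contig, and chromosomes are cycled so no chromosome repeats before every
    represented one has a candidate.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    eligible = calls[
        (calls["placement_status"] == "unique")
        & ~calls["homopolymer_proximal"].astype(bool)
        & ~calls["clustered"].astype(bool)
    ]
    picks = []
    for (cov, mac), group in eligible.groupby(["coverage", "minor_allele_count"]):
        group = group.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        group = group.drop_duplicates("contig_id")
        by_chrom: dict[str, list] = {}
        for _, row in group.iterrows():
            by_chrom.setdefault(row["chromosome"], []).append(row)
        chroms = sorted(by_chrom)
        taken = 0
        while taken < per_class_n and chroms:
            for chrom in list(chroms):
                if taken >= per_class_n:
                    break
                queue = by_chrom[chrom]
                picks.append(queue.pop(0))
                taken += 1
                if not queue:
                    chroms.remove(chrom)
    if not picks:
        return calls.head(0)
    return pd.DataFrame(picks).reset_index(drop=True)


def load_reference_classes(percent_denominator: int | None = None) -> list:
    """The shipped white-tailed deer validation strata (regression fixture).

    ``percent_denominator`` is the count of all putative SNPs in the 3X-150X
    single-hit pool, which the percent-of-all column is relative to; it is
    dataset-specific, so percentages are filled in only when it is supplied.
    """
    with resources.files("rrlsnp.data").joinpath(
        "whitetail_validation_classes.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    classes = [
        ValidationClass(
            coverage=int(r.coverage),
            minor_allele_count=int(r.minor_allele_count),
            total_putative=int(r.total_putative),
            n_tested=int(r.n_tested),
            n_passing_qc=int(r.n_passing_qc),
            n_validated=int(r.n_validated),
        )
        for r in df.itertuples()
    ]
    if percent_denominator:
        for c in classes:
            c.percent_of_all = round(100 * c.total_putative / percent_denominator, 1)
    return classes
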