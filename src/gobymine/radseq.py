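"""RAD-seq sex-determination screen.

Samples with too few reads are removed, loci present exclusively in one
sex are called sex-specific, and the count of such loci is interpreted
against the expected RAD locus density: a whole sex chromosome should
show hundreds of sex-specific loci, a contiguous sex-determining region
larger than the inter-locus spacing at least one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .io import PresenceMatrix


@dataclass
class RadConfig:
    """Screen thresholds.

    ``min_reads_per_sample`` is a strict lower bound on the per-sample
    read total; ``presence_min_count`` is the read count at which a
    locus counts as present in a sample; ``max_other_sex_presence`` is
    how many individuals of the opposite sex may carry the locus before
    exclusivity is broken (0 = absolute); the tier bounds translate
    sex-specific locus counts into an interpretation.
    """

    min_reads_per_sample: int = 150_000
    presence_min_count: int = 1
    max_other_sex_presence: int = 0
    min_carriers: int = 1
    region_tier_min_loci: int = 1
    chromosome_tier_min_loci: int = 100

    def __post_init__(self) -> None:
        if min(self.min_reads_per_sample, self.presence_min_count,
               self.max_other_sex_presence, self.region_tier_min_loci,
               self.chromosome_tier_min_loci) < 0:
            raise ValueError("RadConfig thresholds must be non-negative")
        if self.chromosome_tier_min_loci <= self.region_tier_min_loci:
            raise ValueError(
                "chromosome_tier_min_loci must exceed region_tier_min_loci"
            )


@dataclass(frozen=True)
class DensityExpectation:
    """Expected RAD coverage: bp per locus and markers per chromosome."""

    bp_per_locus: int
    markers_per_chromosome: int

    def __post_init__(self) -> None:
        if self.bp_per_locus <= 0 or self.markers_per_chromosome <= 0:
            raise ValueError("density figures must be positive")


@dataclass(frozen=True)
class SexLocusCall:
    locus: str
    sex: str
    n_present_in_sex: int


def filter_samples(matrix: PresenceMatrix, cfg: RadConfig) -> PresenceMatrix:
    """Drop samples whose read total is not strictly above the minimum."""
    totals = matrix.counts.sum(axis=0)
    keep = [s for s in matrix.samples if totals[s] > cfg.min_reads_per_sample]
    if not keep:
        raise ValueError(
            f"no sample exceeds {cfg.min_reads_per_sample} reads; "
            "screen impossible"
        )
    return PresenceMatrix(
        counts=matrix.counts[keep].copy(),
        sex={s: matrix.sex[s] for s in keep},
    )


def dropped_samples(matrix: PresenceMatrix, cfg: RadConfig) -> dict[str, int]:
    """Samples that would be removed by :func:`filter_samples`, with totals."""
    totals = matrix.counts.sum(axis=0)
    return {
        s: int(totals[s])
        for s in matrix.samples
        if totals[s] <= cfg.min_reads_per_sample
    }


def call_sex_specific_loci(
    matrix: PresenceMatrix, cfg: Optional[RadConfig] = None
) -> list[SexLocusCall]:
    """Call loci present exclusively in one sex.

    A locus is male-specific when at least ``min_carriers`` males carry
    it (count >= ``presence_min_count``) and at most
    ``max_other_sex_presence`` females do; symmetrically for
    female-specific calls. Unknown-sex samples are ignored.
    """
    cfg = cfg or RadConfig()
    males = matrix.samples_of_sex("male")
    females = matrix.samples_of_sex("female")
    if not males or not females:
        raise ValueError("need at least one male and one female sample")
    present = matrix.counts >= cfg.presence_min_count
    calls: list[SexLocusCall] = []
    for locus in matrix.loci:
        in_males = int(present.loc[locus, males].sum())
        in_females = int(present.loc[locus, females].sum())
        if in_males >= cfg.min_carriers and in_females <= cfg.max_other_sex_presence:
            calls.append(SexLocusCall(locus, "male", in_males))
        elif in_females >= cfg.min_carriers and in_males <= cfg.max_other_sex_presence:
            calls.append(SexLocusCall(locus, "female", in_females))
    return calls


def expected_rad_coverage(
    genome_size_bp: int, n_loci: int, n_chromosomes: int
) -> DensityExpectation:
    """Expected locus spacing and markers per average-sized chromosome.

    Both figures are rounded half-away-from-zero to the nearest integer.
    """
    if min(genome_size_bp, n_loci, n_chromosomes) <= 0:
        raise ValueError("genome size, locus and chromosome counts must be > 0")
    return DensityExpectation(
        bp_per_locus=_round_half_away(genome_size_bp / n_loci),
        markers_per_chromosome=_round_half_away(n_loci / n_chromosomes),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def interpret_sex_system(n_sex_specific: int, cfg: Optional[RadConfig] = None) -> str:
    """Interpret the number of sex-specific loci.

    Hundreds of sex-specific loci indicate a sex chromosome
    (``chromosome_scale``); one or more indicate a contiguous
    sex-determining region larger than the locus spacing
    (``region_scale``); zero means ``none_detected``.
    """
    cfg = cfg or RadConfig()
    if n_sex_specific < 0:
        raise ValueError("n_sex_specific must be >= 0")
    if n_sex_specific >= cfg.chromosome_tier_min_loci:
        return "chromosome_scale"
    if n_sex_specific >= cfg.region_tier_min_loci:
        return "region_scale"
    return "none_detected"


def screen_report(
    matrix: PresenceMatrix,
    cfg: Optional[RadConfig] = None,
    genome_size_bp: Optional[int] = None,
    n_chromosomes: Optional[int] = None,
    n_loci: Optional[int] = None,
) -> str:
    """One-page text report: retained samples, calls, tier verdict and,
    when genome size and chromosome number are given, density figures."""
    cfg = cfg or RadConfig()
    dropped = dropped_samples(matrix, cfg)
    filtered = filter_samples(matrix, cfg)
    calls = call_sex_specific_loci(filtered, cfg)
    verdict = interpret_sex_system(len(calls), cfg)
    lines = [
        "RAD-seq sex-determination screen",
        "=" * 34,
        f"samples retained: {len(filtered.samples)} "
        f"({len(filtered.samples_of_sex('male'))} male, "
        f"{len(filtered.samples_of_sex('female'))} female)",
    ]
    if dropped:
        lines.append(
            "samples dropped (<= %d reads): %s"
            % (
                cfg.min_reads_per_sample,
                ", ".join(f"{s}={t}" for s, t in sorted(dropped.items())),
            )
        )
    lines.append(f"loci screened: {len(filtered.loci)}")
    lines.append(f"sex-specific loci: {len(calls)}")
    for call in calls:
        lines.append(
            f"  {call.locus}\t{call.sex}-specific\t"
            f"present in {call.n_present_in_sex} {call.sex}s"
        )
    if genome_size_bp and n_chromosomes:
        try:
            dens = expected_rad_coverage(
                genome_size_bp, n_loci or len(filtered.loci), n_chromosomes
            )
            lines.append(
                f"expected density: one locus per {dens.bp_per_locus} bp, "
                f"{dens.markers_per_chromosome} markers per chromosome"
            )
        except ValueError:
            lines.append("expected density: omitted (too few loci)")
    lines.append(f"verdict: {verdict}")
    return "\n".join(lines) + "\n"
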