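"""Post-calling somatic filters and cross-region mutation rescue.

The filters assume upstream read counting already restricted to
high-quality reads (base quality and mapping quality >= 30); this module
operates on the provided counts only. Rescue re-examines raw pileup
counts in regions where a variant seen elsewhere in the same tumor was
not called, and admits it when the local VAF exceeds 1% and the matched
normal shows fewer than five mutant reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .core_io import MutationCall, ValidationError

logger = logging.getLogger("mrith")

__all__ = ["FilterParams", "apply_somatic_filters", "rescue_cross_region"]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for somatic filtering and cross-region rescue.

    Defaults: a call needs >= 5 mutant reads, >= 10 reads in the matched
    normal, tumor depth > 30, VAF >= 3% and population allele frequency
    <= 1%. Rescue admits a known variant in an uncalled region when its
    local VAF is > 1% and the normal has < 5 mutant reads.
    """

    min_alt_reads: int = 5
    min_normal_depth: int = 10
    min_tumor_depth: int = 30
    min_vaf: float = 0.03
    max_population_af: float = 0.01
    rescue_min_vaf: float = 0.01
    rescue_max_normal_alt: int = 5  # exclusive
    caller_support: bool = False  # two-caller intersection, off by default

    def __post_init__(self) -> None:
        for name in (
            "min_alt_reads",
            "min_normal_depth",
            "min_tumor_depth",
            "min_vaf",
            "max_population_af",
            "rescue_min_vaf",
            "rescue_max_normal_alt",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.min_vaf <= self.rescue_min_vaf:
            raise ValidationError("min_vaf must exceed rescue_min_vaf")


def passes_filters(call: MutationCall, params: FilterParams) -> bool:
    """Single-record somatic predicate (the rule applied by the filter)."""
    if min(call.alt_reads, call.ref_reads, call.normal_alt_reads, call.normal_depth) < 0:
        raise ValidationError(f"negative read count at {call.key}")
    return (
        call.alt_reads >= params.min_alt_reads
        and call.normal_depth >= params.min_normal_depth
        and call.depth > params.min_tumor_depth
        and call.vaf >= params.min_vaf
        and call.population_af <= params.max_population_af
    )


def apply_somatic_filters(
    calls: Sequence[MutationCall], params: FilterParams | None = None
) -> list[MutationCall]:
    """Retain calls passing every somatic filter; order preserved.

    Emits per-rule rejection counts at INFO level. Idempotent.
    """
    params = params or FilterParams()
    rejected = {
        "alt_reads": 0,
        "normal_depth": 0,
        "tumor_depth": 0,
        "vaf": 0,
        "population_af": 0,
    }
    kept: list[MutationCall] = []
    for c in calls:
        if min(c.alt_reads, c.ref_reads, c.normal_alt_reads, c.normal_depth) < 0:
            raise ValidationError(f"negative read count at {c.key}")
        if c.alt_reads < params.min_alt_reads:
            rejected["alt_reads"] += 1
        elif c.normal_depth < params.min_normal_depth:
            rejected["normal_depth"] += 1
        elif c.depth <= params.min_tumor_depth:
            rejected["tumor_depth"] += 1
        elif c.vaf < params.min_vaf:
            rejected["vaf"] += 1
        elif c.population_af > params.max_population_af:
            rejected["population_af"] += 1
        else:
            kept.append(c)
    logger.info(
        "apply_somatic_filters: %d in, %d out, rejected=%s",
        len(calls),
        len(kept),
        rejected,
    )
    return kept


PileupKey = tuple[str, int, str, str]  # (chrom, pos, ref, alt)


def rescue_cross_region(
    calls_by_region: Mapping[str, Sequence[MutationCall]],
    raw_pileups: Mapping[str, Mapping[PileupKey, MutationCall]],
    params: FilterParams | None = None,
) -> dict[str, list[MutationCall]]:
    """Rescue variants called in some but not all regions of one tumor.

    ``raw_pileups[region][key]`` carries the raw read counts at a
    candidate locus in a region where the variant was not called. A
    variant is added to a missing region iff its local VAF is strictly
    above ``rescue_min_vaf`` and the matched normal shows fewer than
    ``rescue_max_normal_alt`` mutant reads. Rescue never removes a call
    and never introduces a variant absent from every region. Rescued
    records carry ``rescued=True``.
    """
    params = params or FilterParams()
    out: dict[str, list[MutationCall]] = {
        r: list(calls) for r, calls in calls_by_region.items()
    }
    present: dict[PileupKey, set[str]] = {}
    for region, calls in calls_by_region.items():
        for c in calls:
            present.setdefault(c.key, set()).add(region)

    n_rescued = 0
    for key, regions_with in present.items():
        missing = [r for r in out if r not in regions_with]
        for region in missing:
            pile = raw_pileups.get(region, {}).get(key)
            if pile is None:
                logger.warning(
                    "rescue: locus %s missing from %s pileups; treated as absent",
                    key,
                    region,
                )
                continue
            if (
                pile.vaf > params.rescue_min_vaf
                and pile.normal_alt_reads < params.rescue_max_normal_alt
            ):
                out[region].append(replace(pile, region_id=region, rescued=True))
                n_rescued += 1
    logger.info("rescue_cross_region: %d records rescued", n_rescued)
    return out
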