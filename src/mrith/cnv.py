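"""Copy-number heterogeneity: gain/loss calls, GII, WGD, Jaccard ITH.

Gains and losses are called on the ploidy-normalized log ratio
``log2(total_cn / ploidy)``: gain when >= log2(2.5/2), loss when
< log2(1.5/2). The genome instability index (GII) is the fraction of
the autosomal genome covered by gain or loss. Whole-genome doubling is
tested with a permutation null on the length-weighted fraction of the
autosomal genome whose major allele count is >= 2, with ploidy-class
specific significance thresholds. Cross-region CNV comparison uses
fixed genomic bins (regions are segmented independently, so a common
universe is required); CNV ITH is the mean pairwise Jaccard distance
between per-region event sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import AUTOSOMES, AUTOSOME_BP, CONTIGS, SegmentCN, ValidationError

logger = logging.getLogger("mrith")

__all__ = [
    "GAIN_LOG_RATIO",
    "LOSS_LOG_RATIO",
    "CnvEvent",
    "WgdResult",
    "call_gain_loss",
    "genome_instability_index",
    "detect_wgd",
    "bin_events",
    "classify_cnv_clonality",
    "cnv_ith",
    "jaccard_distance",
]

#: Gain threshold on log2(total_cn / ploidy); log2(2.5/2).
GAIN_LOG_RATIO = math.log2(2.5 / 2.0)
#: Loss threshold on log2(total_cn / ploidy); log2(1.5/2).
LOSS_LOG_RATIO = math.log2(1.5 / 2.0)

#: WGD p-value thresholds per rounded ploidy class.
WGD_THRESHOLDS = {"<=triploid": 0.001, "tetraploid": 0.05, "pentaploid": 0.5, ">=hexaploid": 1.0}


@dataclass(frozen=True)
class CnvEvent:
    """A called gain or loss on a segment or bin in one region."""

    patient_id: str
    region_id: str
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    loh: bool
    log_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class WgdResult:
    """Outcome of the whole-genome doubling permutation test."""

    is_wgd: bool
    p_value: float
    ploidy_class: str
    observed_statistic: float  # autosomal fraction with major_cn >= 2
    ploidy: float
    n_sim: int
    seed: int | None


def call_gain_loss(segment: SegmentCN, ploidy: float) -> str:
    """Classify one segment as gain / neutral / loss against ploidy."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if segment.total_cn < 0:
        raise ValidationError("total_cn < 0")
    if segment.total_cn == 0:
        return "loss"
    lr = math.log2(segment.total_cn / ploidy)
    if lr >= GAIN_LOG_RATIO:
        return "gain"
    if lr < LOSS_LOG_RATIO:
        return "loss"
    return "neutral"


def call_events(
    segments: Sequence[SegmentCN], ploidy: float
) -> list[CnvEvent]:
    """Gain/loss events for one region's segments."""
    events = []
    for s in segments:
        direction = call_gain_loss(s, ploidy)
        if direction == "neutral":
            continue
        lr = math.log2(s.total_cn / ploidy) if s.total_cn > 0 else float("-inf")
        events.append(
            CnvEvent(
                patient_id=s.patient_id,
                region_id=s.region_id,
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                direction=direction,
                loh=s.is_loh,
                log_ratio=lr,
            )
        )
    return events


def genome_instability_index(
    events: Iterable[CnvEvent], genome_size_bp: int = AUTOSOME_BP
) -> float:
    """Fraction of the genome covered by gain plus loss events."""
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    total = 0
    for e in events:
        if e.end > CONTIGS.get(e.chrom, 0):
            raise ValidationError(
                f"event end {e.end} past contig {e.chrom} end"
            )
        total += e.length
    return total / genome_size_bp


def _ploidy_class(ploidy: float) -> str:
    rounded = round(ploidy)
    if rounded <= 3:
        return "<=triploid"
    if rounded == 4:
        return "tetraploid"
    if rounded == 5:
        return "pentaploid"
    return ">=hexaploid"


def detect_wgd(
    segments: Sequence[SegmentCN],
    n_sim: int = 10_000,
    seed: int | None = 0,
    include_sex: bool = False,
) -> WgdResult | None:
    """Whole-genome doubling test for one region.

    The observed statistic is the length-weighted fraction of the
    autosomal genome with major allele copy number >= 2. The null
    re-assigns each segment's (major, minor) state uniformly across
    segments with lengths kept in place (a permutation null), and
    ``p = (1 + #{sim >= observed}) / (n_sim + 1)``. WGD is called when p
    is at or below the threshold of the rounded-ploidy class
    (<=triploid: 0.001; tetraploid: 0.05; pentaploid: 0.5;
    >=hexaploid: always). A fully doubled genome (statistic 1.0) with
    rounded ploidy >= 4 is degenerate under permutation (every
    permutation ties the observation) and short-circuits to WGD.

    Returns None with a warning when no autosomal segments are present.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    use = [
        s for s in segments if include_sex or s.chrom in AUTOSOMES
    ]
    if not use:
        logger.warning("detect_wgd: no autosomal segments; result undefined")
        return None
    lengths = np.array([s.length for s in use], dtype=float)
    major = np.array([s.major_cn for s in use])
    total_cn = np.array([s.total_cn for s in use], dtype=float)
    genome = lengths.sum()
    observed = float(lengths[major >= 2].sum() / genome)
    ploidy = float((lengths * total_cn).sum() / genome)
    klass = _ploidy_class(ploidy)

    rng = np.random.default_rng(seed)
    doubled = (major >= 2).astype(float)
    n_ge = 0
    for _ in range(n_sim):
        perm = rng.permutation(len(use))
        stat = float(lengths @ doubled[perm] / genome)
        if stat >= observed - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_sim + 1)

    if observed >= 1.0 - 1e-12 and round(ploidy) >= 4:
        is_wgd = True  # degenerate: all permutations tie a fully doubled genome
    else:
        is_wgd = p <= WGD_THRESHOLDS[klass]
    return WgdResult(
        is_wgd=is_wgd,
        p_value=p,
        ploidy_class=klass,
        observed_statistic=observed,
        ploidy=ploidy,
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cross-region comparison on a common binning
# ---------------------------------------------------------------------------

BinKey = tuple[str, int]  # (chrom, bin index)
EventKey = tuple[str, int, str]  # (chrom, bin index, direction)


def bin_events(
    segments: Sequence[SegmentCN],
    ploidy: float,
    bin_size: int = 10_000_000,
    include_sex: bool = False,
) -> tuple[set[EventKey], set[BinKey]]:
    """Project one region's gain/loss calls onto fixed genomic bins.

    Returns the set of (chrom, bin, direction) event keys and the set of
    bins carrying LOH. A bin takes an event when the event covers any
    part of it.
    """
    events: set[EventKey] = set()
    loh_bins: set[BinKey] = set()
    for s in segments:
        if not include_sex and s.chrom not in AUTOSOMES:
            continue
        first = (s.start - 1) // bin_size
        last = (s.end - 1) // bin_size
        direction = call_gain_loss(s, ploidy)
        for b in range(first, last + 1):
            if direction != "neutral":
                events.add((s.chrom, b, direction))
            if s.is_loh:
                loh_bins.add((s.chrom, b))
    return events, loh_bins


def classify_cnv_clonality(
    events_by_region: Mapping[str, set[EventKey]],
    loh_by_region: Mapping[str, set[BinKey]] | None = None,
) -> dict[EventKey, str]:
    """Classify each binned event as clonal or subclonal across regions.

    A gain is clonal iff every region carries the gain in that bin. A
    loss is clonal iff every region shows either the loss or LOH in that
    bin; any event seen in >= 1 but not all regions is subclonal.
    """
    regions = list(events_by_region)
    if len(regions) < 2:
        raise ValueError("need >= 2 regions to classify CNV clonality")
    loh_by_region = loh_by_region or {r: set() for r in regions}
    if set(loh_by_region) != set(regions):
        raise ValueError("LOH bin maps must cover every region")
    out: dict[EventKey, str] = {}
    universe = set().union(*events_by_region.values())
    for key in universe:
        chrom, b, direction = key
        if direction == "gain":
            everywhere = all(key in events_by_region[r] for r in regions)
        else:
            everywhere = all(
                key in events_by_region[r] or (chrom, b) in loh_by_region[r]
                for r in regions
            )
        out[key] = "clonal" if everywhere else "subclonal"
    return out


def jaccard_distance(a: set, b: set) -> float:
    """1 - |A n B| / |A u B|; 0.0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def cnv_ith(events_by_region: Mapping[str, set]) -> float | None:
    """Mean pairwise Jaccard distance between per-region event sets.

    Returns None (missing) with fewer than two regions. Invariant under
    region relabeling; 0 when all regions carry identical events, 1 when
    all pairs are disjoint and non-empty.
    """
    regions = sorted(events_by_region)
    if len(regions) < 2:
        return None
    dists = [
        jaccard_distance(events_by_region[a], events_by_region[b])
        for a, b in combinations(regions, 2)
    ]
    return float(np.mean(dists))
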