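"""End-to-end per-patient analysis: filters to PatientReport.

Order of stages: per-region somatic filters; cross-region rescue; CCF
estimation over the union of nonsilent mutations; binomial-mixture
clustering (cluster count, clonal/subclonal partition, SNV ITH); TMB
and TMB/cluster; binned CNV events (CNV ITH, GII, clonality); per-region
WGD tests; maximum-parsimony region tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clonality as cl
from . import cnv as cn
from . import phylo as ph
from .core_io import MutationCall, PatientReport, RegionProfile, SegmentCN
from .filters import FilterParams, apply_somatic_filters, rescue_cross_region

logger = logging.getLogger("mrith")

__all__ = ["PatientAnalysis", "analyze_patient", "analyze_cohort"]


@dataclass
class PatientAnalysis:
    """All per-patient pipeline outputs."""

    report: PatientReport
    solution: cl.ClusterSolution | None
    ccf_estimates: list
    union_keys: tuple
    presence: ph.PresenceMatrix | None
    tree: ph.PhyloTree | None
    wgd_by_region: dict
    events_by_region: dict
    calls_by_region: dict


def _group_by_region(items, regions):
    out = {r: [] for r in regions}
    for it in items:
        out.setdefault(it.region_id, []).append(it)
    return out


def analyze_patient(
    calls: list,
    segments: list,
    profiles: list,
    filter_params: FilterParams | None = None,
    coding_mb: float = 38.0,
    bin_size: int = 10_000_000,
    k_max: int = 8,
    wgd_n_sim: int = 1000,
    seed: int = 0,
    build_phylogeny: bool = True,
) -> PatientAnalysis:
    """Run the full pipeline for one patient.

    ``calls`` must carry raw counts for every (mutation, region) so the
    cross-region rescue and clustering can re-examine uncalled regions;
    regions without a record at a locus are treated as unobserved.
    """
    params = filter_params or FilterParams()
    patient_id = calls[0].patient_id if calls else profiles[0].patient_id
    regions = sorted({p.region_id for p in profiles})
    purity = {p.region_id: p.purity for p in profiles}
    ploidy = {p.region_id: p.ploidy for p in profiles}
    calls_by_region = _group_by_region(calls, regions)
    segs_by_region = _group_by_region(segments, regions)

    # 1) somatic filters, then cross-region rescue from the raw records
    raw_pileups = {
        r: {c.key: c for c in calls_by_region[r]} for r in regions
    }
    filtered = {
        r: apply_somatic_filters(calls_by_region[r], params) for r in regions
    }
    rescued = rescue_cross_region(filtered, raw_pileups, params)

    # 2) union of nonsilent mutations across regions
    union: dict[tuple, dict[str, MutationCall]] = {}
    for r in regions:
        for c in rescued[r]:
            if c.effect != "nonsilent":
                continue
            union.setdefault(c.key, {})[r] = c
    union_keys = tuple(union)
    n_union = len(union_keys)

    def locate_segment(r, chrom, pos):
        for s in segs_by_region[r]:
            if s.contains(chrom, pos):
                return s
        return None

    # 3) CCF estimation and clustering inputs
    ccf_records = []
    alt = np.zeros((n_union, len(regions)))
    depth = np.zeros((n_union, len(regions)))
    factor = np.full((n_union, len(regions)), 0.5)
    for i, key in enumerate(union_keys):
        chrom, pos, _, _ = key
        for j, r in enumerate(regions):
            raw = raw_pileups[r].get(key)
            if raw is None or raw.depth == 0:
                continue
            seg = locate_segment(r, chrom, pos)
            tcn = seg.total_cn if seg else 2.0
            major = seg.major_cn if seg else 1
            if tcn == 0:
                logger.warning(
                    "mutation %s in zero-copy segment in %s; excluded there",
                    key,
                    r,
                )
                continue
            p = purity[r]
            mcn = cl.mutation_copy_number(raw.vaf, p, tcn)
            mult, ccf, capped = cl.estimate_ccf(mcn, major)
            denom = p * tcn + (1.0 - p) * 2.0
            alt[i, j] = raw.alt_reads
            depth[i, j] = raw.depth
            factor[i, j] = mult * p / denom
            ccf_records.append(
                cl.CcfEstimate(
                    key=key, region_id=r, mut_cn=mcn, multiplicity=mult,
                    ccf=ccf, capped=capped,
                )
            )

    solution = None
    ith = None
    n_clusters = 0
    if n_union > 0:
        est = cl.BinomialMixture(k_max=k_max, random_state=seed)
        est.fit(alt, depth, factor)
        solution = est.solution()
        n_clusters = solution.n_clusters
        clonal_flags = cl.assign_clonality(solution)
        ith = cl.snv_ith(clonal_flags)
        key_index = {k: i for i, k in enumerate(union_keys)}
        ccf_records = [
            cl.CcfEstimate(
                key=rec.key,
                region_id=rec.region_id,
                mut_cn=rec.mut_cn,
                multiplicity=rec.multiplicity,
                ccf=rec.ccf,
                capped=rec.capped,
                cluster_id=int(solution.assignments[key_index[rec.key]]),
                mean_cluster_prevalence=float(
                    solution.mean_prevalence[
                        solution.assignments[key_index[rec.key]]
                    ]
                ),
                clonal=bool(clonal_flags[key_index[rec.key]]),
            )
            for rec in ccf_records
        ]

    tmb_value = cl.tmb(n_union, coding_mb)
    tmb_pc = cl.tmb_per_cluster(tmb_value, n_clusters) if n_clusters else 0.0

    # 4) CNV: binned events, ITH, GII, WGD
    events_by_region = {}
    loh_by_region = {}
    gii_values = []
    wgd_by_region = {}
    for j, r in enumerate(regions):
        ev, loh = cn.bin_events(segs_by_region[r], ploidy[r], bin_size=bin_size)
        events_by_region[r] = ev
        loh_by_region[r] = loh
        region_events = cn.call_events(segs_by_region[r], ploidy[r])
        gii_values.append(cn.genome_instability_index(region_events))
        wgd_by_region[r] = cn.detect_wgd(
            segs_by_region[r], n_sim=wgd_n_sim, seed=seed + j
        )
    cnv_ith_value = cn.cnv_ith(events_by_region)
    gii = float(np.mean(gii_values)) if gii_values else 0.0
    wgd = any(w is not None and w.is_wgd for w in wgd_by_region.values())

    # 5) phylogeny
    presence = None
    tree = None
    if build_phylogeny:
        all_rescued = [c for r in regions for c in rescued[r]]
        presence = ph.presence_matrix(all_rescued, segments, regions=regions)
        if len(presence.keys):
            tree = ph.build_tree(presence)

    report = PatientReport(
        patient_id=patient_id,
        n_mutations=n_union,
        snv_ith=ith,
        cnv_ith=cnv_ith_value,
        tmb=tmb_value,
        n_clusters=n_clusters,
        tmb_per_cluster=tmb_pc,
        wgd=wgd,
        gii=gii,
    )
    return PatientAnalysis(
        report=report,
        solution=solution,
        ccf_estimates=ccf_records,
        union_keys=union_keys,
        presence=presence,
        tree=tree,
        wgd_by_region=wgd_by_region,
        events_by_region=events_by_region,
        calls_by_region=rescued,
    )


def analyze_cohort(
    calls: list,
    segments: list,
    profiles: list,
    seed: int = 0,
    **kwargs,
) -> list[PatientAnalysis]:
    """Run analyze_patient for every patient present in the inputs."""
    patients = sorted({p.patient_id for p in profiles})
    by_patient_calls: dict[str, list] = {p: [] for p in patients}
    by_patient_segs: dict[str, list] = {p: [] for p in patients}
    by_patient_prof: dict[str, list] = {p: [] for p in patients}
    for c in calls:
        by_patient_calls[c.patient_id].append(c)
    for s in segments:
        by_patient_segs[s.patient_id].append(s)
    for p in profiles:
        by_patient_prof[p.patient_id].append(p)
    out = []
    for i, pid in enumerate(patients):
        out.append(
            analyze_patient(
                by_patient_calls[pid],
                by_patient_segs[pid],
                by_patient_prof[pid],
                seed=seed + i,
                **kwargs,
            )
        )
    return out
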