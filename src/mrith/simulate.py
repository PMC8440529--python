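"""Synthetic multi-region SCLC-like cohorts with known ground truth.

Each patient carries a clone tree (a clonal founder plus 0-4 subclones,
linear or branching), multi-region allele-specific copy number with
optional whole-genome doubling, trinucleotide contexts drawn from a
configurable signature mixture, and exponential proportional-hazards
survival linked to the true heterogeneity metrics. Read counts follow
the purity/copy-number model used downstream: the expected VAF of a
mutation with cancer cell fraction CCF and multiplicity m in a region
of purity p and local total copy number q is

    E[VAF] = p * CCF * m / (p*q + (1-p)*2)

with observed alt reads Binomial(depth, E[VAF]) at Poisson-distributed
depth. Subclones occupy a proper subset of their parent clone's regions
(spatial confinement), and per-region clone CCFs obey the sum rule
(children never exceed their parent). The generator emits one count
record per (mutation, region) — a force-called matrix — so the somatic
filters, cross-region rescue and clustering all see realistic inputs.

Per-patient randomness derives from SeedSequence(master seed, patient
index): cohorts are reproducible and patients independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    AUTOSOMES,
    CONTIGS,
    ClinicalRecord,
    MutationCall,
    RegionProfile,
    SegmentCN,
    write_clinical,
    write_mutation_table,
    write_region_profiles,
    write_segments,
)
from .signatures import CONTEXTS_96, load_catalog

logger = logging.getLogger("mrith")

__all__ = ["SimConfig", "SimTruth", "Cohort", "simulate_patient", "simulate_cohort"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Clonal (c) and subclonal (s) driver genes with cohort frequencies,
#: mirroring the mutation landscape the cohort emulates.
_DRIVER_FREQS = {
    "TP53": (0.88, "clonal"),
    "RB1": (0.72, "clonal"),
    "CREBBP": (0.30, "clonal"),
    "LRP1B": (0.22, "subclonal"),
    "PCLO": (0.15, "subclonal"),
    "KMT2D": (0.15, "subclonal"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_patients: int = 40
    regions_per_patient: int = 3
    mean_depth: float = 252.0
    purity_range: tuple = (0.3, 0.9)
    n_clonal_range: tuple = (50, 450)
    n_subclone_range: tuple = (0, 4)
    n_per_subclone_range: tuple = (15, 110)
    subclone_ccf_range: tuple = (0.2, 0.8)  # stick-breaking fraction range
    min_subclone_ccf: float = 0.1  # resolvability floor at exome depth
    wgd_probability: float = 0.4
    signature_mixture: dict = field(
        default_factory=lambda: {
            "Signature.1": 0.40,  # age-like
            "Signature.4": 0.30,  # tobacco-like
            "Signature.3": 0.15,  # HR-deficiency-like
            "Signature.24": 0.15,  # aflatoxin-like
        }
    )
    coding_mb: float = 38.0
    silent_fraction: float = 0.25
    tree_structure: str = "mixed"  # mixed | linear | branching
    cnv_clonal_rate: float = 6.0  # mean clonal CNV events per patient
    cnv_subclonal_rate: float = 3.0  # mean region-private CNV events
    ffpe_noise_rate: float = 0.0  # mean private C>T artifact calls per region
    hazard_coefficients: dict = field(
        default_factory=lambda: {
            "os_snv_ith": 1.5,  # log-hazard per unit SNV ITH (worse OS)
            "dfs_tmb_per_cluster": -0.12,  # log-hazard per mut/Mb (better DFS)
        }
    )
    os_baseline_median: float = 45.0  # months
    dfs_baseline_median: float = 28.0
    censor_range: tuple = (6.0, 84.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_name in (
            "purity_range",
            "n_clonal_range",
            "n_subclone_range",
            "n_per_subclone_range",
            "subclone_ccf_range",
            "censor_range",
        ):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name}: invalid range ({lo}, {hi})")
        w = np.array(list(self.signature_mixture.values()), dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("signature_mixture weights must be >= 0 and sum to 1")
        if self.tree_structure not in ("mixed", "linear", "branching"):
            raise ValueError("tree_structure must be mixed | linear | branching")


@dataclass
class SimTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    regions: tuple
    parents: tuple  # parents[c] = parent clone index (-1 for the root)
    clone_regions: tuple  # per clone: frozenset of occupied region ids
    clone_ccf: np.ndarray  # (n_clones, n_regions)
    mutation_clone: dict  # mutation key -> clone index
    n_clones: int
    true_snv_ith: float
    wgd: bool
    true_cnv_events: dict  # region -> set of (chrom, bin, direction)
    signature_weights: dict
    true_tmb: float
    true_tmb_per_cluster: float


@dataclass
class Cohort:
    """A simulated cohort bundle."""

    calls: list
    segments: list
    profiles: list
    clinical: list
    truths: list
    config: SimConfig


def _patient_rng(config: SimConfig, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(patient_index)])
    )


def _draw_tree(rng, n_sub: int, structure: str, regions: tuple):
    """Clone tree (parent map) and per-clone region occupancy."""
    if structure == "mixed":
        structure = "linear" if rng.random() < 0.5 else "branching"
    parents = [-1]
    for c in range(1, n_sub + 1):
        parents.append(c - 1 if structure == "linear" else 0)
    occupancy = [frozenset(regions)]
    for c in range(1, n_sub + 1):
        parent_occ = sorted(occupancy[parents[c]])
        if len(parent_occ) > 1:
            size = int(rng.integers(1, len(parent_occ)))  # proper subset
        else:
            size = 1
        chosen = rng.choice(len(parent_occ), size=size, replace=False)
        occupancy.append(frozenset(parent_occ[i] for i in chosen))
    return parents, occupancy


def _draw_ccfs(rng, parents, occupancy, regions, ccf_range):
    """Per-clone per-region CCFs obeying the sum rule.

    Sibling CCFs are allocated by stick-breaking on the parent's budget
    (each sibling, in random order, takes a U(ccf_range) fraction of the
    remaining stick), mirroring the Dirichlet-process-style prevalence
    priors of CCF clustering models and yielding diverse clone sizes.
    """
    n_clones = len(parents)
    ccf = np.zeros((n_clones, len(regions)))
    ccf[0, :] = 1.0
    children = {c: [] for c in range(n_clones)}
    for c in range(1, n_clones):
        children[parents[c]].append(c)
    for j, r in enumerate(regions):
        for parent in range(n_clones):
            kids = [c for c in children[parent] if r in occupancy[c]]
            if not kids:
                continue
            remaining = ccf[parent, j] * 0.95
            for i in rng.permutation(len(kids)):
                take = remaining * float(rng.uniform(*ccf_range))
                ccf[kids[i], j] = take
                remaining -= take
    return ccf


def _prune_unresolvable(parents, occupancy, ccf, min_ccf):
    """Drop subclone subtrees whose CCF stays below the floor everywhere."""
    n = len(parents)
    keep = [True] * n
    for c in range(1, n):
        if not keep[parents[c]] or ccf[c].max() < min_ccf:
            keep[c] = False
    idx = [c for c in range(n) if keep[c]]
    remap = {old: new for new, old in enumerate(idx)}
    new_parents = tuple(
        -1 if parents[c] == -1 else remap[parents[c]] for c in idx
    )
    new_occ = tuple(occupancy[c] for c in idx)
    return new_parents, new_occ, ccf[idx]


def _draw_segments(rng, config, patient_id, regions):
    """Shared-breakpoint allele-specific segments per region.

    Returns (segments per region, wgd flag, per-region state arrays).
    Whole-genome doubling doubles the clonal states; post-doubling
    single-copy losses retain a doubled major allele.
    """
    breakpoints = []  # (chrom, start, end)
    for chrom in AUTOSOMES:
        n_parts = int(rng.integers(1, 4))
        length = CONTIGS[chrom]
        if n_parts == 1:
            cuts = []
        else:
            cuts = sorted(
                int(x) for x in rng.integers(2, length, size=n_parts - 1)
            )
        edges = [1] + cuts + [length]
        for a, b in zip(edges[:-1], edges[1:]):
            start = a if a == 1 else a + 1
            if start <= b:
                breakpoints.append((chrom, start, b))
    n_seg = len(breakpoints)
    major = np.ones(n_seg, dtype=int)
    minor = np.ones(n_seg, dtype=int)

    # clonal events, shared by all regions
    n_clonal = rng.poisson(config.cnv_clonal_rate)
    for idx in rng.choice(n_seg, size=min(n_clonal, n_seg), replace=False):
        if rng.random() < 0.5:
            major[idx] += 1  # clonal gain
        else:
            minor[idx] = 0  # clonal LOH loss

    wgd = bool(rng.random() < config.wgd_probability)
    if wgd:
        major *= 2
        minor *= 2

    states = {}
    for r in regions:
        M, m = major.copy(), minor.copy()
        n_private = rng.poisson(config.cnv_subclonal_rate)
        for idx in rng.choice(n_seg, size=min(n_private, n_seg), replace=False):
            if rng.random() < 0.5:
                M[idx] += 1  # private gain
            elif m[idx] >= 1:
                m[idx] -= 1  # private single-copy loss of the minor allele
            # segments already at LOH are left untouched: further loss of the
            # remaining haplotype is strongly selected against
        states[r] = (M, m)
    segments = {
        r: [
            SegmentCN(
                patient_id=patient_id,
                region_id=r,
                chrom=c,
                start=s,
                end=e,
                total_cn=float(states[r][0][i] + states[r][1][i]),
                major_cn=int(states[r][0][i]),
                minor_cn=int(states[r][1][i]),
            )
            for i, (c, s, e) in enumerate(breakpoints)
        ]
        for r in regions
    }
    return segments, wgd, breakpoints, states


def _decode_context(bin_index: int):
    label = CONTEXTS_96[bin_index]  # e.g. "A[C>T]G"
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    return ref, alt, five + ref + three


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def simulate_patient(config: SimConfig, patient_index: int):
    """Simulate one patient.

    Returns (calls, segments, profiles, clinical, truth); ``calls``
    holds one record per (mutation, region) with raw counts.
    """
    rng = _patient_rng(config, patient_index)
    patient_id = f"SIM{patient_index + 1:03d}"
    regions = tuple(f"R{j + 1}" for j in range(config.regions_per_patient))

    n_sub = int(rng.integers(config.n_subclone_range[0], config.n_subclone_range[1] + 1))
    parents, occupancy = _draw_tree(rng, n_sub, config.tree_structure, regions)
    ccf = _draw_ccfs(rng, parents, occupancy, regions, config.subclone_ccf_range)
    # subclones below the resolvability floor in every occupied region are
    # not modeled (they are invisible at exome depth); drop whole subtrees
    parents, occupancy, ccf = _prune_unresolvable(
        parents, occupancy, ccf, config.min_subclone_ccf
    )
    n_clones = len(parents)

    segments, wgd, breakpoints, states = _draw_segments(
        rng, config, patient_id, regions
    )
    purities = {r: float(rng.uniform(*config.purity_range)) for r in regions}
    ploidies = {}
    lengths = np.array([e - s + 1 for _, s, e in breakpoints], dtype=float)
    for r in regions:
        M, m = states[r]
        ploidies[r] = float(((M + m) * lengths).sum() / lengths.sum())
    profiles = [
        RegionProfile(patient_id, r, purities[r], ploidies[r]) for r in regions
    ]

    # --- mutations -------------------------------------------------------
    catalog = load_catalog()
    sig_names = list(config.signature_mixture)
    sig_weights = np.array([config.signature_mixture[s] for s in sig_names])
    sig_cols = catalog[sig_names].to_numpy().T  # (n_sigs, 96)

    n_per_clone = [int(rng.integers(*config.n_clonal_range))]
    for _ in range(n_clones - 1):
        n_per_clone.append(int(rng.integers(*config.n_per_subclone_range)))

    chrom_lengths = np.array([CONTIGS[c] for c in AUTOSOMES], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()

    muts = []  # (key, clone, gene, effect, ref, alt, context)
    used_loci = set()
    for clone, n_mut in enumerate(n_per_clone):
        for _ in range(n_mut):
            while True:
                ci = rng.choice(len(AUTOSOMES), p=chrom_p)
                chrom = AUTOSOMES[ci]
                pos = int(rng.integers(1, CONTIGS[chrom] + 1))
                if (chrom, pos) not in used_loci:
                    used_loci.add((chrom, pos))
                    break
            sig = rng.choice(len(sig_names), p=sig_weights)
            b = rng.choice(96, p=sig_cols[sig] / sig_cols[sig].sum())
            ref, alt, context = _decode_context(int(b))
            if rng.random() < 0.5:  # emit on the purine strand
                ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
            effect = "silent" if rng.random() < config.silent_fraction else "nonsilent"
            gene = f"GENE{int(rng.integers(1, 18000)):05d}"
            muts.append([(chrom, pos, ref, alt), clone, gene, effect, context])

    # driver genes: overwrite gene labels on mutations of the right clonality
    clonal_idx = [i for i, m in enumerate(muts) if m[1] == 0 and m[3] == "nonsilent"]
    sub_idx = [i for i, m in enumerate(muts) if m[1] > 0 and m[3] == "nonsilent"]
    clonal_idx.sort()
    sub_idx.sort()
    rng.shuffle(clonal_idx)
    rng.shuffle(sub_idx)
    egfr_classic = bool(rng.random() < 0.10)
    wanted = [("EGFR", "clonal")] if egfr_classic else []
    wanted += [
        (g, kind) for g, (p, kind) in _DRIVER_FREQS.items() if rng.random() < p
    ]
    for gene, kind in wanted:
        pool = clonal_idx if kind == "clonal" or not sub_idx else sub_idx
        if pool:
            muts[pool.pop()][2] = gene

    # --- per-region read counts -----------------------------------------
    seg_lookup = {
        r: segments[r] for r in regions
    }
    calls = []
    for key, clone, gene, effect, context in muts:
        chrom, pos, ref, alt = key
        for r in regions:
            seg = next(
                (s for s in seg_lookup[r] if s.contains(chrom, pos)), None
            )
            total_cn = seg.total_cn if seg else 2.0
            major_cn = seg.major_cn if seg else 1
            mult = 1
            if clone == 0 and wgd and major_cn >= 2 and rng.random() < 0.75:
                mult = 2  # founder mutation predating the doubling
            p = purities[r]
            cf = ccf[clone, list(regions).index(r)]
            denom = p * total_cn + (1 - p) * 2.0
            evaf = min(0.999, p * cf * mult / denom) if denom > 0 else 0.0
            depth = max(1, int(rng.poisson(config.mean_depth)))
            alt_reads = int(rng.binomial(depth, evaf))
            ndepth = max(1, int(rng.poisson(config.mean_depth)))
            nalt = int(rng.binomial(ndepth, 5e-4))
            pop_af = float(rng.uniform(0.0, 0.05)) if rng.random() < 0.02 else 0.0
            calls.append(
                MutationCall(
                    patient_id=patient_id,
                    region_id=r,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    effect=effect,
                    alt_reads=alt_reads,
                    ref_reads=depth - alt_reads,
                    normal_alt_reads=nalt,
                    normal_depth=ndepth,
                    population_af=pop_af,
                    context=context,
                )
            )

    # optional FFPE artifact knob: private low-VAF C>T noise
    if config.ffpe_noise_rate > 0:
        for r in regions:
            for _ in range(rng.poisson(config.ffpe_noise_rate)):
                ci = rng.choice(len(AUTOSOMES), p=chrom_p)
                chrom = AUTOSOMES[ci]
                pos = int(rng.integers(1, CONTIGS[chrom] + 1))
                if (chrom, pos) in used_loci:
                    continue
                used_loci.add((chrom, pos))
                depth = max(1, int(rng.poisson(config.mean_depth)))
                alt_reads = int(rng.binomial(depth, rng.uniform(0.01, 0.04)))
                five, three = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
                calls.append(
                    MutationCall(
                        patient_id=patient_id,
                        region_id=r,
                        chrom=chrom,
                        pos=pos,
                        ref="C",
                        alt="T",
                        gene=f"GENE{int(rng.integers(1, 18000)):05d}",
                        effect="nonsilent",
                        alt_reads=alt_reads,
                        ref_reads=depth - alt_reads,
                        normal_alt_reads=0,
                        normal_depth=max(1, int(rng.poisson(config.mean_depth))),
                        population_af=0.0,
                        context=f"{five}C{three}",
                    )
                )

    # --- truth metrics ---------------------------------------------------
    nonsilent = [(key, clone) for key, clone, _, eff, _ in muts if eff == "nonsilent"]
    n_nonsilent = len(nonsilent)
    n_subclonal = sum(1 for _, clone in nonsilent if clone > 0)
    true_ith = n_subclonal / n_nonsilent if n_nonsilent else 0.0
    true_tmb = n_nonsilent / config.coding_mb
    true_tmbpc = true_tmb / n_clones

    from .cnv import bin_events  # local import to avoid a cycle

    true_events = {
        r: bin_events(segments[r], ploidies[r])[0] for r in regions
    }

    # --- clinical and survival ------------------------------------------
    coef = config.hazard_coefficients
    lam_os = np.log(2) / config.os_baseline_median * np.exp(
        coef.get("os_snv_ith", 0.0) * (true_ith - 0.3)
    )
    lam_dfs = np.log(2) / config.dfs_baseline_median * np.exp(
        coef.get("dfs_tmb_per_cluster", 0.0) * (true_tmbpc - 4.0)
    )
    t_os = float(rng.exponential(1.0 / lam_os))
    t_dfs = float(rng.exponential(1.0 / lam_dfs))
    c_os = float(rng.uniform(*config.censor_range))
    c_dfs = float(rng.uniform(*config.censor_range))
    tnb = float(rng.poisson(0.12 * n_nonsilent * float(rng.lognormal(0.0, 0.5))))

    clinical = ClinicalRecord(
        patient_id=patient_id,
        age=float(np.clip(round(rng.normal(62, 10)), 23, 76)),
        sex="male" if rng.random() < 0.875 else "female",
        smoking=["non-smoker", "smoker", "NA"][
            int(rng.choice(3, p=[0.20, 0.775, 0.025]))
        ],
        stage=["I", "II", "III"][int(rng.choice(3, p=[0.375, 0.175, 0.45]))],
        tumor_size=float(np.round(rng.lognormal(np.log(22.5), 0.6), 1)),
        histology="C-SCLC" if rng.random() < 0.15 else "P-SCLC",
        treatment_after_surgery=bool(rng.random() < 0.65),
        dfs_time=min(t_dfs, c_dfs),
        dfs_event=t_dfs <= c_dfs,
        os_time=min(t_os, c_os),
        os_event=t_os <= c_os,
        tnb=tnb,
        egfr_classic=egfr_classic,
    )

    truth = SimTruth(
        patient_id=patient_id,
        regions=regions,
        parents=tuple(parents),
        clone_regions=tuple(occupancy),
        clone_ccf=ccf,
        mutation_clone={key: clone for key, clone, _, _, _ in muts},
        n_clones=n_clones,
        true_snv_ith=true_ith,
        wgd=wgd,
        true_cnv_events=true_events,
        signature_weights=dict(config.signature_mixture),
        true_tmb=true_tmb,
        true_tmb_per_cluster=true_tmbpc,
    )
    all_segments = [s for r in regions for s in segments[r]]
    return calls, all_segments, profiles, clinical, truth


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> Cohort:
    """Simulate ``config.n_patients`` independent patients.

    When ``out_dir`` is given, writes mutations.tsv, segments.tsv,
    profiles.tsv, clinical.tsv and truth.tsv there.
    """
    calls, segments, profiles, clinical, truths = [], [], [], [], []
    for i in range(config.n_patients):
        c, s, p, cl, t = simulate_patient(config, i)
        calls += c
        segments += s
        profiles += p
        clinical.append(cl)
        truths.append(t)
    cohort = Cohort(calls, segments, profiles, clinical, truths, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mutation_table(calls, out / "mutations.tsv")
        write_segments(segments, out / "segments.tsv")
        write_region_profiles(profiles, out / "profiles.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        pd.DataFrame(
            [
                {
                    "patient_id": t.patient_id,
                    "n_clones": t.n_clones,
                    "true_snv_ith": t.true_snv_ith,
                    "wgd": t.wgd,
                    "true_tmb": t.true_tmb,
                    "true_tmb_per_cluster": t.true_tmb_per_cluster,
                }
                for t in truths
            ]
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
    logger.info(
        "simulate_cohort: %d patients, %d call records",
        config.n_patients,
        len(calls),
    )
    return cohort
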