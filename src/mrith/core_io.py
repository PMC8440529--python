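"""Domain types, coordinate conventions and tabular I/O.

All coordinates are 1-based inclusive internally (MAF/SEG convention).
VCF positions are already 1-based and are used as-is; any half-open
external dialect must be converted at the boundary.

The contig dictionary is hg19 (autosomes 1-22 plus X and Y). Sex
chromosomes are excluded from genome-wide denominators (GII, WGD) by
default; the generator emits autosomes only.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("mrith")

__all__ = [
    "MutationCall",
    "SegmentCN",
    "RegionProfile",
    "ClinicalRecord",
    "PatientReport",
    "CONTIGS",
    "AUTOSOMES",
    "AUTOSOME_BP",
    "SchemaError",
    "ValidationError",
    "read_mutation_table",
    "write_mutation_table",
    "read_segments",
    "write_segments",
    "read_region_profiles",
    "write_region_profiles",
    "read_clinical",
    "write_clinical",
    "read_patient_reports",
    "write_patient_report",
]


class SchemaError(ValueError):
    """A required column is missing or a row cannot be parsed."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _load_contigs() -> dict[str, int]:
    src = importlib.resources.files("mrith.data").joinpath("hg19_contigs.tsv")
    with importlib.resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


#: hg19 contig lengths, chromosome name -> length in bp.
CONTIGS: dict[str, int] = _load_contigs()
#: Autosome names, in karyotype order.
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
#: Total autosomal genome size in bp (GII / WGD denominator).
AUTOSOME_BP: int = sum(CONTIGS[c] for c in AUTOSOMES)

_EFFECTS = ("nonsilent", "silent")


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def from_half_open(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval (BED-style) to 1-based inclusive."""
    if end0 <= start0:
        raise ValidationError(f"empty half-open interval [{start0}, {end0})")
    return start0 + 1, end0


@dataclass(frozen=True)
class MutationCall:
    """One somatic variant observed (or rescued) in one tumor region."""

    patient_id: str
    region_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    effect: str  # nonsilent | silent
    alt_reads: int
    ref_reads: int
    normal_alt_reads: int
    normal_depth: int
    population_af: float = 0.0
    context: str | None = None  # 3-mer centered on pos, reference strand
    rescued: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if self.chrom not in CONTIGS:
            raise ValidationError(f"unknown contig {self.chrom!r}")
        if not 1 <= self.pos <= CONTIGS[self.chrom]:
            raise ValidationError(
                f"position {self.pos} outside contig {self.chrom}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.key}")
        if self.effect not in _EFFECTS:
            raise ValidationError(f"effect must be one of {_EFFECTS}")
        for name in ("alt_reads", "ref_reads", "normal_alt_reads", "normal_depth"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} < 0 at {self.key}")
        if not 0.0 <= self.population_af <= 1.0:
            raise ValidationError("population_af outside [0, 1]")
        if self.context is not None and len(self.context) != 3:
            raise ValidationError("context must be a 3-mer")

    @property
    def depth(self) -> int:
        return self.alt_reads + self.ref_reads

    @property
    def vaf(self) -> float:
        """Variant allele frequency; 0.0 at zero depth."""
        d = self.depth
        return self.alt_reads / d if d > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Locus identity shared across regions: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class SegmentCN:
    """Allele-specific copy-number segment in one region (1-based, inclusive)."""

    patient_id: str
    region_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if self.chrom not in CONTIGS:
            raise ValidationError(f"unknown contig {self.chrom!r}")
        if self.start > self.end:
            raise ValidationError(
                f"start > end on {self.chrom}:{self.start}-{self.end}"
            )
        if self.end > CONTIGS[self.chrom]:
            raise ValidationError(
                f"segment end {self.end} past contig {self.chrom} end"
            )
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"require major_cn >= minor_cn >= 0, got "
                f"({self.major_cn}, {self.minor_cn})"
            )
        if self.total_cn < 0:
            raise ValidationError("total_cn < 0")
        if round(self.total_cn) != self.major_cn + self.minor_cn:
            raise ValidationError(
                f"major+minor ({self.major_cn}+{self.minor_cn}) != "
                f"round(total_cn={self.total_cn})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        """Loss of heterozygosity: minor allele lost, total copy retained."""
        return self.minor_cn == 0 and self.total_cn > 0

    def contains(self, chrom: str, pos: int) -> bool:
        return _norm_chrom(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionProfile:
    """Per-region tumor purity and ploidy (inputs; estimated upstream)."""

    patient_id: str
    region_id: str
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical covariates and survival endpoints."""

    patient_id: str
    age: float
    sex: str  # male | female
    smoking: str  # smoker | non-smoker | NA
    stage: str  # I | II | III | IV
    tumor_size: float  # mm
    histology: str  # P-SCLC | C-SCLC
    treatment_after_surgery: bool
    dfs_time: float  # months
    dfs_event: bool
    os_time: float  # months
    os_event: bool
    tnb: float | None = None  # simulated neoantigen burden
    egfr_classic: bool = False  # classic activating EGFR mutation

    def __post_init__(self) -> None:
        if self.dfs_time < 0 or self.os_time < 0:
            raise ValidationError("survival times must be >= 0")
        if self.stage not in ("I", "II", "III", "IV"):
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.histology not in ("P-SCLC", "C-SCLC"):
            raise ValidationError(f"unknown histology {self.histology!r}")


@dataclass(frozen=True)
class PatientReport:
    """Per-patient heterogeneity summary (one output row per patient)."""

    patient_id: str
    n_mutations: int  # union of nonsilent mutations across regions
    snv_ith: float | None
    cnv_ith: float | None
    tmb: float
    n_clusters: int
    tmb_per_cluster: float
    wgd: bool
    gii: float

    COLUMNS = (
        "patient_id",
        "n_mutations",
        "snv_ith",
        "cnv_ith",
        "tmb",
        "n_clusters",
        "tmb_per_cluster",
        "wgd",
        "gii",
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_MUT_COLUMNS = (
    "patient_id",
    "region_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "alt_reads",
    "ref_reads",
    "normal_alt_reads",
    "normal_depth",
    "population_af",
    "context",
)

_SEG_COLUMNS = (
    "patient_id",
    "region_id",
    "chrom",
    "start",
    "end",
    "total_cn",
    "major_cn",
    "minor_cn",
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_mutation_table(path: str | Path, dialect: str = "maf_tsv", **kwargs):
    """Read somatic mutation calls; one record per (variant, region).

    ``dialect='maf_tsv'`` expects a TSV with the documented header;
    ``dialect='vcf'`` reads a VCF 4.x file whose samples are the tumor
    regions, with read counts taken from the AD/DP FORMAT fields and
    multiallelic ALTs split into one record per allele.
    """
    if dialect == "maf_tsv":
        return _read_mutations_tsv(Path(path))
    if dialect == "vcf":
        return _read_mutations_vcf(Path(path), **kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_mutations_tsv(path: Path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    _require_columns(df, [c for c in _MUT_COLUMNS if c != "context"], str(path))
    calls: list[MutationCall] = []
    has_ctx = "context" in df.columns
    has_resc = "rescued" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ctx = getattr(row, "context", None) if has_ctx else None
            if isinstance(ctx, float) or ctx in ("", "nan", None):
                ctx = None
            calls.append(
                MutationCall(
                    patient_id=str(row.patient_id),
                    region_id=str(row.region_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene),
                    effect=str(row.effect),
                    alt_reads=int(row.alt_reads),
                    ref_reads=int(row.ref_reads),
                    normal_alt_reads=int(row.normal_alt_reads),
                    normal_depth=int(row.normal_depth),
                    population_af=float(row.population_af),
                    context=ctx,
                    rescued=bool(getattr(row, "rescued", False)) if has_resc else False,
                )
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: unparseable row at line {i + 2}: {exc}") from exc
    logger.info("read_mutation_table: %d records from %s", len(calls), path)
    return calls


def _read_mutations_vcf(
    path: Path,
    patient_id: str = "P1",
    normal_sample: str | None = None,
) -> list[MutationCall]:
    """Read a multi-sample VCF; samples (minus the normal) are regions.

    Per-sample counts come from AD (ref, alt1, alt2, ...); INFO fields
    GENE, EFFECT and POP_AF are honored when present. When no normal
    sample is in the VCF, INFO NORMAL_AD / NORMAL_DP are used (0 / 0
    when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    normal_idx = samples.index(normal_sample) if normal_sample in samples else None
    region_idx = [i for i, s in enumerate(samples) if i != normal_idx]
    calls: list[MutationCall] = []
    for rec in vcf:
        ad = rec.format("AD")  # (n_samples, 1 + n_alt)
        gene = rec.INFO.get("GENE", ".")
        effect = rec.INFO.get("EFFECT", "nonsilent")
        pop_af = float(rec.INFO.get("POP_AF", 0.0))
        if normal_idx is not None and ad is not None:
            n_ref = int(ad[normal_idx][0])
        for ai, alt in enumerate(rec.ALT):
            for si in region_idx:
                ref_reads = int(ad[si][0]) if ad is not None else 0
                alt_reads = int(ad[si][ai + 1]) if ad is not None else 0
                if normal_idx is not None and ad is not None:
                    normal_alt = int(ad[normal_idx][ai + 1])
                    normal_dp = n_ref + sum(
                        int(x) for x in ad[normal_idx][1:] if x >= 0
                    )
                else:
                    normal_alt = int(rec.INFO.get("NORMAL_AD", 0))
                    normal_dp = int(rec.INFO.get("NORMAL_DP", 0))
                calls.append(
                    MutationCall(
                        patient_id=patient_id,
                        region_id=samples[si],
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        gene=gene,
                        effect=effect,
                        alt_reads=alt_reads,
                        ref_reads=ref_reads,
                        normal_alt_reads=normal_alt,
                        normal_depth=normal_dp,
                        population_af=pop_af,
                    )
                )
    logger.info("read_mutation_table(vcf): %d records from %s", len(calls), path)
    return calls


def write_mutation_table(calls: Sequence[MutationCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                **{k: getattr(c, k) for k in _MUT_COLUMNS},
                "rescued": c.rescued,
            }
        )
    df = pd.DataFrame(rows, columns=list(_MUT_COLUMNS) + ["rescued"])
    df["context"] = df["context"].fillna("") if len(df) else df.get("context", "")
    df.to_csv(path, sep="\t", index=False)
    logger.info("write_mutation_table: %d records to %s", len(calls), path)


def read_segments(path: str | Path) -> list[SegmentCN]:
    """Read allele-specific segments, sorted by (chrom, start) per region.

    Overlapping segments within one region are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _SEG_COLUMNS, str(path))
    segs: list[SegmentCN] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            segs.append(
                SegmentCN(
                    patient_id=str(row.patient_id),
                    region_id=str(row.region_id),
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    total_cn=float(row.total_cn),
                    major_cn=int(row.major_cn),
                    minor_cn=int(row.minor_cn),
                )
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: unparseable row at line {i + 2}: {exc}") from exc
    chrom_order = {c: i for i, c in enumerate(CONTIGS)}
    segs.sort(
        key=lambda s: (s.patient_id, s.region_id, chrom_order[s.chrom], s.start)
    )
    _check_overlaps(segs)
    logger.info("read_segments: %d segments from %s", len(segs), path)
    return segs


def _check_overlaps(segs: Sequence[SegmentCN]) -> None:
    prev: SegmentCN | None = None
    for s in segs:
        if (
            prev is not None
            and (s.patient_id, s.region_id, s.chrom)
            == (prev.patient_id, prev.region_id, prev.chrom)
            and s.start <= prev.end
        ):
            raise ValidationError(
                f"overlapping segments in {s.patient_id}/{s.region_id}: "
                f"{prev.chrom}:{prev.start}-{prev.end} and "
                f"{s.chrom}:{s.start}-{s.end}"
            )
        prev = s


def write_segments(segs: Sequence[SegmentCN], path: str | Path) -> None:
    df = pd.DataFrame([{k: getattr(s, k) for k in _SEG_COLUMNS} for s in segs],
                      columns=_SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    logger.info("write_segments: %d segments to %s", len(segs), path)


def read_region_profiles(path: str | Path) -> list[RegionProfile]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("patient_id", "region_id", "purity", "ploidy"), str(path))
    return [
        RegionProfile(str(r.patient_id), str(r.region_id), float(r.purity), float(r.ploidy))
        for r in df.itertuples(index=False)
    ]


def write_region_profiles(profiles: Sequence[RegionProfile], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "region_id": p.region_id,
             "purity": p.purity, "ploidy": p.ploidy}
            for p in profiles
        ],
        columns=["patient_id", "region_id", "purity", "ploidy"],
    ).to_csv(path, sep="\t", index=False)


_CLIN_COLUMNS = tuple(f.name for f in fields(ClinicalRecord))


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    # "NA" is a real smoking category, not a missing value
    df = pd.read_csv(
        path, sep="\t", dtype={"stage": str},
        keep_default_na=False, na_values=[""],
    )
    required = [c for c in _CLIN_COLUMNS if c not in ("tnb", "egfr_classic")]
    _require_columns(df, required, str(path))
    recs = []
    for r in df.itertuples(index=False):
        tnb = getattr(r, "tnb", None)
        if tnb is not None and pd.isna(tnb):
            tnb = None
        recs.append(
            ClinicalRecord(
                patient_id=str(r.patient_id),
                age=float(r.age),
                sex=str(r.sex),
                smoking=str(r.smoking),
                stage=str(r.stage),
                tumor_size=float(r.tumor_size),
                histology=str(r.histology),
                treatment_after_surgery=bool(r.treatment_after_surgery),
                dfs_time=float(r.dfs_time),
                dfs_event=bool(r.dfs_event),
                os_time=float(r.os_time),
                os_event=bool(r.os_event),
                tnb=float(tnb) if tnb is not None else None,
                egfr_classic=bool(getattr(r, "egfr_classic", False)),
            )
        )
    logger.info("read_clinical: %d records from %s", len(recs), path)
    return recs


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{k: getattr(r, k) for k in _CLIN_COLUMNS} for r in records],
        columns=_CLIN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_patient_report(
    reports: PatientReport | Sequence[PatientReport], path: str | Path
) -> None:
    """Write one TSV row per patient, in the documented column order."""
    if isinstance(reports, PatientReport):
        reports = [reports]

    def fmt(v):
        return repr(v) if isinstance(v, float) else v  # shortest round-trip

    pd.DataFrame(
        [{k: fmt(getattr(r, k)) for k in PatientReport.COLUMNS} for r in reports],
        columns=PatientReport.COLUMNS,
    ).to_csv(path, sep="\t", index=False)
    logger.info("write_patient_report: %d rows to %s", len(reports), path)


def read_patient_reports(path: str | Path) -> list[PatientReport]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, PatientReport.COLUMNS, str(path))
    out = []
    for r in df.itertuples(index=False):
        out.append(
            PatientReport(
                patient_id=str(r.patient_id),
                n_mutations=int(r.n_mutations),
                snv_ith=None if pd.isna(r.snv_ith) else float(r.snv_ith),
                cnv_ith=None if pd.isna(r.cnv_ith) else float(r.cnv_ith),
                tmb=float(r.tmb),
                n_clusters=int(r.n_clusters),
                tmb_per_cluster=float(r.tmb_per_cluster),
                wgd=bool(r.wgd),
                gii=float(r.gii),
            )
        )
    return out
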