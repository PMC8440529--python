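"""96-context mutation spectra, signature refitting and driver scores.

Single-base substitutions are counted in the standard 96 trinucleotide
categories (pyrimidine-reference convention: substitutions at purine
reference bases are reverse-complemented), ordered C>A, C>G, C>T, T>A,
T>C, T>G by 16 flanking contexts each. Signature exposures are refit
against a catalog by non-negative least squares on the normalized
spectrum; exposures below a pruning threshold (default 0.06) are zeroed
and the remainder renormalized.

The packaged catalog (``synthetic_sbs_v2_like_catalog.tsv``) is a
synthetic 30-signature stand-in with the same shape and conventions as
the COSMIC SBS v2 catalog; refitting is catalog-agnostic and any 96 x S
column-stochastic matrix may be supplied instead.

Driver statistics: a gene's occurrence is frequency / n (patients
carrying it over cohort size), and its dominant score aggregates the
reciprocal frequencies of co-occurring driver genes, scaled by the
gene's own reciprocal frequency.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import MutationCall, ValidationError

logger = logging.getLogger("mrith")

__all__ = [
    "CONTEXTS_96",
    "Spectrum96",
    "SignatureExposure",
    "DriverScore",
    "context_index",
    "trinucleotide_spectrum",
    "load_catalog",
    "load_driver_genes",
    "fit_signatures",
    "occurrence",
    "dominant_score",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: The 96 category labels, e.g. "A[C>A]A", in canonical order.
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBS
    for five in _BASES
    for three in _BASES
)
_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def context_index(ref: str, alt: str, context: str) -> int:
    """96-bin index of an SNV, applying the pyrimidine-strand convention."""
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValidationError("context_index needs an SNV with a 3-mer context")
    if context[1] != ref:
        raise ValidationError(
            f"context {context} center does not match ref {ref}"
        )
    if ref in "GA":  # purine reference: flip to the pyrimidine strand
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    return _INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


@dataclass(frozen=True)
class Spectrum96:
    """96-bin trinucleotide substitution spectrum."""

    counts: np.ndarray  # (96,), non-negative
    scope: str = "patient"  # patient | trunk | branch | region
    n_skipped: int = 0  # non-SNV or context-less records

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (96,):
            raise ValidationError("spectrum must have 96 bins")
        if np.any(c < 0):
            raise ValidationError("spectrum counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        s = self.counts.sum()
        if s == 0:
            raise ValueError("empty spectrum")
        return self.counts / s

    def __add__(self, other: "Spectrum96") -> "Spectrum96":
        return Spectrum96(
            counts=self.counts + other.counts,
            scope="patient",
            n_skipped=self.n_skipped + other.n_skipped,
        )


def trinucleotide_spectrum(
    snvs: Iterable[MutationCall], scope: str = "patient"
) -> Spectrum96:
    """Count SNVs into the 96 categories; non-SNVs are skipped."""
    counts = np.zeros(96)
    skipped = 0
    for c in snvs:
        if not c.is_snv or c.context is None:
            skipped += 1
            continue
        counts[context_index(c.ref, c.alt, c.context)] += 1
    if skipped:
        logger.info("trinucleotide_spectrum: skipped %d non-SNV records", skipped)
    return Spectrum96(counts=counts, scope=scope, n_skipped=skipped)


@dataclass(frozen=True)
class SignatureExposure:
    """Non-negative signature weights for one spectrum."""

    weights: pd.Series  # indexed by signature name, sums to 1
    residual: float  # NNLS residual norm on the normalized spectrum
    n_mutations: int


@lru_cache(maxsize=1)
def _catalog_cached() -> pd.DataFrame:
    src = importlib.resources.files("mrith.data").joinpath(
        "synthetic_sbs_v2_like_catalog.tsv"
    )
    with importlib.resources.as_file(src) as p:
        df = pd.read_csv(p, sep="\t", index_col=0, comment="#")
    df = df.loc[list(CONTEXTS_96)]
    return df / df.sum(axis=0)  # undo 6-decimal rounding in the file


def load_catalog() -> pd.DataFrame:
    """Packaged synthetic SBS-v2-like catalog (96 contexts x 30 signatures).

    A synthetic stand-in with COSMIC-v2 shape and naming; columns sum
    to 1 and rows are indexed by the 96 context labels.
    """
    return _catalog_cached().copy()


def load_driver_genes() -> frozenset[str]:
    """Packaged synthetic driver-gene list (census-style stand-in)."""
    src = importlib.resources.files("mrith.data").joinpath(
        "synthetic_driver_census.txt"
    )
    with importlib.resources.as_file(src) as p:
        genes = [
            line.strip()
            for line in p.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
    return frozenset(genes)


def fit_signatures(
    spectrum: Spectrum96,
    catalog: pd.DataFrame | np.ndarray | None = None,
    prune_below: float = 0.06,
) -> SignatureExposure:
    """Refit signature exposures by non-negative least squares.

    Solves min ||catalog @ w - normalized spectrum||_2 with w >= 0,
    renormalizes w to sum 1, zeroes exposures below ``prune_below`` and
    renormalizes again.
    """
    if catalog is None:
        catalog = load_catalog()
    if isinstance(catalog, pd.DataFrame):
        names = list(catalog.columns)
        mat = catalog.to_numpy(dtype=float)
    else:
        mat = np.asarray(catalog, dtype=float)
        names = [f"Signature.{i + 1}" for i in range(mat.shape[1])]
    if mat.shape[0] != 96:
        raise ValueError("catalog must have 96 rows")
    colsum = mat.sum(axis=0)
    if not np.allclose(colsum, 1.0, atol=1e-6):
        raise ValueError("catalog columns must sum to 1")
    target = spectrum.normalized()  # raises on empty spectrum
    w, residual = nnls(mat, target)
    if w.sum() == 0:
        w = np.full(mat.shape[1], 1.0 / mat.shape[1])
    w = w / w.sum()
    w[w < prune_below] = 0.0
    if w.sum() == 0:  # everything pruned: keep the single largest exposure
        w_raw, _ = nnls(mat, target)
        w[np.argmax(w_raw)] = 1.0
    w = w / w.sum()
    return SignatureExposure(
        weights=pd.Series(w, index=names),
        residual=float(residual),
        n_mutations=spectrum.n_mutations,
    )


@dataclass(frozen=True)
class DriverScore:
    gene: str
    frequency: int  # patients carrying the gene
    occurrence: float  # frequency / n
    dominant_score: float


def occurrence(frequency: int, n: int) -> float:
    """Fraction of patients carrying a driver gene."""
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if not 0 <= frequency <= n:
        raise ValueError("need 0 <= frequency <= n")
    return frequency / n


def dominant_score(
    gene: str,
    tumors: Mapping[str, set],
    driver_genes: frozenset[str] | set[str] | None = None,
    mode: str = "pooled",
) -> float:
    """Co-occurrence-weighted dominance of one driver gene.

    ``tumors`` maps patient id -> set of mutated genes. With
    ``mode='pooled'`` (default) the score is

        [ sum over tumors t containing g,
          sum over co-occurring drivers d != g in t, 1/frequency(d) ]
        * 1/frequency(g)

    ``mode='per_tumor'`` averages the inner sum over the tumors carrying
    the gene instead of pooling it.
    """
    if driver_genes is None:
        driver_genes = load_driver_genes()
    freq: dict[str, int] = {}
    for genes in tumors.values():
        for g in genes & set(driver_genes):
            freq[g] = freq.get(g, 0) + 1
    if gene not in freq:
        raise ValueError(f"gene {gene!r} absent from all tumors")
    inner_terms = []
    for genes in tumors.values():
        if gene not in genes:
            continue
        inner_terms.append(
            sum(1.0 / freq[d] for d in genes & set(driver_genes) if d != gene)
        )
    if mode == "pooled":
        inner = sum(inner_terms)
    elif mode == "per_tumor":
        inner = float(np.mean(inner_terms))
    else:
        raise ValueError("mode must be 'pooled' or 'per_tumor'")
    return inner / freq[gene]


def driver_table(
    tumors: Mapping[str, set],
    driver_genes: frozenset[str] | set[str] | None = None,
    mode: str = "pooled",
) -> list[DriverScore]:
    """Occurrence and dominant score for every driver seen in the cohort."""
    if driver_genes is None:
        driver_genes = load_driver_genes()
    n = len(tumors)
    seen: dict[str, int] = {}
    for genes in tumors.values():
        for g in genes & set(driver_genes):
            seen[g] = seen.get(g, 0) + 1
    return [
        DriverScore(
            gene=g,
            frequency=f,
            occurrence=occurrence(f, n),
            dominant_score=dominant_score(g, tumors, driver_genes, mode=mode),
        )
        for g, f in sorted(seen.items())
    ]
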