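"""Cancer cell fraction estimation, mutation clustering and SNV ITH.

A mutation observed at variant allele frequency ``v`` in a region with
tumor purity ``p``, local tumor copy number ``q`` and normal copy number
``q_n`` has mutation copy number

    m = v * (p*q + (1-p)*q_n) / p

The multiplicity (number of mutated copies per tumor cell) is the
rounded mutation copy number clamped to [1, major_cn], and the cancer
cell fraction is CCF = m / multiplicity, capped at ``CCF_CAP`` (raw
values above 1 arise from sampling noise and FFPE artifacts).

Mutations are clustered across regions with a binomial mixture over
per-region cluster prevalences, fitted by EM with BIC model selection —
a deterministic stand-in for PyClone-VI that preserves the two outputs
this pipeline consumes: the cluster count and the clonal/subclonal
partition. The cluster whose mean prevalence across regions is maximal
is the clonal cluster; SNV ITH is the subclonal fraction of the
patient-level mutation union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("mrith")

__all__ = [
    "CCF_CAP",
    "CcfEstimate",
    "ClusterSolution",
    "mutation_copy_number",
    "estimate_ccf",
    "BinomialMixture",
    "cluster_ccf",
    "assign_clonality",
    "snv_ith",
    "tmb",
    "tmb_per_cluster",
]

#: Cap applied to CCF estimates (noise can push raw CCF above 1).
CCF_CAP = 1.5


@dataclass(frozen=True)
class CcfEstimate:
    """Per (mutation, region) clonality estimate."""

    key: tuple  # (chrom, pos, ref, alt)
    region_id: str
    mut_cn: float
    multiplicity: int
    ccf: float
    capped: bool
    cluster_id: int = -1
    mean_cluster_prevalence: float = float("nan")
    clonal: bool = False


@dataclass(frozen=True)
class ClusterSolution:
    """A fitted mutation clustering across regions."""

    n_clusters: int
    prevalences: np.ndarray  # (k, n_regions) per-cluster per-region prevalence
    assignments: np.ndarray  # (n_mutations,) cluster index
    weights: np.ndarray  # (k,) mixture weights
    log_likelihood: float
    bic: float

    @property
    def mean_prevalence(self) -> np.ndarray:
        """Mean prevalence of each cluster across regions."""
        return self.prevalences.mean(axis=1)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)


def mutation_copy_number(
    vaf: float, purity: float, tumor_cn: float, normal_cn: float = 2.0
):
    """Mutation copy number from VAF corrected by purity and copy number."""
    vaf = np.asarray(vaf, dtype=float)
    if np.any(np.asarray(purity) <= 0) or np.any(np.asarray(purity) > 1):
        raise ValueError("purity must be in (0, 1]")
    if np.any(np.asarray(tumor_cn) < 0):
        raise ValueError("tumor_cn must be >= 0")
    out = vaf * (purity * tumor_cn + (1.0 - purity) * normal_cn) / purity
    return float(out) if out.ndim == 0 else out


def estimate_ccf(
    mut_cn: float, major_cn: int, cap: float = CCF_CAP
) -> tuple[int, float, bool]:
    """Multiplicity and CCF from a mutation copy number.

    multiplicity = clamp(round(mut_cn), 1, max(major_cn, 1));
    CCF = mut_cn / multiplicity, capped at ``cap`` (flag set when the
    cap engages).
    """
    multiplicity = int(np.clip(round(mut_cn), 1, max(int(major_cn), 1)))
    raw = mut_cn / multiplicity
    capped = raw > cap
    return multiplicity, min(raw, cap), capped


# ---------------------------------------------------------------------------
# Binomial mixture EM (PyClone-VI stand-in)
# ---------------------------------------------------------------------------


class BinomialMixture:
    """Binomial mixture over per-region cluster prevalences.

    Model: mutation i in cluster k has, in region r,
    ``alt[i, r] ~ Binomial(depth[i, r], factor[i, r] * phi[k, r])``
    where ``factor`` converts a cluster prevalence phi into an expected
    VAF (``multiplicity * purity / (purity*tumor_cn + (1-purity)*2)``).
    Entries with depth 0 are treated as unobserved. Fitted by EM with
    k-means++-style seeded initialization and ``n_restarts`` restarts;
    the number of clusters is selected by BIC over ``k = 1..k_max``
    unless ``n_clusters`` is fixed.

    Parameters
    ----------
    n_clusters : int or None
        Fixed number of clusters; when None, selected by BIC.
    k_max : int
        Largest number of clusters tried during BIC selection.
    n_restarts, max_iter, tol : EM controls.
    merge_tol : float
        Post-selection consolidation: clusters whose prevalence vectors
        differ by less than this (max over regions) are merged. Mixture
        likelihoods overfit unimodal populations near the prevalence
        boundary; consolidation of indistinguishable clusters is the
        standard remedy in CCF clustering.
    random_state : int or numpy Generator; makes fits deterministic.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int = 8,
        n_restarts: int = 4,
        max_iter: int = 300,
        tol: float = 1e-7,
        merge_tol: float = 0.06,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.merge_tol = merge_tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "k_max": self.k_max,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "merge_tol": self.merge_tol,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "BinomialMixture":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _validate(alt, depth, factor):
        alt = np.asarray(alt, dtype=float)
        depth = np.asarray(depth, dtype=float)
        if alt.ndim != 2 or alt.shape != depth.shape:
            raise ValueError("alt and depth must be 2-D arrays of equal shape")
        if factor is None:
            factor = np.full_like(alt, 0.5)
        factor = np.asarray(factor, dtype=float)
        if factor.shape != alt.shape:
            raise ValueError("factor must match alt shape")
        if np.any(alt > depth):
            raise ValueError("alt > depth")
        return alt, depth, np.clip(factor, 1e-9, 1.0 - 1e-9)

    @staticmethod
    def _loglik_matrix(alt, depth, factor, phi):
        """(n, k) per-mutation per-cluster binomial log-likelihood."""
        # p[i, k, r] = factor[i, r] * phi[k, r]
        p = np.clip(factor[:, None, :] * phi[None, :, :], 1e-9, 1.0 - 1e-9)
        ll = alt[:, None, :] * np.log(p) + (depth - alt)[:, None, :] * np.log1p(-p)
        return ll.sum(axis=2)

    @staticmethod
    def _mstep_phi(alt, depth, factor, resp):
        """Per-cluster per-region prevalence MLE by bisection.

        Maximizes sum_i resp_ik * [a log(c phi) + (d - a) log(1 - c phi)]
        for each (k, r); the derivative is strictly decreasing in phi, so
        bisection on it is exact.
        """
        n, k = resp.shape
        _, nr = alt.shape
        phi = np.zeros((k, nr))
        for r in range(nr):
            a = alt[:, r]
            d = depth[:, r]
            c = factor[:, r]
            for j in range(k):
                w = resp[:, j]
                sa = float(w @ a)
                if sa <= 1e-12:
                    phi[j, r] = 0.0
                    continue
                wb = w * (d - a) * c

                def deriv(x):
                    return sa / x - np.sum(wb / (1.0 - c * x))

                hi = 1.0
                if deriv(hi - 1e-9) >= 0:
                    phi[j, r] = hi
                    continue
                lo = 1e-9
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if deriv(mid) > 0:
                        lo = mid
                    else:
                        hi = mid
                phi[j, r] = 0.5 * (lo + hi)
        return phi

    def _fit_k(self, alt, depth, factor, k, rng):
        n, nr = alt.shape
        ccf_hat = np.zeros((n, nr))
        obs = depth > 0
        ccf_hat[obs] = np.clip(
            alt[obs] / (depth[obs] * factor[obs]), 0.0, CCF_CAP
        )
        inits = []
        if k <= n:
            # k-means centers over the naive CCF rows: a strong, cheap init
            import warnings

            from sklearn.cluster import KMeans
            from sklearn.exceptions import ConvergenceWarning

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(
                    n_clusters=k,
                    n_init=10,
                    random_state=int(rng.integers(2**31 - 1)),
                ).fit(ccf_hat)
            inits.append(km.cluster_centers_)
        for _ in range(self.n_restarts):
            # k-means++-style spread of initial centers over ccf rows
            centers = [ccf_hat[rng.integers(n)]]
            while len(centers) < k:
                d2 = np.min(
                    [((ccf_hat - c) ** 2).sum(axis=1) for c in centers], axis=0
                )
                tot = d2.sum()
                if tot <= 0:
                    centers.append(ccf_hat[rng.integers(n)])
                else:
                    centers.append(ccf_hat[rng.choice(n, p=d2 / tot)])
            inits.append(np.array(centers))
        best = None
        for centers in inits:
            phi = np.clip(centers, 1e-4, 1.0)
            pi = np.full(k, 1.0 / k)
            prev_ll = -np.inf
            for _ in range(self.max_iter):
                ll_mat = self._loglik_matrix(alt, depth, factor, phi)
                logw = ll_mat + np.log(pi + 1e-300)
                m = logw.max(axis=1, keepdims=True)
                lse = m[:, 0] + np.log(np.exp(logw - m).sum(axis=1))
                ll = float(lse.sum())
                resp = np.exp(logw - lse[:, None])
                pi = resp.mean(axis=0)
                phi = self._mstep_phi(alt, depth, factor, resp)
                if abs(ll - prev_ll) < self.tol * max(1.0, abs(ll)):
                    prev_ll = ll
                    break
                prev_ll = ll
            if best is None or prev_ll > best[0]:
                best = (prev_ll, phi, pi, resp)
        ll, phi, pi, resp = best
        return ll, phi, pi, resp.argmax(axis=1)

    # -- public API ---------------------------------------------------------

    def fit(self, alt, depth, factor=None) -> "BinomialMixture":
        """Fit on (n_mutations, n_regions) alt/depth count matrices."""
        alt, depth, factor = self._validate(alt, depth, factor)
        n, nr = alt.shape
        if n < 1:
            raise ValueError("need at least one mutation")
        rng = np.random.default_rng(self.random_state)
        ks = (
            [self.n_clusters]
            if self.n_clusters is not None
            else list(range(1, min(self.k_max, n) + 1))
        )
        if ks[0] < 1:
            raise ValueError("number of clusters must be >= 1")
        best = None
        for k in ks:
            ll, phi, pi, labels = self._fit_k(alt, depth, factor, k, rng)
            n_params = k * nr + (k - 1)
            bic = -2.0 * ll + n_params * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, ll, phi, pi, labels)
        bic, ll, phi, pi, labels = best
        # drop clusters that ended up empty and relabel compactly
        used = np.unique(labels)
        remap = {old: new for new, old in enumerate(used)}
        labels = np.array([remap[x] for x in labels])
        phi = phi[used]
        # consolidation: merge prevalence-indistinguishable clusters
        while phi.shape[0] > 1:
            kk = phi.shape[0]
            pair = None
            best_d = self.merge_tol
            for i in range(kk):
                for j in range(i + 1, kk):
                    d = float(np.max(np.abs(phi[i] - phi[j])))
                    if d < best_d:
                        best_d = d
                        pair = (i, j)
            if pair is None:
                break
            i, j = pair
            labels[labels == j] = i
            labels[labels > j] -= 1
            resp = np.zeros((n, kk - 1))
            resp[np.arange(n), labels] = 1.0
            phi = self._mstep_phi(alt, depth, factor, resp)
        sizes = np.bincount(labels, minlength=phi.shape[0]).astype(float)
        self.labels_ = labels
        self.prevalences_ = phi
        self.weights_ = sizes / sizes.sum()
        self.n_clusters_ = phi.shape[0]
        self.log_likelihood_ = ll
        self.bic_ = bic
        return self

    def predict(self, alt, depth, factor=None) -> np.ndarray:
        """Assign mutations to the fitted clusters."""
        alt, depth, factor = self._validate(alt, depth, factor)
        ll = self._loglik_matrix(alt, depth, factor, self.prevalences_)
        return (ll + np.log(self.weights_ + 1e-300)).argmax(axis=1)

    def solution(self) -> ClusterSolution:
        return ClusterSolution(
            n_clusters=self.n_clusters_,
            prevalences=self.prevalences_,
            assignments=self.labels_,
            weights=self.weights_,
            log_likelihood=self.log_likelihood_,
            bic=self.bic_,
        )


def cluster_ccf(
    ccf: np.ndarray,
    k_max: int = 8,
    seed: int | None = 0,
    pseudo_depth: int = 250,
) -> ClusterSolution:
    """Cluster a (mutations x regions) CCF matrix.

    CCF values are converted to pseudo-binomial observations at
    ``pseudo_depth`` (expected VAF = CCF / 2, the pure-diploid analog);
    missing entries (NaN) are treated as prevalence-zero observations.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ccf = np.asarray(ccf, dtype=float)
    if ccf.ndim == 1:
        ccf = ccf[:, None]
    filled = np.nan_to_num(ccf, nan=0.0)
    vaf = np.clip(filled / 2.0, 0.0, 1.0)
    depth = np.full(ccf.shape, float(pseudo_depth))
    alt = np.round(vaf * depth)
    est = BinomialMixture(k_max=k_max, random_state=seed).fit(
        alt, depth, np.full(ccf.shape, 0.5)
    )
    return est.solution()


def assign_clonality(solution: ClusterSolution) -> np.ndarray:
    """Per-mutation clonal flag from a fitted clustering.

    The cluster of maximum mean-across-regions prevalence is clonal;
    ties break toward the larger cluster, then the lower cluster id.
    """
    mean_prev = solution.mean_prevalence
    sizes = solution.cluster_sizes
    order = sorted(
        range(solution.n_clusters),
        key=lambda j: (-round(mean_prev[j], 12), -sizes[j], j),
    )
    clonal_cluster = order[0]
    return solution.assignments == clonal_cluster


def snv_ith(clonal_flags) -> float | None:
    """Subclonal fraction: (# subclonal mutations) / (# mutations).

    Returns None (missing) for an empty input.
    """
    flags = np.asarray(clonal_flags, dtype=bool)
    if flags.size == 0:
        return None
    return float((~flags).sum() / flags.size)


def tmb(n_nonsilent_union: int, coding_mb: float = 38.0) -> float:
    """Multi-region TMB: union of nonsilent mutations per callable Mb."""
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    return n_nonsilent_union / coding_mb


def tmb_per_cluster(tmb_value: float, n_clusters: int) -> float:
    """Average TMB per mutation cluster."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    return tmb_value / n_clusters
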