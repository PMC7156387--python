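"""Cluster mutations by their CCF profile across regions.

A finite mixture of per-region binomial read-count distributions: each
cluster k has a CCF centre c[k, r] per region r, and a variant's alt reads
in region r are Binomial(depth, c[k, r] * f[i, r]) where f maps CCF to
expected VAF (purity / copy-number / multiplicity factor). Fitting is by
expectation–maximisation with k-means and random restarts; the number of
clusters is chosen by the Bayesian information criterion. Mutations absent
in a region enter with their observed zero counts at the observed depth —
absence is informative for separating clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

log = logging.getLogger(__name__)

_EPS = 1e-9
CCF_CEIL = 1.2  # cluster centres are allowed modest super-clonal slack


@dataclass
class MutationCluster:
    cluster_id: int
    variant_ids: tuple[str, ...]
    mean_ccf: np.ndarray  # per region, in [0, CCF_CEIL]
    size: int


@dataclass
class ClusterFit:
    clusters: list[MutationCluster]
    assignments: np.ndarray  # cluster_id per variant
    centres: np.ndarray      # k x R
    weights: np.ndarray
    log_likelihood: float
    bic: float
    k: int
    region_ids: tuple[str, ...]


def _binom_loglik(alt, depth, p):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return (
        special.gammaln(depth + 1)
        - special.gammaln(alt + 1)
        - special.gammaln(depth - alt + 1)
        + alt * np.log(p)
        + (depth - alt) * np.log1p(-p)
    )


def _mstep_centre(alt, depth, f, resp):
    """Weighted binomial MLE of a cluster's CCF in one region.

    Maximises sum_i w_i [a_i log(c f_i) + (d_i - a_i) log(1 - c f_i)] over
    c in [0, CCF_CEIL] by bisection on the monotone score function; closed
    form when f is constant across variants.
    """
    w = resp
    wa = float(np.dot(w, alt))
    if wa <= 0:
        return 0.0
    fmax = float(np.max(f))
    hi = min(CCF_CEIL, (1.0 - 1e-6) / fmax)
    if np.ptp(f) < 1e-12:  # constant factor: c = sum(w a) / (f sum(w d))
        c = wa / (f.flat[0] * float(np.dot(w, depth)))
        return float(np.clip(c, 0.0, hi))

    def score(c):
        q = np.clip(c * f, _EPS, 1.0 - _EPS)
        return float(np.dot(w, alt / c - f * (depth - alt) / (1.0 - q)))

    lo = 1e-8
    if score(hi) >= 0.0:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if score(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _em(alt, depth, f, centres0, seed, max_iter=200, tol=1e-6):
    n, R = alt.shape
    k = centres0.shape[0]
    centres = centres0.copy()
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step
        logp = np.empty((n, k))
        for j in range(k):
            logp[:, j] = _binom_loglik(alt, depth, centres[j] * f).sum(axis=1)
        logp += np.log(np.clip(weights, _EPS, None))
        norm = special.logsumexp(logp, axis=1)
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        # M-step
        weights = resp.mean(axis=0)
        for j in range(k):
            if resp[:, j].sum() < _EPS:
                continue
            for r in range(R):
                centres[j, r] = _mstep_centre(alt[:, r], depth[:, r], f[:, r], resp[:, j])
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return centres, weights, prev_ll, resp


def _init_centres(ccf_naive, k, rng, method):
    n = ccf_naive.shape[0]
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        km.fit(ccf_naive)
        return np.clip(km.cluster_centers_, 0.0, CCF_CEIL)
    idx = rng.choice(n, size=k, replace=False)
    return np.clip(ccf_naive[idx] + rng.normal(0, 0.02, size=(k, ccf_naive.shape[1])),
                   0.0, CCF_CEIL)


def cluster_mutations(
    alt: np.ndarray,
    depth: np.ndarray,
    vaf_factor: np.ndarray,
    variant_ids: list[str] | None = None,
    region_ids: tuple[str, ...] | None = None,
    k_range: tuple[int, int] = (1, 10),
    min_cluster_size: int = 3,
    seed: int = 0,
    n_restarts: int = 4,
) -> ClusterFit:
    """Fit the binomial mixture over a k range and select k by BIC.

    Parameters
    ----------
    alt, depth
        Integer matrices, variants x regions.
    vaf_factor
        Matrix of CCF→VAF multipliers f[i, r] (purity, copy number,
        multiplicity); expected VAF is ``ccf * f``.
    k_range
        Inclusive range of cluster numbers scored by BIC.
    min_cluster_size
        Clusters smaller than this are merged into the nearest centre.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    f = np.asarray(vaf_factor, dtype=float)
    n, R = alt.shape
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(n)]
    if region_ids is None:
        region_ids = tuple(f"r{j}" for j in range(R))
    if n < 2 * min_cluster_size:
        raise ValueError(f"need at least {2 * min_cluster_size} variants, got {n}")

    with np.errstate(invalid="ignore", divide="ignore"):
        ccf_naive = np.where(depth > 0, alt / np.maximum(depth, 1.0) / f, 0.0)
    ccf_naive = np.clip(ccf_naive, 0.0, CCF_CEIL)
    if np.allclose(ccf_naive, ccf_naive[0], atol=1e-12):
        log.warning("all variants identical; returning a single cluster")
        k_range = (1, 1)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(k_range[0], min(k_range[1], n) + 1):
        for restart in range(n_restarts):
            method = "kmeans" if restart < 2 else "random"
            if k == 1:
                centres0 = ccf_naive.mean(axis=0, keepdims=True)
            else:
                centres0 = _init_centres(ccf_naive, k, rng, method)
            centres, weights, ll, resp = _em(alt, depth, f, centres0, seed)
            n_params = k * R + (k - 1)
            bic = -2.0 * ll + n_params * np.log(n)
            if best is None or bic < best[0] - 1e-9:
                best = (bic, k, centres, weights, ll, resp)
            if k == 1:
                break

    bic, k, centres, weights, ll, resp = best
    hard = resp.argmax(axis=1)

    # merge undersized clusters into the nearest surviving centre
    counts = np.bincount(hard, minlength=k)
    keep = np.where(counts >= min_cluster_size)[0]
    if len(keep) == 0:
        keep = np.array([counts.argmax()])
    if len(keep) < k:
        kept_centres = centres[keep]
        for i in range(len(hard)):
            if hard[i] not in keep:
                d = np.linalg.norm(kept_centres - ccf_naive[i], axis=1)
                hard[i] = keep[d.argmin()]
    # relabel surviving clusters 1..k' by descending total CCF (truncal first)
    surviving = sorted(set(hard.tolist()),
                       key=lambda j: (-float(centres[j].sum()), j))
    relabel = {old: new + 1 for new, old in enumerate(surviving)}
    assignments = np.array([relabel[j] for j in hard])

    clusters = []
    for old in surviving:
        cid = relabel[old]
        members = np.where(assignments == cid)[0]
        # depth-weighted mean of member per-variant CCF estimates: stays in
        # the convex hull of member CCFs per region
        wgt = depth[members]
        mean_ccf = (ccf_naive[members] * wgt).sum(axis=0) / np.maximum(wgt.sum(axis=0), _EPS)
        clusters.append(
            MutationCluster(
                cluster_id=cid,
                variant_ids=tuple(variant_ids[i] for i in members),
                mean_ccf=np.clip(mean_ccf, 0.0, CCF_CEIL),
                size=len(members),
            )
        )
    return ClusterFit(
        clusters=clusters,
        assignments=assignments,
        centres=np.array([c.mean_ccf for c in clusters]),
        weights=np.array([c.size / n for c in clusters]),
        log_likelihood=ll,
        bic=bic,
        k=len(clusters),
        region_ids=tuple(region_ids),
    )


def assign_cluster(
    alt: np.ndarray,
    depth: np.ndarray,
    vaf_factor: np.ndarray,
    fit: ClusterFit,
) -> int:
    """Maximum-likelihood cluster for one variant (row vectors over regions).

    Ties break deterministically to the lowest cluster_id.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    f = np.asarray(vaf_factor, dtype=float)
    best_id, best_ll = None, -np.inf
    for cl in sorted(fit.clusters, key=lambda c: c.cluster_id):
        ll = float(_binom_loglik(alt, depth, cl.mean_ccf * f).sum())
        if ll > best_ll + 1e-12:
            best_id, best_ll = cl.cluster_id, ll
    return best_id


def cluster_table(fit: ClusterFit) -> "pd.DataFrame":
    """Cluster summary: cluster_id, size, one mean-CCF column per region."""
    import pandas as pd

    rows = []
    for cl in fit.clusters:
        row = {"cluster_id": cl.cluster_id, "size": cl.size}
        row.update({f"ccf_{rid}": cl.mean_ccf[j] for j, rid in enumerate(fit.region_ids)})
        rows.append(row)
    return pd.DataFrame(rows)
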