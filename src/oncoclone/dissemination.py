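"""Low-frequency presence testing of metastasis-specific mutations.

If a metastasis-private mutation truly arose after dissemination, the
matched primary regions should carry it at no more than the sequencing
background. For each (metastasis, primary) pair, a one-sided
likelihood-ratio test compares H0 — both samples share one beta-binomial
success rate — against H1 — the metastasis rate exceeds the primary rate.
Overdispersion is estimated from putatively error-only control sites by the
method of moments and held fixed; with dispersion 0 the model reduces to a
binomial. The null distribution of the LRT statistic for the one-sided
boundary hypothesis is the half-mixture 0.5*chi2(1) + 0.5*delta(0).

A variant significant against EVERY primary region supports a
post-dissemination (late) origin; anything less leaves an early origin
possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class PresenceTest:
    variant_id: str
    test_region: str
    control_region: str
    p_value: float
    dispersion: float
    significant: bool


def fit_dispersion(control_counts: Sequence[tuple[int, int]]) -> float:
    """Method-of-moments beta-binomial overdispersion from error-only sites.

    ``control_counts`` are (alt, depth) pairs at sites believed to carry
    only sequencing error. Uses the dispersion-score moment estimator
    rho = (X2 - n) / sum(depth - 1) with X2 the binomial chi-squared
    against the pooled rate; floored at 0 (binomial).
    """
    counts = [(int(a), int(d)) for a, d in control_counts if d > 0]
    if len(counts) < 20:
        raise ValueError(f"need >= 20 control sites, got {len(counts)}")
    alt = np.array([a for a, _ in counts], dtype=float)
    depth = np.array([d for _, d in counts], dtype=float)
    pbar = alt.sum() / depth.sum()
    if pbar <= 0.0 or pbar >= 1.0:
        return 0.0
    x2 = float(np.sum((alt - depth * pbar) ** 2 / (depth * pbar * (1.0 - pbar))))
    denom = float(np.sum(depth - 1.0))
    rho = (x2 - len(counts)) / denom if denom > 0 else 0.0
    return max(rho, 0.0)


def _bb_loglik(alt: float, depth: float, mu: float, rho: float) -> float:
    mu = min(max(mu, _EPS), 1.0 - _EPS)
    if rho <= _EPS:
        return float(
            alt * np.log(mu) + (depth - alt) * np.log1p(-mu)
        )  # binomial kernel (combinatorial term cancels in the LRT)
    s = (1.0 - rho) / rho
    a, b = mu * s, (1.0 - mu) * s
    return float(
        special.betaln(alt + a, depth - alt + b) - special.betaln(a, b)
    )


def _mle_mu(alts: np.ndarray, depths: np.ndarray, rho: float) -> float:
    if rho <= _EPS:
        return float(alts.sum() / depths.sum())
    neg = lambda mu: -sum(_bb_loglik(a, d, mu, rho) for a, d in zip(alts, depths))
    res = optimize.minimize_scalar(neg, bounds=(_EPS, 1.0 - _EPS), method="bounded")
    return float(res.x)


def test_presence(
    met_obs: tuple[int, int],
    primary_obs: tuple[int, int],
    dispersion: float = 0.0,
    alpha: float = 0.05,
    variant_id: str = "",
    test_region: str = "",
    control_region: str = "",
) -> PresenceTest:
    """One-sided beta-binomial LRT of met rate > primary rate.

    ``met_obs`` and ``primary_obs`` are (alt, depth) pairs. The p-value is
    0.5 * P(chi2_1 > LR) when the unconstrained fit puts the metastasis
    rate above the primary rate, and 1 otherwise (the constrained and
    unconstrained fits coincide, LR = 0).
    """
    (ma, md), (pa, pd_) = met_obs, primary_obs
    if md <= 0 or pd_ <= 0:
        raise ValueError("zero-depth observation: presence test undefined")
    if ma > md or pa > pd_:
        raise ValueError("alt count exceeds depth")
    mu_met = _mle_mu(np.array([ma], float), np.array([md], float), dispersion)
    mu_pri = _mle_mu(np.array([pa], float), np.array([pd_], float), dispersion)
    if mu_met <= mu_pri:
        p = 1.0
    else:
        mu0 = _mle_mu(np.array([ma, pa], float), np.array([md, pd_], float), dispersion)
        l0 = _bb_loglik(ma, md, mu0, dispersion) + _bb_loglik(pa, pd_, mu0, dispersion)
        l1 = _bb_loglik(ma, md, mu_met, dispersion) + _bb_loglik(pa, pd_, mu_pri, dispersion)
        lr = max(0.0, 2.0 * (l1 - l0))
        p = 1.0 if lr <= 0.0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return PresenceTest(
        variant_id=variant_id,
        test_region=test_region,
        control_region=control_region,
        p_value=p,
        dispersion=dispersion,
        significant=p < alpha,
    )


def classify_timing(tests: Sequence[PresenceTest], alpha: float = 0.05) -> str:
    """Aggregate one variant's per-primary-region tests into a verdict.

    ``late_supported`` requires significance against every primary region;
    otherwise ``early_possible``. Raw p-values are used, matching the
    source analysis; for family-wise control across a cohort, adjust with
    :func:`adjust_bh` first.
    """
    if not tests:
        raise ValueError("no presence tests supplied")
    pvals = np.array([t.p_value for t in tests])
    return "late_supported" if bool((pvals < alpha).all()) else "early_possible"


def adjust_bh(tests: Sequence[PresenceTest], alpha: float = 0.05) -> list[PresenceTest]:
    """Benjamini–Hochberg adjustment across a family of presence tests.

    Returns new tests carrying step-up adjusted p-values (and
    significance at ``alpha``); apply over the whole cohort before
    ``classify_timing`` when correction is wanted.
    """
    from dataclasses import replace

    pvals = np.array([t.p_value for t in tests])
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, pvals[i] * n / (rank_idx + 1))
        adj[i] = prev
    return [
        replace(t, p_value=float(a), significant=bool(a < alpha))
        for t, a in zip(tests, adj)
    ]


def presence_test_table(tests: Sequence[PresenceTest], verdicts: dict[str, str]):
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                variant_id=t.variant_id,
                met_region=t.test_region,
                primary_region=t.control_region,
                p_value=t.p_value,
                verdict=verdicts.get(t.variant_id, ""),
            )
            for t in tests
        ]
    )
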