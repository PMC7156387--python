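"""Cancer cell fractions, low-VAF presence rescue, clonality and sharing.

The CCF of a mutation in a region links its variant allele frequency (VAF)
to tumour purity, local total copy number and mutation multiplicity m:

    CCF = VAF * (purity * CN_total + (1 - purity) * 2) / (purity * m)

Normal cells are assumed diploid at every somatic site (autosomes; the
cohort modelled is female, so no X-ploidy special-casing). Presence calls
below the caller threshold are rescued when the VAF reaches 1% with at
least two supporting reads, mirroring the manual cross-region review step
used in multi-region studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import Region, RegionObservation, VariantCall

log = logging.getLogger(__name__)

SHARING_CATEGORIES = ("shared", "primary_private", "metastasis_private")


@dataclass
class ClonalityConfig:
    """Thresholds for presence rescue and clonality assignment.

    The source study defines clonal/subclonal verbally; these cut-offs are
    the package's explicit operationalisation and are all adjustable.
    """

    clonal_min_ccf: float = 0.8      # per-region CCF floor for "clonal"
    clonal_min_ci_upper: float = 0.9  # per-region CI-upper floor for "clonal"
    rescue_min_vaf: float = 0.01      # >=1% VAF rescues an uncalled region
    rescue_min_alt: int = 2           # guard against single-read artefacts
    call_min_vaf: float = 0.05        # primary caller emulation: VAF floor
    call_min_alt: int = 3             # primary caller emulation: alt-read floor
    ccf_cap: float = 1.5
    contralateral_as_met: bool = True


@dataclass(frozen=True)
class CCFEntry:
    variant_id: str
    region_id: str
    multiplicity: int
    ccf: float
    ci95: tuple[float, float]
    present: bool

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        lo, hi = self.ci95
        if not math.isnan(self.ccf) and not (lo <= self.ccf + 1e-12 and self.ccf <= hi + 1e-12):
            raise ValueError(f"ccf {self.ccf} outside its CI {self.ci95}")


@dataclass(frozen=True)
class ClonalityCall:
    variant_id: str
    scope: str  # primary | metastasis | overall
    status: str  # clonal | subclonal | absent


@dataclass(frozen=True)
class SharingCall:
    variant_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in SHARING_CATEGORIES:
            raise ValueError(f"unknown sharing category {self.category!r}")


def vaf_to_ccf_factor(purity: float, cn_total: int, multiplicity: int) -> float:
    """Multiplier f with CCF = VAF / f; f = purity*m / (purity*CN + (1-purity)*2)."""
    return purity * multiplicity / (purity * cn_total + (1.0 - purity) * 2.0)


def estimate_multiplicity(vaf: float, purity: float, cn_total: int, cn_major: int) -> int:
    """Integer mutation multiplicity from the VAF.

    m = round(vaf * (purity*CN + (1-purity)*2) / purity), clamped to
    [1, max(cn_major, 1)]. A homozygous-deletion conflict (CN_total = 0 with
    observed reads) returns m = 1 with a warning.
    """
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf {vaf} outside [0,1]")
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0,1]")
    if cn_total == 0:
        log.warning("mutation in homozygous deletion (cn_total=0); using m=1")
        return 1
    raw = round(vaf * (purity * cn_total + (1.0 - purity) * 2.0) / purity)
    return int(min(max(raw, 1), max(cn_major, 1)))


def compute_ccf(
    obs: RegionObservation,
    purity: float,
    cn_total: int,
    multiplicity: int,
    cap: float = 1.5,
) -> CCFEntry:
    """CCF point estimate with a Clopper–Pearson 95% interval.

    The exact binomial interval on alt/depth is transformed by the same
    linear VAF→CCF map as the point estimate. Estimates above ``cap``
    (copy-number/purity misspecification) are capped with a warning. A
    zero-depth observation yields an undefined (NaN) entry flagged absent.
    """
    if obs.depth == 0:
        return CCFEntry(obs.variant_id, obs.region_id, multiplicity,
                        float("nan"), (float("nan"), float("nan")), present=False)
    f = vaf_to_ccf_factor(purity, cn_total, multiplicity)
    a, d = obs.alt_count, obs.depth
    vaf_lo = 0.0 if a == 0 else stats.beta.ppf(0.025, a, d - a + 1)
    vaf_hi = 1.0 if a == d else stats.beta.ppf(0.975, a + 1, d - a)
    ccf = obs.vaf / f
    lo, hi = vaf_lo / f, vaf_hi / f
    if ccf > cap:
        log.warning("%s/%s: CCF %.3f capped at %.2f", obs.variant_id, obs.region_id, ccf, cap)
        ccf = cap
        hi = max(hi, cap)
        lo = min(lo, cap)
    return CCFEntry(obs.variant_id, obs.region_id, multiplicity, ccf,
                    (lo, min(hi, cap + 1.0)), present=True)


def rescue_low_vaf(
    observations: Sequence[RegionObservation],
    called_in: set[str],
    config: ClonalityConfig | None = None,
) -> dict[str, bool]:
    """Per-region presence flags for one variant after low-VAF rescue.

    A region is present if the caller reported the variant there, or if the
    VAF reaches ``rescue_min_vaf`` with at least ``rescue_min_alt``
    supporting reads (cross-region retrieval of missed calls).
    """
    cfg = config or ClonalityConfig()
    if not called_in:
        raise ValueError("variant must be called in at least one region")
    flags = {}
    for obs in observations:
        rescued = (
            obs.depth > 0
            and obs.vaf >= cfg.rescue_min_vaf
            and obs.alt_count >= cfg.rescue_min_alt
        )
        flags[obs.region_id] = obs.region_id in called_in or rescued
    return flags


def assign_clonality(
    entries: Sequence[CCFEntry],
    scope: str,
    config: ClonalityConfig | None = None,
) -> ClonalityCall:
    """Clonal/subclonal/absent status of one variant within a region scope.

    Clonal means present in every region of the scope with CCF >=
    ``clonal_min_ccf`` and CI-upper >= ``clonal_min_ci_upper`` everywhere;
    present anywhere but not clonal is subclonal; present nowhere is absent.
    """
    cfg = config or ClonalityConfig()
    if not entries:
        raise ValueError("scope must contain at least one region")
    vid = entries[0].variant_id
    if not any(e.present for e in entries):
        return ClonalityCall(vid, scope, "absent")
    clonal = all(
        e.present and e.ccf >= cfg.clonal_min_ccf and e.ci95[1] >= cfg.clonal_min_ci_upper
        for e in entries
    )
    return ClonalityCall(vid, scope, "clonal" if clonal else "subclonal")


def categorise_sharing(
    presence: Mapping[str, bool],
    regions: Sequence[Region],
    config: ClonalityConfig | None = None,
) -> SharingCall:
    """Shared / primary-private / metastasis-private category of one event."""
    cfg = config or ClonalityConfig()
    by_id = {r.region_id: r for r in regions}
    in_primary = any(
        present and not by_id[rid].is_metastasis(cfg.contralateral_as_met)
        for rid, present in presence.items()
    )
    in_met = any(
        present and by_id[rid].is_metastasis(cfg.contralateral_as_met)
        for rid, present in presence.items()
    )
    vid = next(iter(presence.keys()), "")
    if in_primary and in_met:
        return SharingCall(vid, "shared")
    if in_primary:
        return SharingCall(vid, "primary_private")
    if in_met:
        return SharingCall(vid, "metastasis_private")
    raise ValueError("event present in no region (should not occur after rescue)")


def ccf_table(
    variants: Sequence[VariantCall],
    observations: Sequence[RegionObservation],
    regions: Sequence[Region],
    segments: Sequence = (),
    config: ClonalityConfig | None = None,
) -> pd.DataFrame:
    """Long-format per-variant-per-region table driving all downstream stages.

    Columns: variant_id, region_id, depth, alt, vaf, cn_total, multiplicity,
    ccf, ci_lo, ci_hi, present, clonality_primary, clonality_metastasis,
    clonality_overall, sharing.
    """
    from .variant_io import lookup_cn

    cfg = config or ClonalityConfig()
    region_by_id = {r.region_id: r for r in regions}
    var_by_id = {v.variant_id: v for v in variants}
    obs_by_var: dict[str, list[RegionObservation]] = {}
    for obs in observations:
        if obs.region_id not in region_by_id:
            raise ValueError(f"observation references unknown region {obs.region_id!r}")
        obs_by_var.setdefault(obs.variant_id, []).append(obs)

    rows = []
    for vid, obs_list in obs_by_var.items():
        v = var_by_id[vid]
        called_in = {
            o.region_id
            for o in obs_list
            if o.depth > 0 and o.vaf >= cfg.call_min_vaf and o.alt_count >= cfg.call_min_alt
        }
        if not called_in:  # keep best-supported region as the anchor call
            called_in = {max(obs_list, key=lambda o: o.alt_count).region_id}
        presence = rescue_low_vaf(obs_list, called_in, cfg)
        entries = {}
        for o in obs_list:
            region = region_by_id[o.region_id]
            major, minor, _ = lookup_cn(segments, o.region_id, v.chrom, v.pos) if segments else (1, 1, "unknown")
            cn_total = major + minor
            vaf = 0.0 if o.depth == 0 else o.vaf
            m = estimate_multiplicity(min(vaf, 1.0), region.purity, cn_total, major)
            entry = compute_ccf(o, region.purity, cn_total, m, cap=cfg.ccf_cap)
            entries[o.region_id] = (o, entry, cn_total)
        scoped = {
            "primary": [e for rid, (_, e, _) in entries.items()
                        if not region_by_id[rid].is_metastasis(cfg.contralateral_as_met)],
            "metastasis": [e for rid, (_, e, _) in entries.items()
                           if region_by_id[rid].is_metastasis(cfg.contralateral_as_met)],
            "overall": [e for (_, e, _) in entries.values()],
        }

        def _masked(e: CCFEntry, rid: str) -> CCFEntry:
            if presence[rid] or not e.present:
                return e
            return CCFEntry(e.variant_id, e.region_id, e.multiplicity, e.ccf, e.ci95, False)

        scoped = {
            scope: [
                _masked(e, e.region_id) for e in ents
            ]
            for scope, ents in scoped.items()
        }
        clonality = {
            scope: (assign_clonality(ents, scope, cfg).status if ents else "absent")
            for scope, ents in scoped.items()
        }
        sharing = categorise_sharing(presence, regions, cfg).category
        for rid, (o, e, cn_total) in entries.items():
            rows.append(
                dict(
                    variant_id=vid,
                    region_id=rid,
                    depth=o.depth,
                    alt=o.alt_count,
                    vaf=o.vaf,
                    cn_total=cn_total,
                    multiplicity=e.multiplicity,
                    ccf=e.ccf,
                    ci_lo=e.ci95[0],
                    ci_hi=e.ci95[1],
                    present=presence[rid],
                    clonality_primary=clonality["primary"],
                    clonality_metastasis=clonality["metastasis"],
                    clonality_overall=clonality["overall"],
                    sharing=sharing,
                )
            )
    return pd.DataFrame(rows)
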