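"""Synthetic multi-region primary/metastasis patients with known truth.

Each simulated patient carries a rooted clone tree with a truncal cluster
(CCF 1 everywhere), a cluster-by-region CCF matrix obeying the pigeonhole
sum rule, mutations assigned to clusters with trinucleotide contexts drawn
from a configurable signature mixture, and per-region read counts drawn
binomially at the expected VAF implied by CCF, purity, copy number and
multiplicity.

Clonal structure is generated to hit a target fraction of mutations in
clusters present in both the primary and metastatic compartment: a
connected subtree containing the root is marked shared; every remaining
subtree is private to one compartment. Within a region, the child clones
of a node jointly occupy a budget of 50–85% of the parent's CCF, split by
a minimum-fraction Dirichlet draw — each subclone steps down appreciably
from its parent (clusters too close in CCF to resolve would never be
reported as distinct), and the split is drawn independently per region so
sibling clones have decorrelated CCF profiles (which is what makes them
resolvable from multi-region data, as in real tumours with spatially
segregated subclones).

What this generator does NOT emulate: subclonal copy-number evolution,
strand- or position-specific sequencing error, caller-specific artefacts,
and mutation hotspots. Recovery results on this generator therefore speak
to the statistical machinery, not to caller robustness on real reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trinuc import CHANNELS, parse_channel
from .variant_io import (
    Region,
    RegionObservation,
    SegmentCN,
    VariantCall,
    write_regions,
    write_segments,
    write_variant_table,
)

_DEFAULT_SIGNATURE_MIX = {"S1": 0.25, "S3": 0.55, "S15": 0.20}
_CHROM_LENGTH = 135_000_000

_CONSEQUENCE_PROBS = {
    "synonymous": 0.25,
    "missense": 0.58,
    "nonsense": 0.08,
    "splice": 0.04,
    "other": 0.05,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated patient.

    Defaults mirror a multi-region exome design: 4–6 regions per patient
    split across both compartments, 2–10 mutation clusters (default 7),
    ~200x coverage, purity spanning 0.2–1.0 and an HGSOC-like signature
    mixture dominated by a flat homologous-recombination-deficiency-like
    process.
    """

    n_primary_regions: int = 3
    n_met_regions: int = 3
    n_clusters: int = 7
    mutations_per_cluster: int = 20
    purity_range: tuple[float, float] = (0.2, 1.0)
    mean_depth: float = 200.0
    sequencing_error: float = 0.001
    shared_fraction_target: float = 0.75
    signature_weights: dict[str, float] | None = None
    indel_fraction: float = 0.05
    cnv_events: tuple = ()  # optional (region_id, chrom, start, end, major, minor, hap)
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > 1 and self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2 for subclonal structure")
        if self.n_primary_regions < 1 or self.n_met_regions < 1:
            raise ValueError("need at least one region per compartment")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.sequencing_error <= 0.01):
            raise ValueError("sequencing_error must be in [0, 0.01]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must sit inside (0, 1]")
        if not (0.0 <= self.shared_fraction_target <= 1.0):
            raise ValueError("shared_fraction_target must be in [0, 1]")
        w = self.mixture()
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("signature_weights must sum to 1")
        if any(x < 0 for x in w.values()):
            raise ValueError("signature_weights must be non-negative")

    def mixture(self) -> dict[str, float]:
        return dict(self.signature_weights or _DEFAULT_SIGNATURE_MIX)


@dataclass
class SimulatedPatient:
    patient_id: str
    config: SimConfig
    regions: list[Region]
    variants: list[VariantCall]
    observations: list[RegionObservation]
    segments: list[SegmentCN]
    truth_parent: dict[int, int]  # child cluster -> parent cluster
    truth_root: int
    truth_ccf: np.ndarray  # clusters x regions, row i = cluster i+1
    cluster_of: dict[str, int]  # variant_id -> truth cluster
    truth_shared_fraction: float

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def truth_tree(self):
        from .phylogeny import CloneTree

        nodes = tuple(range(1, self.truth_ccf.shape[0] + 1))
        return CloneTree(nodes, dict(self.truth_parent), self.truth_root)

    def count_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(alt, depth, vaf_factor) matrices over variants x regions.

        The VAF factor uses the true per-region purity and the diploid
        (or configured CNV) state, i.e. the matrices a perfectly informed
        CCF stage would produce.
        """
        from .ccf import vaf_to_ccf_factor
        from .variant_io import lookup_cn

        vids = [v.variant_id for v in self.variants]
        vidx = {vid: i for i, vid in enumerate(vids)}
        ridx = {rid: j for j, rid in enumerate(self.region_ids)}
        n, R = len(vids), len(self.regions)
        alt = np.zeros((n, R))
        depth = np.zeros((n, R))
        f = np.zeros((n, R))
        purities = {r.region_id: r.purity for r in self.regions}
        var_by_id = {v.variant_id: v for v in self.variants}
        for obs in self.observations:
            i, j = vidx[obs.variant_id], ridx[obs.region_id]
            alt[i, j] = obs.alt_count
            depth[i, j] = obs.depth
            v = var_by_id[obs.variant_id]
            major, minor, _ = lookup_cn(self.segments, obs.region_id, v.chrom, v.pos) \
                if self.config.cnv_events else (1, 1, "unknown")
            f[i, j] = vaf_to_ccf_factor(purities[obs.region_id], major + minor, 1)
        return alt, depth, f


def expected_vaf(ccf: float, purity: float, cn_total: int, multiplicity: int) -> float:
    """Expected VAF of a mutation: ccf*purity*m / (purity*CN + (1-purity)*2)."""
    return ccf * purity * multiplicity / (purity * cn_total + (1.0 - purity) * 2.0)


def simulate_reads(
    ccf: float,
    purity: float,
    cn_total: int,
    multiplicity: int,
    depth: int,
    error: float = 0.0,
    rng: np.random.Generator | int | None = None,
    variant_id: str = "v",
    region_id: str = "r",
) -> RegionObservation:
    """Draw one region observation binomially at the expected VAF.

    Sequencing error is symmetric and context-independent: each read
    reports the alternate allele with probability
    ``vaf*(1-error) + (1-vaf)*error``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if cn_total >= 1 and multiplicity > cn_total:
        raise ValueError("multiplicity cannot exceed total copy number")
    if not (0.0 <= ccf <= 1.0 and 0.0 < purity <= 1.0):
        raise ValueError("ccf in [0,1] and purity in (0,1] required")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = expected_vaf(ccf, purity, cn_total, multiplicity)
    p_eff = p * (1.0 - error) + (1.0 - p) * error
    alt = int(rng.binomial(depth, p_eff))
    return RegionObservation(variant_id, region_id, depth=int(depth), alt_count=alt)


def _sample_topology(k: int, rng: np.random.Generator) -> dict[int, int]:
    """Uniform random labelled rooted tree on k nodes, root = 1.

    Nodes are relabelled in breadth-first order so every parent id is
    smaller than its children's.
    """
    if k == 1:
        return {}
    import networkx as nx

    tree = nx.random_labeled_tree(k, seed=int(rng.integers(2**31)))
    root0 = 0
    order = [root0]
    parent0 = {}
    seen = {root0}
    queue = [root0]
    while queue:
        node = queue.pop(0)
        for nb in sorted(tree.neighbors(node)):
            if nb not in seen:
                seen.add(nb)
                parent0[nb] = node
                order.append(nb)
                queue.append(nb)
    relabel = {old: i + 1 for i, old in enumerate(order)}
    return {relabel[c]: relabel[p] for c, p in parent0.items()}


def _shared_private_split(
    parent: dict[int, int], k: int, target: float, rng: np.random.Generator
) -> tuple[set[int], dict[int, str]]:
    s = int(math.floor(target * k + 0.5))
    if s < 1:
        raise ValueError(
            f"shared_fraction_target {target} infeasible: the truncal cluster is "
            "always shared, so the shared fraction cannot fall below 1/n_clusters"
        )
    s = min(s, k)
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    shared = {1}
    frontier = sorted(children.get(1, []))
    while len(shared) < s and frontier:
        pick = int(rng.choice(frontier))
        shared.add(pick)
        frontier.remove(pick)
        frontier.extend(children.get(pick, []))
        frontier.sort()
    side: dict[int, str] = {}
    for node in sorted(parent):  # parents precede children by construction
        if node in shared:
            continue
        p = parent[node]
        if p in shared:
            side[node] = "primary" if rng.random() < 0.5 else "metastasis"
        else:
            side[node] = side[p]
    return shared, side


def _assign_ccf(
    parent: dict[int, int],
    k: int,
    shared: set[int],
    side: dict[int, str],
    compartment: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truth CCF vector for one region of the given compartment."""
    present = {
        n for n in range(1, k + 1)
        if n in shared or side.get(n) == compartment
    }
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    ccf = np.zeros(k)
    ccf[0] = 1.0
    stack = [1]
    while stack:
        node = stack.pop()
        ch = sorted(c for c in children.get(node, []) if c in present)
        if not ch:
            continue
        m = len(ch)
        budget = rng.uniform(0.5, 0.85)
        min_g = min(0.15, 0.5 / m)
        g = min_g + rng.dirichlet(np.ones(m)) * (1.0 - min_g * m)
        for frac, c in zip(g, ch):
            ccf[c - 1] = ccf[node - 1] * budget * frac
            stack.append(c)
    return ccf


def _sample_ccf_matrix(
    parent: dict[int, int],
    k: int,
    shared: set[int],
    side: dict[int, str],
    regions: Sequence[Region],
    rng: np.random.Generator,
    min_separation: float = 0.25,
    min_total_separation: float = 0.5,
    min_branch_excess: float = 0.1,
    max_attempts: int = 100,
) -> tuple[np.ndarray, float]:
    """Cluster-by-region truth CCFs with resolvable, identifiable profiles.

    Draws are rejected until (a) every pair of clusters differs by at
    least ``min_separation`` CCF in some region and
    ``min_total_separation`` summed over regions — pairs closer than that
    carry too little read-count information at exome-scale depth to ever
    be reported as distinct clusters — and (b) every non-truncal cluster
    exceeds each cluster that is not its ancestor by at least
    ``min_branch_excess`` in some region, so the true parent is the unique
    minimal containing clone and the topology is recoverable at all. The
    best attempt is kept if the cap is reached.
    """
    ancestors: dict[int, set[int]] = {}
    for node in range(1, k + 1):
        chain = set()
        cur = node
        while cur in parent:
            cur = parent[cur]
            chain.add(cur)
        ancestors[node] = chain
    best, best_sep = None, -1.0
    for _ in range(max_attempts):
        cols = []
        for r in regions:
            compartment = "metastasis" if r.is_metastasis() else "primary"
            cols.append(_assign_ccf(parent, k, shared, side, compartment, rng))
        mat = np.column_stack(cols)
        sep = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                diff = np.abs(mat[i] - mat[j])
                pair = min(float(diff.max()) / min_separation,
                           float(diff.sum()) / min_total_separation)
                sep = min(sep, pair)
        for c in range(2, k + 1):
            for q in range(1, k + 1):
                if q == c or q in ancestors[c]:
                    continue
                excess = float(np.max(mat[c - 1] - mat[q - 1]))
                sep = min(sep, excess / min_branch_excess)
        if sep > best_sep:
            best, best_sep = mat, sep
        if sep >= 1.0:
            break
    return best, best_sep


def _draw_variants(
    config: SimConfig,
    patient_id: str,
    k: int,
    rng: np.random.Generator,
) -> tuple[list[VariantCall], dict[str, int]]:
    from .signatures import synthetic_signature_matrix

    ref = synthetic_signature_matrix()
    mix = config.mixture()
    missing = set(mix) - set(ref.columns)
    if missing:
        raise ValueError(f"unknown signatures in mixture: {sorted(missing)}")
    probs = np.zeros(96)
    for name, w in mix.items():
        probs += w * ref[name].to_numpy()
    probs /= probs.sum()

    conseq_names = list(_CONSEQUENCE_PROBS)
    conseq_p = np.array(list(_CONSEQUENCE_PROBS.values()))
    conseq_p = conseq_p / conseq_p.sum()

    variants = []
    cluster_of = {}
    used_pos: set[tuple[str, int]] = set()
    idx = 0
    for cluster in range(1, k + 1):
        for _ in range(config.mutations_per_cluster):
            idx += 1
            vid = f"{patient_id}_v{idx:04d}"
            while True:
                chrom = str(int(rng.integers(1, 23)))
                pos = int(rng.integers(1, _CHROM_LENGTH))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            gene = f"GENE{int(rng.integers(1, 301)):03d}"
            driver = False
            if cluster == 1 and idx == 1:  # truncal driver, as in HGSOC (TP53)
                gene, driver = "TP53", True
            if rng.random() < config.indel_fraction:
                variants.append(VariantCall(vid, chrom, pos, "AT", "A", gene,
                                            "indel", "", driver))
            else:
                channel = CHANNELS[int(rng.choice(96, p=probs))]
                ref_b, alt_b, _ = parse_channel(channel)
                if rng.random() < 0.5:  # report on the purine strand half the time
                    from .trinuc import _COMPLEMENT
                    ref_b, alt_b = _COMPLEMENT[ref_b], _COMPLEMENT[alt_b]
                conseq = conseq_names[int(rng.choice(len(conseq_names), p=conseq_p))]
                variants.append(VariantCall(vid, chrom, pos, ref_b, alt_b, gene,
                                            conseq, channel, driver))
            cluster_of[vid] = cluster
    return variants, cluster_of


def _default_segments(region_ids: Sequence[str], cnv_events: tuple) -> list[SegmentCN]:
    segments = []
    cnv_by_region_chrom: dict[tuple[str, str], list] = {}
    for ev in cnv_events:
        rid, chrom = ev[0], str(ev[1])
        cnv_by_region_chrom.setdefault((rid, chrom), []).append(ev)
    for rid in region_ids:
        for chrom in (str(c) for c in range(1, 23)):
            events = cnv_by_region_chrom.get((rid, chrom))
            if events:
                for (_, _, start, end, major, minor, hap) in events:
                    segments.append(SegmentCN(rid, chrom, int(start), int(end),
                                              int(major), int(minor), hap))
            else:
                segments.append(SegmentCN(rid, chrom, 1, _CHROM_LENGTH, 1, 1, "unknown"))
    return segments


def simulate_patient(config: SimConfig, patient_id: str = "SIM_001") -> SimulatedPatient:
    """Generate one synthetic patient; deterministic given the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters

    regions = []
    lo, hi = config.purity_range
    for i in range(config.n_primary_regions):
        regions.append(Region(f"P{i + 1}", patient_id, "primary", "ovary",
                              purity=float(rng.uniform(lo, hi))))
    for i in range(config.n_met_regions):
        regions.append(Region(f"M{i + 1}", patient_id, "distant_metastasis", "spleen",
                              purity=float(rng.uniform(lo, hi))))

    # some topologies (deep chains low in the tree) cannot yield resolvable
    # cluster profiles at all; resample the topology in that case — the
    # emulated condition is the set of cluster structures a study could
    # actually report as distinct
    best = None
    for _ in range(20):
        parent = _sample_topology(k, rng)
        shared, side = _shared_private_split(parent, k, config.shared_fraction_target, rng)
        truth_ccf, sep = _sample_ccf_matrix(parent, k, shared, side, regions, rng)
        if best is None or sep > best[3]:
            best = (parent, shared, truth_ccf, sep)
        if sep >= 1.0:
            break
    parent, shared, truth_ccf, _ = best

    variants, cluster_of = _draw_variants(config, patient_id, k, rng)

    segments = _default_segments([r.region_id for r in regions], config.cnv_events)

    observations = []
    for v in variants:
        cluster = cluster_of[v.variant_id]
        for j, r in enumerate(regions):
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            if config.cnv_events:
                from .variant_io import lookup_cn

                major, minor, _ = lookup_cn(segments, r.region_id, v.chrom, v.pos)
                cn_total = major + minor
            else:
                cn_total = 2
            obs = simulate_reads(
                ccf=float(truth_ccf[cluster - 1, j]),
                purity=r.purity,
                cn_total=cn_total,
                multiplicity=1,
                depth=depth,
                error=config.sequencing_error,
                rng=rng,
                variant_id=v.variant_id,
                region_id=r.region_id,
            )
            observations.append(obs)

    return SimulatedPatient(
        patient_id=patient_id,
        config=config,
        regions=regions,
        variants=variants,
        observations=observations,
        segments=segments,
        truth_parent=parent,
        truth_root=1,
        truth_ccf=truth_ccf,
        cluster_of=cluster_of,
        truth_shared_fraction=len(shared) / k,
    )


def simulate_cohort(
    n_patients: int,
    config: SimConfig,
    seed: int | None = None,
) -> list[SimulatedPatient]:
    """Independent patients; per-patient seeds derived from ``seed``."""
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    out = []
    for i, child in enumerate(ss.spawn(n_patients)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=sub_seed)
        out.append(simulate_patient(cfg, patient_id=f"SIM_{i + 1:03d}"))
    return out


def write_patient(patient: SimulatedPatient, outdir: str | Path) -> dict[str, Path]:
    """Write a patient's tables plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = patient.patient_id
    paths = {
        "regions": outdir / f"{pid}.regions.tsv",
        "variants": outdir / f"{pid}.variants.tsv",
        "segments": outdir / f"{pid}.segments.tsv",
        "truth": outdir / f"{pid}.truth.json",
    }
    write_regions(patient.regions, paths["regions"])
    write_variant_table(patient.variants, patient.observations, paths["variants"])
    write_segments(patient.segments, paths["segments"])
    truth = {
        "patient_id": pid,
        "root": patient.truth_root,
        "parent": {str(c): p for c, p in sorted(patient.truth_parent.items())},
        "ccf": {
            str(cid): [float(x) for x in patient.truth_ccf[cid - 1]]
            for cid in range(1, patient.truth_ccf.shape[0] + 1)
        },
        "region_ids": patient.region_ids,
        "cluster_of": patient.cluster_of,
        "shared_fraction": patient.truth_shared_fraction,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return paths
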