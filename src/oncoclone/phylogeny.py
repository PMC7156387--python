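"""Clone-tree reconstruction, dissemination timing and parallel evolution.

The clone tree is found by exhaustive search over parent assignments that
satisfy, per region, the containment constraint (a child clone's CCF cannot
exceed its parent's, up to tolerance) and the pigeonhole sum rule (sibling
CCFs cannot sum above their parent's, up to tolerance). Among valid trees
the winner minimises, lexicographically, (1) the total constraint
violation absorbed by the tolerance — the summed per-region CCF excess of
children over parents and of sibling sums over parents — so the tree that
needs the least noise forgiveness is preferred, then (2) the total
containment margin, so each clone hangs from the closest clone that can
contain it; remaining ties break on the lexicographically smallest parent
map.

Molecular time of metastatic divergence is the mutation-weighted fraction
of clustered mutations belonging to clusters detected in both the primary
and the metastatic compartment; >= 50% calls linear (late-dissemination)
progression, below calls parallel (early) progression.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import MutationCluster
from .variant_io import Region, SegmentCN, VariantCall

log = logging.getLogger(__name__)

MAX_EXHAUSTIVE = 12


class TreeSearchError(ValueError):
    pass


@dataclass
class CloneTree:
    nodes: tuple[int, ...]
    parent: dict[int, int]  # child -> parent; root absent
    root: int

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def ancestors(self, node: int) -> list[int]:
        out = []
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if a is a (strict) ancestor of b."""
        return a in self.ancestors(b)

    def validate(self, ccf: Mapping[int, np.ndarray], tolerance: float = 0.0) -> None:
        seen = set()
        for node in self.nodes:
            cur, path = node, set()
            while cur in self.parent:
                if cur in path:
                    raise TreeSearchError(f"cycle through node {cur}")
                path.add(cur)
                cur = self.parent[cur]
            if cur != self.root:
                raise TreeSearchError(f"node {node} not reachable from root {self.root}")
            seen.add(node)
        for child, parent in self.parent.items():
            gap = np.asarray(ccf[parent]) - np.asarray(ccf[child])
            if np.min(gap) < -tolerance - 1e-12:
                raise TreeSearchError(f"containment violated for {child} under {parent}")
        for node in self.nodes:
            ch = self.children(node)
            if ch:
                sums = np.sum([np.asarray(ccf[c]) for c in ch], axis=0)
                if np.max(sums - np.asarray(ccf[node])) > tolerance + 1e-12:
                    raise TreeSearchError(f"sum rule violated at node {node}")

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            ch = self.children(node)
            if not ch:
                return str(node)
            return "(" + ",".join(rec(c) for c in ch) + ")" + str(node)

        return rec(self.root) + ";"

    def to_parent_json(self) -> str:
        return json.dumps(
            {"root": self.root, "parent": {str(c): p for c, p in sorted(self.parent.items())}}
        )


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    shared_fraction: float
    model: str  # linear | parallel
    threshold: float = 0.5

    @property
    def molecular_time_pct(self) -> float:
        return 100.0 * self.shared_fraction


@dataclass(frozen=True)
class ParallelEvent:
    gene: str
    variant_ids: tuple[str, ...]
    branch_nodes: tuple[int, ...]


@dataclass(frozen=True)
class MsaiEvent:
    chrom: str
    start: int
    end: int
    region_pair: tuple[str, str]
    flipped: bool = True


def _tree_score(parent: Mapping[int, int], ccf: Mapping[int, np.ndarray]) -> tuple[float, float]:
    """(total violation, total margin) of a parent map; lower is better.

    Violation sums every per-region CCF excess of a child over its parent
    and of sibling sums over their parent (noise-driven breaches inside the
    hard tolerance); margin sums the per-region CCF gap to the parent, so
    ties in violation resolve to the closest containing parent.
    """
    violation = 0.0
    margin = 0.0
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        gap = np.asarray(ccf[p]) - np.asarray(ccf[c])
        violation += float(np.clip(-gap, 0.0, None).sum())
        margin += float(np.clip(gap, 0.0, None).sum())
        children.setdefault(p, []).append(c)
    for p, ch in children.items():
        excess = np.sum([np.asarray(ccf[c]) for c in ch], axis=0) - np.asarray(ccf[p])
        violation += float(np.clip(excess, 0.0, None).sum())
    return violation, margin


def enumerate_trees(
    ccf: Mapping[int, np.ndarray], root: int, tolerance: float
) -> list[dict[int, int]]:
    """All parent maps satisfying containment, sum rule and acyclicity.

    Brute force over every parent assignment; practical for <= 7 clusters
    and used as the oracle route in tests as well as by build_tree for
    small problems.
    """
    nodes = sorted(ccf.keys())
    others = [n for n in nodes if n != root]
    valid = []
    candidates = {
        c: [p for p in nodes
            if p != c and np.min(np.asarray(ccf[p]) - np.asarray(ccf[c])) >= -tolerance]
        for c in others
    }
    for combo in itertools.product(*(candidates[c] for c in others)):
        parent = dict(zip(others, combo))
        tree = CloneTree(tuple(nodes), parent, root)
        try:
            tree.validate(ccf, tolerance)
        except TreeSearchError:
            continue
        valid.append(parent)
    return valid


def build_tree(
    clusters: Sequence[MutationCluster],
    tolerance: float = 0.1,
    truncal_min_ccf: float = 0.8,
) -> CloneTree:
    """Reconstruct the clone tree from cluster CCF profiles.

    Requires exactly one truncal cluster (CCF >= ``truncal_min_ccf`` in
    every region), which roots the tree. Exhaustive search with pruning up
    to 12 clusters; a greedy closest-parent heuristic (with a warning)
    beyond that.
    """
    ccf = {c.cluster_id: np.asarray(c.mean_ccf, dtype=float) for c in clusters}
    nodes = sorted(ccf.keys())
    truncal = [n for n in nodes if np.min(ccf[n]) >= truncal_min_ccf]
    if not truncal:
        raise TreeSearchError("no truncal cluster (CCF >= %.2f in all regions)" % truncal_min_ccf)
    if len(truncal) > 1:
        raise TreeSearchError(f"multiple truncal candidates: {truncal}")
    root = truncal[0]
    if len(nodes) == 1:
        return CloneTree((root,), {}, root)

    if len(nodes) > MAX_EXHAUSTIVE:
        log.warning("%d clusters exceeds exhaustive cap; greedy tree search", len(nodes))
        return _greedy_tree(ccf, root, tolerance)

    # depth-first search over nodes in decreasing total-CCF order with
    # incremental sum-rule pruning
    order = sorted((n for n in nodes if n != root), key=lambda n: (-float(ccf[n].sum()), n))
    candidates = {
        c: sorted(
            p for p in nodes
            if p != c and float(np.min(ccf[p] - ccf[c])) >= -tolerance
        )
        for c in order
    }
    for c, cand in candidates.items():
        if not cand:
            raise TreeSearchError(
                f"no valid parent for cluster {c}: containment violated against all others"
            )

    best: tuple[float, tuple, dict] | None = None
    child_sum = {n: np.zeros_like(ccf[root]) for n in nodes}
    parent: dict[int, int] = {}

    def rec(i: int) -> None:
        nonlocal best
        if i == len(order):
            tree = CloneTree(tuple(nodes), dict(parent), root)
            try:
                tree.validate(ccf, tolerance)
            except TreeSearchError:
                return
            score = _tree_score(parent, ccf)
            key = tuple(parent[c] for c in sorted(parent))
            if best is None or (score, key) < (best[0], best[1]):
                best = (score, key, dict(parent))
            return
        c = order[i]
        for p in candidates[c]:
            new_sum = child_sum[p] + ccf[c]
            if float(np.max(new_sum - ccf[p])) > tolerance:
                continue
            child_sum[p] = new_sum
            parent[c] = p
            rec(i + 1)
            del parent[c]
            child_sum[p] = new_sum - ccf[c]

    rec(0)
    if best is None:
        raise TreeSearchError(
            "no valid tree: containment/sum-rule constraints are jointly unsatisfiable "
            f"at tolerance {tolerance}"
        )
    return CloneTree(tuple(nodes), best[2], root)


def _greedy_tree(ccf, root, tolerance):
    nodes = sorted(ccf.keys())
    order = sorted((n for n in nodes if n != root), key=lambda n: (-float(ccf[n].sum()), n))
    parent: dict[int, int] = {}
    placed = [root]
    for c in order:
        best_p, best_score = None, (np.inf, np.inf)
        for p in placed:
            gap = ccf[p] - ccf[c]
            if float(np.min(gap)) < -tolerance:
                continue
            sibs = [s for s, q in parent.items() if q == p] + [c]
            sums = np.sum([ccf[s] for s in sibs], axis=0)
            if float(np.max(sums - ccf[p])) > tolerance:
                continue
            score = (float(np.clip(-gap, 0.0, None).sum()),
                     float(np.clip(gap, 0.0, None).sum()))
            if score < best_score:
                best_p, best_score = p, score
        if best_p is None:
            raise TreeSearchError(f"greedy search: no valid parent for cluster {c}")
        parent[c] = best_p
        placed.append(c)
    return CloneTree(tuple(nodes), parent, root)


def molecular_time(
    tree: CloneTree,
    clusters: Sequence[MutationCluster],
    regions: Sequence[Region],
    patient_id: str = "",
    presence_threshold: float = 0.05,
    linear_threshold: float = 0.5,
    weighted: bool = True,
    contralateral_as_met: bool = True,
    region_ids: Sequence[str] | None = None,
) -> ProgressionCall:
    """Molecular time of metastatic divergence and progression model.

    A cluster counts as shared when its mean CCF reaches
    ``presence_threshold`` in at least one primary and one metastatic
    region. The shared fraction is mutation-count-weighted by default
    (fraction of clustered mutations in shared clusters); ``weighted=False``
    switches to the plain fraction of shared clusters.
    """
    if region_ids is None:
        region_ids = [r.region_id for r in regions]
    by_id = {r.region_id: r for r in regions}
    met_mask = np.array([by_id[rid].is_metastasis(contralateral_as_met) for rid in region_ids])
    if not met_mask.any() or met_mask.all():
        raise ValueError("patient must have both primary and metastatic regions")
    total = 0.0
    shared = 0.0
    for cl in clusters:
        ccf = np.asarray(cl.mean_ccf)
        mass = cl.size if weighted else 1.0
        total += mass
        in_primary = bool((ccf[~met_mask] >= presence_threshold).any())
        in_met = bool((ccf[met_mask] >= presence_threshold).any())
        if in_primary and in_met:
            shared += mass
    frac = shared / total if total else 0.0
    model = "linear" if frac >= linear_threshold else "parallel"
    return ProgressionCall(patient_id, frac, model, linear_threshold)


def detect_parallel_snv(
    variants: Sequence[VariantCall],
    assignments: Mapping[str, int],
    tree: CloneTree,
) -> list[ParallelEvent]:
    """Convergent mutation of one gene on distinct, non-ancestral branches."""
    by_gene: dict[str, list[VariantCall]] = {}
    for v in variants:
        if v.gene and v.variant_id in assignments:
            by_gene.setdefault(v.gene, []).append(v)
    events = []
    for gene, vs in sorted(by_gene.items()):
        if len(vs) < 2:
            continue
        hits = []
        for a, b in itertools.combinations(vs, 2):
            ca, cb = assignments[a.variant_id], assignments[b.variant_id]
            if ca == cb:
                continue
            if tree.is_ancestor(ca, cb) or tree.is_ancestor(cb, ca):
                continue
            hits.append((a, b, ca, cb))
        if hits:
            vids = tuple(sorted({v.variant_id for h in hits for v in h[:2]}))
            branches = tuple(sorted({c for h in hits for c in h[2:]}))
            events.append(ParallelEvent(gene, vids, branches))
    return events


def detect_msai(segments: Sequence[SegmentCN]) -> list[MsaiEvent]:
    """Mirrored subclonal allelic imbalance between region pairs.

    For every pair of overlapping segments from different regions where both
    are allelically imbalanced (major != minor) with known, opposite major
    haplotypes, one event is reported over the overlapping interval.
    """
    events = []
    usable = [s for s in segments
              if s.major_haplotype != "unknown" and s.major_cn != s.minor_cn]
    for a, b in itertools.combinations(usable, 2):
        if a.region_id == b.region_id or a.chrom != b.chrom:
            continue
        start, end = max(a.start, b.start), min(a.end, b.end)
        if start > end:
            continue
        if a.major_haplotype != b.major_haplotype:
            pair = tuple(sorted((a.region_id, b.region_id)))
            events.append(MsaiEvent(a.chrom, start, end, pair, flipped=True))
    return events
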