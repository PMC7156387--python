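import itertools

import numpy as np
import pytest

from oncoclone.clustering import MutationCluster
from oncoclone.phylogeny import (
    CloneTree,
    TreeSearchError,
    build_tree,
    detect_msai,
    detect_parallel_snv,
    molecular_time,
)
from oncoclone.variant_io import Region, SegmentCN, VariantCall


def make_clusters(ccfs, sizes=None):
    sizes = sizes or [10] * len(ccfs)
    return [
        MutationCluster(i + 1, tuple(f"v{i}_{j}" for j in range(s)), np.asarray(c, float), s)
        for i, (c, s) in enumerate(zip(ccfs, sizes))
    ]


def brute_force_best_tree(ccfs, tolerance=0.1):
    """Independent oracle: score every acyclic parent map directly."""
    k = len(ccfs)
    ccf = {i + 1: np.asarray(ccfs[i], float) for i in range(k)}
    root = 1
    best = None
    others = list(range(2, k + 1))
    for combo in itertools.product(range(1, k + 1), repeat=len(others)):
        parent = {c: p for c, p in zip(others, combo) if p != c}
        if len(parent) != len(others):
            continue
        # reachability from root
        ok = True
        for node in others:
            seen, cur = set(), node
            while cur in parent and cur not in seen:
                seen.add(cur)
                cur = parent[cur]
            ok &= cur == root
        if not ok:
            continue
        # hard constraints
        valid = all(
            (ccf[p] - ccf[c] >= -tolerance).all() for c, p in parent.items()
        )
        for node in range(1, k + 1):
            ch = [c for c, p in parent.items() if p == node]
            if ch and (np.sum([ccf[c] for c in ch], axis=0) > ccf[node] + tolerance).any():
                valid = False
        if not valid:
            continue
        violation = margin = 0.0
        for c, p in parent.items():
            gap = ccf[p] - ccf[c]
            violation += np.clip(-gap, 0, None).sum()
            margin += np.clip(gap, 0, None).sum()
        for node in range(1, k + 1):
            ch = [c for c, p in parent.items() if p == node]
            if ch:
                violation += np.clip(
                    np.sum([ccf[c] for c in ch], axis=0) - ccf[node], 0, None
                ).sum()
        key = (violation, margin, tuple(parent[c] for c in sorted(parent)))
        if best is None or key < best[0]:
            best = (key, parent)
    return None if best is None else best[1]


def test_chain_example_forced_by_sum_rule():
    """A=(1,1), B=(.6,.9), C=(.5,.05): branching under A breaks the sum rule
    in region 1, so the only valid tree is the chain A->B->C."""
    ccfs = [(1.0, 1.0), (0.6, 0.9), (0.5, 0.05)]
    tree = build_tree(make_clusters(ccfs), tolerance=0.0)
    assert tree.parent == {2: 1, 3: 2}
    assert brute_force_best_tree(ccfs, tolerance=0.0) == tree.parent


def test_single_cluster_gives_single_node_tree():
    tree = build_tree(make_clusters([(1.0, 1.0)]))
    assert tree.parent == {} and tree.root == 1


def test_no_truncal_cluster_is_an_error():
    with pytest.raises(TreeSearchError, match="truncal"):
        build_tree(make_clusters([(0.5, 0.6), (0.3, 0.2)]))


def test_unsatisfiable_constraints_raise():
    # two "truncal-like" children that cannot both fit under the root
    ccfs = [(1.0, 1.0), (0.9, 0.9), (0.9, 0.9)]
    with pytest.raises(TreeSearchError):
        build_tree(make_clusters(ccfs), tolerance=0.0)


@pytest.mark.parametrize("seed", range(8))
def test_search_matches_brute_force_enumeration(seed):
    """On random <=6-cluster instances the pruned search returns exactly the
    enumeration optimum (or raises when no valid tree exists)."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 7))
    ccfs = [np.ones(3)]
    for _ in range(k - 1):
        ccfs.append(np.round(rng.uniform(0, 0.9, 3), 2))
    oracle = brute_force_best_tree(ccfs)
    if oracle is None:
        with pytest.raises(TreeSearchError):
            build_tree(make_clusters(ccfs))
    else:
        assert build_tree(make_clusters(ccfs)).parent == oracle


def test_output_tree_satisfies_constraints(deep_patient):
    p = deep_patient
    clusters = make_clusters([p.truth_ccf[i] for i in range(p.truth_ccf.shape[0])])
    tree = build_tree(clusters, tolerance=1e-6)
    tree.validate({c.cluster_id: c.mean_ccf for c in clusters}, tolerance=1e-6)
    assert tree.parent == p.truth_parent


def test_newick_and_parent_json_exports():
    tree = CloneTree((1, 2, 3), {2: 1, 3: 2}, 1)
    assert tree.to_newick() == "((3)2)1;"
    import dendropy

    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert len(parsed.nodes()) == 3
    import json

    payload = json.loads(tree.to_parent_json())
    assert payload["root"] == 1 and payload["parent"] == {"2": 1, "3": 2}


REGIONS = [
    Region("P1", "pt", "primary", purity=0.5),
    Region("M1", "pt", "distant_metastasis", purity=0.5),
]


class TestMolecularTime:
    def test_all_clusters_shared_is_linear_at_time_one(self):
        clusters = make_clusters([(1.0, 1.0), (0.5, 0.5)])
        call = molecular_time(None, clusters, REGIONS, region_ids=["P1", "M1"])
        assert call.shared_fraction == 1.0
        assert call.model == "linear"

    def test_truncal_only_shared_gives_early_parallel(self):
        clusters = make_clusters([(1.0, 1.0), (0.6, 0.0)], sizes=[10, 90])
        call = molecular_time(None, clusters, REGIONS, region_ids=["P1", "M1"])
        assert call.shared_fraction == pytest.approx(0.10)
        assert call.model == "parallel"
        assert call.molecular_time_pct == pytest.approx(10.0)

    def test_late_dissemination_fraction_is_linear(self):
        clusters = make_clusters([(1.0, 1.0), (0.6, 0.4), (0.5, 0.0)], sizes=[40, 37, 23])
        call = molecular_time(None, clusters, REGIONS, region_ids=["P1", "M1"])
        assert call.shared_fraction == pytest.approx(0.77)
        assert call.model == "linear"

    def test_invariant_to_cluster_relabelling_and_region_order(self):
        ccfs = [(1.0, 1.0), (0.6, 0.0), (0.2, 0.3)]
        sizes = [10, 20, 30]
        a = molecular_time(None, make_clusters(ccfs, sizes), REGIONS,
                           region_ids=["P1", "M1"])
        perm = [2, 0, 1]
        b = molecular_time(
            None,
            make_clusters([ccfs[i] for i in perm], [sizes[i] for i in perm]),
            REGIONS,
            region_ids=["P1", "M1"],
        )
        rev = molecular_time(
            None,
            make_clusters([c[::-1] for c in ccfs], sizes),
            list(reversed(REGIONS)),
            region_ids=["M1", "P1"],
        )
        assert a.shared_fraction == b.shared_fraction == rev.shared_fraction

    def test_unweighted_variant_counts_clusters_not_mutations(self):
        clusters = make_clusters([(1.0, 1.0), (0.6, 0.0)], sizes=[10, 90])
        call = molecular_time(None, clusters, REGIONS, region_ids=["P1", "M1"],
                              weighted=False)
        assert call.shared_fraction == pytest.approx(0.5)

    def test_missing_tumour_class_is_an_error(self):
        primaries = [Region("P1", "pt", "primary", purity=0.5)]
        with pytest.raises(ValueError):
            molecular_time(None, make_clusters([(1.0,)]), primaries, region_ids=["P1"])


class TestParallelEvolution:
    tree = CloneTree((1, 2, 3, 4), {2: 1, 3: 1, 4: 2}, 1)

    def _variant(self, vid, gene):
        return VariantCall(vid, "1", 1, "C", "A", gene, "missense", "A[C>A]A")

    def test_gene_hit_on_sibling_branches_is_an_event(self):
        variants = [self._variant("a", "FLNA"), self._variant("b", "FLNA")]
        events = detect_parallel_snv(variants, {"a": 2, "b": 3}, self.tree)
        assert len(events) == 1
        assert events[0].gene == "FLNA"
        assert events[0].branch_nodes == (2, 3)

    def test_two_hits_in_one_cluster_is_not_parallel(self):
        variants = [self._variant("a", "MUC16"), self._variant("b", "MUC16")]
        assert detect_parallel_snv(variants, {"a": 2, "b": 2}, self.tree) == []

    def test_ancestral_pair_is_not_parallel(self):
        variants = [self._variant("a", "RYR2"), self._variant("b", "RYR2")]
        assert detect_parallel_snv(variants, {"a": 1, "b": 4}, self.tree) == []


class TestMsai:
    def seg(self, rid, major, minor, hap, start=1, end=1000, chrom="7"):
        return SegmentCN(rid, chrom, start, end, major, minor, hap)

    def test_opposite_major_haplotypes_flag_msai(self):
        events = detect_msai([self.seg("P1", 2, 1, "A"), self.seg("M1", 2, 1, "B")])
        assert len(events) == 1
        assert events[0].region_pair == ("M1", "P1")
        assert events[0].flipped

    def test_same_haplotype_is_not_msai(self):
        assert detect_msai([self.seg("P1", 2, 1, "A"), self.seg("M1", 2, 1, "A")]) == []

    def test_balanced_segment_cannot_be_msai(self):
        assert detect_msai([self.seg("P1", 2, 2, "A"), self.seg("M1", 2, 1, "B")]) == []

    def test_non_overlapping_segments_ignored(self):
        events = detect_msai(
            [self.seg("P1", 2, 1, "A", 1, 100), self.seg("M1", 2, 1, "B", 200, 300)]
        )
        assert events == []

    def test_unknown_haplotype_skipped(self):
        assert detect_msai([self.seg("P1", 2, 1, "unknown"), self.seg("M1", 2, 1, "B")]) == []
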