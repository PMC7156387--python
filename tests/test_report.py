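import itertools

import numpy as np
import pytest
from scipy import stats

from oncoclone.report import (
    annotate_actionable,
    compare_groups,
    compare_proportions,
    load_actionable_table,
    run_pipeline,
    tabulate_sharing,
)


class TestSharingTable:
    def test_counts_to_percentages(self):
        tab = tabulate_sharing(
            {
                "mutation": {"shared": 619, "primary_private": 238, "metastasis_private": 338},
                "cnv": {"shared": 244, "primary_private": 308, "metastasis_private": 300},
            }
        )
        assert tab.percentages("mutation") == {
            "shared": 51.8, "primary_private": 19.9, "metastasis_private": 28.3,
        }
        assert tab.percentages("cnv") == {
            "shared": 28.6, "primary_private": 36.2, "metastasis_private": 35.2,
        }
        assert tab.total("mutation") == 1195
        assert tab.total("cnv") == 852

    def test_single_event(self):
        tab = tabulate_sharing([("mutation", "shared")])
        assert tab.percentages("mutation") == {
            "shared": 100.0, "primary_private": 0.0, "metastasis_private": 0.0,
        }

    def test_empty_cohort_gives_zero_table(self):
        tab = tabulate_sharing([])
        assert tab.total("mutation") == 0
        assert tab.percentages("cnv")["shared"] == 0.0

    def test_round_half_up(self):
        # 1/8 = 12.5% must round to 12.5; 5/16=31.25 -> 31.3 (half-up)
        tab = tabulate_sharing(
            {"mutation": {"shared": 5, "primary_private": 6, "metastasis_private": 5}}
        )
        assert tab.percentages("mutation")["shared"] == 31.3

    def test_percentages_sum_to_one_hundred(self):
        tab = tabulate_sharing(
            {"mutation": {"shared": 1, "primary_private": 1, "metastasis_private": 1}}
        )
        assert sum(tab.percentages("mutation").values()) == pytest.approx(100.0, abs=0.2)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            tabulate_sharing([("mutation", "nope")])


class TestCompareProportions:
    def test_identical_rows_give_zero_statistic(self):
        stat, p, dof = compare_proportions(np.array([[10, 20], [10, 20]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_expected_counts(self):
        table = np.array([[338, 857], [300, 552]], dtype=float)
        # independent oracle: Pearson statistic assembled from first principles
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        chi2 = ((table - expected) ** 2 / expected).sum()
        stat, p, dof = compare_proportions(table)
        assert stat == pytest.approx(chi2)
        assert dof == 1
        assert p == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_small_expected_cell_advises_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            compare_proportions(np.array([[1, 1000], [0, 3]]))


class TestCompareGroups:
    def test_exact_p_for_disjoint_groups(self):
        u, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_rank_split_enumeration(self):
        """Oracle: enumerate every assignment of ranks to group A."""
        a = [1.3, 2.1, 5.0]
        b = [0.4, 3.3, 4.2, 6.1]
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}

        def u_of(group_ranks, n_a):
            r = sum(group_ranks)
            return r - n_a * (n_a + 1) / 2

        obs_u = u_of([ranks[v] for v in a], len(a))
        n = len(pooled)
        us = [
            u_of(combo, len(a))
            for combo in itertools.combinations(range(1, n + 1), len(a))
        ]
        lo, hi = min(obs_u, len(a) * len(b) - obs_u), max(obs_u, len(a) * len(b) - obs_u)
        p_exact = np.mean([(u <= lo) or (u >= hi) for u in us])
        u, p = compare_groups(a, b)
        assert p == pytest.approx(p_exact)

    def test_identical_groups_in_approx_mode(self):
        vals = list(range(10))
        u, p = compare_groups(vals, vals)
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestActionable:
    def test_shared_pik3ca_mutation_matches(self):
        events = annotate_actionable([("PIK3CA", "mutation", "shared")])
        assert len(events) == 1
        assert events[0].category == "shared"

    def test_met_private_nfkbia_deletion_matches(self):
        events = annotate_actionable([("NFKBIA", "deletion", "metastasis_private")])
        assert len(events) == 1

    def test_gene_not_in_table_ignored(self):
        assert annotate_actionable([("TTN", "mutation", "shared")]) == []

    def test_event_type_must_match(self):
        # NFKBIA is actionable for deletion, not amplification
        assert annotate_actionable([("NFKBIA", "amplification", "shared")]) == []

    def test_bundled_table_covers_the_expected_genes(self):
        table = load_actionable_table()
        assert set(table["gene"]) == {
            "PIK3CA", "ALK", "MYC", "MCL1", "IGF1R", "CCND2", "CCND3", "CDK6", "NFKBIA",
        }


class TestPipeline:
    def _config(self, tmp_path, out, stages=None):
        import yaml

        cfg = {
            "seed": 11,
            "out_dir": str(out),
            "simulate": {"n_patients": 2, "n_clusters": 4, "mutations_per_cluster": 12},
            "stages": stages or {},
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg))
        return path

    def test_report_contains_one_progression_call_per_patient(self, tmp_path):
        out = run_pipeline(self._config(tmp_path, tmp_path / "rep"))
        import pandas as pd

        summary = pd.read_csv(out / "patients.tsv", sep="\t")
        assert len(summary) == 2
        assert set(summary["model"]) <= {"linear", "parallel"}

    def test_rerun_with_same_seed_is_identical(self, tmp_path):
        out1 = run_pipeline(self._config(tmp_path, tmp_path / "rep1"))
        out2 = run_pipeline(self._config(tmp_path, tmp_path / "rep2"))
        for name in ("patients.tsv", "sharing.tsv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_stage_toggle_suppresses_outputs(self, tmp_path):
        out = run_pipeline(
            self._config(tmp_path, tmp_path / "rep3", stages={"cluster": False})
        )
        assert not (out / "SIM_001" / "clusters.tsv").exists()
        assert not (out / "sharing.tsv").exists()
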