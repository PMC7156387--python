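import numpy as np
import pandas as pd
import pytest

from oncoclone.signatures import (
    Catalogue96,
    build_catalogue,
    correlate_exposure_burden,
    dissect_temporally,
    fit_exposures,
    read_signature_matrix,
    synthetic_signature_matrix,
    write_signature_matrix,
)
from oncoclone.trinuc import CHANNELS
from oncoclone.variant_io import VariantCall


def _snv(vid, ref, alt, ctx_channel):
    return VariantCall(vid, "1", 1, ref, alt, "g", "missense", ctx_channel)


class TestCatalogue:
    def test_pyrimidine_context_bins_directly(self):
        cat = build_catalogue([_snv("a", "C", "A", "A[C>A]A")])
        assert cat.counts[CHANNELS.index("A[C>A]A")] == 1

    def test_purine_context_collapses_by_reverse_complement(self):
        from oncoclone.trinuc import channel_name

        assert channel_name("G", "T", "TGT") == "A[C>A]A"

    def test_empty_input_gives_zero_vector(self):
        cat = build_catalogue([])
        assert cat.counts.sum() == 0

    def test_indels_excluded_and_counted(self, caplog):
        indel = VariantCall("i", "1", 2, "AT", "A", "g", "indel", "")
        with caplog.at_level("INFO"):
            cat = build_catalogue([_snv("a", "C", "A", "A[C>A]A"), indel])
        assert cat.n_mutations == 1

    def test_conservation_total_equals_snv_count(self, default_patient):
        snvs = [v for v in default_patient.variants if v.is_snv]
        cat = build_catalogue(snvs)
        assert cat.n_mutations == len(snvs)


class TestReference:
    def test_columns_sum_to_one(self, signature_reference):
        assert np.allclose(signature_reference.sum(axis=0), 1.0)
        assert signature_reference.shape == (96, 30)

    def test_tsv_roundtrip(self, signature_reference, tmp_path):
        path = tmp_path / "sigs.tsv"
        write_signature_matrix(signature_reference, path)
        back = read_signature_matrix(path)
        assert np.allclose(back.to_numpy(), signature_reference.to_numpy())

    def test_deterministic(self):
        a = synthetic_signature_matrix()
        b = synthetic_signature_matrix()
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestFitExposures:
    def test_exact_mixture_recovered(self, signature_reference):
        S = signature_reference.to_numpy()
        true_w = np.zeros(30)
        true_w[[0, 2]] = (0.7, 0.3)
        counts = np.round(10_000 * (S @ true_w))
        exp = fit_exposures(Catalogue96("s", counts), signature_reference)
        assert np.abs(exp.weights - true_w).sum() < 0.02
        assert exp.reconstruction_cosine > 0.999

    def test_single_signature_catalogue(self, signature_reference):
        counts = np.round(5000 * signature_reference["S4"].to_numpy())
        exp = fit_exposures(Catalogue96("s", counts), signature_reference)
        assert exp.weights[signature_reference.columns.get_loc("S4")] > 0.99

    def test_sparsity_weights_below_threshold_are_zero(self, signature_reference, rng):
        counts = rng.multinomial(3000, signature_reference.to_numpy().mean(axis=1))
        exp = fit_exposures(Catalogue96("s", counts), signature_reference, min_weight=0.06)
        nonzero = exp.weights[exp.weights > 0]
        assert (nonzero >= 0.06).all()
        assert exp.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, signature_reference):
        S = signature_reference.to_numpy()
        counts = np.round(2000 * (S @ np.eye(30)[3]))
        w1 = fit_exposures(Catalogue96("s", counts), signature_reference).weights
        w2 = fit_exposures(Catalogue96("s", counts * 10), signature_reference).weights
        assert np.allclose(w1, w2)

    def test_small_catalogue_flagged_unstable(self, signature_reference, caplog):
        counts = np.zeros(96)
        counts[0] = 10
        with caplog.at_level("WARNING"):
            exp = fit_exposures(Catalogue96("s", counts), signature_reference)
        assert not exp.stable

    def test_empty_catalogue_rejected(self, signature_reference):
        with pytest.raises(ValueError):
            fit_exposures(Catalogue96("s", np.zeros(96)), signature_reference)


class TestTemporalDissection:
    def _table(self, signature_reference, rng):
        S = signature_reference
        rows = []
        for tclass in ("primary", "metastasis"):
            for clon, sig in (("clonal", "S1"), ("subclonal", "S3")):
                probs = S[sig].to_numpy()
                for ch in rng.choice(96, size=400, p=probs):
                    rows.append(dict(context96=CHANNELS[ch], tumour_class=tclass,
                                     clonality=clon))
        return pd.DataFrame(rows)

    def test_subclonal_only_process_enriches_subclonal_stratum(
        self, signature_reference, rng
    ):
        table = self._table(signature_reference, rng)
        out = dissect_temporally(table, signature_reference)
        s3 = signature_reference.columns.get_loc("S3")
        for tclass in ("primary", "metastasis"):
            assert (
                out[(tclass, "subclonal")].weights[s3]
                > out[(tclass, "clonal")].weights[s3]
            )

    def test_clonal_plus_subclonal_catalogues_sum_to_overall(
        self, signature_reference, rng
    ):
        table = self._table(signature_reference, rng)
        total = build_catalogue(list(table["context96"]))
        parts = np.zeros(96)
        for (_, _), sub in table.groupby(["tumour_class", "clonality"]):
            parts += build_catalogue(list(sub["context96"])).counts
        assert np.array_equal(parts, total.counts)

    def test_all_clonal_leaves_no_subclonal_stratum(self, signature_reference):
        table = pd.DataFrame(
            dict(context96=["A[C>A]A"] * 25, tumour_class="primary", clonality="clonal")
        )
        out = dissect_temporally(table, signature_reference)
        assert ("primary", "subclonal") not in out


class TestSpearman:
    def test_concordant_ranks(self):
        rho, _ = correlate_exposure_burden([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert rho == pytest.approx(1.0)

    def test_anticoncordant_ranks(self):
        rho, _ = correlate_exposure_burden([1, 2, 3, 4, 5, 6], [60, 50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_single_transposition_closed_form(self):
        # one adjacent swap: rho = 1 - 6*2/(6*35) = 0.9429
        rho, p = correlate_exposure_burden([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 6, 5])
        assert rho == pytest.approx(1 - 12 / 210, abs=1e-9)
        # exact permutation two-sided p: 12 of 720 permutations reach |rho|
        assert p == pytest.approx(12 / 720, abs=1e-9)

    def test_exact_matches_enumeration_oracle_with_ties(self):
        from itertools import permutations

        from scipy.stats import rankdata

        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0]

        def rho_of(a, b):
            ra, rb = rankdata(a), rankdata(b)
            ra, rb = ra - ra.mean(), rb - rb.mean()
            return float(ra @ rb / np.sqrt((ra**2).sum() * (rb**2).sum()))

        obs = rho_of(x, y)
        perms = [rho_of(x, p) for p in permutations(y)]
        expected_p = np.mean([abs(r) >= abs(obs) - 1e-12 for r in perms])
        rho, p = correlate_exposure_burden(x, y)
        assert rho == pytest.approx(obs)
        assert p == pytest.approx(expected_p)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            correlate_exposure_burden([1, 2, 3], [1, 2, 3])
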