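"""Trinucleotide contexts, NNLS refitting, NMF extraction, Wilcoxon test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triovar import (
    SBS96_CHANNELS,
    TissueSample,
    VariantRecord,
    build_sbs_matrix,
    extract_denovo,
    refit_signatures,
    signature_percent_contribution,
    synthetic_signature_catalog,
    trinucleotide_context,
    wilcoxon_signed_rank,
)
from triovar.signatures import (
    ContigEdgeError,
    ReferenceMismatchError,
    largest_remainder_round,
)


REF = {"1": "GGACGTGATT"}  # 1-based: G G A C G T G A T T


class TestTrinucleotideContext:
    def test_pyrimidine_center_direct(self):
        # positions 3..5 = A C G
        assert trinucleotide_context(REF, "1", 4, "C", "T") == "A[C>T]G"

    def test_purine_center_reverse_complemented(self):
        # positions 6..8 = T G A; G>A on the minus strand is C>T in TCA context
        assert trinucleotide_context(REF, "1", 7, "G", "A") == "T[C>T]A"

    def test_all_12_substitutions_map_to_pyrimidine_channels(self):
        for ref_base, alt in itertools.permutations("ACGT", 2):
            seq = {"1": f"A{ref_base}G"}
            channel = trinucleotide_context(seq, "1", 2, ref_base, alt)
            assert channel in SBS96_CHANNELS

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            trinucleotide_context(REF, "1", 4, "CG", "C")

    def test_reference_mismatch_is_integrity_error(self):
        with pytest.raises(ReferenceMismatchError):
            trinucleotide_context(REF, "1", 4, "T", "A")

    def test_contig_edge_raises(self):
        with pytest.raises(ContigEdgeError):
            trinucleotide_context(REF, "1", 1, "G", "A")
        with pytest.raises(ContigEdgeError):
            trinucleotide_context(REF, "1", 10, "T", "C")


class TestBuildSbsMatrix:
    def _sample(self, variants, pid="P1", tissue="tumor"):
        return TissueSample(pid, tissue, variants)

    def test_empty_sample_all_zero(self):
        mat, skipped = build_sbs_matrix([self._sample([])], REF)
        assert mat.shape == (96, 1) and mat.to_numpy().sum() == 0

    def test_repeated_context_counts(self):
        v = [VariantRecord("1", 4, "C", "T", dp=10, ad_alt=5)]
        samples = [self._sample(v, pid=f"P{i}") for i in range(1, 4)]
        mat, _ = build_sbs_matrix(samples, REF)
        assert (mat.loc["A[C>T]G"] == 1).all()
        assert mat.sum().sum() == 3

    def test_non_snv_and_edges_tallied(self):
        v = [
            VariantRecord("1", 4, "C", "CT", dp=10, ad_alt=5),  # indel
            VariantRecord("1", 1, "G", "A", dp=10, ad_alt=5),  # contig edge
            VariantRecord("1", 4, "C", "G", dp=10, ad_alt=5),
        ]
        mat, skipped = build_sbs_matrix([self._sample(v)], REF)
        assert skipped["P1_tumor"] == {"non_snv": 1, "contig_edge": 1}
        assert mat["P1_tumor"].sum() == 1

    def test_strand_invariance(self):
        """Reporting every call on the opposite strand (reverse-complemented
        genome, mirrored coordinates) leaves the SBS spectrum unchanged."""
        comp = str.maketrans("ACGT", "TGCA")
        fwd = "TTACGTGATCCGTA"
        L = len(fwd)
        rc_ref = {"1": fwd.translate(comp)[::-1]}
        variants = [
            VariantRecord("1", 4, "C", "A", dp=10, ad_alt=5),
            VariantRecord("1", 7, "G", "C", dp=10, ad_alt=5),
            VariantRecord("1", 9, "T", "G", dp=10, ad_alt=5),
        ]
        flipped = [
            VariantRecord("1", L + 1 - v.pos, v.ref.translate(comp),
                          v.alt.translate(comp), dp=v.dp, ad_alt=v.ad_alt)
            for v in variants
        ]
        m1, _ = build_sbs_matrix([self._sample(variants)], {"1": fwd})
        m2, _ = build_sbs_matrix([self._sample(flipped)], rc_ref)
        pd.testing.assert_frame_equal(m1, m2)

    def test_cohort_spectrum_matches_generating_signature(self):
        from triovar import SimConfig, simulate_cohort

        catalog = synthetic_signature_catalog(("SOLO",), seed=31)
        cfg = SimConfig(n_patients=4, n_genes=150, n_germline_per_patient=300,
                        n_tumor_private=0, n_normal_private=0,
                        n_shared_somatic=0, signature_mix={"SOLO": 1.0}, seed=33)
        cohort = simulate_cohort(cfg, catalog)
        ref = {"1": cohort.reference}
        samples = [p.blood for p in cohort.patients]
        mat, _ = build_sbs_matrix(samples, ref)
        observed = mat.sum(axis=1).to_numpy(dtype=float)
        n = observed.sum()
        expected = catalog.matrix["SOLO"].to_numpy() * n
        keep = expected > 5
        chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        assert stats.chi2.sf(chi2, int(keep.sum()) - 1) > 1e-4


class TestRefit:
    def _matrix(self, counts_by_sample):
        return pd.DataFrame(counts_by_sample, index=list(SBS96_CHANNELS))

    def test_single_source_recovery(self):
        catalog = synthetic_signature_catalog(("A", "B", "C"), seed=1)
        v = np.round(catalog.matrix["B"].to_numpy() * 1000)
        exp = refit_signatures(self._matrix({"s1": v}), catalog)
        assert exp.fractions.loc["s1", "B"] > 0.999
        assert exp.cosine["s1"] > 0.999

    def test_noiseless_mixture_on_disjoint_support(self):
        catalog = synthetic_signature_catalog(("A", "B"), seed=2, disjoint=True)
        v = 0.6 * catalog.matrix["A"] + 0.4 * catalog.matrix["B"]
        exp = refit_signatures(self._matrix({"s1": v * 10_000}), catalog)
        assert exp.fractions.loc["s1", "A"] == pytest.approx(0.6, abs=1e-6)
        assert exp.fractions.loc["s1", "B"] == pytest.approx(0.4, abs=1e-6)

    def test_multinomial_noise_recovery_within_3pct(self, rng):
        catalog = synthetic_signature_catalog(("A", "B", "C"), seed=3)
        truth = np.array([0.5, 0.3, 0.2])
        p = catalog.values @ truth
        counts = rng.multinomial(10_000, p)
        exp = refit_signatures(self._matrix({"s1": counts}), catalog)
        assert np.allclose(exp.fractions.loc["s1"].to_numpy(), truth, atol=0.03)

    def test_refit_self_consistency(self, rng):
        catalog = synthetic_signature_catalog(("A", "B", "C"), seed=4)
        counts = rng.multinomial(5_000, catalog.values @ [0.2, 0.5, 0.3])
        exp1 = refit_signatures(self._matrix({"s": counts}), catalog)
        recon = catalog.values @ (exp1.fractions.loc["s"].to_numpy() * counts.sum())
        exp2 = refit_signatures(self._matrix({"s": recon}), catalog)
        assert np.allclose(exp1.fractions.loc["s"], exp2.fractions.loc["s"],
                           atol=1e-9)

    def test_zero_sample_flagged(self):
        catalog = synthetic_signature_catalog(("A", "B"), seed=5)
        exp = refit_signatures(self._matrix({"s": np.zeros(96)}), catalog)
        assert (exp.fractions.loc["s"] == 0).all()
        assert np.isnan(exp.cosine["s"])

    def test_fraction_rows_sum_to_one_and_counts_sum_to_total(self, rng):
        catalog = synthetic_signature_catalog(("A", "B", "C"), seed=6)
        mix = catalog.values @ np.array([1 / 3, 1 / 3, 1 / 3])
        cols = {f"s{i}": rng.multinomial(777, mix) for i in range(4)}
        exp = refit_signatures(self._matrix(cols), catalog)
        assert np.allclose(exp.fractions.sum(axis=1), 1.0, atol=1e-6)
        assert (exp.counts.sum(axis=1) == 777).all()


class TestLargestRemainder:
    @pytest.mark.parametrize("total", [0, 1, 7, 100, 999])
    def test_sums_exact(self, total, rng):
        v = rng.random(5)
        out = largest_remainder_round(v, total)
        assert out.sum() == total and (out >= 0).all()

    def test_proportionality(self):
        assert list(largest_remainder_round([1, 1], 10)) == [5, 5]
        assert list(largest_remainder_round([3, 1], 100)) == [75, 25]


class TestDenovo:
    def test_rank_one_exact(self):
        catalog = synthetic_signature_catalog(("A",), seed=7)
        sig = catalog.matrix["A"].to_numpy()
        exposures = np.array([100.0, 400.0, 250.0])
        x = pd.DataFrame(np.outer(sig, exposures), index=list(SBS96_CHANNELS),
                         columns=["s1", "s2", "s3"])
        w, h = extract_denovo(x, k=1, n_restarts=4, seed=8)
        recon = w.to_numpy() @ h.to_numpy()
        assert np.linalg.norm(recon - x.to_numpy()) < 1e-6
        assert np.allclose(w.sum(axis=0), 1.0)

    def test_two_signature_recovery_by_cosine(self, rng):
        catalog = synthetic_signature_catalog(("A", "B"), seed=9, disjoint=True)
        mix = rng.dirichlet([1, 1], size=12).T * 3000
        x = pd.DataFrame(catalog.values @ mix, index=list(SBS96_CHANNELS),
                         columns=[f"s{i}" for i in range(12)])
        w, _ = extract_denovo(x, k=2, n_restarts=6, seed=10)
        cos = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                a, b = catalog.values[:, i], w.to_numpy()[:, j]
                cos[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        best = max(cos[0, 0] + cos[1, 1], cos[0, 1] + cos[1, 0]) / 2
        assert best >= 0.95

    def test_seed_determinism(self, rng):
        x = pd.DataFrame(rng.poisson(5, size=(96, 6)).astype(float),
                         index=list(SBS96_CHANNELS),
                         columns=[f"s{i}" for i in range(6)])
        out1 = extract_denovo(x, k=2, n_restarts=3, seed=11)
        out2 = extract_denovo(x, k=2, n_restarts=3, seed=11)
        pd.testing.assert_frame_equal(out1[0], out2[0])

    def test_k_out_of_range(self):
        x = pd.DataFrame(np.ones((96, 3)), index=list(SBS96_CHANNELS))
        with pytest.raises(ValueError):
            extract_denovo(x, k=5)


class TestPercentContribution:
    def _exposures(self, fractions, totals):
        from triovar.signatures import ExposureTable

        fr = pd.DataFrame(fractions).T
        counts = pd.DataFrame(
            {s: largest_remainder_round(fr.loc[s], totals[s]) for s in fr.index},
            index=fr.columns,
        ).T
        return ExposureTable(fractions=fr, counts=counts,
                             cosine=pd.Series(1.0, index=fr.index),
                             totals=pd.Series(totals))

    def test_single_signature_full_attribution(self):
        exp = self._exposures({"s1": {"SIG": 1.0}}, {"s1": 100})
        res = signature_percent_contribution(exp, {"g": ["s1"]})
        assert res.iloc[0]["n_attributed"] == 100
        assert res.iloc[0]["percent"] == pytest.approx(100.0)

    def test_even_split(self):
        exp = self._exposures(
            {"s1": {"A": 0.5, "B": 0.5}, "s2": {"A": 0.5, "B": 0.5}},
            {"s1": 100, "s2": 100},
        )
        res = signature_percent_contribution(exp, {"g": ["s1", "s2"]})
        assert set(res["percent"].round(6)) == {50.0}
        assert res["n_attributed"].sum() == 200

    def test_three_signature_cohort_percents_recovered(self):
        """A cohort generated at a 19/59/22 signature mixture is recovered
        within 2 percentage points by NNLS refit + attribution."""
        from triovar import SimConfig, simulate_cohort

        mix = {"SBS1": 0.19, "SBS5": 0.59, "SBS54": 0.22}
        cfg = SimConfig(n_patients=24, n_genes=250, n_germline_per_patient=400,
                        n_tumor_private=0, n_normal_private=0,
                        n_shared_somatic=0, signature_mix=mix, seed=41)
        cohort = simulate_cohort(cfg)
        ref = {"1": cohort.reference}
        # ~10k distinct germline SNVs across the cohort (blood samples)
        mat, _ = build_sbs_matrix([p.blood for p in cohort.patients], ref)
        exp = refit_signatures(mat, cohort.catalog)
        res = signature_percent_contribution(
            exp, {"blood": list(mat.columns)})
        got = dict(zip(res["signature"], res["percent"]))
        for sig, frac in mix.items():
            assert got[sig] == pytest.approx(100 * frac, abs=2.0)


class TestWilcoxon:
    def test_identical_vectors_not_testable(self):
        x = np.arange(10, dtype=float)
        res = wilcoxon_signed_rank(x, x)
        assert not res.testable and res.p is None

    def test_all_positive_n6_exact_p(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_signed_rank(x, np.zeros(6))
        # oracle: all 2^6 sign patterns; both one-sided extremes
        assert res.p == pytest.approx(2 / 64)

    def test_exact_matches_sign_enumeration(self, rng):
        """Exact p equals full enumeration of 2^n sign assignments."""
        d = np.array([0.3, -1.2, 2.1, 0.7, -0.4, 1.5, 0.9, -2.2])
        n = len(d)
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        w_all = np.array(
            [ranks[list(signs)].sum() if signs else 0.0
             for k in range(n + 1)
             for signs in itertools.combinations(range(n), k)]
        )
        mean = n * (n + 1) / 4
        p_oracle = np.mean(np.abs(w_all - mean) >= np.abs(w_obs - mean) - 1e-12)
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_null_calibration(self, rng):
        reps, n, alpha = 2000, 20, 0.05
        rejections = 0
        for _ in range(reps):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            rejections += res.p < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        # exact test is conservative at finite n; reject only gross miscalibration
        assert rejections / reps < alpha + 3 * se
        assert rejections / reps > 0.01
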