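"""Pathway attribution and preranked GSEA against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triovar import (
    PathwayCatalog,
    enrichment_score,
    germline_somatic_contribution,
    gsea_preranked,
    pathway_alteration_matrix,
    rank_genes_log_or,
)


def es_bruteforce(scores, in_set, weight_p=1.0):
    """Literal running-sum ES: walk the list, track the extreme deviation."""
    scores = list(scores)
    n = len(scores)
    hits = [abs(s) ** weight_p for s, m in zip(scores, in_set) if m]
    total = sum(hits)
    n_hit = sum(in_set)
    if n_hit == n:
        return 1.0
    running, best = 0.0, 0.0
    for s, m in zip(scores, in_set):
        if m:
            running += (abs(s) ** weight_p / total) if total > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def origin_table(rows):
    df = pd.DataFrame(rows, columns=["gene", "origin_class"])
    df["item"] = [f"v{i}" for i in range(len(df))]
    for t in ("blood", "normal", "tumor"):
        df[f"in_{t}"] = True
        df[f"vaf_{t}"] = 0.5
    return df.set_index("item")


class TestAlterationMatrix:
    def test_no_somatic_variants_gives_zero_row(self):
        catalog = PathwayCatalog({"PW1": {"G1", "G2"}})
        classified = {"p1": origin_table([("G1", "germline_all")])}
        mat = pathway_alteration_matrix(classified, catalog, ["tumor_private"])
        assert mat.loc["p1", "PW1"] == 0

    def test_single_gene_hit_sets_cell(self):
        catalog = PathwayCatalog({"PW1": {"G1"}})
        classified = {"p1": origin_table([("G1", "tumor_private")])}
        mat = pathway_alteration_matrix(classified, catalog, ["tumor_private"])
        assert mat.loc["p1", "PW1"] == 1

    def test_column_sum_matches_seeded_patients(self, small_cohort, classified):
        catalog = PathwayCatalog({"PWX": set(small_cohort.genes["gene"].head(30))})
        somatic = ["tumor_private", "normal_private", "shared_somatic"]
        mat = pathway_alteration_matrix(classified, catalog, somatic)
        expected = 0
        for pid, table in classified.items():
            genes = set(table.loc[table.origin_class.isin(somatic), "gene"])
            expected += bool(genes & catalog["PWX"])
        assert mat["PWX"].sum() == expected


class TestContribution:
    def test_all_germline_gives_zero_somatic_percent(self):
        catalog = PathwayCatalog({"PW": {"G1", "G2"}})
        classified = {"p1": origin_table([("G1", "germline_all")])}
        res = germline_somatic_contribution(classified, catalog, "A")
        assert res.loc["PW", "somatic_pct"] == 0.0
        assert res.loc["PW", "germline_pct"] == 50.0

    def test_definition_a_percent_arithmetic(self):
        members = {f"G{i}" for i in range(10)}
        catalog = PathwayCatalog({"PW": members})
        rows = [(f"G{i}", "germline_all") for i in range(4)]
        rows.append(("G9", "tumor_private"))
        classified = {"p1": origin_table(rows)}
        res = germline_somatic_contribution(classified, catalog, "A")
        assert res.loc["PW", "germline_pct"] == pytest.approx(40.0)
        assert res.loc["PW", "somatic_pct"] == pytest.approx(10.0)

    def test_definition_b_includes_shared_classes(self):
        catalog = PathwayCatalog({"PW": {"G1", "G2", "G3", "G4"}})
        rows = [("G1", "blood_normal"), ("G2", "shared_somatic"),
                ("G3", "normal_private"), ("G4", "tumor_private")]
        classified = {"p1": origin_table(rows)}
        res = germline_somatic_contribution(classified, catalog, "B")
        assert res.loc["PW", "germline_pct"] == pytest.approx(25.0)  # G1
        assert res.loc["PW", "somatic_pct"] == pytest.approx(50.0)  # G2+G3

    def test_unobserved_pathway_flagged(self):
        catalog = PathwayCatalog({"PW": {"NOT_SEEN"}})
        classified = {"p1": origin_table([("G1", "germline_all")])}
        res = germline_somatic_contribution(classified, catalog, "A")
        assert res.loc["PW", "observed_genes"] == 0
        assert np.isnan(res.loc["PW", "germline_pct"])

    def test_disjoint_origin_percents_sum_below_100(self, classified):
        """Under definition A the origin classes are disjoint per gene, so
        the two percents can never total more than 100."""
        genes = sorted(set().union(*(set(t["gene"]) for t in classified.values())))
        catalog = PathwayCatalog({"ALL": set(genes)})
        res = germline_somatic_contribution(classified, catalog, "A")
        total = res["germline_pct"] + res["somatic_pct"]
        assert (total <= 100 + 1e-9).all()

    def test_configured_germline_somatic_ratio_recovered(self, small_cohort, classified):
        """Cohort built with ~4x more germline than somatic gene hits should
        show a germline-dominated attribution."""
        genes = sorted(set(small_cohort.genes["gene"]))
        catalog = PathwayCatalog({"ALL": set(genes)})
        res = germline_somatic_contribution(classified, catalog, "B")
        assert res.loc["ALL", "germline_pct"] > 2 * res.loc["ALL", "somatic_pct"]


class TestRanking:
    def test_equal_frequencies_score_zero(self):
        a = pd.DataFrame({"g": [1, 0, 1]}, index=list("abc"))
        b = pd.DataFrame({"g": [0, 1, 1]}, index=list("xyz"))
        assert rank_genes_log_or(a, b)["g"] == pytest.approx(0.0)

    def test_formula_no_zero_cells(self):
        a = pd.DataFrame({"g": [1] * 20 + [0] * 4}, index=[f"a{i}" for i in range(24)])
        b = pd.DataFrame({"g": [1] * 5 + [0] * 19}, index=[f"b{i}" for i in range(24)])
        assert rank_genes_log_or(a, b)["g"] == pytest.approx(
            np.log((20 * 19) / (4 * 5))
        )

    def test_one_sided_gene_gets_maximal_finite_score(self):
        a = pd.DataFrame({"g": [1, 1], "h": [1, 0]}, index=["a1", "a2"])
        b = pd.DataFrame({"g": [0, 0], "h": [1, 0]}, index=["b1", "b2"])
        ranked = rank_genes_log_or(a, b)
        assert np.isfinite(ranked["g"]) and ranked.index[0] == "g"


class TestEnrichmentScore:
    def test_whole_list_set_gives_one(self):
        scores = np.array([3.0, 2.0, 1.0])
        assert enrichment_score(scores, np.ones(3, bool)) == 1.0

    def test_hand_computed_top2_case(self):
        # list (5,4,3,2,1), set = top 2, p=1: hits 5/9, 4/9; misses 1/3
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        in_set = np.array([True, True, False, False, False])
        assert enrichment_score(scores, in_set, 1.0) == pytest.approx(1.0)
        assert es_bruteforce(scores, in_set, 1.0) == pytest.approx(1.0)

    def test_bottom_set_is_negative(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        in_set = np.array([False, False, False, False, True])
        assert enrichment_score(scores, in_set, 0.0) < 0

    def test_matches_bruteforce_on_exhaustive_small_cases(self):
        rng = np.random.default_rng(99)
        for n in range(2, 9):
            scores = np.sort(rng.normal(size=n))[::-1]
            for k in range(1, min(4, n) + 1):
                for combo in itertools.combinations(range(n), k):
                    mask = np.zeros(n, bool)
                    mask[list(combo)] = True
                    for wp in (0.0, 1.0):
                        assert enrichment_score(scores, mask, wp) == pytest.approx(
                            es_bruteforce(scores, mask, wp), abs=1e-12
                        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(size=40))[::-1]
        mask = rng.random(40) < 0.2
        if not mask.any():
            mask[3] = True
        for c in (2.0, 17.5):
            assert enrichment_score(scores * c, mask, 1.0) == pytest.approx(
                enrichment_score(scores, mask, 1.0)
            )

    def test_reversal_flips_sign_at_weight_zero(self):
        rng = np.random.default_rng(6)
        scores = np.sort(rng.normal(size=31))[::-1]
        mask = np.zeros(31, bool)
        mask[[0, 4, 9, 30]] = True
        es = enrichment_score(scores, mask, 0.0)
        es_rev = enrichment_score(scores[::-1], mask[::-1], 0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            enrichment_score(np.array([1.0, 0.5]), np.zeros(2, bool))


class TestGseaPreranked:
    def _ranked(self, n=60, seed=4):
        rng = np.random.default_rng(seed)
        return pd.Series(np.sort(rng.normal(size=n))[::-1],
                         index=[f"G{i}" for i in range(n)])

    def test_result_contract(self):
        ranked = self._ranked()
        sets = {"TOP": list(ranked.index[:8]), "BOTTOM": list(ranked.index[-8:]),
                "NONE": ["ZZZ1", "ZZZ2"]}
        res = gsea_preranked(ranked, sets, n_perm=200, seed=1)
        assert res.loc["TOP", "es"] > 0 > res.loc["BOTTOM", "es"]
        assert not res.loc["NONE", "tested"]
        tested = res[res.tested]
        assert ((tested["es"].abs() <= 1) & (tested["p"] > 0)
                & (tested["p"] <= 1)).all()
        assert (np.sign(tested["nes"]) == np.sign(tested["es"])).all()

    def test_top_set_is_significant(self):
        ranked = self._ranked()
        res = gsea_preranked(ranked, {"TOP": list(ranked.index[:10])},
                             n_perm=500, seed=2)
        assert res.loc["TOP", "p"] < 0.05

    def test_deterministic_for_fixed_seed(self):
        ranked = self._ranked()
        sets = {"A": list(ranked.index[5:15])}
        r1 = gsea_preranked(ranked, sets, n_perm=300, seed=7)
        r2 = gsea_preranked(ranked, sets, n_perm=300, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_p_values_are_calibrated(self):
        """Type-I error of the permutation p under an i.i.d. null sits in the
        95% binomial band around alpha=0.05 (200 null sets, 1000 perms)."""
        rng = np.random.default_rng(12)
        n, n_sets, alpha = 200, 200, 0.05
        genes = [f"G{i}" for i in range(n)]
        rejections = 0
        for s in range(n_sets):
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(scores, index=genes)
            members = rng.choice(genes, size=10, replace=False)
            res = gsea_preranked(ranked, {"NULL": list(members)},
                                 n_perm=1000, seed=1000 + s)
            rejections += res.loc["NULL", "p"] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_sets)
        assert abs(rejections / n_sets - alpha) < 1.96 * se + 1e-12
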