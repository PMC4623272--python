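"""Population statistics: frequencies, chi-square, correlation, age, LD, ΔΔCq."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from ere_scout import datasets, popgen
from ere_scout.popgen import (
    PCRAssay,
    allele_genotype_frequencies,
    chisq_goodness_of_fit,
    chisq_independence,
    classify_insertion_age,
    fold_change_ddcq,
    genotype_from_pcr,
    two_locus_concordance_and_r2,
)


class TestPCRGenotyping:
    @pytest.mark.parametrize(
        "bands,expected",
        [
            ([441], "+/+"),
            ([214], "-/-"),
            ([214, 441], "+/-"),
            ([441, 214], "+/-"),
            ([350], "./."),
            ([100, 200, 300], "./."),
            ([446], "+/+"),   # within +/-5 tolerance
            ([447], "./."),
        ],
    )
    def test_band_calls(self, bands, expected):
        assert genotype_from_pcr(bands) == expected

    def test_indistinguishable_assay_rejected(self):
        with pytest.raises(ValueError):
            PCRAssay(size_plus=220, size_minus=214, tolerance=5)


# every printed percentage of the breed genotyping survey
_EXPECTED = {
    "Quarter Horse": (57.5, 42.5, 45.0, 30.0, 25.0),
    "Andalusian": (7.5, 92.5, 0.0, 85.0, 15.0),
    "Lipizzaner": (0.0, 100.0, 0.0, 100.0, 0.0),
    "Norwegian Fjord": (0.0, 100.0, 0.0, 100.0, 0.0),
    "Icelandic Pony": (0.0, 100.0, 0.0, 100.0, 0.0),
    "Przewalski's Horse": (0.0, 100.0, 0.0, 100.0, 0.0),
    "Show Jumpers": (1.7, 98.3, 0.0, 96.7, 3.3),
    "Italian Trotters": (0.0, 100.0, 0.0, 100.0, 0.0),
    "Unselected Italian Thoroughbreds": (43.3, 56.7, 24.0, 37.3, 38.7),
    "Elite Italian Thoroughbreds": (57.7, 42.3, 28.2, 12.8, 59.0),
}


class TestFrequencies:
    def test_every_survey_percentage_reproduced(self):
        table = datasets.myostatin_genotype_counts()
        for row in table.itertuples():
            f = allele_genotype_frequencies(row.n_pp, row.n_pm, row.n_mm)
            got = (
                f["pct_allele_plus"],
                f["pct_allele_minus"],
                f["pct_hom_plus"],
                f["pct_hom_minus"],
                f["pct_het"],
            )
            assert got == _EXPECTED[row.group], row.group
            assert f["n_individuals"] == row.n

    def test_allele_counts_conserve(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = (int(x) for x in rng.integers(0, 50, 3))
            if a + b + c == 0:
                continue
            f = allele_genotype_frequencies(a, b, c)
            assert f["n_allele_plus"] + f["n_allele_minus"] == 2 * f["n_individuals"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            allele_genotype_frequencies(0, 0, 0)


class TestChiSquare:
    def test_elite_vs_unselected_example(self):
        res = chisq_goodness_of_fit([135, 99], [65 / 150, 85 / 150])
        assert abs(res.statistic - 19.648) < 0.01
        assert res.df == 1

    def test_proportional_observed_gives_zero(self):
        res = chisq_goodness_of_fit([65, 85], [65 / 150, 85 / 150])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_bad_expected_rejected(self):
        with pytest.raises(ValueError):
            chisq_goodness_of_fit([10, 10], [0.6, 0.5])
        with pytest.raises(ValueError):
            chisq_goodness_of_fit([10, 10], [1.0, 0.0])

    def test_2x2_closed_form(self):
        # chi2 = N (ad-bc)^2 / (r1 r2 c1 c2)
        res = chisq_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value < 1e-4

    def test_independent_table_zero(self):
        res = chisq_independence([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence([[0, 0], [5, 5]])

    def test_gof_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            obs = rng.integers(5, 200, k).astype(float)
            frac = rng.dirichlet(np.ones(k) * 5)
            res = chisq_goodness_of_fit(obs, frac)
            ref_stat, ref_p = st.chisquare(obs, f_exp=frac * obs.sum())
            assert abs(res.statistic - ref_stat) <= 1e-10 * max(1, abs(ref_stat))
            assert abs(res.p_value - ref_p) <= 1e-10 * max(1e-300, ref_p)

    def test_independence_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            r, c = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            table = rng.integers(1, 100, (r, c)).astype(float)
            res = chisq_independence(table)
            ref = st.chi2_contingency(table, correction=False)
            assert abs(res.statistic - ref.statistic) <= 1e-10 * max(1, ref.statistic)
            assert abs(res.p_value - ref.pvalue) <= 1e-10 * max(1e-300, ref.pvalue)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(8.0)
        res = popgen.pearson_correlation(x, 3 * x - 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = x + rng.normal(scale=0.7, size=n)
            res = popgen.pearson_correlation(x, y)
            ref = st.pearsonr(x, y)
            assert abs(res.r - ref.statistic) <= 1e-10
            assert abs(res.p_value - ref.pvalue) <= 1e-10 * max(1e-300, ref.pvalue)

    def test_identity_logfreq_requires_three_classes(self):
        df = pd.DataFrame(
            {
                "identity_class": ["98-100", "96-98", "94-96"],
                "n_loci": [100, 100, 100],
                "n_polymorphic": [5, 2, 0],
                "fraction": [0.05, 0.02, 0.0],
                "midpoint": [99.0, 97.0, 95.0],
            }
        )
        with pytest.raises(ValueError):
            popgen.pearson_identity_logfreq(popgen.IdentityClassSummary(df))


def _geno(sp_states):
    base = {
        "caballus": ["+/+"] * 5,
        "przewalskii": ["+/+"] * 5,
        "asinus": ["+/+"] * 2,
        "kiang": ["+/+"],
        "grevyi": ["+/+"],
    }
    base.update(sp_states)
    return base


class TestAgeClassification:
    def test_present_in_all_species(self):
        assert classify_insertion_age(_geno({})).age_class == "all_equus"

    def test_horse_lineage_only(self):
        g = _geno({"asinus": ["-/-"] * 2, "kiang": ["-/-"], "grevyi": ["-/-"]})
        assert classify_insertion_age(g).age_class == "horse_lineage"

    def test_caballus_only_polymorphic(self):
        g = _geno(
            {
                "caballus": ["+/-", "-/-", "-/-", "+/+", "-/-"],
                "przewalskii": ["-/-"] * 5,
                "asinus": ["-/-"] * 2,
                "kiang": ["-/-"],
                "grevyi": ["-/-"],
            }
        )
        res = classify_insertion_age(g)
        assert res.age_class == "caballus_only"
        assert res.polymorphic_in["caballus"]

    def test_tree_violating_pattern_unresolved(self):
        g = _geno({"caballus": ["-/-"] * 5, "przewalskii": ["-/-"] * 5})
        assert classify_insertion_age(g).age_class == "unresolved"

    def test_permutation_invariance(self):
        g = _geno({"caballus": ["+/-", "-/-", "+/+", "-/-", "+/-"]})
        a = classify_insertion_age(g).age_class
        g2 = dict(g, caballus=list(reversed(g["caballus"])))
        assert classify_insertion_age(g2).age_class == a

    def test_missing_required_species_rejected(self):
        with pytest.raises(ValueError):
            classify_insertion_age({"caballus": ["+/+"]})


class TestConservation:
    def test_all_conserved(self):
        df = popgen.conservation_by_identity_class(
            ["98-100", "84-86", "98-100"], ["all_equus"] * 3
        )
        assert (df["fraction_conserved"] == 1.0).all()
        assert df["n_loci"].sum() == 3

    def test_counts_conserve(self):
        idc = ["98-100"] * 5 + ["90-92"] * 3
        age = ["caballus_only"] * 4 + ["all_equus"] * 4
        df = popgen.conservation_by_identity_class(idc, age)
        assert df["n_loci"].sum() == 8


class TestLinkageDisequilibrium:
    def test_perfect_concordance_r2_one(self):
        ga = ["+/+"] * 5 + ["+/-"] * 5 + ["-/-"] * 5
        gb = ["C/C"] * 5 + ["C/T"] * 5 + ["T/T"] * 5
        res = two_locus_concordance_and_r2(ga, gb)
        assert res.n_concordant == res.n_total == 15
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_double_heterozygote_is_concordant(self):
        res = two_locus_concordance_and_r2(["+/-"], ["C/T"])
        assert res.n_concordant == 1

    def test_em_equals_closed_form_without_double_hets(self):
        # phase-unambiguous sample: no (+/-, C/T) individuals
        ga = ["+/+"] * 4 + ["+/-"] * 3 + ["-/-"] * 8
        gb = ["C/C"] * 4 + ["T/T"] * 3 + ["T/T"] * 8
        res = two_locus_concordance_and_r2(ga, gb)
        # direct haplotype counting
        haps = {"AB": 8 + 3 * 0, "Ab": 3, "aB": 0, "ab": 16 + 3}
        n = sum(haps.values())
        pA = (haps["AB"] + haps["Ab"]) / n
        pB = (haps["AB"] + haps["aB"]) / n
        d = haps["AB"] / n - pA * pB
        r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
        assert res.r2 == pytest.approx(r2, abs=1e-9)

    def test_em_recovers_truth_at_n200(self):
        rng = np.random.default_rng(42)
        hf = {"AB": 0.42, "Ab": 0.08, "aB": 0.07, "ab": 0.43}
        haps = list(hf)
        pr = np.array(list(hf.values()))
        h1, h2 = rng.choice(4, 200, p=pr), rng.choice(4, 200, p=pr)
        ga = ["-/-", "+/-", "+/+"]
        gb = ["T/T", "C/T", "C/C"]
        da = [(haps[a][0] == "A") + (haps[b][0] == "A") for a, b in zip(h1, h2)]
        db = [(haps[a][1] == "B") + (haps[b][1] == "B") for a, b in zip(h1, h2)]
        res = two_locus_concordance_and_r2([ga[d] for d in da], [gb[d] for d in db])
        pA, pB = 0.50, 0.49
        d = hf["AB"] - pA * pB
        truth = d * d / (pA * (1 - pA) * pB * (1 - pB))
        assert abs(res.r2 - truth) <= 0.05

    def test_monomorphic_locus_r2_undefined(self):
        res = two_locus_concordance_and_r2(["+/+"] * 5, ["C/C", "C/T", "T/T", "C/C", "C/T"])
        assert res.r2 is None


class TestDdcq:
    def _cq(self, ddcq_shift):
        rows = []
        for cond, shift in [("ref", 0.0), ("ins", ddcq_shift)]:
            for rep in range(3):
                rows.append({"condition": cond, "gene": "egfp", "cq": 20.0 + shift + 0.01 * rep})
                rows.append({"condition": cond, "gene": "gapdh", "cq": 18.0 + 0.01 * rep})
        return pd.DataFrame(rows)

    def test_reference_condition_fold_one(self):
        res = fold_change_ddcq(
            self._cq(2.0), target_gene="egfp", control_gene="gapdh",
            reference_condition="ref",
        )
        assert res.fold_change["ref"] == pytest.approx(1.0)

    def test_fold_reduction(self):
        res = fold_change_ddcq(
            self._cq(2.68), target_gene="egfp", control_gene="gapdh",
            reference_condition="ref",
        )
        assert res.fold_change["ins"] == pytest.approx(2 ** -2.68, rel=1e-9)
        assert 1 / res.fold_change["ins"] == pytest.approx(6.4, abs=0.05)

    def test_doubling(self):
        res = fold_change_ddcq(
            self._cq(-1.0), target_gene="egfp", control_gene="gapdh",
            reference_condition="ref",
        )
        assert res.fold_change["ins"] == pytest.approx(2.0)

    def test_missing_control_rejected(self):
        df = self._cq(1.0)
        df = df[df.gene != "gapdh"]
        with pytest.raises(ValueError):
            fold_change_ddcq(df, target_gene="egfp", control_gene="gapdh",
                             reference_condition="ref")
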